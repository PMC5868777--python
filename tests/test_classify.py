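"""Automated recruitment, conflict arrest, posterior inclusion."""

import numpy as np
import pytest

from profclust import (
    BenchmarkSpec,
    ConflictReport,
    Group,
    InternalBackend,
    classify_auto,
    cluster_training_set,
    parse_newick,
    posterior_inclusion,
    score_drop_policy,
    simulate_superfamily,
    split_root_policy,
)
from profclust.classify import (
    recruit_round,
    resolve_conflicts,
    update_group,
)
from profclust.profiles import NOT_DETECTED, Profile, ScoreTable
from profclust.sequences import SequenceRecord


def stub_group(gid, members, threshold, scores, training=None, frozen=False):
    return Group(
        group_id=gid,
        origin_cluster_id=gid.replace("G", "C"),
        training_ids=frozenset(training if training is not None else members),
        member_ids=frozenset(members),
        profile=Profile(profile_id=gid, backend="stub"),
        threshold=threshold,
        score_table=ScoreTable(profile_id=gid, scores=scores),
        frozen=frozen,
    )


@pytest.fixture(scope="module")
def classified(small_benchmark, engine):
    tree = parse_newick(small_benchmark.newick)
    part = cluster_training_set(
        tree, list(small_benchmark.training), engine,
        accept_policy=split_root_policy,
    )
    result = classify_auto(
        part, list(small_benchmark.training), list(small_benchmark.targets), engine
    )
    return part, result


class TestRecruitRound:
    def test_single_assignment(self):
        pool = {"t1": SequenceRecord("t1", "AAAA")}
        g1 = stub_group("G1", {"a"}, 10.0, {"t1": 12.0, "a": 15.0})
        g2 = stub_group("G2", {"b"}, 10.0, {"t1": 5.0, "b": 15.0})
        assert recruit_round([g1, g2], pool, engine=None) == {"t1": ["G1"]}

    def test_multi_assignment_flagged(self):
        pool = {"t1": SequenceRecord("t1", "AAAA")}
        g1 = stub_group("G1", {"a"}, 10.0, {"t1": 12.0, "a": 15.0})
        g2 = stub_group("G2", {"b"}, 10.0, {"t1": 10.0, "b": 15.0})  # == thr
        assert recruit_round([g1, g2], pool, engine=None) == {"t1": ["G1", "G2"]}

    def test_empty_pool(self):
        g1 = stub_group("G1", {"a"}, 10.0, {"a": 15.0})
        assert recruit_round([g1], {}, engine=None) == {}


class TestResolveConflicts:
    def test_target_conflict_discards_and_freezes(self):
        groups = [
            stub_group("G1", {"a"}, 10.0, {}),
            stub_group("G2", {"b"}, 10.0, {}),
        ]
        pool = {"t": SequenceRecord("t", "AAAA")}
        discarded = []
        reports, surviving = resolve_conflicts(
            {"t": ["G1", "G2"]}, groups, pool, discarded, iteration=1
        )
        assert [r.sequence_id for r in reports] == ["t"]
        assert reports[0].sequence_class == "target"
        assert pool == {} and discarded == ["t"]
        assert all(g.frozen for g in groups)
        assert surviving == {}

    def test_training_conflict_keeps_origin(self):
        groups = [
            stub_group("G1", {"a"}, 10.0, {}),
            stub_group("G2", {"b"}, 10.0, {}),
        ]
        reports, _ = resolve_conflicts(
            {}, groups, {}, [], iteration=2,
            training_detections={"a": ["G1", "G2"]},
        )
        assert reports[0].sequence_class == "training"
        assert set(reports[0].group_ids) == {"G1", "G2"}
        assert "a" in groups[0].member_ids  # stays with its origin
        assert "a" not in groups[1].member_ids
        assert all(g.frozen for g in groups)

    def test_no_conflicts_no_mutation(self):
        groups = [stub_group("G1", {"a"}, 10.0, {})]
        pool = {"t": SequenceRecord("t", "AAAA")}
        reports, surviving = resolve_conflicts(
            {"t": ["G1"]}, groups, pool, [], iteration=1
        )
        assert reports == [] and surviving == {"t": ["G1"]}
        assert not groups[0].frozen and "t" in pool

    def test_conflict_report_needs_two_groups(self):
        with pytest.raises(ValueError):
            ConflictReport("x", ("G1",), 1, "target")


class TestUpdateGroup:
    def test_no_new_members_is_history_only(self, classified, engine):
        _, result = classified
        g = result.groups[0]
        seqs = {r.id: r for r in g.msa.degapped()}
        g2 = update_group(g, [], seqs, engine, round_index=9)
        assert g2.member_ids == g.member_ids
        assert g2.threshold == g.threshold
        assert g2.history[-1].added == ()

    def test_readding_existing_member_is_noop(self, classified, engine):
        _, result = classified
        g = result.groups[0]
        seqs = {r.id: r for r in g.msa.degapped()}
        existing = sorted(g.member_ids)[0]
        g2 = update_group(g, [existing], seqs, engine, round_index=9)
        assert g2.member_ids == g.member_ids
        assert g2.threshold == g.threshold

    def test_frozen_group_refuses_update(self, classified, engine):
        from dataclasses import replace

        _, result = classified
        g = replace(result.groups[0], frozen=True)
        with pytest.raises(ValueError, match="frozen"):
            update_group(g, ["x"], {}, engine)

    def test_thresholds_non_increasing_over_rounds(self, classified):
        """Recruits are at/above the old threshold, so rebuilt thresholds
        drift down or stay put across automated rounds."""
        _, result = classified
        for g in result.groups:
            thresholds = [h.threshold for h in g.history if h.added]
            assert all(b <= a + 1e-6 for a, b in zip(thresholds, thresholds[1:]))


class TestClassifyAuto:
    def test_planted_targets_recovered(self, small_benchmark, classified):
        _, result = classified
        labels = small_benchmark.labels
        for g in result.groups:
            fam = labels[sorted(g.training_ids)[0]]
            for sid in g.target_member_ids:
                assert labels[sid] == fam

    def test_no_dual_membership(self, classified):
        _, result = classified
        seen = set()
        for g in result.groups:
            assert not (g.member_ids & seen)
            seen |= g.member_ids

    def test_group_invariants_after_rounds(self, classified, engine):
        _, result = classified
        for g in result.groups:
            scores = g.score_table.scores
            assert all(scores[m] >= g.threshold for m in g.member_ids)
            nonmember = {i: s for i, s in scores.items() if i not in g.member_ids}
            assert min(scores[m] for m in g.member_ids) > max(nonmember.values())

    def test_random_noise_targets_never_recruited(self, small_benchmark, engine):
        rng = np.random.default_rng(8)
        from profclust.sequences import AMINO_ACIDS

        noise = [
            SequenceRecord(
                f"noise{k}",
                "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, 120)),
            )
            for k in range(10)
        ]
        tree = parse_newick(small_benchmark.newick)
        part = cluster_training_set(
            tree, list(small_benchmark.training), engine,
            accept_policy=split_root_policy,
        )
        result = classify_auto(part, list(small_benchmark.training), noise, engine)
        assert result.rounds == 1 and result.converged
        assert sorted(result.pool_ids) == sorted(n.id for n in noise)

    def test_fixed_point_idempotence(self, small_benchmark, classified, engine):
        """Rerunning the automated phase on its own converged output
        recruits nothing."""
        part, result = classified
        from profclust.classify import _auto_rounds

        targ = {r.id: r for r in small_benchmark.targets}
        train = {r.id: r for r in small_benchmark.training}
        universe = {**train, **targ}
        groups = list(result.groups)
        pool = {i: targ[i] for i in result.pool_ids}
        before = [g.membership_hash() for g in groups]
        conflicts, discarded = [], []
        _, converged = _auto_rounds(
            groups, pool, universe, engine, None, conflicts, discarded, 100
        )
        assert converged
        assert [g.membership_hash() for g in groups] == before
        assert conflicts == [] and discarded == []

    def test_targets_overlapping_training_rejected(self, small_benchmark, engine):
        part, _ = cluster_training_set(
            parse_newick(small_benchmark.newick),
            list(small_benchmark.training), engine,
            accept_policy=split_root_policy,
        ), None
        with pytest.raises(ValueError, match="overlap"):
            classify_auto(
                part[0] if isinstance(part, tuple) else part,
                list(small_benchmark.training),
                list(small_benchmark.training)[:1],
                engine,
            )


class TestScoreDropPolicy:
    def test_sharp_paper_scale_drop_stops(self):
        series = [520.0, 515.0, 512.0, 509.3, 269.3]
        assert score_drop_policy(series, 3) is False

    def test_uniform_gaps_never_stop(self):
        series = list(np.linspace(100, 60, 21))
        for b in range(1, 19):
            assert score_drop_policy(series, b) is True

    def test_single_outlier_gap_found_by_scan(self):
        rng = np.random.default_rng(11)
        scores = np.sort(rng.uniform(300, 330, 30))[::-1].tolist() + [80.0]
        # brute-force scan: the only boundary where the policy stops is the
        # outlier gap at the end
        stops = [
            b for b in range(1, len(scores) - 1)
            if not score_drop_policy(scores, b)
        ]
        assert stops == [len(scores) - 2]

    def test_tiny_series_accepts(self):
        assert score_drop_policy([10.0, 1.0], 0) is True

    def test_noise_gap_in_homogeneous_group_continues(self):
        """A few-bit gap above a dense continuum is not a boundary even if
        member-to-member gaps are hundredths of bits."""
        members = list(np.linspace(362, 361, 12))
        assert score_drop_policy(members + [358.0], len(members) - 1) is True


class TestPosteriorInclusion:
    def test_below_threshold_family_members_recovered(
        self, small_benchmark, classified, engine
    ):
        part, auto = classified
        result = posterior_inclusion(
            auto, list(small_benchmark.training), list(small_benchmark.targets),
            engine,
        )
        labels = small_benchmark.labels
        for g in result.groups:
            fam = labels[sorted(g.training_ids)[0]]
            assert all(labels[s] == fam for s in g.target_member_ids)
        n_auto = sum(len(g.target_member_ids) for g in auto.groups)
        n_post = sum(len(g.target_member_ids) for g in result.groups)
        assert n_post >= n_auto
        assert any(d == "accepted" for _, _, d in result.posterior_log)

    def test_rejection_restores_group_exactly(self, small_benchmark, classified, engine):
        """Force-rejecting policy: groups come back structurally identical
        and the pool is untouched."""
        _, auto = classified
        result = posterior_inclusion(
            auto, list(small_benchmark.training), list(small_benchmark.targets),
            engine, policy=lambda scores, b: False,  # user stops immediately
        )
        assert [g.membership_hash() for g in result.groups] == [
            g.membership_hash() for g in auto.groups
        ]
        assert result.pool_ids == auto.pool_ids

    def test_empty_candidates_noop(self, small_benchmark, classified, engine):
        _, auto = classified
        done = posterior_inclusion(
            auto, list(small_benchmark.training), list(small_benchmark.targets),
            engine,
        )
        again = posterior_inclusion(
            done, list(small_benchmark.training), list(small_benchmark.targets),
            engine,
        )
        assert [g.membership_hash() for g in again.groups] == [
            g.membership_hash() for g in done.groups
        ]

    def test_frozen_groups_untouched(self, small_benchmark, classified, engine):
        import copy
        from dataclasses import replace

        _, auto = classified
        frozen_auto = copy.copy(auto)
        frozen_auto.groups = list(auto.groups)
        frozen_auto.groups[0] = replace(auto.groups[0], frozen=True)
        h = frozen_auto.groups[0].membership_hash()
        result = posterior_inclusion(
            frozen_auto, list(small_benchmark.training),
            list(small_benchmark.targets), engine,
        )
        assert result.groups[0].membership_hash() == h
        assert result.groups[0].frozen
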