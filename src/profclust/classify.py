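"""Target classification: automated recruitment and posterior inclusion.

Each training cluster seeds a *group*. Rounds of automated classification
score the unclassified pool against every live group's profile, recruit
sequences at or above the group threshold, rebuild each grown group's
alignment/profile, rescore the combined universe and reset the threshold to
the lowest member score — until a round recruits nothing. A sequence claimed
by more than one group is a conflict: conflicting targets are discarded from
all groups and the pool, conflicting training sequences stay only with their
origin group, and every involved group is frozen out of further iterations
(its members are kept in the final output).

After convergence, posterior inclusion revisits detected-but-below-threshold
candidates in descending score order: each is provisionally added, the
profile rebuilt, and kept only if strict self-detection still holds with the
candidate inside the profile; a rejection restores the group exactly. An
acceptance re-opens automated recruitment (the automated cycle is nested
inside the supervised one). A score-drop policy stands in for the
supervising user: it stops a group's posterior phase when the score gap to
the next candidate dwarfs the typical gap between accepted members.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .profiles import NOT_DETECTED, Profile, ScoreTable, build_msa
from .sequences import SequenceRecord, as_dict
from .training import Partition, self_detection_test


@dataclass(frozen=True)
class HistoryEntry:
    round_index: int
    added: Tuple[str, ...]
    threshold: float
    self_detection_ok: bool


@dataclass(frozen=True)
class Group:
    """A cluster grown with accepted target sequences."""

    group_id: str
    origin_cluster_id: str
    training_ids: frozenset
    member_ids: frozenset
    profile: Profile
    threshold: float
    score_table: ScoreTable
    msa: object = None  # MSA of the current members
    history: Tuple[HistoryEntry, ...] = ()
    frozen: bool = False

    @property
    def target_member_ids(self) -> frozenset:
        return self.member_ids - self.training_ids

    def membership_hash(self) -> int:
        return hash(tuple(sorted(self.member_ids)))


@dataclass(frozen=True)
class ConflictReport:
    sequence_id: str
    group_ids: Tuple[str, ...]
    iteration: int
    sequence_class: str  # "training" | "target"

    def __post_init__(self) -> None:
        if len(self.group_ids) < 2:
            raise ValueError("a conflict involves at least two groups")


@dataclass
class ClassificationResult:
    groups: List[Group]
    conflicts: List[ConflictReport]
    pool_ids: List[str]        # never recruited
    discarded_ids: List[str]   # removed by conflicts
    rounds: int
    converged: bool
    posterior_log: List[Tuple[str, str, str]] = field(default_factory=list)

    def assignment(self) -> Dict[str, str]:
        """Final id -> group id for every group member (training included)."""
        out = {}
        for g in self.groups:
            for m in g.member_ids:
                out[m] = g.group_id
        return out


# --------------------------------------------------------------------------
# Round primitives
# --------------------------------------------------------------------------

def _ensure_score_table(group: Group, universe: Sequence[SequenceRecord], engine) -> Group:
    have = set(group.score_table.scores) if group.score_table else set()
    need = {s.id for s in universe}
    if need <= have:
        return group
    table = engine.score_sequences(group.profile, list(universe))
    return replace(group, score_table=table)


def recruit_round(
    groups: Sequence[Group],
    pool: Mapping[str, SequenceRecord],
    engine,
) -> Dict[str, List[str]]:
    """Score the pool against each live group and collect assignments.

    Returns ``{sequence_id: [group_ids with score >= that group's
    threshold]}`` (group order = input order); multi-entries are the
    conflicts the caller must resolve.
    """
    assignments: Dict[str, List[str]] = {}
    pool_seqs = [pool[i] for i in sorted(pool)]
    for g in groups:
        if g.frozen:
            continue
        if pool_seqs:
            g = _ensure_score_table(g, pool_seqs, engine)
        for s in pool_seqs:
            if g.score_table.scores[s.id] >= g.threshold:
                assignments.setdefault(s.id, []).append(g.group_id)
    return assignments


def resolve_conflicts(
    assignments: Dict[str, List[str]],
    groups: List[Group],
    pool: Dict[str, SequenceRecord],
    discarded: List[str],
    iteration: int,
    training_detections: Optional[Dict[str, List[str]]] = None,
) -> Tuple[List[ConflictReport], Dict[str, List[str]]]:
    """Apply the arrest rules; returns reports and surviving single
    assignments.

    Multi-assigned targets leave the pool permanently; multi-detected
    training sequences stay only with their origin group; every involved
    group is frozen.
    """
    by_id = {g.group_id: k for k, g in enumerate(groups)}
    reports: List[ConflictReport] = []
    frozen_now: set = set()
    for sid in sorted(assignments):
        gids = assignments[sid]
        if len(gids) >= 2:
            reports.append(
                ConflictReport(sid, tuple(gids), iteration, "target")
            )
            if sid in pool:
                del pool[sid]
                discarded.append(sid)
            frozen_now.update(gids)
    for sid in sorted(training_detections or {}):
        gids = training_detections[sid]
        reports.append(ConflictReport(sid, tuple(gids), iteration, "training"))
        frozen_now.update(gids)
    for gid in frozen_now:
        k = by_id[gid]
        groups[k] = replace(groups[k], frozen=True)
    surviving = {
        sid: gids
        for sid, gids in assignments.items()
        if len(gids) == 1 and gids[0] not in frozen_now and sid in pool
    }
    return reports, surviving


def update_group(
    group: Group,
    new_members: Sequence[str],
    universe: Mapping[str, SequenceRecord],
    engine,
    aligner=None,
    round_index: int = 0,
) -> Group:
    """Rebuild a group after member additions.

    Members plus ``new_members`` are realigned from scratch, the profile is
    rebuilt, the whole universe rescored and the threshold reset to the new
    minimum member score. A post-rebuild self-detection violation is
    recorded in the history, not raised — the next round's conflict
    machinery deals with intruders.
    """
    if group.frozen:
        raise ValueError(f"group {group.group_id} is frozen")
    added = tuple(sorted(set(new_members) - group.member_ids))
    if not added:
        entry = HistoryEntry(round_index, (), group.threshold, True)
        return replace(group, history=group.history + (entry,))
    members = sorted(group.member_ids | set(added))
    msa = build_msa([universe[m] for m in members], aligner)
    profile = engine.build_profile(msa, profile_id=group.group_id)
    table = engine.score_sequences(
        profile, [universe[i] for i in sorted(universe)]
    )
    member_scores = {m: table.scores[m] for m in members}
    nonmember_scores = {
        i: s for i, s in table.scores.items() if i not in set(members)
    }
    threshold = min(member_scores.values())
    ok, _ = self_detection_test(member_scores, nonmember_scores)
    entry = HistoryEntry(round_index, added, threshold, ok)
    return replace(
        group,
        member_ids=frozenset(members),
        profile=profile,
        threshold=threshold,
        score_table=table,
        msa=msa,
        history=group.history + (entry,),
    )


# --------------------------------------------------------------------------
# Automated classification (iteration 2)
# --------------------------------------------------------------------------

def _training_detections(
    groups: Sequence[Group], training_by_group: Dict[str, frozenset]
) -> Dict[str, List[str]]:
    """Foreign training sequences detected at/above a live group's
    threshold."""
    all_training = frozenset().union(*training_by_group.values()) if training_by_group else frozenset()
    det: Dict[str, List[str]] = {}
    origin = {}
    for gid, ids in training_by_group.items():
        for i in ids:
            origin[i] = gid
    for g in groups:
        if g.frozen or g.score_table is None:
            continue
        for t in sorted(all_training - g.training_ids):
            if g.score_table.scores.get(t, NOT_DETECTED) >= g.threshold:
                gids = [origin[t], g.group_id] if t in origin else [g.group_id]
                prev = det.setdefault(t, [])
                for x in gids:
                    if x not in prev:
                        prev.append(x)
    # a detection is a conflict only when >= 2 groups are involved
    return {t: gids for t, gids in det.items() if len(gids) >= 2}


def _auto_rounds(
    groups: List[Group],
    pool: Dict[str, SequenceRecord],
    universe: Dict[str, SequenceRecord],
    engine,
    aligner,
    conflicts: List[ConflictReport],
    discarded: List[str],
    max_rounds: int,
    start_round: int = 1,
) -> Tuple[int, bool]:
    """Run recruit/resolve/update rounds in place until convergence."""
    training_by_group = {g.group_id: g.training_ids for g in groups}
    rounds = 0
    converged = False
    universe_seqs = [universe[i] for i in sorted(universe)]
    for r in range(start_round, start_round + max_rounds):
        live_idx = [k for k, g in enumerate(groups) if not g.frozen]
        if not live_idx:
            converged = True
            break
        for k in live_idx:
            groups[k] = _ensure_score_table(groups[k], universe_seqs, engine)
        assignments = recruit_round([groups[k] for k in live_idx], pool, engine)
        tdet = _training_detections([groups[k] for k in live_idx], training_by_group)
        reports, surviving = resolve_conflicts(
            assignments, groups, pool, discarded, r, tdet
        )
        conflicts.extend(reports)
        rounds = r
        if not surviving:
            converged = True
            break
        recruits_by_group: Dict[str, List[str]] = {}
        for sid, gids in sorted(surviving.items()):
            recruits_by_group.setdefault(gids[0], []).append(sid)
        for k, g in enumerate(groups):
            new = recruits_by_group.get(g.group_id)
            if not new or g.frozen:
                continue
            groups[k] = update_group(g, new, universe, engine, aligner, r)
            for sid in new:
                del pool[sid]
    return rounds, converged


def classify_auto(
    partition: Partition,
    training_seqs: Sequence[SequenceRecord],
    targets: Sequence[SequenceRecord],
    engine,
    aligner=None,
    max_rounds: int = 100,
) -> ClassificationResult:
    """Automated classification of ``targets`` from a training partition.

    Terminates when a round recruits nothing new (convergence) or after
    ``max_rounds`` rounds, in which case the result is partial and flagged
    unconverged.
    """
    train = as_dict(training_seqs)
    targ = as_dict(targets)
    overlap = sorted(set(train) & set(targ))
    if overlap:
        raise ValueError(f"targets overlap training ids: {overlap[:10]}")
    universe = {**train, **targ}
    pool = dict(sorted(targ.items()))
    groups: List[Group] = []
    for c in partition.clusters:
        gid = c.cluster_id.replace("C", "G", 1)
        groups.append(
            Group(
                group_id=gid,
                origin_cluster_id=c.cluster_id,
                training_ids=frozenset(c.member_ids),
                member_ids=frozenset(c.member_ids),
                profile=c.profile,
                threshold=c.threshold,
                score_table=None,
                msa=c.msa,
                history=(HistoryEntry(0, tuple(sorted(c.member_ids)), c.threshold, True),),
            )
        )
    conflicts: List[ConflictReport] = []
    discarded: List[str] = []
    rounds, converged = _auto_rounds(
        groups, pool, universe, engine, aligner, conflicts, discarded, max_rounds
    )
    if not converged:
        import warnings

        warnings.warn(
            f"classification did not converge within {max_rounds} rounds; "
            "returning partial result"
        )
    return ClassificationResult(
        groups=groups,
        conflicts=conflicts,
        pool_ids=sorted(pool),
        discarded_ids=sorted(discarded),
        rounds=rounds,
        converged=converged,
    )


# --------------------------------------------------------------------------
# Score-drop policy and posterior inclusion (iteration 3)
# --------------------------------------------------------------------------

def score_drop_policy(
    sorted_scores: Sequence[float],
    boundary_index: int,
    factor: float = 10.0,
    rel_drop: float = 0.25,
) -> bool:
    """Decide whether to continue past a score boundary.

    ``sorted_scores`` is descending; ``boundary_index`` is the last
    position inside the group, the candidate sits just below it. The
    automated stand-in for a supervisor stopping at a sharp drop in the
    score plot: stop (return False) when the gap below the boundary is
    both locally anomalous — more than ``factor`` times the median
    successive gap above it — and large on the scale of the scores
    themselves — more than ``rel_drop`` of the boundary score. The second
    condition keeps very homogeneous groups, whose member-to-member gaps
    are fractions of a bit, from mistaking bit-level noise for a boundary.
    Fewer than 3 scores always accept.
    """
    s = np.asarray(sorted_scores, dtype=float)
    if len(s) < 3 or boundary_index < 1 or boundary_index + 1 >= len(s):
        return True
    gap_below = s[boundary_index] - s[boundary_index + 1]
    gaps_above = -np.diff(s[: boundary_index + 1])
    med = float(np.median(gaps_above))
    sharp = gap_below > factor * med and gap_below > rel_drop * abs(s[boundary_index])
    return not sharp


def posterior_inclusion(
    result: ClassificationResult,
    training_seqs: Sequence[SequenceRecord],
    targets: Sequence[SequenceRecord],
    engine,
    aligner=None,
    drop_factor: float = 10.0,
    rel_drop: float = 0.25,
    policy: Optional[Callable[[Sequence[float], int], bool]] = None,
    max_rounds: int = 100,
) -> ClassificationResult:
    """Supervised-style inclusion of below-threshold candidates.

    Per live group, candidates are the pool sequences the group detects
    below its threshold, tried in descending score order. Each is
    provisionally included; the group is kept only when strict
    self-detection holds with the rebuilt (posterior) profile, otherwise
    the previous group is restored exactly. An acceptance re-runs the
    automated recruitment rounds over all live groups. The (score-drop)
    policy terminates a group's phase at a sharp boundary.
    """
    policy = policy or (
        lambda scores, b: score_drop_policy(scores, b, drop_factor, rel_drop)
    )
    train = as_dict(training_seqs)
    targ = as_dict(targets)
    universe = {**train, **targ}
    universe_seqs = [universe[i] for i in sorted(universe)]
    groups = list(result.groups)
    pool = {i: targ[i] for i in result.pool_ids}
    conflicts = list(result.conflicts)
    discarded = list(result.discarded_ids)
    log: List[Tuple[str, str, str]] = list(result.posterior_log)
    rounds = result.rounds

    for k in range(len(groups)):
        if groups[k].frozen:
            continue
        tried: set = set()
        while True:
            g = groups[k]
            if g.frozen:
                break
            g = _ensure_score_table(g, universe_seqs, engine)
            groups[k] = g
            candidates = [
                (i, g.score_table.scores[i])
                for i in pool
                if i not in tried
                and g.score_table.scores[i] != NOT_DETECTED
                and g.score_table.scores[i] < g.threshold
            ]
            if not candidates:
                break
            candidates.sort(key=lambda kv: (-kv[1], kv[0]))
            cand_id, cand_score = candidates[0]
            tried.add(cand_id)
            member_scores = sorted(
                (g.score_table.scores[m] for m in g.member_ids), reverse=True
            )
            series = member_scores + [cand_score]
            if not policy(series, len(member_scores) - 1):
                log.append((g.group_id, cand_id, "stopped"))
                break
            before_hash = g.membership_hash()
            trial = update_group(
                g, [cand_id], universe, engine, aligner, rounds + 1
            )
            last = trial.history[-1]
            if last.self_detection_ok:
                groups[k] = trial
                del pool[cand_id]
                log.append((g.group_id, cand_id, "accepted"))
                r, _ = _auto_rounds(
                    groups, pool, universe, engine, aligner,
                    conflicts, discarded, max_rounds, start_round=rounds + 1,
                )
                rounds = max(rounds, r)
            else:
                # restoration: the provisional group is discarded untouched
                assert groups[k].membership_hash() == before_hash
                log.append((g.group_id, cand_id, "rejected"))
    return ClassificationResult(
        groups=groups,
        conflicts=conflicts,
        pool_ids=sorted(pool),
        discarded_ids=sorted(discarded),
        rounds=rounds,
        converged=True,
        posterior_log=log,
    )
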