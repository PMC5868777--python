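"""Training-phase clustering.

Walk the size-ordered candidate clade list; for each clade build an MSA and
profile from its sequences, score the whole training universe, and keep the
clade only if it shows strict self-detection: the lowest-scoring member must
outscore the highest-scoring non-member (a tie fails). The lowest member
score becomes the cluster's inclusion threshold. Accepting a clade removes
every clade sharing a leaf with it (nested or overlapping) from the queue,
so the resulting partition is a set of leaf-disjoint clusters plus orphan
sequences that ended up in no accepted cluster.

Acceptance of a passing clade is delegated to a policy callback, which is
where a supervising user plugs in: the default accepts everything, while
:func:`split_root_policy` declines any clade spanning the entire training
set (the point of the method being subfamily, not superfamily, resolution).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .phylo import Clade, TreeNode, check_leaf_labels, enumerate_candidate_clades
from .profiles import MSA, NOT_DETECTED, Profile, ScoreTable, build_msa
from .sequences import SequenceRecord, as_dict


def self_detection_test(
    member_scores: Mapping[str, float],
    nonmember_scores: Mapping[str, float],
) -> Tuple[bool, Optional[float]]:
    """Strict separation test deriving the inclusion threshold.

    Passes iff every member score is finite and the minimum member score is
    strictly greater than the maximum non-member score (an empty non-member
    set passes). On a pass the threshold is the minimum member score; ties
    between the boundary member and the best non-member fail.
    """
    if not member_scores:
        raise ValueError("member_scores must be non-empty")
    lo = min(member_scores.values())
    if lo == NOT_DETECTED:
        return False, None
    if nonmember_scores:
        hi = max(nonmember_scores.values())
        if not lo > hi:
            return False, None
    return True, lo


def score_drop_series(scores: Mapping[str, float]) -> Tuple[List[str], np.ndarray, np.ndarray]:
    """Sort detected scores descending and compute successive drops.

    Returns (ids, scores, drops) where ``drops[k] = scores[k] - scores[k+1]``;
    undetected sequences are excluded. This is the decision surface a
    supervising user inspects when accepting clusters or stopping posterior
    inclusion.
    """
    items = [(i, s) for i, s in scores.items() if s != NOT_DETECTED]
    items.sort(key=lambda kv: (-kv[1], kv[0]))
    ids = [i for i, _ in items]
    vals = np.array([s for _, s in items], dtype=float)
    drops = -np.diff(vals) if len(vals) > 1 else np.array([], dtype=float)
    return ids, vals, drops


@dataclass(frozen=True)
class Cluster:
    """An accepted training cluster with its profile and threshold."""

    cluster_id: str
    clade: Clade
    member_ids: frozenset
    msa: MSA
    profile: Profile
    threshold: float
    score_table: ScoreTable

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class Rejection:
    clade: Clade
    reason: str  # "not_separable" | "policy" | "superseded"


@dataclass
class Partition:
    """Disjoint accepted clusters plus orphans over the training universe."""

    clusters: List[Cluster]
    orphan_ids: List[str]
    rejections: List[Rejection]
    universe_ids: List[str]

    def cluster_of(self) -> Dict[str, str]:
        out = {}
        for c in self.clusters:
            for m in c.member_ids:
                out[m] = c.cluster_id
        return out


def evaluate_clade(
    clade: Clade,
    training_seqs: Mapping[str, SequenceRecord],
    engine,
    aligner=None,
    cluster_id: str = "cluster",
):
    """Build a clade profile, screen the training universe, apply the
    self-detection test. Returns a :class:`Cluster` on pass, a
    :class:`Rejection` on fail."""
    members = sorted(clade.leaf_ids)
    missing = [m for m in members if m not in training_seqs]
    if missing:
        raise ValueError(f"clade members not in training set: {missing[:10]}")
    try:
        msa = build_msa([training_seqs[m] for m in members], aligner)
        profile = engine.build_profile(msa, profile_id=cluster_id)
        universe = [training_seqs[i] for i in sorted(training_seqs)]
        table = engine.score_sequences(profile, universe)
    except Exception as exc:
        raise RuntimeError(f"engine failure while evaluating {clade!r}: {exc}") from exc
    member_scores = {i: table.scores[i] for i in members}
    nonmember_scores = {
        i: s for i, s in table.scores.items() if i not in clade.leaf_ids
    }
    ok, threshold = self_detection_test(member_scores, nonmember_scores)
    if not ok:
        return Rejection(clade=clade, reason="not_separable")
    return Cluster(
        cluster_id=cluster_id,
        clade=clade,
        member_ids=frozenset(members),
        msa=msa,
        profile=profile,
        threshold=threshold,
        score_table=table,
    )


def accept_all_policy(cluster: Cluster, drops=None) -> bool:
    """Batch default: accept every clade that passes self-detection."""
    return True


def split_root_policy(cluster: Cluster, drops=None) -> bool:
    """Decline clusters spanning the whole training set.

    The universe-wide clade always passes self-detection vacuously (there
    are no non-members); a supervisor after subfamily resolution rejects it
    so the walk descends into the subfamily clades.
    """
    return cluster.size < len(cluster.score_table.scores)


def cluster_training_set(
    tree: TreeNode,
    training_seqs: Sequence[SequenceRecord],
    engine,
    aligner=None,
    accept_policy: Callable[[Cluster, object], bool] = accept_all_policy,
    min_size: int = 2,
) -> Partition:
    """Iterate candidate clades size-descending and emit the partition.

    Clades failing self-detection are rejected automatically; passing
    clades are offered to ``accept_policy`` together with their score-drop
    series. On acceptance, every queued clade sharing at least one leaf is
    dropped (recorded as "superseded").
    """
    seqs = as_dict(training_seqs)
    check_leaf_labels(tree, list(seqs))
    queue = enumerate_candidate_clades(tree, min_size=min_size)
    clusters: List[Cluster] = []
    rejections: List[Rejection] = []
    clustered: set = set()
    k = 0
    while queue:
        clade = queue.pop(0)
        k += 1
        result = evaluate_clade(
            clade, seqs, engine, aligner, cluster_id=f"C{len(clusters) + 1}"
        )
        if isinstance(result, Rejection):
            rejections.append(result)
            continue
        _, _, drops = score_drop_series(result.score_table.scores)
        if not accept_policy(result, drops):
            rejections.append(Rejection(clade=clade, reason="policy"))
            continue
        clusters.append(result)
        clustered |= result.member_ids
        kept = []
        for other in queue:
            if other.leaf_ids & result.member_ids:
                rejections.append(Rejection(clade=other, reason="superseded"))
            else:
                kept.append(other)
        queue = kept
    orphans = sorted(set(seqs) - clustered)
    return Partition(
        clusters=clusters,
        orphan_ids=orphans,
        rejections=rejections,
        universe_ids=sorted(seqs),
    )
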