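"""Recall/precision accounting against a reference labeling.

Per group g mapped to reference label L: TP are sequences classified into g
whose reference label is L; FP are sequences classified into g with a
different label; FN are sequences labeled L that ended up unclassified or in
another group (conflict-discarded sequences therefore count as FN for their
label). The overall figure is the micro-average recall, the pooled ratio
sum(TP) / sum(TP + FN) across groups. Training sequences are excluded from
these counts and reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple


@dataclass(frozen=True)
class GroupCounts:
    group_id: str
    label: str
    tp: int
    fp: int
    fn: int

    @property
    def recall(self) -> Optional[float]:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def precision(self) -> Optional[float]:
        d = self.tp + self.fp
        return self.tp / d if d else None


@dataclass
class EvaluationReport:
    per_group: List[GroupCounts]
    micro_average_recall: Optional[float]
    overall_precision: Optional[float]
    unclassified: int
    training_misplaced: int = 0

    def as_rows(self) -> List[dict]:
        rows = []
        for g in self.per_group:
            rows.append(
                {
                    "group_id": g.group_id,
                    "label": g.label,
                    "TP": g.tp,
                    "FP": g.fp,
                    "FN": g.fn,
                    "recall": g.recall,
                }
            )
        return rows


def derive_group_mapping(
    training_members: Mapping[str, Iterable[str]],
    reference: Mapping[str, str],
) -> Dict[str, str]:
    """Map each group to the majority reference label of its training
    members (ties break lexicographically)."""
    mapping = {}
    for gid in sorted(training_members):
        counts: Dict[str, int] = {}
        for sid in training_members[gid]:
            lab = reference.get(sid)
            if lab is not None:
                counts[lab] = counts.get(lab, 0) + 1
        if not counts:
            raise ValueError(f"group {gid!r} has no labeled training members")
        mapping[gid] = max(sorted(counts), key=lambda k: counts[k])
    return mapping


def per_group_recall(
    predicted: Mapping[str, str],
    reference: Mapping[str, str],
    mapping: Mapping[str, str],
    exclude_ids: Iterable[str] = (),
) -> EvaluationReport:
    """Count TP/FP/FN per group and pool the micro-average recall.

    ``predicted`` maps classified sequence ids to group ids; ``reference``
    maps every evaluated id to its true label; ``mapping`` maps group id to
    reference label and must be injective over the evaluated groups.
    ``exclude_ids`` (typically the training set) are removed from all
    counts; misplaced excluded sequences are tallied separately.
    """
    seen: Dict[str, str] = {}
    for gid, lab in mapping.items():
        if lab in seen:
            raise ValueError(
                f"mapping is not injective: label {lab!r} used by both "
                f"{seen[lab]!r} and {gid!r}"
            )
        seen[lab] = gid
    unmapped = sorted({g for g in predicted.values() if g not in mapping})
    if unmapped:
        raise ValueError(f"groups without a reference label: {unmapped}")
    excl = set(exclude_ids)
    training_misplaced = 0
    for sid in excl:
        gid = predicted.get(sid)
        if gid is not None and reference.get(sid) not in (None, mapping[gid]):
            training_misplaced += 1
    eval_ids = [i for i in reference if i not in excl]
    per_group: List[GroupCounts] = []
    for gid in sorted(mapping):
        lab = mapping[gid]
        tp = fp = fn = 0
        for sid in eval_ids:
            pred = predicted.get(sid)
            if pred == gid:
                if reference[sid] == lab:
                    tp += 1
                else:
                    fp += 1
            elif reference[sid] == lab:
                fn += 1
        per_group.append(GroupCounts(gid, lab, tp, fp, fn))
    sum_tp = sum(g.tp for g in per_group)
    sum_fn = sum(g.fn for g in per_group)
    sum_fp = sum(g.fp for g in per_group)
    micro = sum_tp / (sum_tp + sum_fn) if (sum_tp + sum_fn) else None
    precision = sum_tp / (sum_tp + sum_fp) if (sum_tp + sum_fp) else None
    unclassified = sum(1 for i in eval_ids if i not in predicted)
    return EvaluationReport(
        per_group=per_group,
        micro_average_recall=micro,
        overall_precision=precision,
        unclassified=unclassified,
        training_misplaced=training_misplaced,
    )


def recall_interval(
    predicted: Mapping[str, str],
    group_clades: Mapping[str, Sequence[Iterable[str]]],
    exclude_ids: Iterable[str] = (),
) -> Dict[str, Tuple[float, float]]:
    """Recall interval per group over nested alternative reference clades.

    For each group, the candidate clades (leaf-id sets, e.g. from
    alternative reference-tree cuts) must form a nested chain. The
    interval spans the lowest and highest possible coverage over the
    candidates — typically the recall against the largest clade (low) and
    against the smallest (high); when only one candidate exists the
    interval is degenerate.
    """
    excl = set(exclude_ids)
    out: Dict[str, Tuple[float, float]] = {}
    for gid in sorted(group_clades):
        clades = [frozenset(getattr(c, "leaf_ids", c)) - excl for c in group_clades[gid]]
        if not clades:
            raise ValueError(f"group {gid!r} has no candidate clades")
        clades.sort(key=len)
        for small, big in zip(clades, clades[1:]):
            if not small <= big:
                raise ValueError(
                    f"candidate clades for group {gid!r} are not nested"
                )
        members = {i for i, g in predicted.items() if g == gid} - excl

        def _recall(clade: frozenset) -> float:
            if not clade:
                return float("nan")
            return len(members & clade) / len(clade)

        recalls = [_recall(c) for c in clades]
        out[gid] = (min(recalls), max(recalls))
    return out
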