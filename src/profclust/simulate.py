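"""Synthetic superfamily benchmarks with planted subfamily structure.

A benchmark emulates the shape of data the classifier is built for: several
subfamilies with low within-family and high between-family divergence, a
training/target split, a true training-sequence tree in which every family
is a clade, and planted labels for every sequence.

Sequences evolve from a superfamily consensus by independent per-site
substitution (a Jukes-Cantor-style model over the 20 amino acids): along a
branch of length ``d`` expected substitutions/site, each site changes with
probability ``(19/20) * (1 - exp(-20/19 * d))`` to a uniformly drawn other
residue. The consensus-to-family-ancestor branch is ``between / 2`` and the
ancestor-to-sequence branch ``within / 2``, so expected pairwise divergence
is ~``within`` inside a family and ~``between + within`` across families.

Perturbation helpers plant the two dataset pathologies the method is known
to be sensitive to: a *rogue* (a training sequence attached inside a foreign
clade of the tree while keeping its own family's residues — a misplaced
training sequence) and a *repeat* (a target replaced by a tandem
concatenation of partial family segments, which inflates full-sequence
scores).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .sequences import AMINO_ACIDS, SequenceRecord, write_fasta


@dataclass(frozen=True)
class BenchmarkSpec:
    """Parameters of a simulated superfamily (divergences in expected
    substitutions per site)."""

    n_families: int = 8
    n_train: int = 12
    n_target: int = 30
    length: int = 150
    within: float = 0.2
    between: float = 1.2
    indel_rate: float = 0.0
    n_rogue: int = 0
    n_mimic: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_families < 1:
            raise ValueError("need at least one family")
        if self.n_train < 2:
            raise ValueError("need >= 2 training sequences per family")
        if self.n_target < 0 or self.length < 1:
            raise ValueError("invalid target count or length")
        if self.within < 0 or self.between < 0 or self.indel_rate < 0:
            raise ValueError("divergences and rates must be >= 0")


@dataclass(frozen=True)
class SyntheticBenchmark:
    spec: BenchmarkSpec
    training: Tuple[SequenceRecord, ...]
    targets: Tuple[SequenceRecord, ...]
    labels: Dict[str, str]          # every sequence id -> family label
    flags: Dict[str, str]           # id -> ROGUE | REPEAT | MIMIC
    tree_assignment: Dict[str, Tuple[str, ...]]  # family -> training leaf ids

    @property
    def newick(self) -> str:
        w = self.spec.within / 2.0
        b = self.spec.between / 2.0
        fams = []
        for fam in sorted(self.tree_assignment):
            leaves = self.tree_assignment[fam]
            inner = ",".join(f"{leaf}:{w:.6f}" for leaf in leaves)
            fams.append(f"({inner}):{b:.6f}")
        return "(" + ",".join(fams) + ");\n"

    def write(self, outdir) -> Dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "training": outdir / "training.fasta",
            "targets": outdir / "targets.fasta",
            "tree": outdir / "tree.nwk",
            "labels": outdir / "labels.tsv",
            "spec": outdir / "spec.json",
        }
        write_fasta(self.training, paths["training"])
        write_fasta(self.targets, paths["targets"])
        paths["tree"].write_text(self.newick)
        lines = ["sequence_id\tlabel\trole\tflag"]
        roles = {r.id: "training" for r in self.training}
        roles.update({r.id: "target" for r in self.targets})
        for sid in sorted(self.labels):
            lines.append(
                f"{sid}\t{self.labels[sid]}\t{roles.get(sid, '-')}\t"
                f"{self.flags.get(sid, '-')}"
            )
        paths["labels"].write_text("\n".join(lines) + "\n")
        paths["spec"].write_text(json.dumps(self.spec.__dict__, indent=2) + "\n")
        return paths


def _p_substitution(d: float) -> float:
    return (19.0 / 20.0) * (1.0 - math.exp(-20.0 / 19.0 * d))


def _evolve(seq: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    p = _p_substitution(d)
    out = seq.copy()
    hit = rng.random(len(seq)) < p
    if hit.any():
        shift = rng.integers(1, 20, size=int(hit.sum()))
        out[hit] = (out[hit] + shift) % 20
    return out


def _apply_indels(residues: str, rate: float, length: int, rng: np.random.Generator) -> str:
    n_events = rng.poisson(rate * length)
    s = list(residues)
    for _ in range(n_events):
        size = int(rng.integers(1, 4))
        pos = int(rng.integers(0, max(len(s), 1)))
        if rng.random() < 0.5 and len(s) > size + 1:
            del s[pos : pos + size]
        else:
            ins = [AMINO_ACIDS[int(rng.integers(0, 20))] for _ in range(size)]
            s[pos:pos] = ins
    return "".join(s)


def _to_str(codes: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[c] for c in codes)


def simulate_superfamily(spec: BenchmarkSpec) -> SyntheticBenchmark:
    """Simulate a superfamily benchmark; byte-identical under a fixed
    seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    consensus = rng.integers(0, 20, size=spec.length)
    training: List[SequenceRecord] = []
    targets: List[SequenceRecord] = []
    labels: Dict[str, str] = {}
    flags: Dict[str, str] = {}
    assignment: Dict[str, Tuple[str, ...]] = {}
    half_b = spec.between / 2.0
    half_w = spec.within / 2.0
    ancestors = {}
    for f in range(spec.n_families):
        fam = f"fam{f + 1:02d}"
        ancestor = _evolve(consensus, half_b, rng)
        ancestors[fam] = ancestor
        leaf_ids = []
        for k in range(spec.n_train):
            sid = f"{fam}_tr{k + 1:02d}"
            res = _to_str(_evolve(ancestor, half_w, rng))
            if spec.indel_rate > 0:
                res = _apply_indels(res, spec.indel_rate, spec.length, rng)
            training.append(SequenceRecord(sid, res))
            labels[sid] = fam
            leaf_ids.append(sid)
        for k in range(spec.n_target):
            sid = f"{fam}_tg{k + 1:02d}"
            res = _to_str(_evolve(ancestor, half_w, rng))
            if spec.indel_rate > 0:
                res = _apply_indels(res, spec.indel_rate, spec.length, rng)
            targets.append(SequenceRecord(sid, res))
            labels[sid] = fam
        assignment[fam] = tuple(leaf_ids)
    # mimics: target-side sequences at intermediate divergence, near the
    # detection boundary of their source family
    fams = sorted(assignment)
    for m in range(spec.n_mimic):
        fam = fams[m % len(fams)]
        sid = f"{fam}_mimic{m + 1:02d}"
        res = _to_str(_evolve(ancestors[fam], spec.within * 1.5, rng))
        targets.append(SequenceRecord(sid, res))
        labels[sid] = fam
        flags[sid] = "MIMIC"
    bench = SyntheticBenchmark(
        spec=spec,
        training=tuple(training),
        targets=tuple(targets),
        labels=labels,
        flags=flags,
        tree_assignment=assignment,
    )
    for r in range(spec.n_rogue):
        src = fams[r % len(fams)]
        dst = fams[(r + 1) % len(fams)]
        bench = inject_rogue(bench, src, dst, seed=spec.seed + 1000 + r)
    return bench


def inject_rogue(
    benchmark: SyntheticBenchmark,
    family_from: str,
    family_to: str,
    seed: int = 0,
) -> SyntheticBenchmark:
    """Re-attach one training leaf of ``family_from`` inside
    ``family_to``'s clade while keeping its family_from-like residues —
    the misplaced-training-sequence scenario."""
    if family_from == family_to:
        raise ValueError("rogue source and destination must differ")
    for fam in (family_from, family_to):
        if fam not in benchmark.tree_assignment:
            raise ValueError(f"unknown family {fam!r}")
    src_leaves = benchmark.tree_assignment[family_from]
    if len(src_leaves) < 3:
        raise ValueError(
            f"family {family_from!r} too small to donate a rogue "
            f"({len(src_leaves)} training leaves; >= 3 required)"
        )
    rng = np.random.default_rng(seed)
    rogue = src_leaves[int(rng.integers(0, len(src_leaves)))]
    assignment = dict(benchmark.tree_assignment)
    assignment[family_from] = tuple(x for x in src_leaves if x != rogue)
    assignment[family_to] = benchmark.tree_assignment[family_to] + (rogue,)
    flags = dict(benchmark.flags)
    flags[rogue] = "ROGUE"
    return replace(benchmark, tree_assignment=assignment, flags=flags)


def remove_sequence(
    benchmark: SyntheticBenchmark, seq_id: str, to_targets: bool = True
) -> SyntheticBenchmark:
    """Drop a training sequence from tree and training set (optionally
    transferring it to the target set) — the corrective action for a
    rogue."""
    if seq_id not in {r.id for r in benchmark.training}:
        raise ValueError(f"{seq_id!r} is not a training sequence")
    training = tuple(r for r in benchmark.training if r.id != seq_id)
    moved = next(r for r in benchmark.training if r.id == seq_id)
    targets = benchmark.targets + (moved,) if to_targets else benchmark.targets
    assignment = {
        fam: tuple(x for x in leaves if x != seq_id)
        for fam, leaves in benchmark.tree_assignment.items()
    }
    flags = dict(benchmark.flags)
    flags.pop(seq_id, None)
    labels = dict(benchmark.labels)
    if not to_targets:
        labels.pop(seq_id, None)
    return replace(
        benchmark,
        training=training,
        targets=targets,
        tree_assignment=assignment,
        flags=flags,
        labels=labels,
    )


def inject_repeat(
    benchmark: SyntheticBenchmark,
    family: str,
    n_copies: int = 3,
    seed: int = 0,
    fraction: float = 0.7,
) -> SyntheticBenchmark:
    """Replace one target of ``family`` by a tandem concatenation of
    ``n_copies`` partial segments of itself (a repeat protein)."""
    if n_copies < 2:
        raise ValueError("a repeat needs >= 2 copies")
    fam_targets = [
        r for r in benchmark.targets if benchmark.labels.get(r.id) == family
        and benchmark.flags.get(r.id) is None
    ]
    if not fam_targets:
        raise ValueError(f"family {family!r} has no target sequences")
    rng = np.random.default_rng(seed)
    victim = fam_targets[int(rng.integers(0, len(fam_targets)))]
    L = len(victim.residues)
    seg_len = max(2, int(round(fraction * L)))
    parts = []
    for _ in range(n_copies):
        start = int(rng.integers(0, max(L - seg_len, 0) + 1))
        parts.append(victim.residues[start : start + seg_len])
    repeat = SequenceRecord(victim.id, "".join(parts))
    targets = tuple(repeat if r.id == victim.id else r for r in benchmark.targets)
    flags = dict(benchmark.flags)
    flags[victim.id] = "REPEAT"
    return replace(benchmark, targets=targets, flags=flags)


def read_labels(path) -> Tuple[Dict[str, str], Dict[str, str], Dict[str, str]]:
    """Read a labels TSV -> (labels, roles, flags) keyed by sequence id."""
    labels: Dict[str, str] = {}
    roles: Dict[str, str] = {}
    flags: Dict[str, str] = {}
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    idx = {name: k for k, name in enumerate(header)}
    if "sequence_id" not in idx or "label" not in idx:
        raise ValueError(f"labels file {path} lacks sequence_id/label columns")
    for line in lines[1:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        sid = parts[idx["sequence_id"]]
        labels[sid] = parts[idx["label"]]
        if "role" in idx and len(parts) > idx["role"]:
            roles[sid] = parts[idx["role"]]
        if "flag" in idx and len(parts) > idx["flag"]:
            flags[sid] = parts[idx["flag"]]
    return labels, roles, flags
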