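"""Run artifacts: partition/classification TSVs, per-group FASTA/MSA files
and the JSON run manifest. All artifacts are plain text and deterministic
(no timestamps), so identical runs produce byte-identical outputs."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

from .classify import ClassificationResult, Group
from .phylo import Clade
from .profiles import MSA, NOT_DETECTED, ScoreTable
from .sequences import SequenceRecord, read_fasta, write_fasta
from .training import Cluster, Partition


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(outdir: Path, config: Mapping, files: Sequence[Path]) -> Path:
    from . import __version__

    outdir = Path(outdir)
    manifest = {
        "profclust_version": __version__,
        "config": dict(config),
        "outputs": {
            str(p.relative_to(outdir)): _sha256(p) for p in sorted(files)
        },
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _fmt_score(s: float) -> str:
    return "NOT_DETECTED" if s == NOT_DETECTED else f"{s:.4f}"


# --------------------------------------------------------------------------
# Partition artifacts
# --------------------------------------------------------------------------

def write_partition(
    partition: Partition,
    training: Sequence[SequenceRecord],
    outdir,
    config: Optional[Mapping] = None,
) -> List[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "clusters").mkdir(exist_ok=True)
    files: List[Path] = []

    assign = partition.cluster_of()
    p = outdir / "partition.tsv"
    rows = ["sequence_id\tcluster_id"]
    for sid in partition.universe_ids:
        rows.append(f"{sid}\t{assign.get(sid, 'ORPHAN')}")
    p.write_text("\n".join(rows) + "\n")
    files.append(p)

    p = outdir / "thresholds.tsv"
    rows = ["cluster_id\tthreshold_bits\tsize"]
    for c in partition.clusters:
        rows.append(f"{c.cluster_id}\t{c.threshold:.4f}\t{c.size}")
    p.write_text("\n".join(rows) + "\n")
    files.append(p)

    p = outdir / "rejections.tsv"
    rows = ["reason\tsize\tleaf_ids"]
    for r in partition.rejections:
        rows.append(
            f"{r.reason}\t{r.clade.size}\t{','.join(sorted(r.clade.leaf_ids))}"
        )
    p.write_text("\n".join(rows) + "\n")
    files.append(p)

    p = outdir / "training.fasta"
    write_fasta(training, p)
    files.append(p)

    for c in partition.clusters:
        fp = outdir / "clusters" / f"{c.cluster_id}.fasta"
        write_fasta(c.msa.degapped(), fp)
        files.append(fp)
        mp = outdir / "clusters" / f"{c.cluster_id}.msa.fasta"
        write_fasta(c.msa.rows, mp)
        files.append(mp)

    files.append(write_manifest(outdir, config or {}, files))
    return files


def load_partition(indir, engine) -> tuple:
    """Reload partition artifacts; profiles are rebuilt from the stored
    per-cluster MSAs with the supplied engine. Returns (partition,
    training_records)."""
    indir = Path(indir)
    for required in ("partition.tsv", "thresholds.tsv", "training.fasta"):
        if not (indir / required).exists():
            raise FileNotFoundError(f"missing partition artifact: {indir / required}")
    training = read_fasta(indir / "training.fasta")
    lines = (indir / "thresholds.tsv").read_text().splitlines()[1:]
    clusters: List[Cluster] = []
    for line in lines:
        if not line.strip():
            continue
        cid, thr, _size = line.split("\t")
        rows = read_fasta(indir / "clusters" / f"{cid}.msa.fasta")
        msa = MSA(tuple(rows))
        profile = engine.build_profile(msa, profile_id=cid)
        members = frozenset(r.id for r in rows)
        clusters.append(
            Cluster(
                cluster_id=cid,
                clade=Clade(leaf_ids=members, postorder_index=0),
                member_ids=members,
                msa=msa,
                profile=profile,
                threshold=float(thr),
                score_table=ScoreTable(profile_id=cid, scores={}),
            )
        )
    assign_lines = (indir / "partition.tsv").read_text().splitlines()[1:]
    universe = [l.split("\t")[0] for l in assign_lines if l.strip()]
    clustered = set().union(*(c.member_ids for c in clusters)) if clusters else set()
    orphans = [i for i in universe if i not in clustered]
    partition = Partition(
        clusters=clusters, orphan_ids=orphans, rejections=[], universe_ids=universe
    )
    return partition, training


# --------------------------------------------------------------------------
# Classification artifacts
# --------------------------------------------------------------------------

def _acceptance_info(group: Group, sid: str) -> tuple:
    """(iteration, threshold) at which sid entered the group."""
    for entry in group.history:
        if sid in entry.added:
            return entry.round_index, entry.threshold
    return 0, group.threshold


def classification_rows(result: ClassificationResult) -> List[str]:
    rows = ["sequence_id\tgroup_id\tscore\tthreshold_at_acceptance\titeration"]
    entries = []
    for g in sorted(result.groups, key=lambda g: g.group_id):
        for sid in sorted(g.member_ids):
            score = g.score_table.scores.get(sid, NOT_DETECTED) if g.score_table else NOT_DETECTED
            it, thr = _acceptance_info(g, sid)
            entries.append((sid, g.group_id, _fmt_score(score), f"{thr:.4f}", str(it)))
    for sid in result.pool_ids:
        entries.append((sid, "UNCLASSIFIED", "-", "-", "-"))
    for sid in result.discarded_ids:
        entries.append((sid, "CONFLICT", "-", "-", "-"))
    entries.sort(key=lambda e: e[0])
    rows.extend("\t".join(e) for e in entries)
    return rows


def write_classification(
    result: ClassificationResult,
    outdir,
    config: Optional[Mapping] = None,
) -> List[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "groups").mkdir(exist_ok=True)
    files: List[Path] = []

    p = outdir / "classification.tsv"
    p.write_text("\n".join(classification_rows(result)) + "\n")
    files.append(p)

    p = outdir / "conflicts.tsv"
    rows = ["sequence_id\tgroup_ids\titeration\tclass"]
    for c in result.conflicts:
        rows.append(
            f"{c.sequence_id}\t{';'.join(c.group_ids)}\t{c.iteration}\t{c.sequence_class}"
        )
    p.write_text("\n".join(rows) + "\n")
    files.append(p)

    p = outdir / "group_thresholds.tsv"
    rows = ["group_id\tthreshold_bits\tsize\tfrozen"]
    for g in sorted(result.groups, key=lambda g: g.group_id):
        rows.append(f"{g.group_id}\t{g.threshold:.4f}\t{len(g.member_ids)}\t{int(g.frozen)}")
    p.write_text("\n".join(rows) + "\n")
    files.append(p)

    for g in sorted(result.groups, key=lambda g: g.group_id):
        if g.msa is not None:
            fp = outdir / "groups" / f"{g.group_id}.fasta"
            write_fasta(g.msa.degapped(), fp)
            files.append(fp)
            mp = outdir / "groups" / f"{g.group_id}.msa.fasta"
            write_fasta(g.msa.rows, mp)
            files.append(mp)
        if g.score_table is None:
            continue
        sp = outdir / "groups" / f"{g.group_id}_scores.tsv"
        rows = ["sequence_id\tscore\tmember"]
        items = sorted(
            g.score_table.scores.items(), key=lambda kv: (-kv[1], kv[0])
        )
        for sid, s in items:
            rows.append(f"{sid}\t{_fmt_score(s)}\t{int(sid in g.member_ids)}")
        sp.write_text("\n".join(rows) + "\n")
        files.append(sp)

    p = outdir / "posterior_log.tsv"
    rows = ["group_id\tsequence_id\tdecision"]
    for gid, sid, decision in result.posterior_log:
        rows.append(f"{gid}\t{sid}\t{decision}")
    p.write_text("\n".join(rows) + "\n")
    files.append(p)

    files.append(write_manifest(outdir, config or {}, files))
    return files
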