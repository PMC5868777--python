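"""Alignment, profile construction and sequence scoring.

Two scoring backends satisfy one contract (build a profile from an MSA,
return one score-or-sentinel per queried sequence id):

* :class:`InternalBackend` — a self-contained position-specific log-odds
  scorer with a glocal, optionally multihit, affine-gap dynamic program.
  Deterministic and dependency-free; it is the default throughout.
* :class:`~profclust.hmmer.PyhmmerBackend` — profile HMMs built and searched
  with pyhmmer (default build settings, full-sequence bit scores).

Scores are bits. A sequence the backend does not report (or whose score
falls below the internal floor of 0) is recorded as :data:`NOT_DETECTED`,
which compares below every finite score.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np

from . import _dp
from .sequences import AMINO_ACIDS, SequenceRecord, write_fasta, read_fasta

#: sentinel for "not reported by the backend"; below every finite score
NOT_DETECTED = float("-inf")

GAP_CHARS = "-."

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_UNKNOWN_CODE = len(AMINO_ACIDS)  # catch-all column, log-odds 0


# --------------------------------------------------------------------------
# MSA
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MSA:
    """A multiple sequence alignment: equal-length gapped rows."""

    rows: tuple  # tuple[SequenceRecord] with gap characters allowed

    def __post_init__(self) -> None:
        if len(self.rows) < 1:
            raise ValueError("MSA needs at least one row")
        ncol = len(self.rows[0].residues)
        for r in self.rows:
            if len(r.residues) != ncol:
                raise ValueError(
                    f"MSA rows have unequal lengths: {self.rows[0].id!r} has "
                    f"{ncol} columns, {r.id!r} has {len(r.residues)}"
                )

    @property
    def n_columns(self) -> int:
        return len(self.rows[0].residues)

    @property
    def ids(self) -> List[str]:
        return [r.id for r in self.rows]

    def degapped(self) -> List[SequenceRecord]:
        out = []
        for r in self.rows:
            res = "".join(c for c in r.residues if c not in GAP_CHARS)
            out.append(SequenceRecord(r.id, res))
        return out


# --------------------------------------------------------------------------
# Aligners
# --------------------------------------------------------------------------

class PassThroughAligner:
    """Fixture aligner: accepts pre-aligned input and verifies it.

    Rows must already have equal length (gap characters allowed). Useful
    whenever upstream sequences are simulated without indels.
    """

    name = "as-is"

    def align(self, seqs: Sequence[SequenceRecord]) -> MSA:
        lengths = {len(s.residues) for s in seqs}
        if len(lengths) != 1:
            raise ValueError(
                "pass-through aligner requires equal-length rows; got lengths "
                f"{sorted(lengths)}"
            )
        return MSA(tuple(seqs))


class MafftAligner:
    """External aligner: ``mafft --anysymbol --auto`` via subprocess."""

    name = "mafft"

    def __init__(self, binary: str = "mafft") -> None:
        self.binary = binary

    def align(self, seqs: Sequence[SequenceRecord]) -> MSA:
        if shutil.which(self.binary) is None:
            raise EnvironmentError(
                f"external aligner binary {self.binary!r} not found on PATH"
            )
        with tempfile.TemporaryDirectory() as td:
            inp = Path(td) / "in.fasta"
            write_fasta(seqs, inp)
            proc = subprocess.run(
                [self.binary, "--anysymbol", "--auto", str(inp)],
                capture_output=True, text=True,
            )
            if proc.returncode != 0:
                raise RuntimeError(f"mafft failed: {proc.stderr[-2000:]}")
            out = Path(td) / "out.fasta"
            out.write_text(proc.stdout)
            rows = read_fasta(out)
        by_id = {r.id: r for r in rows}
        # mafft preserves ids; restore input order
        ordered = tuple(by_id[s.id] for s in seqs)
        return MSA(ordered)


class AutoAligner:
    """Pass sequences through when they are already equal-length, otherwise
    delegate to the external aligner."""

    name = "auto"

    def __init__(self, external: Optional[MafftAligner] = None) -> None:
        self.external = external or MafftAligner()

    def align(self, seqs: Sequence[SequenceRecord]) -> MSA:
        lengths = {len(s.residues) for s in seqs}
        if len(lengths) == 1:
            return MSA(tuple(seqs))
        return self.external.align(seqs)


def build_msa(seqs: Sequence[SequenceRecord], aligner=None) -> MSA:
    """Align ``seqs`` (>= 2) into an MSA using ``aligner`` (default auto)."""
    if len(seqs) < 2:
        raise ValueError(f"an alignment needs >= 2 sequences, got {len(seqs)}")
    aligner = aligner or AutoAligner()
    return aligner.align(seqs)


# --------------------------------------------------------------------------
# Profiles and score tables
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Profile:
    """A scoring profile; ``backend`` tags which engine built it.

    For the internal backend, ``emissions`` holds per-match-column log-odds
    (bits) over the 20 amino acids plus a trailing catch-all slot for
    unknown residues, and ``match_mask`` marks which MSA columns became
    match columns. For external backends ``handle`` is an opaque object.
    """

    profile_id: str
    backend: str
    emissions: Optional[np.ndarray] = None
    match_mask: Optional[np.ndarray] = None
    gap_open: float = -4.0
    gap_extend: float = -1.0
    handle: object = None

    @property
    def n_match_columns(self) -> int:
        if self.emissions is not None:
            return int(self.emissions.shape[0])
        raise AttributeError("external profile: match-column count is opaque")


@dataclass(frozen=True)
class ScoreTable:
    """Mapping sequence id -> bit score for one profile over one universe.

    Every queried id is present exactly once; undetected ids hold
    :data:`NOT_DETECTED` (-inf), which sorts below every finite score.
    """

    profile_id: str
    scores: Mapping[str, float]

    def score(self, seq_id: str) -> float:
        return self.scores[seq_id]

    def detected(self, seq_id: str) -> bool:
        return self.scores[seq_id] != NOT_DETECTED

    def subset(self, ids: Iterable[str]) -> Dict[str, float]:
        return {i: self.scores[i] for i in ids}


# --------------------------------------------------------------------------
# Internal backend
# --------------------------------------------------------------------------

def _encode(seqs: Sequence[SequenceRecord]) -> tuple:
    nmax = max(len(s.residues) for s in seqs)
    codes = np.full((len(seqs), max(nmax, 1)), _UNKNOWN_CODE, dtype=np.int8)
    lengths = np.empty(len(seqs), dtype=np.int64)
    for k, s in enumerate(seqs):
        lengths[k] = len(s.residues)
        for i, c in enumerate(s.residues):
            codes[k, i] = _AA_INDEX.get(c, _UNKNOWN_CODE)
    return codes, lengths


class InternalBackend:
    """Self-contained position-specific log-odds scorer.

    Match columns are MSA columns with < 50% gaps. Column probabilities are
    ``(count + alpha*bg) / (N + alpha)`` with pseudocount ``alpha = 1`` and
    uniform background ``bg = 1/20`` over the residues observed in the
    column; emissions are the log2 odds against the background (unknown
    residues score 0).

    Raw small-sample counts produce strongly over-specific profiles: a
    member's own counts push its self-score far above sequences of the same
    subfamily that are not in the alignment, which stalls threshold-based
    recruitment. Like profile-HMM entropy weighting, the builder therefore
    shrinks column probabilities toward the background until the mean
    per-column information content drops to ``info_target`` bits
    (default 1.0; pass ``None`` for raw counts).

    Scoring aligns the profile glocally to the sequence (all match columns
    consumed; affine gap penalties, open -4 / extend -1 bits; flanking
    residues free). The default full-sequence mode is multihit: disjoint
    repeated passes add up, so tandem repeats accumulate elevated scores.
    ``score_mode="best_domain"`` restricts scoring to the single best
    pass. Raw scores below 0 are reported as NOT_DETECTED.
    """

    name = "internal"

    def __init__(
        self,
        score_mode: str = "full",
        alpha: float = 1.0,
        background: float = 1.0 / 20.0,
        gap_open: float = -4.0,
        gap_extend: float = -1.0,
        max_gap_fraction: float = 0.5,
        info_target: Optional[float] = 1.0,
        score_floor: float = 0.0,
        max_passes: int = 6,
    ) -> None:
        if score_mode not in ("full", "best_domain"):
            raise ValueError(f"unknown score mode {score_mode!r}")
        self.score_mode = score_mode
        self.alpha = alpha
        self.background = background
        self.gap_open = gap_open
        self.gap_extend = gap_extend
        self.max_gap_fraction = max_gap_fraction
        self.info_target = info_target
        self.score_floor = score_floor
        self.max_passes = max_passes

    # -- building ----------------------------------------------------------

    def build_profile(self, msa: MSA, profile_id: str = "profile") -> Profile:
        ncol = msa.n_columns
        nrow = len(msa.rows)
        cols = []
        mask = np.zeros(ncol, dtype=bool)
        for j in range(ncol):
            column = [r.residues[j] for r in msa.rows]
            gaps = sum(1 for c in column if c in GAP_CHARS)
            if gaps / nrow >= self.max_gap_fraction:
                continue
            mask[j] = True
            counts = np.zeros(len(AMINO_ACIDS), dtype=np.float64)
            for c in column:
                idx = _AA_INDEX.get(c)
                if idx is not None:
                    counts[idx] += 1.0
            n = counts.sum()
            if n > 0:
                probs = (counts + self.alpha * self.background) / (n + self.alpha)
            else:  # only unknown residues: uninformative column
                probs = np.full(len(AMINO_ACIDS), self.background)
            cols.append(probs)
        if not cols:
            raise ValueError(
                f"MSA for {profile_id!r} yields zero match columns "
                f"(every column is >= {self.max_gap_fraction:.0%} gaps)"
            )
        probs = np.vstack(cols)
        probs = self._shrink_to_info_target(probs)
        emissions = np.zeros((probs.shape[0], len(AMINO_ACIDS) + 1))
        emissions[:, : len(AMINO_ACIDS)] = np.log2(probs / self.background)
        return Profile(
            profile_id=profile_id,
            backend=self.name,
            emissions=emissions,
            match_mask=mask,
            gap_open=self.gap_open,
            gap_extend=self.gap_extend,
        )

    def _mean_info(self, probs: np.ndarray) -> float:
        return float(np.mean(np.sum(probs * np.log2(probs / self.background), axis=1)))

    def _shrink_to_info_target(self, probs: np.ndarray) -> np.ndarray:
        """Blend column distributions toward the background until the mean
        per-column information content reaches ``info_target`` bits."""
        if self.info_target is None or self._mean_info(probs) <= self.info_target:
            return probs
        lo, hi = 0.0, 1.0  # mixing weight of the observed distribution
        for _ in range(60):
            lam = 0.5 * (lo + hi)
            blended = lam * probs + (1.0 - lam) * self.background
            if self._mean_info(blended) > self.info_target:
                hi = lam
            else:
                lo = lam
        return lo * probs + (1.0 - lo) * self.background

    # -- scoring -----------------------------------------------------------

    def score_sequences(
        self, profile: Profile, seqs: Sequence[SequenceRecord]
    ) -> ScoreTable:
        if len(seqs) == 0:
            raise ValueError("no sequences to score")
        if profile.backend != self.name or profile.emissions is None:
            raise ValueError(
                f"profile {profile.profile_id!r} was built by backend "
                f"{profile.backend!r}, not {self.name!r}"
            )
        codes, lengths = _encode(seqs)
        raw = _dp.score_batch(
            profile.emissions,
            codes,
            lengths,
            profile.gap_open,
            profile.gap_extend,
            self.score_mode == "full",
            self.max_passes,
        )
        scores = {}
        for s, v in zip(seqs, raw):
            scores[s.id] = float(v) if v >= self.score_floor else NOT_DETECTED
        return ScoreTable(profile_id=profile.profile_id, scores=scores)


# --------------------------------------------------------------------------
# Tabular score I/O (external-tool per-sequence table dialect)
# --------------------------------------------------------------------------

def parse_tabular_scores(
    text: str,
    profile_id: str = "profile",
    queried_ids: Optional[Iterable[str]] = None,
) -> ScoreTable:
    """Parse a per-sequence tabular hits file ('tblout' dialect).

    Whitespace-delimited rows, ``#`` comment lines, target id in the first
    column and the full-sequence bit score in the sixth. Ids listed in
    ``queried_ids`` but absent from the table are recorded NOT_DETECTED.
    """
    scores: Dict[str, float] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 6:
            raise ValueError(
                f"malformed score-table row at line {lineno}: "
                f"expected >= 6 columns, got {len(parts)}"
            )
        try:
            score = float(parts[5])
        except ValueError as exc:
            raise ValueError(
                f"malformed score at line {lineno}: {parts[5]!r}"
            ) from exc
        scores[parts[0]] = score
    if queried_ids is not None:
        for i in queried_ids:
            scores.setdefault(i, NOT_DETECTED)
    return ScoreTable(profile_id=profile_id, scores=scores)


def write_tabular_scores(table: ScoreTable, profile_name: str = "-") -> str:
    """Emit detected hits in the canonical tabular dialect (sorted by score
    descending, then id)."""
    lines = ["#target              accession query               accession   evalue  score"]
    items = [(i, s) for i, s in table.scores.items() if s != NOT_DETECTED]
    items.sort(key=lambda kv: (-kv[1], kv[0]))
    for sid, score in items:
        lines.append(f"{sid:<20} -         {profile_name:<19} -           -  {score:.1f}")
    return "\n".join(lines) + "\n"
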