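"""Sequence records and FASTA input/output (Biopython-backed)."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence: unique id plus IUPAC one-letter residues."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} has no residues")

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: Union[str, Path]) -> List[SequenceRecord]:
    """Read a FASTA file into SequenceRecords.

    Ids are the FASTA identifiers (first whitespace-delimited token),
    trimmed of surrounding whitespace. Duplicate ids are an error.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id.strip()
        if rid in seen:
            raise ValueError(f"duplicate sequence id {rid!r} in {path}")
        seen.add(rid)
        records.append(SequenceRecord(rid, str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: Union[str, Path]) -> None:
    bio = [_BioRecord(Seq(r.residues), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


def as_dict(records: Iterable[SequenceRecord]) -> dict:
    """Index records by id, erroring on duplicates."""
    out = {}
    for r in records:
        if r.id in out:
            raise ValueError(f"duplicate sequence id {r.id!r}")
        out[r.id] = r
    return out
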