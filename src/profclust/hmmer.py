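"""External profile-HMM backend built on pyhmmer.

Profiles are built with default build settings and searched without
alignment output; the full-sequence bit score is extracted per target.
Targets absent from the hit list (below the tool's reporting thresholds)
are recorded as NOT_DETECTED.
"""

from __future__ import annotations

from typing import Sequence

import pyhmmer

from .profiles import MSA, NOT_DETECTED, Profile, ScoreTable
from .sequences import SequenceRecord

_ALPHABET = pyhmmer.easel.Alphabet.amino()


class PyhmmerBackend:
    """Profile-HMM backend (hmmbuild/hmmsearch equivalents via pyhmmer)."""

    name = "hmmer"

    def __init__(self, score_mode: str = "full") -> None:
        if score_mode not in ("full", "best_domain"):
            raise ValueError(f"unknown score mode {score_mode!r}")
        self.score_mode = score_mode

    def build_profile(self, msa: MSA, profile_id: str = "profile") -> Profile:
        sequences = [
            pyhmmer.easel.TextSequence(name=r.id.encode(), sequence=r.residues)
            for r in msa.rows
        ]
        text_msa = pyhmmer.easel.TextMSA(
            name=profile_id.encode(), sequences=sequences
        )
        digital = text_msa.digitize(_ALPHABET)
        builder = pyhmmer.plan7.Builder(_ALPHABET)
        background = pyhmmer.plan7.Background(_ALPHABET)
        hmm, _, _ = builder.build_msa(digital, background)
        return Profile(profile_id=profile_id, backend=self.name, handle=hmm)

    def score_sequences(
        self, profile: Profile, seqs: Sequence[SequenceRecord]
    ) -> ScoreTable:
        if len(seqs) == 0:
            raise ValueError("no sequences to score")
        if profile.backend != self.name or profile.handle is None:
            raise ValueError(
                f"profile {profile.profile_id!r} was built by backend "
                f"{profile.backend!r}, not {self.name!r}"
            )
        digital = pyhmmer.easel.DigitalSequenceBlock(
            _ALPHABET,
            [
                pyhmmer.easel.TextSequence(
                    name=r.id.encode(), sequence=r.residues
                ).digitize(_ALPHABET)
                for r in seqs
            ],
        )
        pipeline = pyhmmer.plan7.Pipeline(_ALPHABET)
        try:
            hits = pipeline.search_hmm(profile.handle, digital)
        except Exception as exc:  # propagate with the backend's diagnostics
            raise RuntimeError(f"pyhmmer search failed: {exc}") from exc
        scores = {r.id: NOT_DETECTED for r in seqs}
        for hit in hits:
            sid = hit.name.decode() if isinstance(hit.name, bytes) else hit.name
            if self.score_mode == "full":
                scores[sid] = float(hit.score)
            else:
                scores[sid] = float(hit.best_domain.score)
        return ScoreTable(profile_id=profile.profile_id, scores=scores)
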