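"""Circular DNA sequences and base-pair-step typing.

Positions are 1-based and wrap modulo the circle length, so ``bp N+1`` is
``bp 1``; this matches the coordinate labels used for minicircle motifs
(e.g. "bp14-25").  Step ``i`` is the ordered dinucleotide from position
``i`` to ``i+1`` (circularly), so an N-bp circle has exactly N steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGT")
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

#: pyrimidine-purine steps: flexurally soft, denaturation prone
YPR_STEPS = frozenset({"TA", "TG", "CA", "CG"})
#: the step set empirically enriched in base-pair breathing events
BREATHING_PRONE_STEPS = frozenset({"CA", "TA", "CG", "AT"})


@dataclass(frozen=True)
class CircularSequence:
    """A closed circular DNA sequence on the reference strand, 5'->3'."""

    bases: str
    name: str = "circle"

    def __post_init__(self) -> None:
        seq = self.bases.upper()
        object.__setattr__(self, "bases", seq)
        if len(seq) < 3:
            raise ValueError(f"circular sequence needs >= 3 bp, got {len(seq)}")
        for i, b in enumerate(seq, start=1):
            if b not in ALPHABET:
                raise ValueError(
                    f"non-ACGT symbol {b!r} at position {i} in {self.name!r}"
                )

    def __len__(self) -> int:
        return len(self.bases)

    def base(self, pos: int) -> str:
        """Base at 1-based circular position ``pos``."""
        return self.bases[(pos - 1) % len(self.bases)]

    def step(self, pos: int) -> str:
        """Dinucleotide of the step from ``pos`` to ``pos + 1`` (circular)."""
        return self.base(pos) + self.base(pos + 1)

    def steps(self) -> list[str]:
        """All N step dinucleotides, including the wrap step N->1."""
        return [self.step(i) for i in range(1, len(self) + 1)]

    def rotate(self, k: int) -> "CircularSequence":
        """Rotate so new position 1 is old position ``k + 1``."""
        k %= len(self)
        return CircularSequence(self.bases[k:] + self.bases[:k], name=self.name)

    def at_mask(self) -> np.ndarray:
        """Boolean array per position: True for A·T base pairs."""
        return np.array([b in "AT" for b in self.bases], dtype=bool)


@dataclass(frozen=True)
class StepType:
    """An ordered base-pair step with its purine/pyrimidine class."""

    dinucleotide: str

    def __post_init__(self) -> None:
        d = self.dinucleotide.upper()
        object.__setattr__(self, "dinucleotide", d)
        if len(d) != 2 or any(b not in ALPHABET for b in d):
            raise ValueError(f"invalid dinucleotide {self.dinucleotide!r}")

    @property
    def category(self) -> str:
        """One of YpR, RpY, RpR, YpY (Y = C/T pyrimidine, R = A/G purine)."""
        first = "Y" if self.dinucleotide[0] in PYRIMIDINES else "R"
        second = "Y" if self.dinucleotide[1] in PYRIMIDINES else "R"
        return f"{first}p{second}"

    @property
    def is_ypr(self) -> bool:
        return self.category == "YpR"


def step_types(seq: CircularSequence) -> list[StepType]:
    """Step types of all N circular steps, wrap step included."""
    return [StepType(d) for d in seq.steps()]


# DESIGNED circle: four 12-bp motifs of mechanical interest embedded in a
# poly-CG circle.  For 106 bp the printed motif ranges are bp14-25 (TA),
# bp41-52 (AT), bp68-79 (AA), bp95-106 (CA), which forces a 13-bp leading
# CG block: 13 + 12 + 15 + 12 + 15 + 12 + 15 + 12 = 106.  The 108-bp
# variant (twist-deficit-corrected size) extends the leading block to 15.
_MOTIFS = {
    "TA": "TA" * 6,
    "AT": "AT" * 6,
    "AA": "A" * 12,
    "CA": "CA" * 6,
}

DESIGNED_MOTIF_RANGES_106 = {
    "TA": (14, 25),
    "AT": (41, 52),
    "AA": (68, 79),
    "CA": (95, 106),
}


def _cg_block(length: int) -> str:
    return ("CG" * length)[:length]


def build_designed(n_bp: int = 106) -> CircularSequence:
    """Construct the DESIGNED repetitive-motif minicircle.

    Four 12-bp motifs -- (TA)6, (AT)6, A12 and (CA)6 -- alternate with
    poly-CG spacers inside an otherwise GC-only circle.  Supported sizes
    are 106 bp (motifs at bp14-25 / 41-52 / 68-79 / 95-106) and the
    108-bp twist-corrected variant (leading CG block grown by 2 bp).
    """
    if n_bp not in (106, 108):
        raise ValueError(f"DESIGNED circle supports 106 or 108 bp, got {n_bp}")
    lead = 13 + (n_bp - 106)
    parts = [
        _cg_block(lead),
        _MOTIFS["TA"],
        _cg_block(15),
        _MOTIFS["AT"],
        _cg_block(15),
        _MOTIFS["AA"],
        _cg_block(15),
        _MOTIFS["CA"],
    ]
    bases = "".join(parts)
    assert len(bases) == n_bp
    return CircularSequence(bases, name=f"DESIGNED_{n_bp}")


def read_circular_fasta(path) -> CircularSequence:
    """Read a single-record FASTA file as a circular sequence.

    The record is uppercased and validated against the ACGT alphabet;
    multi-record files and ambiguity codes are rejected with diagnostics.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise ValueError(f"no FASTA records found in {path}")
    if len(records) > 1:
        names = ", ".join(r.id for r in records)
        raise ValueError(
            f"expected a single record in {path}, found {len(records)}: {names}"
        )
    rec = records[0]
    return CircularSequence(str(rec.seq), name=rec.id)


def write_circular_fasta(seq: CircularSequence, path) -> None:
    """Write a circular sequence as a single-record FASTA file."""
    rec = SeqRecord(Seq(seq.bases), id=seq.name, description="circular")
    SeqIO.write([rec], str(path), "fasta")
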