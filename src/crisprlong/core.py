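"""Shared sequence primitives and reference types.

Coordinates are 0-based and half-open throughout the package. Cut sites are
*bond* coordinates: a cut at position c falls between bases c-1 and c.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

DNA_ALPHABET = "ACGT"

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

# IUPAC code -> set of concrete bases it matches
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_match(code: str, base: str) -> bool:
    """True when an IUPAC code in a query is compatible with a concrete base."""
    return base in IUPAC.get(code, "")


def random_dna(rng: np.random.Generator, length: int, gc_fraction: float = 0.5) -> str:
    """i.i.d. random DNA at the requested GC content."""
    p_gc = gc_fraction / 2.0
    p_at = (1.0 - gc_fraction) / 2.0
    bases = rng.choice(np.frombuffer(b"ACGT", dtype="S1"),
                       size=length, p=[p_at, p_gc, p_gc, p_at])
    return bases.tobytes().decode()


_DINUC_RE = re.compile(r"(?=((.)(.)(?:\2\3)+))")


def longest_dinucleotide_run(seq: str) -> int:
    """Longest tandem run of a two-base unit (both bases distinct), in units.

    Homopolymers do not count: an AT-unit run is a genuine dinucleotide
    repeat, an AA-unit run is just a homopolymer.
    """
    best = 0
    for m in _DINUC_RE.finditer(seq):
        unit = m.group(1)[:2]
        if unit[0] == unit[1]:
            continue
        best = max(best, len(m.group(1)) // 2)
    return best


@dataclass(frozen=True)
class ReferenceLocus:
    """An amplicon reference: one locus spanning a Cas9 cleavage site.

    ``cut_position`` is the bond coordinate of the blunt cut; ``primer_span``
    is the half-open interval that long-range PCR can amplify.
    """

    name: str
    sequence: str
    cut_position: int
    primer_span: tuple[int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.primer_span is None:
            object.__setattr__(self, "primer_span", (0, len(self.sequence)))
        if not 0 < self.cut_position < len(self.sequence):
            raise ValueError(
                f"cut_position {self.cut_position} outside locus "
                f"(length {len(self.sequence)})")
        lo, hi = self.primer_span
        if not (0 <= lo < hi <= len(self.sequence)):
            raise ValueError(f"primer_span {self.primer_span} outside locus")
        if set(self.sequence) - set("ACGTN"):
            raise ValueError("locus sequence restricted to A/C/G/T/N")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def amplicon(self) -> str:
        lo, hi = self.primer_span
        return self.sequence[lo:hi]


@dataclass(frozen=True)
class GuideSpec:
    """A CRISPR guide: 20-nt protospacer plus PAM pattern (SpCas9 NGG).

    ``intended_cut`` is the bond coordinate of the intended blunt cut on
    ``intended_locus``: 3 nt 5' of the PAM, between protospacer positions
    17 and 18.
    """

    name: str
    protospacer: str
    pam_pattern: str = "NGG"
    intended_locus: str | None = None
    intended_cut: int | None = None

    def __post_init__(self):
        if len(self.protospacer) != 20:
            raise ValueError("protospacer must be 20 nt")
        if len(self.pam_pattern) != 3:
            raise ValueError("pam_pattern must be 3 nt")
        for c in self.protospacer + self.pam_pattern:
            if c not in IUPAC:
                raise ValueError(f"invalid IUPAC code {c!r}")

    @property
    def query(self) -> str:
        """Protospacer + PAM pattern: the 23-nt alignment query."""
        return self.protospacer + self.pam_pattern

    # Bond offset of the blunt cut from the protospacer start: 3 nt 5' of
    # the PAM, i.e. between protospacer bases 17 and 18 (1-based).
    CUT_OFFSET = 17
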