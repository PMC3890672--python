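"""Minisatellite allele decomposition and haplotype assignment.

The psbZ-trnfM minisatellite is a VNTR built from two 12 bp motifs,

    M1 = CTAACTACTATA        M2 = GTAGTTAGTATA

which form a pattern of inverted repeats shifted by 4 bp relative to the
mutational unit boundaries: reverse-complement(M1) is M2 cyclically rotated
by four positions.  One recorded allele additionally carries a 5 bp partial
unit, P5 = CTATA, i.e. an M1 unit whose first seven bases (CTAACTA) were
deleted.

Seven haplotypes are recorded in *Phoenix*; alleles outside that set are
reported as ``"novel"`` rather than rejected, so new field haplotypes
surface as first-class results.  Haplotypes 1 and 7 are a size homoplasy:
both are 36 bp but differ in unit content (2×M1+M2 vs M1+2×M2), so they are
indistinguishable by fragment-length genotyping yet separable here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import NovelAlleleError

M1 = "CTAACTACTATA"
M2 = "GTAGTTAGTATA"
P5 = "CTATA"

MOTIFS = {"M1": M1, "M2": M2, "P5": P5}

#: unit composition of the seven recorded haplotypes, keyed by haplotype id
RECORDED_HAPLOTYPES: dict[int, tuple[str, ...]] = {
    1: ("M1", "M1", "M2"),
    2: ("M1", "M1", "M1", "M2"),
    3: ("M1", "M1", "M1", "M1", "M2"),
    4: ("M1", "M1", "M1", "M1", "M1", "M2"),
    5: ("M1", "M1", "M1", "M1", "M1", "M1", "M2"),
    6: ("M1", "M1", "P5", "M2"),
    7: ("M1", "M2", "M2"),
}

_UNITS_TO_HAPLOTYPE = {units: hap for hap, units in RECORDED_HAPLOTYPES.items()}

NOVEL = "novel"


@dataclass(frozen=True)
class MinisatAllele:
    """Ordered decomposition of a minisatellite region into motif units."""

    units: tuple[str, ...]
    n_M1: int = field(init=False)
    n_M2: int = field(init=False)
    has_partial: bool = field(init=False)
    haplotype_id: int | str = field(init=False)
    length_bp: int = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "n_M1", self.units.count("M1"))
        object.__setattr__(self, "n_M2", self.units.count("M2"))
        object.__setattr__(self, "has_partial", "P5" in self.units)
        object.__setattr__(
            self, "haplotype_id", _UNITS_TO_HAPLOTYPE.get(self.units, NOVEL)
        )
        object.__setattr__(
            self, "length_bp", sum(len(MOTIFS[u]) for u in self.units)
        )

    @property
    def sequence(self) -> str:
        return "".join(MOTIFS[u] for u in self.units)

    def __str__(self) -> str:
        return ".".join(self.units)


def decompose(region: str) -> MinisatAllele:
    """Decompose ``region`` into an ordered sequence of M1/M2/P5 units.

    Matching is greedy left-to-right, trying M1, then M2, then P5 at each
    unit boundary.  The three motifs are mutually prefix-distinguishable
    within their first four bases (M1/M2 differ at position 0, M1/P5 at
    position 3, M2/P5 at position 0), so at most one motif can match at any
    boundary and greedy matching coincides with exhaustive search: a
    decomposition, if it exists, is unique.

    Raises
    ------
    NovelAlleleError
        If the region is empty or some residual matches no motif.  The
        error carries the consumed unit prefix and the residual string.
    """
    units: list[str] = []
    pos = 0
    region = region.upper()
    if not region:
        raise NovelAlleleError((), "")
    while pos < len(region):
        for label in ("M1", "M2", "P5"):
            motif = MOTIFS[label]
            if region.startswith(motif, pos):
                units.append(label)
                pos += len(motif)
                break
        else:
            raise NovelAlleleError(units, region[pos:])
    return MinisatAllele(tuple(units))


def assign_haplotype(units) -> int | str:
    """Map a unit tuple to its recorded haplotype id (1-7) or ``"novel"``."""
    return _UNITS_TO_HAPLOTYPE.get(tuple(units), NOVEL)


def allele_for_haplotype(haplotype_id: int) -> MinisatAllele:
    """Return the :class:`MinisatAllele` of a recorded haplotype."""
    return MinisatAllele(RECORDED_HAPLOTYPES[haplotype_id])


def enumerate_recorded_haplotypes() -> list[str]:
    """Concatenated allele sequences of the seven recorded haplotypes, in id order."""
    return [allele_for_haplotype(h).sequence for h in sorted(RECORDED_HAPLOTYPES)]
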