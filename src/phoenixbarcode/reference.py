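"""Reference model of the ~700 bp psbZ-trnfM amplicon.

This module defines the coordinate system, the polymorphic loci and the
packaged observed character matrix, and builds the synthetic reference
scaffold every other stage works against.  The scaffold reproduces the
*Phoenix dactylifera* 'Khalas' reference allele combination: reference
SNP states (C,T,G,A,T), the 9 bp segment GTACTTTAC present, minisatellite
haplotype 3 (four M1 units plus one M2) and a 7C+5A homopolymer.

Coordinates
-----------
Local coordinates are 0-based half-open on the 700 bp amplicon and are
authoritative.  The familiar chloroplast-genome positions (36607, 36754,
37099, 37183, 37190, spans 36795-36803, 37050-37098, 37128-37139) are kept
as site *labels* only: the published minisatellite span (49 bp) cannot hold
the 60 bp reference allele, so genome coordinates downstream of the repeat
are not trusted for arithmetic.  ``to_local``/``to_global`` convert between
the two frames by a constant offset, which is exact for the loci upstream
of the minisatellite and label-only downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import minisat
from .errors import ConstructionError
from .minisat import MinisatAllele, allele_for_haplotype

AMPLICON_LENGTH = 700

PRIMER_FWD = "GGTACMTCATTATGGATTGG"  # psbZ forward, IUPAC M = A/C
PRIMER_REV = "GCGGAGTAGAGCAGTTTGGT"  # trnfM reverse

_COMPLEMENT = str.maketrans("ACGTMRWSYKVHDBN", "TGCAKYWSRMBDHVN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# -- locus layout (local 0-based coordinates on the reference scaffold) -----

OFFSET = 36560  # global label of local position 0

SNP_LABELS = (36607, 36754, 37099, 37183, 37190)
SNP_LOCAL = (47, 194, 525, 625, 645)
SNP_REF_STATES = ("C", "T", "G", "A", "T")

DELETION_SPAN = (235, 244)  # labelled 36795-36803
DELETION_REF_ALLELE = "GTACTTTAC"

MINISAT_SPAN = (440, 500)  # labelled 37050-37098; reference = haplotype 3
HOMOPOLYMER_SPAN = (585, 597)  # labelled 37128-37139; reference = 7C + 5A
HOMOPOLYMER_REF = (7, 5)

ANCHOR_K = 15

#: ordered locus table: name -> (start, end) reference span, SNPs width 1
LOCI: dict[str, tuple[int, int]] = {
    "snp36607": (47, 48),
    "snp36754": (194, 195),
    "del9": DELETION_SPAN,
    "minisat": MINISAT_SPAN,
    "snp37099": (525, 526),
    "homopolymer": HOMOPOLYMER_SPAN,
    "snp37183": (625, 626),
    "snp37190": (645, 646),
}

SNP_NAMES = ("snp36607", "snp36754", "snp37099", "snp37183", "snp37190")


def anchor_spans() -> dict[str, tuple[tuple[int, int], tuple[int, int]]]:
    """Reference coordinates of the up/downstream k-mer anchors of each locus."""
    spans = {}
    for name, (start, end) in LOCI.items():
        spans[name] = ((start - ANCHOR_K, start), (end, end + ANCHOR_K))
    return spans


@dataclass(frozen=True)
class ReferenceMap:
    """Coordinate system and locus table of the reference scaffold."""

    offset: int = OFFSET
    snp_labels: tuple[int, ...] = SNP_LABELS
    snp_local: tuple[int, ...] = SNP_LOCAL
    snp_ref_states: tuple[str, ...] = SNP_REF_STATES
    deletion_span: tuple[int, int] = DELETION_SPAN
    deletion_ref_allele: str = DELETION_REF_ALLELE
    minisat_span: tuple[int, int] = MINISAT_SPAN
    homopolymer_span: tuple[int, int] = HOMOPOLYMER_SPAN
    primer_fwd: str = PRIMER_FWD
    primer_rev: str = PRIMER_REV

    def to_local(self, global_pos: int) -> int:
        local = global_pos - self.offset
        if not 0 <= local < AMPLICON_LENGTH:
            raise ValueError(
                f"global position {global_pos} outside the amplicon frame "
                f"[{self.offset}, {self.offset + AMPLICON_LENGTH})"
            )
        return local

    def to_global(self, local_pos: int) -> int:
        if not 0 <= local_pos < AMPLICON_LENGTH:
            raise ValueError(
                f"local position {local_pos} outside [0, {AMPLICON_LENGTH})"
            )
        return local_pos + self.offset


@dataclass(frozen=True)
class ReferenceScaffold:
    """The frozen 700 bp reference amplicon plus its locus map."""

    sequence: str
    map: ReferenceMap
    minisat_allele: MinisatAllele

    def __post_init__(self):
        assert len(self.sequence) == AMPLICON_LENGTH


# -- packaged observed character matrix --------------------------------------


@dataclass(frozen=True)
class KeyRow:
    """One row of the observed character matrix: a composite haplotype in one species."""

    row_id: str
    species: str
    count: int
    snp_states: tuple[str, str, str, str, str]
    deletion: str  # "present" | "absent"
    minisat_haplotype: int
    homopolymer: tuple[int, int]  # (n_C, n_A)


def _row(row_id, species, count, snps, deletion, hap, homopol):
    return KeyRow(row_id, species, count, tuple(snps), deletion, hap, tuple(homopol))


# Observed distribution of composite haplotypes across the 136-individual
# sampling of 13 Phoenix species.  Rows r01-r13 are private (single-species)
# profiles; r14/r15 share one profile (rupicola/theophrasti); r16-r18 share
# one profile (the date-palm complex: atlantica/dactylifera/sylvestris).
CHARACTER_MATRIX_ROWS: tuple[KeyRow, ...] = (
    _row("r01", "canariensis", 7, "CTGAT", "absent", 4, (7, 5)),
    _row("r02", "reclinata", 4, "CTCAT", "absent", 6, (6, 5)),
    _row("r03", "reclinata", 6, "CTGAT", "absent", 7, (7, 5)),
    _row("r04", "caespitosa", 2, "CTGCT", "absent", 5, (7, 5)),
    _row("r05", "loureiroi", 1, "CCGAG", "absent", 1, (7, 5)),
    _row("r06", "loureiroi", 1, "ACGAT", "absent", 2, (6, 6)),
    _row("r07", "acaulis", 1, "ACGAT", "absent", 1, (7, 5)),
    _row("r08", "pusilla", 2, "CCGAT", "absent", 1, (6, 6)),
    _row("r09", "paludosa", 2, "CTGAT", "present", 1, (6, 6)),
    _row("r10", "roebelenii", 3, "CTGAT", "present", 3, (5, 7)),
    _row("r11", "roebelenii", 1, "CTGAT", "present", 2, (5, 7)),
    _row("r12", "dactylifera", 78, "CTGAT", "absent", 3, (7, 5)),
    _row("r13", "sylvestris", 1, "CTGAT", "absent", 1, (8, 5)),
    _row("r14", "rupicola", 3, "CTGAT", "absent", 5, (7, 5)),
    _row("r15", "theophrasti", 4, "CTGAT", "absent", 5, (7, 5)),
    _row("r16", "atlantica", 1, "CTGAT", "absent", 2, (7, 5)),
    _row("r17", "dactylifera", 16, "CTGAT", "absent", 2, (7, 5)),
    _row("r18", "sylvestris", 3, "CTGAT", "absent", 2, (7, 5)),
)

REFERENCE_ROW_ID = "r12"  # the dactylifera haplotype-3 reference profile


def load_character_matrix() -> list[KeyRow]:
    """The packaged 18-row character matrix (counts sum to 136)."""
    return list(CHARACTER_MATRIX_ROWS)


# -- scaffold construction ---------------------------------------------------

PACKAGED_SEED = 101
_MAX_ATTEMPTS = 200


def _fixed_segments() -> list[tuple[int, str]]:
    """(start, sequence) pairs of all non-filler scaffold segments."""
    segs = [(0, PRIMER_FWD.replace("M", "A"))]
    for pos, state in zip(SNP_LOCAL, SNP_REF_STATES):
        segs.append((pos, state))
    segs.append((DELETION_SPAN[0], DELETION_REF_ALLELE))
    segs.append((MINISAT_SPAN[0], allele_for_haplotype(3).sequence))
    n_c, n_a = HOMOPOLYMER_REF
    segs.append((HOMOPOLYMER_SPAN[0], "C" * n_c + "A" * n_a))
    segs.append((AMPLICON_LENGTH - len(PRIMER_REV), revcomp(PRIMER_REV)))
    return segs


def _filler_ok(seq: str) -> bool:
    """Constraint check: motifs and anchors unique, homopolymer flanks clean."""
    for motif in (minisat.M1, minisat.M2):
        start = 0
        lo, hi = MINISAT_SPAN
        while (i := seq.find(motif, start)) != -1:
            if not (lo <= i and i + len(motif) <= hi):
                return False
            start = i + 1
    for (up, down) in anchor_spans().values():
        for a, b in (up, down):
            if seq.count(seq[a:b]) != 1:
                return False
    # flanks of the homopolymer must not extend or seed C/A runs
    hp_lo, hp_hi = HOMOPOLYMER_SPAN
    if seq[hp_lo - 1] == "C" or seq[hp_hi] == "A":
        return False
    for window in (seq[hp_lo - ANCHOR_K : hp_lo], seq[hp_hi : hp_hi + ANCHOR_K]):
        if "CCCC" in window or "AAAA" in window:
            return False
    return True


def build_reference(seed: int = PACKAGED_SEED) -> ReferenceScaffold:
    """Build the 700 bp reference scaffold.

    Filler between the fixed segments (primers, SNP sites, indel,
    minisatellite, homopolymer) is drawn uniformly from ACGT with a seeded
    generator and regenerated until no stray motif or anchor k-mer occurs
    outside its designated locus and no C/A run abuts the homopolymer.
    Deterministic given ``seed``; the packaged scaffold uses
    :data:`PACKAGED_SEED`.
    """
    rng = np.random.default_rng(seed)
    fixed = _fixed_segments()
    fixed_mask = np.zeros(AMPLICON_LENGTH, dtype=bool)
    template = [""] * AMPLICON_LENGTH
    for start, segment in fixed:
        for i, base in enumerate(segment):
            template[start + i] = base
            fixed_mask[start + i] = True
    n_filler = int((~fixed_mask).sum())
    filler_idx = np.flatnonzero(~fixed_mask)
    bases = np.array(list("ACGT"))
    for _ in range(_MAX_ATTEMPTS):
        draw = bases[rng.integers(0, 4, size=n_filler)]
        chars = template.copy()
        for i, base in zip(filler_idx, draw):
            chars[i] = base
        seq = "".join(chars)
        if _filler_ok(seq):
            return ReferenceScaffold(
                sequence=seq,
                map=ReferenceMap(),
                minisat_allele=allele_for_haplotype(3),
            )
    raise ConstructionError(
        f"no scaffold satisfying filler constraints in {_MAX_ATTEMPTS} attempts"
    )


# -- exports -----------------------------------------------------------------

KEY_TSV_COLUMNS = [
    "row_id", "species", "count",
    "snp36607", "snp36754", "snp37099", "snp37183", "snp37190",
    "del9", "minisat_hap", "homopol_C", "homopol_A",
]


def key_to_frame(rows: list[KeyRow]) -> pd.DataFrame:
    records = []
    for r in rows:
        rec = dict(row_id=r.row_id, species=r.species, count=r.count)
        rec.update(dict(zip(KEY_TSV_COLUMNS[3:8], r.snp_states)))
        rec["del9"] = r.deletion
        rec["minisat_hap"] = r.minisat_haplotype
        rec["homopol_C"], rec["homopol_A"] = r.homopolymer
        records.append(rec)
    return pd.DataFrame.from_records(records, columns=KEY_TSV_COLUMNS)


def frame_to_key(frame: pd.DataFrame) -> list[KeyRow]:
    rows = []
    for rec in frame.to_dict("records"):
        rows.append(
            KeyRow(
                row_id=str(rec["row_id"]),
                species=str(rec["species"]),
                count=int(rec["count"]),
                snp_states=tuple(str(rec[c]) for c in KEY_TSV_COLUMNS[3:8]),
                deletion=str(rec["del9"]),
                minisat_haplotype=int(rec["minisat_hap"]),
                homopolymer=(int(rec["homopol_C"]), int(rec["homopol_A"])),
            )
        )
    return rows


def write_key_tsv(rows: list[KeyRow], path) -> None:
    key_to_frame(rows).to_csv(path, sep="\t", index=False)


def read_key_tsv(path) -> list[KeyRow]:
    return frame_to_key(pd.read_csv(path, sep="\t", comment="#"))


def scaffold_to_fasta(scaffold: ReferenceScaffold) -> str:
    """Reference scaffold as a single-record FASTA string (70-column wrap)."""
    lines = [">reference_scaffold psbZ-trnfM synthetic reference, haplotype 3"]
    seq = scaffold.sequence
    lines += [seq[i : i + 70] for i in range(0, len(seq), 70)]
    return "\n".join(lines) + "\n"
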