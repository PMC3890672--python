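"""Synthetic amplicon cohorts realizing character-matrix rows.

A cohort is a multi-FASTA of ~700 bp psbZ-trnfM amplicons plus a truth TSV
(sample, species, generating row, completeness).  The default specification
reproduces the study conditions: the full 18-row composition (136
individuals over 13 species), of which 13 individuals — drawn from the
dactylifera haplotype-3 row — are "single read" records truncated to 80% of
their length, emulating sequencing that succeeded with only one primer.
Optional uniform base noise can be added outside the diagnostic loci (or
inside them, in adversarial mode) for robustness testing.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass

import numpy as np
import yaml
from Bio import SeqIO

from . import reference
from .errors import CohortSpecError, TruthFileError
from .minisat import allele_for_haplotype
from .reference import (
    DELETION_SPAN,
    HOMOPOLYMER_SPAN,
    KeyRow,
    MINISAT_SPAN,
    REFERENCE_ROW_ID,
    ReferenceScaffold,
    SNP_LOCAL,
    CHARACTER_MATRIX_ROWS,
)

_ACGT = "ACGT"


@dataclass(frozen=True)
class CohortSpec:
    """Composition and read-quality model of a synthetic cohort."""

    rows: tuple = None  # tuple[(KeyRow, count)]; None = full observed composition
    n_incomplete: int = 13
    incomplete_source: str = REFERENCE_ROW_ID
    truncation_fraction: float = 0.80
    reverse_reads: bool = False  # truncate 3' suffix reads instead of 5' prefix
    noise_rate: float = 0.0
    noise_in_loci: bool = False  # adversarial mode: noise may hit diagnostic loci
    seed: int = 0

    def __post_init__(self):
        if self.rows is None:
            object.__setattr__(
                self, "rows", tuple((row, row.count) for row in CHARACTER_MATRIX_ROWS)
            )
        if not 0.0 < self.truncation_fraction <= 1.0:
            raise CohortSpecError("truncation_fraction must be in (0, 1]")
        if self.truncation_fraction < 0.5:
            raise CohortSpecError("truncation must keep at least half the amplicon")
        if self.noise_rate < 0:
            raise CohortSpecError("noise_rate must be non-negative")
        src = {rid: n for (row, n), rid in ((rc, rc[0].row_id) for rc in self.rows)}
        if self.n_incomplete > 0 and src.get(self.incomplete_source, 0) < self.n_incomplete:
            raise CohortSpecError(
                f"n_incomplete={self.n_incomplete} exceeds count of source row "
                f"{self.incomplete_source}"
            )

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "rows": {row.row_id: count for row, count in self.rows},
            "n_incomplete": self.n_incomplete,
            "incomplete_source": self.incomplete_source,
            "truncation_fraction": self.truncation_fraction,
            "reverse_reads": self.reverse_reads,
            "noise_rate": self.noise_rate,
            "noise_in_loci": self.noise_in_loci,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "CohortSpec":
        data = dict(data)
        counts = data.pop("rows", None)
        rows = None
        if counts is not None:
            by_id = {row.row_id: row for row in CHARACTER_MATRIX_ROWS}
            unknown = set(counts) - set(by_id)
            if unknown:
                raise CohortSpecError(f"unknown row ids: {sorted(unknown)}")
            rows = tuple((by_id[rid], int(n)) for rid, n in counts.items())
        return cls(rows=rows, **data)

    @classmethod
    def from_file(cls, path) -> "CohortSpec":
        text = open(path).read()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        if "seed" not in data:
            raise CohortSpecError("cohort config must carry an explicit seed")
        return cls.from_dict(data)


@dataclass(frozen=True)
class CohortRecord:
    sample_id: str
    species: str
    row_id: str
    complete: bool
    sequence: str


def realize_row(row: KeyRow, scaffold: ReferenceScaffold) -> str:
    """Splice a row's character states into the reference scaffold.

    Substituting reference states for every character yields the scaffold
    itself; when profiled, the returned sequence reproduces the row exactly.
    """
    if any(s not in _ACGT for s in row.snp_states):
        raise ValueError(f"invalid SNP states {row.snp_states}")
    if row.minisat_haplotype not in range(1, 8):
        raise ValueError(f"haplotype {row.minisat_haplotype} outside 1-7")
    if min(row.homopolymer) < 1:
        raise ValueError("homopolymer run lengths must be >= 1")
    seq = scaffold.sequence
    s = row.snp_states
    pre = list(seq[: DELETION_SPAN[0]])
    pre[SNP_LOCAL[0]] = s[0]
    pre[SNP_LOCAL[1]] = s[1]
    del_allele = "" if row.deletion == "present" else seq[slice(*DELETION_SPAN)]
    mid1 = seq[DELETION_SPAN[1] : MINISAT_SPAN[0]]
    ms = allele_for_haplotype(row.minisat_haplotype).sequence
    mid2 = list(seq[MINISAT_SPAN[1] : HOMOPOLYMER_SPAN[0]])
    mid2[SNP_LOCAL[2] - MINISAT_SPAN[1]] = s[2]
    n_c, n_a = row.homopolymer
    hp = "C" * n_c + "A" * n_a
    tail = list(seq[HOMOPOLYMER_SPAN[1] :])
    tail[SNP_LOCAL[3] - HOMOPOLYMER_SPAN[1]] = s[3]
    tail[SNP_LOCAL[4] - HOMOPOLYMER_SPAN[1]] = s[4]
    return "".join(pre) + del_allele + mid1 + "".join(ms) + "".join(mid2) + hp + "".join(tail)


def _locus_mask(row: KeyRow, length: int) -> np.ndarray:
    """Boolean mask over the realized record marking diagnostic-locus bases."""
    mask = np.zeros(length, dtype=bool)
    shift = 0
    mask[SNP_LOCAL[0]] = mask[SNP_LOCAL[1]] = True
    if row.deletion == "present":
        shift -= DELETION_SPAN[1] - DELETION_SPAN[0]
    else:
        mask[slice(*DELETION_SPAN)] = True
    ms_len = allele_for_haplotype(row.minisat_haplotype).length_bp
    mask[MINISAT_SPAN[0] + shift : MINISAT_SPAN[0] + shift + ms_len] = True
    shift += ms_len - (MINISAT_SPAN[1] - MINISAT_SPAN[0])
    mask[SNP_LOCAL[2] + shift] = True
    hp_len = sum(row.homopolymer)
    mask[HOMOPOLYMER_SPAN[0] + shift : HOMOPOLYMER_SPAN[0] + shift + hp_len] = True
    shift += hp_len - (HOMOPOLYMER_SPAN[1] - HOMOPOLYMER_SPAN[0])
    mask[SNP_LOCAL[3] + shift] = True
    mask[SNP_LOCAL[4] + shift] = True
    return mask


def generate_cohort(spec: CohortSpec, scaffold: ReferenceScaffold) -> list[CohortRecord]:
    """Generate the cohort records a spec describes; deterministic given its seed.

    Under the default spec: 136 records over 13 species matching the packaged
    character-matrix counts, with 13 records of the dactylifera haplotype-3
    row flagged incomplete and truncated to the 5' 80% of their sequence.
    Record order is shuffled by the seed; the truth composition is not.
    """
    rng = np.random.default_rng(spec.seed)
    staged = []
    for row, count in spec.rows:
        if count < 0:
            raise CohortSpecError(f"negative count for row {row.row_id}")
        full = realize_row(row, scaffold)
        n_trunc = spec.n_incomplete if row.row_id == spec.incomplete_source else 0
        for i in range(count):
            truncate = i < n_trunc
            staged.append((row, full, truncate))
    order = rng.permutation(len(staged))
    width = max(3, len(str(len(staged))))
    records = []
    for rank, idx in enumerate(order, start=1):
        row, seq, truncate = staged[idx]
        if spec.noise_rate > 0:
            seq = _add_noise(seq, row, spec, rng)
        complete = not truncate
        if truncate:
            keep = int(round(spec.truncation_fraction * len(seq)))
            seq = seq[-keep:] if spec.reverse_reads else seq[:keep]
        records.append(
            CohortRecord(
                sample_id=f"s{rank:0{width}d}",
                species=row.species,
                row_id=row.row_id,
                complete=complete,
                sequence=seq,
            )
        )
    return records


def _add_noise(seq: str, row: KeyRow, spec: CohortSpec, rng) -> str:
    eligible = np.ones(len(seq), dtype=bool)
    if not spec.noise_in_loci:
        eligible = ~_locus_mask(row, len(seq))
    hits = np.flatnonzero((rng.random(len(seq)) < spec.noise_rate) & eligible)
    if hits.size == 0:
        return seq
    chars = list(seq)
    for i in hits:
        choices = [b for b in _ACGT if b != chars[i]]
        chars[i] = choices[rng.integers(0, 3)]
    return "".join(chars)


# -- FASTA and truth-table I/O ----------------------------------------------


def write_fasta(records: list[CohortRecord], path) -> None:
    """Write cohort sequences as multi-FASTA wrapped at 70 columns."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.sample_id}\n")
            for i in range(0, len(rec.sequence), 70):
                fh.write(rec.sequence[i : i + 70] + "\n")


def read_fasta(path) -> list[tuple[str, str]]:
    """(sample_id, uppercase sequence) pairs from a FASTA file."""
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


TRUTH_COLUMNS = ("sample_id", "species", "row_id", "complete")


def write_truth(records: list[CohortRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TRUTH_COLUMNS)
        for rec in records:
            writer.writerow(
                [rec.sample_id, rec.species, rec.row_id, str(rec.complete).lower()]
            )


def read_truth(path) -> dict[str, dict]:
    """Truth labels keyed by sample_id; validates schema and uniqueness."""
    labels: dict[str, dict] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, fields in enumerate(reader, start=1):
            if not fields or fields[0].startswith("#"):
                continue
            if lineno == 1 or fields[0] == "sample_id":
                if tuple(fields) != TRUTH_COLUMNS:
                    raise TruthFileError(f"line {lineno}: bad header {fields!r}")
                continue
            if len(fields) != len(TRUTH_COLUMNS):
                raise TruthFileError(
                    f"line {lineno}: expected {len(TRUTH_COLUMNS)} fields, got {len(fields)}"
                )
            sample_id, species, row_id, complete = fields
            if sample_id in labels:
                raise TruthFileError(f"line {lineno}: duplicate sample_id {sample_id!r}")
            if complete not in ("true", "false"):
                raise TruthFileError(f"line {lineno}: bad complete flag {complete!r}")
            labels[sample_id] = {
                "species": species,
                "row_id": row_id,
                "complete": complete == "true",
            }
    return labels
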