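"""Distance-based identification: Best Match and Best Close Match tests.

Both tests are leave-one-out nearest-neighbour identification over a
cohort: a query is *correct* when all of its nearest neighbours (ties
included) are conspecific, *incorrect* when none is, *ambiguous* when the
tie set spans species.  Best Close Match additionally leaves queries
*unidentified* when even the nearest neighbour is farther than a distance
threshold (3% by default).

Distances are uncorrected p-distances over homologous alignment columns.
In ``substitutions_only`` mode only substitution columns are compared —
the indel, minisatellite and homopolymer columns are excluded, as in
SNP-only barcode analyses.  In ``with_indels`` mode each differing
indel/repeat/homopolymer locus additionally counts as one event (added to
both numerator and denominator), reflecting direct sequence comparison of
all mutation classes.  Distances are kept as exact rationals so that
nearest-neighbour ties are resolved exactly, never by float rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from . import characters
from .characters import AnchorSet, CompositeProfile
from .errors import UndefinedDistanceError
from .reference import AMPLICON_LENGTH, LOCI, SNP_NAMES, ReferenceScaffold

_ACGT_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: scaffold columns compared in substitutions_only mode: everything outside
#: the indel, minisatellite and homopolymer loci (SNP sites are included)
_EXCLUDED = np.zeros(AMPLICON_LENGTH, dtype=bool)
for _name in ("del9", "minisat", "homopolymer"):
    _EXCLUDED[slice(*LOCI[_name])] = True
SUBSTITUTION_COLUMNS = np.flatnonzero(~_EXCLUDED)

_ORDERED_LOCI = list(LOCI.items())


@dataclass(frozen=True)
class DistanceConfig:
    mode: str = "substitutions_only"  # or "with_indels"
    threshold: float = 0.03

    def __post_init__(self):
        if self.mode not in ("substitutions_only", "with_indels"):
            raise ValueError(f"unknown distance mode {self.mode!r}")
        if not np.isfinite(self.threshold) or self.threshold < 0:
            raise ValueError("threshold must be finite and non-negative")

    @property
    def threshold_fraction(self) -> Fraction:
        t = self.threshold
        return t if isinstance(t, Fraction) else Fraction(repr(float(t)))


@dataclass(frozen=True)
class ProfiledRecord:
    """A record projected onto scaffold columns, ready for distance computation."""

    sample_id: str
    species: str
    profile: CompositeProfile
    columns: np.ndarray  # uint8 bases over SUBSTITUTION_COLUMNS, 0 where absent
    valid: np.ndarray  # boolean: unambiguous base present

    def __eq__(self, other):  # identity semantics; arrays are payload
        return self is other

    def __hash__(self):
        return id(self)


def project_record(
    seq: str, scaffold: ReferenceScaffold, anchors: AnchorSet | None = None
) -> np.ndarray:
    """Project a record onto scaffold coordinates (uint8 per column, 0 = absent).

    Inter-locus blocks are mapped through the anchored locus spans — an
    implicit alignment that is exact whenever length variation is confined
    to the loci.  If any block length disagrees, the whole record is mapped
    through the global aligner instead.
    """
    seq = seq.upper()
    if anchors is None:
        anchors = AnchorSet.from_scaffold(scaffold)
    spans = characters.locate_loci(seq, anchors, scaffold=scaffold)
    out = np.zeros(AMPLICON_LENGTH, dtype=np.uint8)
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)

    def _copy(sc_start, sc_end, q_start):
        out[sc_start:sc_end] = raw[q_start : q_start + (sc_end - sc_start)]

    prev_end, q_prev_end = 0, 0
    for name, (start, end) in _ORDERED_LOCI:
        span = spans[name]
        if span is None:
            prev_end, q_prev_end = end, None
            continue
        if q_prev_end is not None:
            if span[0] - q_prev_end != start - prev_end:
                return _project_by_alignment(seq, scaffold)
            _copy(prev_end, start, q_prev_end)
        if name in SNP_NAMES and span[1] - span[0] == end - start:
            _copy(start, end, span[0])
        prev_end, q_prev_end = end, span[1]
    if q_prev_end is not None:
        if len(seq) - q_prev_end != AMPLICON_LENGTH - prev_end:
            return _project_by_alignment(seq, scaffold)
        _copy(prev_end, AMPLICON_LENGTH, q_prev_end)
    return out


def _project_by_alignment(seq: str, scaffold: ReferenceScaffold) -> np.ndarray:
    colmap = characters._alignment_column_map(seq, scaffold)
    out = np.zeros(AMPLICON_LENGTH, dtype=np.uint8)
    for col, q in enumerate(colmap):
        if q is not None:
            out[col] = ord(seq[q])
    return out


def profile_cohort(records, scaffold: ReferenceScaffold) -> list[ProfiledRecord]:
    """Profile and project cohort records (objects with sample_id/species/sequence)."""
    anchors = AnchorSet.from_scaffold(scaffold)
    out = []
    for rec in records:
        profile = characters.extract_profile(rec.sequence, scaffold, anchors)
        proj = project_record(rec.sequence, scaffold, anchors)[SUBSTITUTION_COLUMNS]
        out.append(
            ProfiledRecord(
                sample_id=rec.sample_id,
                species=rec.species,
                profile=profile,
                columns=proj,
                valid=np.isin(proj, _ACGT_BYTES),
            )
        )
    return out


def filter_dataset(records: list[ProfiledRecord]) -> list[ProfiledRecord]:
    """Identification-test filter: drop partial profiles, then singleton species."""
    complete = [r for r in records if not r.profile.partial]
    per_species: dict[str, int] = {}
    for r in complete:
        per_species[r.species] = per_species.get(r.species, 0) + 1
    return [r for r in complete if per_species[r.species] > 1]


def pdistance(a: ProfiledRecord, b: ProfiledRecord, config: DistanceConfig) -> Fraction:
    """Uncorrected p-distance between two projected records, as an exact Fraction."""
    valid = a.valid & b.valid
    den = int(valid.sum())
    num = int(((a.columns != b.columns) & valid).sum())
    if config.mode == "with_indels":
        for pa, pb in (
            (a.profile.deletion9, b.profile.deletion9),
            (a.profile.minisat, b.profile.minisat),
            (a.profile.homopolymer, b.profile.homopolymer),
        ):
            if pa is not None and pb is not None and pa != pb:
                num += 1
                den += 1
    if den == 0:
        raise UndefinedDistanceError(
            f"no comparable columns between {a.sample_id} and {b.sample_id}"
        )
    return Fraction(num, den)


@dataclass(frozen=True)
class IdentificationOutcome:
    sample_id: str
    best_distance: Fraction
    best_match_species: frozenset
    outcome: str  # correct | ambiguous | incorrect | unidentified


def _nearest(dataset, config):
    n = len(dataset)
    if n < 2:
        raise ValueError("identification tests need at least two records")
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = pdistance(dataset[i], dataset[j], config)
    for i in range(n):
        best = min(dist[tuple(sorted((i, j)))] for j in range(n) if j != i)
        neighbours = frozenset(
            dataset[j].species
            for j in range(n)
            if j != i and dist[tuple(sorted((i, j)))] == best
        )
        yield dataset[i], best, neighbours


def _classify(query_species, neighbours) -> str:
    if neighbours == {query_species}:
        return "correct"
    if query_species in neighbours:
        return "ambiguous"
    return "incorrect"


def best_match(dataset: list[ProfiledRecord], config: DistanceConfig) -> list[IdentificationOutcome]:
    """Leave-one-out Best Match test over a filtered dataset."""
    return [
        IdentificationOutcome(rec.sample_id, best, neighbours, _classify(rec.species, neighbours))
        for rec, best, neighbours in _nearest(dataset, config)
    ]


def best_close_match(
    dataset: list[ProfiledRecord], config: DistanceConfig
) -> list[IdentificationOutcome]:
    """Best Close Match: as Best Match, but distant queries become unidentified."""
    ceiling = config.threshold_fraction
    out = []
    for rec, best, neighbours in _nearest(dataset, config):
        outcome = "unidentified" if best > ceiling else _classify(rec.species, neighbours)
        out.append(IdentificationOutcome(rec.sample_id, best, neighbours, outcome))
    return out


OUTCOME_CLASSES = ("correct", "ambiguous", "incorrect", "unidentified")


def summarize_outcomes(outcomes: list[IdentificationOutcome]) -> dict:
    """Percentage of queries per outcome class, rounded to two decimals."""
    from .haplokey import round_half_up

    if not outcomes:
        raise ValueError("no outcomes to summarize")
    counts = {c: 0 for c in OUTCOME_CLASSES}
    for o in outcomes:
        counts[o.outcome] += 1
    n = len(outcomes)
    summary = {"n_queries": n}
    for c in OUTCOME_CLASSES:
        summary[f"pct_{c}"] = round_half_up(counts[c], n, 2)
        summary[f"n_{c}"] = counts[c]
    return summary
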