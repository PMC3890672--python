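"""Diagnostic haplotype key: private/shared profiles and species diagnosability.

The key is the observed mapping from composite profiles to the species (and
individual counts) they were recorded in.  A profile found in exactly one
species is *private* — diagnostic for that species — while profiles shared
by two or more species are ambiguous.  A species is *diagnosable* when
every one of its observed profiles is private, in which case any individual
carrying one of those profiles is unambiguously assigned; this is also the
basis for identifying the maternal (seed) parent of hybrids from their
inherited chloroplast haplotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .characters import CompositeProfile, profile_from_row
from .errors import LabelError
from .reference import KeyRow

logger = logging.getLogger(__name__)


def round_half_up(numerator: int, denominator: int, ndigits: int) -> float:
    """Percentage ``100 * numerator / denominator`` rounded half-up."""
    q = Decimal(100 * numerator) / Decimal(denominator)
    return float(q.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class HaplotypeKey:
    """Map from complete composite profiles to per-species individual counts."""

    entries: dict  # CompositeProfile -> {species: count}
    n_individuals: int

    def species(self) -> frozenset:
        return frozenset(s for counts in self.entries.values() for s in counts)


@dataclass(frozen=True)
class SharingSummary:
    pct_single: float
    pct_two: float
    pct_three_plus: float
    n_single: int
    n_two: int
    n_three_plus: int
    diagnosable: frozenset


def build_key(profiles: dict, labels: dict) -> HaplotypeKey:
    """Build the key from per-sample profiles and species labels.

    Partial profiles are excluded (their number is logged); equality of
    profiles is exact equality of every character slot, homopolymer run
    lengths included.
    """
    entries: dict[CompositeProfile, dict[str, int]] = {}
    n_partial = 0
    n_counted = 0
    for sample_id, profile in profiles.items():
        if sample_id not in labels:
            raise LabelError(f"sample {sample_id!r} has no species label")
        if profile.partial:
            n_partial += 1
            continue
        species = labels[sample_id]
        counts = entries.setdefault(profile, {})
        counts[species] = counts.get(species, 0) + 1
        n_counted += 1
    if n_partial:
        logger.info("excluded %d partial profiles from key construction", n_partial)
    return HaplotypeKey(entries=entries, n_individuals=n_counted)


def build_key_from_rows(rows: list[KeyRow]) -> HaplotypeKey:
    """Build the key directly from a pre-counted character matrix."""
    entries: dict[CompositeProfile, dict[str, int]] = {}
    total = 0
    for row in rows:
        profile = profile_from_row(row)
        counts = entries.setdefault(profile, {})
        counts[row.species] = counts.get(row.species, 0) + row.count
        total += row.count
    return HaplotypeKey(entries=entries, n_individuals=total)


def diagnosable_species(key: HaplotypeKey) -> frozenset:
    """Species whose every observed profile is private to them."""
    if not key.entries:
        raise ValueError("empty key")
    bad = set()
    for counts in key.entries.values():
        if len(counts) > 1:
            bad.update(counts)
    return key.species() - bad


def summarize_sharing(key: HaplotypeKey) -> SharingSummary:
    """Partition of counted individuals by how many species share their profile."""
    if not key.entries:
        raise ValueError("empty key")
    n = [0, 0, 0]  # single, two, three-plus
    for counts in key.entries.values():
        bucket = min(len(counts), 3) - 1
        n[bucket] += sum(counts.values())
    total = key.n_individuals
    return SharingSummary(
        pct_single=round_half_up(n[0], total, 1),
        pct_two=round_half_up(n[1], total, 1),
        pct_three_plus=round_half_up(n[2], total, 1),
        n_single=n[0],
        n_two=n[1],
        n_three_plus=n[2],
        diagnosable=diagnosable_species(key),
    )


def identify_candidates(profile: CompositeProfile, key: HaplotypeKey):
    """Candidate species compatible with every non-missing slot of a query profile.

    Returns ``(species, match_class)`` with match_class one of
    ``"unique"``, ``"ambiguous"``, ``"no_match"``.  Partial profiles are
    legitimate queries: missing slots constrain nothing.
    """
    candidates: set[str] = set()
    for entry, counts in key.entries.items():
        if _compatible(profile, entry):
            candidates.update(counts)
    if not candidates:
        match_class = "no_match"
    elif len(candidates) == 1:
        match_class = "unique"
    else:
        match_class = "ambiguous"
    return frozenset(candidates), match_class


def _compatible(query: CompositeProfile, entry: CompositeProfile) -> bool:
    for q, e in zip(query.snp_states, entry.snp_states):
        if q is not None and q != e:
            return False
    if query.deletion9 is not None and query.deletion9 != entry.deletion9:
        return False
    if query.minisat is not None and query.minisat != entry.minisat:
        return False
    if query.homopolymer is not None and query.homopolymer != entry.homopolymer:
        return False
    return True
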