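"""Best Match / Best Close Match tests, p-distances and the dataset filter."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phoenixbarcode import identification
from phoenixbarcode.characters import profile_from_row
from phoenixbarcode.errors import UndefinedDistanceError
from phoenixbarcode.identification import (
    SUBSTITUTION_COLUMNS,
    DistanceConfig,
    ProfiledRecord,
    best_close_match,
    best_match,
    filter_dataset,
    pdistance,
    summarize_outcomes,
)

CFG = DistanceConfig()


def make_record(sample_id, species, vector, profile=None):
    """A minimal ProfiledRecord around a raw base vector (for oracle tests)."""
    arr = np.frombuffer("".join(vector).encode(), dtype=np.uint8)
    return ProfiledRecord(
        sample_id=sample_id,
        species=species,
        profile=profile,
        columns=arr,
        valid=np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8)),
    )


def oracle_outcomes(records, threshold=None):
    """Independent all-pairs nearest-neighbour oracle using plain Python."""

    def dist(a, b):
        pairs = [
            (x, y)
            for x, y, va, vb in zip(a.columns, b.columns, a.valid, b.valid)
            if va and vb
        ]
        return Fraction(sum(x != y for x, y in pairs), len(pairs))

    out = {}
    for q in records:
        ds = [(dist(q, r), r.species) for r in records if r is not q]
        best = min(d for d, _ in ds)
        neighbours = {s for d, s in ds if d == best}
        if threshold is not None and best > Fraction(str(threshold)):
            out[q.sample_id] = "unidentified"
        elif neighbours == {q.species}:
            out[q.sample_id] = "correct"
        elif q.species in neighbours:
            out[q.sample_id] = "ambiguous"
        else:
            out[q.sample_id] = "incorrect"
    return out


class TestFilter:
    def test_default_cohort_retains_121_records_in_11_species(self, profiled_cohort):
        retained = filter_dataset(profiled_cohort)
        assert len(retained) == 121
        species = {r.species for r in retained}
        assert len(species) == 11
        assert {"acaulis", "atlantica"}.isdisjoint(species)

    def test_two_records_of_one_species_are_both_kept(self, profiled_cohort):
        caespitosa = [r for r in profiled_cohort if r.species == "caespitosa"]
        assert filter_dataset(caespitosa) == caespitosa

    def test_singletons_only_yields_empty(self, profiled_cohort):
        singles = [
            next(r for r in profiled_cohort if r.species == "caespitosa"),
            next(r for r in profiled_cohort if r.species == "pusilla"),
        ]
        assert filter_dataset(singles) == []


class TestPDistance:
    def test_identical_records_have_zero_distance(self, profiled_cohort):
        a = next(r for r in profiled_cohort if not r.profile.partial)
        assert pdistance(a, a, CFG) == 0

    def test_one_snp_over_619_compared_columns(self, profiled_cohort):
        # caespitosa and rupicola rows differ at a single SNP (site 37183)
        a = next(r for r in profiled_cohort if r.species == "caespitosa")
        b = next(r for r in profiled_cohort if r.species == "rupicola")
        assert len(SUBSTITUTION_COLUMNS) == 700 - 9 - 60 - 12 == 619
        assert pdistance(a, b, CFG) == Fraction(1, 619)

    def test_matches_brute_force_snp_count_between_all_row_pairs(
        self, profiled_cohort, default_cohort, matrix_rows
    ):
        by_row = {}
        truth = {r.sample_id: r.row_id for r in default_cohort}
        for rec in profiled_cohort:
            if not rec.profile.partial:
                by_row.setdefault(truth[rec.sample_id], rec)
        rows = {r.row_id: r for r in matrix_rows}
        for ra, a in by_row.items():
            for rb, b in by_row.items():
                expected = sum(
                    x != y for x, y in zip(rows[ra].snp_states, rows[rb].snp_states)
                )
                assert pdistance(a, b, CFG) == Fraction(expected, 619)

    def test_with_indels_mode_counts_locus_events(self, profiled_cohort, default_cohort):
        truth = {r.sample_id: r.row_id for r in default_cohort}
        by_row = {truth[r.sample_id]: r for r in profiled_cohort if not r.profile.partial}
        cfg = DistanceConfig(mode="with_indels")
        # r12 vs r17: same SNPs, minisatellite haplotype 3 vs 2 -> one event
        assert pdistance(by_row["r12"], by_row["r17"], cfg) == Fraction(1, 620)
        # r12 vs r01: minisatellite differs only -> 1/620; substitutions-only 0
        assert pdistance(by_row["r12"], by_row["r01"], CFG) == 0
        assert pdistance(by_row["r12"], by_row["r01"], cfg) == Fraction(1, 620)
        # r12 vs r09: deletion + minisatellite + homopolymer all differ
        assert pdistance(by_row["r12"], by_row["r09"], cfg) == Fraction(3, 622)

    def test_symmetry(self, profiled_cohort):
        recs = [r for r in profiled_cohort if not r.profile.partial][:10]
        for a in recs:
            for b in recs:
                assert pdistance(a, b, CFG) == pdistance(b, a, CFG)

    def test_no_comparable_columns_is_an_error(self):
        a = make_record("a", "x", "NN")
        b = make_record("b", "y", "NN")
        with pytest.raises(UndefinedDistanceError):
            pdistance(a, b, CFG)


class TestBestMatch:
    def test_conspecific_pair_plus_outlier(self):
        data = [
            make_record("x1", "A", "AAAA"),
            make_record("x2", "A", "AAAA"),
            make_record("y1", "B", "TTTT"),
        ]
        outcomes = {o.sample_id: o.outcome for o in best_match(data, CFG)}
        assert outcomes == {"x1": "correct", "x2": "correct", "y1": "incorrect"}

    def test_tie_spanning_species_is_ambiguous(self):
        data = [
            make_record("x1", "A", "AAAA"),
            make_record("y1", "B", "AAAA"),
            make_record("x2", "A", "AAAA"),
        ]
        outcomes = {o.sample_id: o.outcome for o in best_match(data, CFG)}
        assert outcomes["x1"] == "ambiguous"

    def test_identical_conspecific_dataset_is_all_correct(self):
        data = [make_record(f"s{i}", "A", "ACGT") for i in range(4)]
        assert all(o.outcome == "correct" for o in best_match(data, CFG))

    def test_fewer_than_two_records_rejected(self):
        with pytest.raises(ValueError):
            best_match([make_record("a", "x", "AC")], CFG)

    @given(st.data())
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_agrees_with_brute_force_oracle(self, data):
        n = data.draw(st.integers(min_value=2, max_value=30))
        species_pool = ["A", "B", "C", "D"]
        records = []
        for i in range(n):
            sp = data.draw(st.sampled_from(species_pool))
            vec = data.draw(
                st.lists(st.sampled_from("ACGTN"), min_size=12, max_size=12)
            )
            records.append(make_record(f"s{i}", sp, vec))
        try:
            got = {o.sample_id: o.outcome for o in best_match(records, CFG)}
        except UndefinedDistanceError:
            return
        assert got == oracle_outcomes(records)
        got_bcm = {o.sample_id: o.outcome for o in best_close_match(records, CFG)}
        assert got_bcm == oracle_outcomes(records, threshold=CFG.threshold)


class TestBestCloseMatch:
    def test_threshold_zero_with_distinct_sequences_all_unidentified(self):
        data = [
            make_record("a", "A", "AAAA"),
            make_record("b", "A", "AAAT"),
            make_record("c", "B", "AATT"),
        ]
        cfg = DistanceConfig(threshold=0.0)
        assert all(o.outcome == "unidentified" for o in best_close_match(data, cfg))

    def test_zero_distance_conspecific_duplicate_is_correct(self):
        data = [
            make_record("a", "A", "AAAA"),
            make_record("b", "A", "AAAA"),
            make_record("c", "B", "TTTT"),
        ]
        out = {o.sample_id: o.outcome for o in best_close_match(data, CFG)}
        assert out["a"] == "correct"

    def test_default_cohort_bcm_equals_bm(self, profiled_cohort):
        dataset = filter_dataset(profiled_cohort)
        bm = best_match(dataset, CFG)
        bcm = best_close_match(dataset, CFG)
        assert [o.outcome for o in bm] == [o.outcome for o in bcm]
        assert max(o.best_distance for o in bm) <= Fraction(3, 100)

    def test_unidentified_count_non_increasing_in_threshold(self):
        data = [
            make_record("a", "A", "AAAAAAAA"),
            make_record("b", "A", "AAAATTTT"),
            make_record("c", "B", "TTTTTTTT"),
            make_record("d", "B", "TTTTAAAA"),
        ]
        counts = []
        for t in (0.0, 0.25, 0.5, 1.0):
            cfg = DistanceConfig(threshold=t)
            outs = best_close_match(data, cfg)
            counts.append(sum(o.outcome == "unidentified" for o in outs))
        assert counts == sorted(counts, reverse=True)


class TestSummaries:
    def test_percentages_at_two_decimals(self):
        outcomes = (
            [make_outcome("correct")] * 100
            + [make_outcome("ambiguous")] * 18
            + [make_outcome("incorrect")] * 3
        )
        s = summarize_outcomes(outcomes)
        assert s["pct_correct"] == 82.64
        assert s["pct_ambiguous"] == 14.88
        assert s["pct_incorrect"] == 2.48

    def test_all_correct(self):
        s = summarize_outcomes([make_outcome("correct")] * 5)
        assert (s["pct_correct"], s["pct_ambiguous"], s["pct_incorrect"],
                s["pct_unidentified"]) == (100.0, 0.0, 0.0, 0.0)

    def test_empty_outcomes_raise(self):
        with pytest.raises(ValueError):
            summarize_outcomes([])

    def test_species_relabelling_preserves_summary(self, profiled_cohort):
        dataset = filter_dataset(profiled_cohort)
        renamed = [
            ProfiledRecord(
                sample_id=r.sample_id,
                species="sp_" + r.species[::-1],
                profile=r.profile,
                columns=r.columns,
                valid=r.valid,
            )
            for r in dataset
        ]
        s1 = summarize_outcomes(best_match(dataset, CFG))
        s2 = summarize_outcomes(best_match(renamed, CFG))
        assert s1 == s2


def make_outcome(outcome):
    return identification.IdentificationOutcome(
        sample_id="q", best_distance=Fraction(0), best_match_species=frozenset(), outcome=outcome
    )
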