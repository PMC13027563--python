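"""Diagnostic ratio indices: worked values, identities and summaries."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dendromorph import (
    CohortTable,
    SpecimenRecord,
    Taxon,
    ValidationError,
    arc_excess_summary,
    cohort_index_table,
    compute_index_profile,
    percent_difference,
)
from .test_cohort import make_record


class TestComputeIndexProfile:
    def test_published_sibiricus_means_reproduce_index_means(self, sibiricus_mean_record):
        # ratio of published structure means vs published index means
        prof = compute_index_profile(sibiricus_mean_record)
        assert prof.hl_vl == pytest.approx(0.656, abs=0.005)
        assert prof.cgpi_straight == pytest.approx(0.852, abs=0.010)
        assert prof.cl_al_arc == pytest.approx(0.039, abs=0.001)

    def test_unit_record_gives_unit_indices(self):
        rec = SpecimenRecord(
            specimen_id="unit", taxon="pini",
            valva_length=1, harpe_length=1, aedeagus_length_straight=1,
            aedeagus_length_arc=1, aedeagus_width=1, cornuti=(1,),
        )
        prof = compute_index_profile(rec)
        for col, value in prof.as_dict().items():
            assert value == pytest.approx(1.0), col

    def test_doubling_arc_halves_arc_variants(self):
        rec = make_record(aedeagus_length_arc=2 * 3.7)
        prof = compute_index_profile(rec)
        assert prof.aw_al_arc == pytest.approx(prof.aw_al_straight / 2)

    def test_missing_cornuti_leaves_dependent_indices_absent(self):
        prof = compute_index_profile(make_record(cornuti=()))
        assert prof.cl_al_straight is None
        assert prof.cgpi_arc is None
        assert prof.hl_vl is not None

    measurement = st.floats(0.05, 10.0)

    @settings(max_examples=50, deadline=None)
    @given(measurement, measurement, measurement, st.floats(1.0, 2.0),
           measurement, measurement)
    def test_arc_straight_ratio_identity(self, vl, hl, al_s, arc_factor, aw, cl):
        # CL/AL_arc divided by CL/AL_straight must equal AL_s/AL_a exactly
        rec = SpecimenRecord(
            specimen_id="r", taxon="hybrid",
            valva_length=vl, harpe_length=hl,
            aedeagus_length_straight=al_s, aedeagus_length_arc=al_s * arc_factor,
            aedeagus_width=aw, cornuti=(cl,),
        )
        prof = compute_index_profile(rec)
        assert prof.cl_al_arc / prof.cl_al_straight == pytest.approx(
            al_s / rec.aedeagus_length_arc
        )

    @settings(max_examples=30, deadline=None)
    @given(st.floats(0.1, 50.0))
    def test_scale_invariance(self, k):
        record = make_record("scale", cornuti=(0.18, 0.22))
        prof = compute_index_profile(record)
        scaled = compute_index_profile(record.scaled(k))
        for col, value in prof.as_dict().items():
            assert scaled.as_dict()[col] == pytest.approx(value, rel=1e-9), col


class TestPercentDifference:
    @pytest.mark.parametrize(
        "ref,other,expected_rounded",
        [
            (2.002, 1.356, 32),   # valva
            (1.312, 0.339, 74),   # harpe
            (0.798, 0.576, 28),   # aedeagus width
            (3.712, 2.663, 28),   # aedeagus straight length
        ],
    )
    def test_published_species_contrasts(self, ref, other, expected_rounded):
        assert round(percent_difference(ref, other)) == expected_rounded

    def test_equal_means_give_zero(self):
        assert percent_difference(1.5, 1.5) == 0.0

    def test_non_positive_reference_rejected(self):
        with pytest.raises(ValidationError):
            percent_difference(0.0, 1.0)


class TestArcExcess:
    def test_published_means_average_to_27_percent(self):
        means = {
            "sibiricus": (3.712, 4.844),
            "hybrid": (3.315, 4.194),
            "pini": (2.663, 3.295),
        }
        table = arc_excess_summary(means).set_index("taxon")["percent_excess"]
        assert table["sibiricus"] == pytest.approx(30.5, abs=0.1)
        assert table["hybrid"] == pytest.approx(26.5, abs=0.1)
        assert table["pini"] == pytest.approx(23.7, abs=0.1)
        assert table["grand"] == pytest.approx(26.9, abs=0.1)

    def test_equal_lengths_give_zero(self):
        table = arc_excess_summary({"pini": (2.0, 2.0)})
        assert (table["percent_excess"] == 0).all()

    def test_single_taxon_grand_equals_taxon(self):
        table = arc_excess_summary({"pini": (2.0, 2.5)}).set_index("taxon")
        assert table.loc["grand", "percent_excess"] == pytest.approx(
            table.loc["pini", "percent_excess"]
        )


class TestCohortIndexTable:
    def test_identical_records_have_zero_sd(self):
        cohort = CohortTable(tuple(make_record(f"s{i}") for i in range(4)))
        table = cohort_index_table(cohort)
        assert (table["sd"].dropna() == 0).all()

    def test_cornuti_free_taxon_flagged_absent(self):
        cohort = CohortTable((make_record("a", cornuti=()), make_record("b", cornuti=())))
        table = cohort_index_table(cohort)
        cl_rows = table[table["index"].isin(["cl_al", "cgpi"])]
        assert (cl_rows["n"] == 0).all()
        assert cl_rows["mean"].isna().all()

    def test_seeded_cohort_mean_hl_vl_matches_reference(self, default_cohort):
        # published sibiricus HL/VL 0.656 +- 0.069 (n=33)
        table = cohort_index_table(default_cohort)
        row = table[(table["taxon"] == "sibiricus") & (table["index"] == "hl_vl")]
        se = 0.069 / math.sqrt(33)
        assert abs(float(row["mean"].iloc[0]) - 0.656) < 3 * se

    def test_mean_of_ratios_close_to_ratio_of_means(self, default_cohort):
        # at the observed coefficients of variation the Jensen gap between
        # the two constructions stays below 1% relative
        from dendromorph.pipeline import _structure_frame

        table = cohort_index_table(default_cohort).set_index(["taxon", "index", "variant"])
        struct = _structure_frame(default_cohort)
        for taxon in ("sibiricus", "pini"):
            sub = struct[struct["taxon"] == taxon]
            ratio_of_means = sub["HL"].mean() / sub["VL"].mean()
            mean_of_ratios = float(table.loc[(taxon, "hl_vl", "na"), "mean"])
            assert mean_of_ratios == pytest.approx(ratio_of_means, rel=0.01)

    def test_hybrid_minmax_inside_truncation_envelope(self, default_cohort):
        table = cohort_index_table(default_cohort).set_index(["taxon", "index", "variant"])
        row = table.loc[("hybrid", "hl_vl", "na")]
        assert 0.317 <= row["min"] <= row["max"] <= 0.503
        row = table.loc[("hybrid", "cgpi", "straight")]
        assert 0.568 <= row["min"] <= row["max"] <= 0.664
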