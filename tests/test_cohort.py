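"""Data model, CSV round-tripping and descriptive summaries."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dendromorph import (
    CohortTable,
    SchemaError,
    SpecimenRecord,
    Taxon,
    ValidationError,
    cornuti_mean,
    read_specimen_table,
    summarize_structure_by_taxon,
    write_specimen_table,
)
from dendromorph.cohort import CSV_COLUMNS


def make_record(specimen_id="s1", taxon="sibiricus", **overrides):
    base = dict(
        valva_length=2.0,
        harpe_length=1.3,
        aedeagus_length_straight=3.7,
        aedeagus_length_arc=4.8,
        aedeagus_width=0.8,
        cornuti=(0.18, 0.19, 0.20),
        region="Krasnoyarsk",
        year="1956",
        depository="ZIN",
    )
    base.update(overrides)
    return SpecimenRecord(specimen_id=specimen_id, taxon=taxon, **base)


class TestSpecimenRecord:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("valva_length", -1.0),
            ("harpe_length", 0.0),
            ("aedeagus_width", float("nan")),
            ("cornuti", (0.2, -0.1)),
        ],
    )
    def test_non_positive_measurements_rejected(self, field, value):
        with pytest.raises(ValidationError):
            make_record(**{field: value})

    def test_arc_shorter_than_straight_rejected(self):
        with pytest.raises(ValidationError, match="arc"):
            make_record(aedeagus_length_arc=3.0, aedeagus_length_straight=3.7)

    def test_more_than_ten_cornuti_rejected(self):
        with pytest.raises(ValidationError, match="10"):
            make_record(cornuti=tuple([0.2] * 11))

    def test_harpe_exceeding_valva_warns_but_passes(self, caplog):
        # hybrid/sibiricus HL/VL approaches 1; above 1.2 is only a warning
        with caplog.at_level("WARNING"):
            rec = make_record(harpe_length=2.6, valva_length=2.0)
        assert rec.harpe_length == 2.6
        assert any("HL/VL" in m for m in caplog.messages)

    def test_unknown_taxon_accepted_case_insensitive(self):
        assert make_record(taxon="UNKNOWN").taxon is Taxon.UNKNOWN


class TestCornutiMean:
    def test_simple_means(self):
        assert cornuti_mean(make_record(cornuti=(0.2, 0.2, 0.2))) == pytest.approx(0.2)
        assert cornuti_mean(make_record(cornuti=(0.1, 0.3))) == pytest.approx(0.2)
        # ten equal cornuti reproduce the published sibiricus mean exactly
        assert cornuti_mean(make_record(cornuti=(0.188,) * 10)) == pytest.approx(0.188)

    def test_empty_cornuti_is_an_error(self):
        rec = make_record(cornuti=())
        with pytest.raises(ValidationError, match="cornuti required"):
            cornuti_mean(rec)

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(0.01, 2.0), min_size=1, max_size=10),
        st.randoms(use_true_random=False),
    )
    def test_permutation_invariance(self, cornuti, rnd):
        rec = make_record(cornuti=tuple(cornuti))
        shuffled = list(cornuti)
        rnd.shuffle(shuffled)
        rec2 = make_record(cornuti=tuple(shuffled))
        assert cornuti_mean(rec) == pytest.approx(cornuti_mean(rec2))


class TestCohortTable:
    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError, match="at least one record"):
            CohortTable(())

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            CohortTable((make_record("a"), make_record("a")))


class TestCsvRoundTrip:
    def test_write_read_identity(self, default_cohort, tmp_path):
        path = write_specimen_table(default_cohort, tmp_path / "cohort.csv")
        back = read_specimen_table(path)
        assert back.records == default_cohort.records

    def test_default_cohort_counts(self, default_cohort, tmp_path):
        path = write_specimen_table(default_cohort, tmp_path / "cohort.csv")
        back = read_specimen_table(path)
        counts = {t.value: n for t, n in back.taxon_counts().items()}
        assert counts == {"sibiricus": 33, "pini": 33, "hybrid": 4}

    def test_ten_cornuti_round_trip(self, default_cohort, tmp_path):
        path = write_specimen_table(default_cohort, tmp_path / "cohort.csv")
        back = read_specimen_table(path)
        assert all(len(rec.cornuti) == 10 for rec in back)

    def test_missing_optional_metadata_round_trips(self, tmp_path):
        cohort = CohortTable((make_record(region="", year="", depository=""),))
        back = read_specimen_table(write_specimen_table(cohort, tmp_path / "c.csv"))
        assert back.records == cohort.records

    def test_missing_mandatory_column_names_it(self, default_cohort, tmp_path):
        path = write_specimen_table(default_cohort, tmp_path / "cohort.csv")
        text = path.read_text().replace("harpe_length_mm", "harpe")
        bad = tmp_path / "bad.csv"
        bad.write_text(text)
        with pytest.raises(SchemaError, match="harpe_length_mm"):
            read_specimen_table(bad)

    def test_invalid_row_strict_vs_lenient(self, tmp_path):
        header = ",".join(CSV_COLUMNS)
        good = "g1,pini,,,,1.3,0.3,2.6,3.3,0.5" + ",0.2" + "," * 9
        bad = "b1,pini,,,,1.3,0.3,3.3,2.6,0.5" + ",0.2" + "," * 9  # arc < straight
        path = tmp_path / "mixed.csv"
        path.write_text("\n".join([header, good, bad]) + "\n")
        with pytest.raises(ValidationError, match="b1"):
            read_specimen_table(path, strict=True)
        cohort = read_specimen_table(path, strict=False)
        assert [r.specimen_id for r in cohort] == ["g1"]


class TestSummaries:
    def test_identical_records_have_zero_sd(self):
        cohort = CohortTable(tuple(make_record(f"s{i}") for i in range(5)))
        table = summarize_structure_by_taxon(cohort)
        vl = table[(table["structure"] == "VL")].iloc[0]
        assert vl["sd"] == pytest.approx(0.0)
        assert vl["min"] == vl["max"] == vl["mean"] == pytest.approx(2.0)

    def test_single_specimen_taxon_sd_undefined(self):
        cohort = CohortTable((make_record("h1", taxon="hybrid"),))
        table = summarize_structure_by_taxon(cohort)
        assert table["n"].eq(1).all()
        assert table["sd"].isna().all()

    def test_generator_matches_published_valva_mean(self, default_cohort):
        # published sibiricus valva 2.002 +- 0.226 (n=33): the seeded
        # synthetic cohort should land within 3 standard errors
        table = summarize_structure_by_taxon(default_cohort)
        row = table[(table["taxon"] == "sibiricus") & (table["structure"] == "VL")]
        se = 0.226 / math.sqrt(33)
        assert abs(float(row["mean"].iloc[0]) - 2.002) < 3 * se

    def test_missing_cornuti_tracked_separately(self):
        cohort = CohortTable(
            (make_record("a"), make_record("b", cornuti=()))
        )
        table = summarize_structure_by_taxon(cohort)
        cl = table[table["structure"] == "CL"].iloc[0]
        assert cl["n"] == 1
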