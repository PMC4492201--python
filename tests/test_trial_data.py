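"""Cohort data model, fixture integrity and CSV round-trip."""

import dataclasses

import pytest

import chemorad as cr
from chemorad.trial_data import (
    CSV_COLUMNS,
    ChemoCategory,
    CohortTable,
    Modality,
    SchemaError,
    TreatmentSchedule,
    TrialCohort,
    ValidationError,
    derive_survivor_count,
    read_cohorts,
    write_cohorts,
)


@pytest.mark.parametrize(
    "fraction,n_total,expected",
    [
        (0.07, 28, 2),  # 1.96 rounds to nearest
        (0.0, 50, 0),
        (0.50, 16, 8),
        (0.10, 25, 3),  # 2.5 tie rounds half away from zero
        (1.0, 7, 7),
    ],
)
def test_survivor_count_reconstruction(fraction, n_total, expected):
    assert derive_survivor_count(fraction, n_total) == expected


def test_survivor_count_rejects_bad_inputs():
    with pytest.raises(ValidationError):
        derive_survivor_count(1.2, 10)
    with pytest.raises(ValidationError):
        derive_survivor_count(0.5, 0)


class TestTreatmentSchedule:
    def test_total_dose_defaults_to_product(self):
        s = TreatmentSchedule(Modality.XRAY, 1.8, 28, fractions_per_week=5)
        assert s.total_dose == pytest.approx(50.4)

    def test_inconsistent_total_dose_rejected(self):
        with pytest.raises(ValidationError):
            TreatmentSchedule(
                Modality.XRAY, 1.8, 28, total_dose=55.0, fractions_per_week=5
            )

    def test_requires_exactly_one_time_convention(self):
        with pytest.raises(ValidationError):
            TreatmentSchedule(Modality.XRAY, 2.0, 10)
        with pytest.raises(ValidationError):
            TreatmentSchedule(
                Modality.XRAY, 2.0, 10, fractions_per_week=5, overall_time_days=12
            )

    def test_total_dose_outside_printed_range_rejected(self):
        with pytest.raises(ValidationError):
            TreatmentSchedule(
                Modality.XRAY,
                2.0,
                10,
                dose_low=25.0,
                dose_high=28.0,
                fractions_per_week=5,
            )


class TestTrialCohort:
    def _schedule(self):
        return TreatmentSchedule(Modality.XRAY, 2.0, 10, fractions_per_week=5)

    def test_survivors_derived_when_absent(self):
        c = TrialCohort(
            "x", 2000, self._schedule(), ChemoCategory.NONE, 28, 0.07
        )
        assert c.n_survivors_1y == 2

    def test_zero_patients_rejected(self):
        with pytest.raises(ValidationError):
            TrialCohort("x", 2000, self._schedule(), ChemoCategory.NONE, 0, 0.5)

    def test_survivors_inconsistent_with_fraction_rejected(self):
        with pytest.raises(ValidationError):
            TrialCohort(
                "x",
                2000,
                self._schedule(),
                ChemoCategory.NONE,
                28,
                0.07,
                n_survivors_1y=10,
            )

    def test_excluded_cohort_needs_reason(self):
        with pytest.raises(ValidationError):
            TrialCohort(
                "x",
                2000,
                self._schedule(),
                ChemoCategory.NONE,
                28,
                0.07,
                included_in_fit=False,
            )


def test_fixture_row_counts(fixtures):
    """Fixtures hold exactly the source tables' arm counts."""
    assert {name: len(t) for name, t in fixtures.items()} == {
        "table1": 5,
        "table2": 18,
        "table4": 27,
        "table5": 10,
        "table6": 6,
    }


def test_fixture_chemo_categories(fixtures):
    assert {c.chemo_category for c in fixtures["table1"]} == {ChemoCategory.NONE}
    assert {c.chemo_category for c in fixtures["table2"]} == {
        ChemoCategory.GEMCITABINE
    }
    assert {c.chemo_category for c in fixtures["table4"]} == {ChemoCategory.OTHER}
    assert {c.chemo_category for c in fixtures["table5"]} == {
        ChemoCategory.GEM_PLUS_OTHER
    }


def test_first_fixture_row_is_oldest_rt_alone_cohort(fixtures):
    c = fixtures["table1"].cohorts[0]
    assert c.study_label == "Moertel 1969"
    assert c.n_total == 28
    assert c.os1y_fraction == pytest.approx(0.07)
    assert c.n_survivors_1y == 2
    assert c.schedule.dose_low == 35 and c.schedule.dose_high == 40


def test_every_excluded_fixture_row_has_a_reason(fixtures):
    excluded = [
        c for t in fixtures.values() for c in t if not c.included_in_fit
    ]
    # the two carbon-ion monotherapy arms are flagged out of the particle fit
    assert len(excluded) == 2
    assert all(c.exclusion_reason for c in excluded)
    assert all(c.schedule.modality is Modality.CARBON for c in excluded)


def test_fixture_csv_round_trip_is_lossless(fixtures, tmp_path):
    for name, table in fixtures.items():
        path = write_cohorts(table, tmp_path / f"{name}.csv")
        again = read_cohorts(path, source_label=table.source_label)
        assert again == table


def test_round_trip_preserves_particle_modalities(fixtures, tmp_path):
    path = write_cohorts(fixtures["table6"], tmp_path / "t6.csv")
    again = read_cohorts(path)
    for a, b in zip(again, fixtures["table6"]):
        assert dataclasses.asdict(a) == dataclasses.asdict(b)


def test_empty_file_with_valid_header_reads_as_empty_table(tmp_path):
    empty = CohortTable((), "empty")
    path = write_cohorts(empty, tmp_path / "empty.csv")
    assert len(read_cohorts(path)) == 0


def test_missing_schema_line_and_columns_rejected(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text(",".join(CSV_COLUMNS) + "\n")
    with pytest.raises(SchemaError):
        read_cohorts(path)
    path.write_text("# cohort-csv v1\nstudy_label,year\n")
    with pytest.raises(SchemaError):
        read_cohorts(path)


def test_invalid_rows_reported_with_line_numbers(tmp_path, fixtures):
    path = write_cohorts(fixtures["table1"], tmp_path / "t1.csv")
    text = path.read_text().replace(",28,7.0,", ",0,7.0,")  # n_total -> 0
    path.write_text(text)
    with pytest.raises(ValidationError, match="line 3"):
        read_cohorts(path)


def test_duplicate_study_labels_rejected():
    s = TreatmentSchedule(Modality.XRAY, 2.0, 10, fractions_per_week=5)
    c = TrialCohort("dup", 2000, s, ChemoCategory.NONE, 10, 0.5)
    with pytest.raises(ValidationError, match="dup"):
        CohortTable((c, c), "t")
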