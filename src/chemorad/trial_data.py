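"""Data model and CSV round-trip for published LAUPC trial cohorts.

A *cohort* is one arm of a published trial of locally advanced unresectable
pancreatic cancer (LAUPC): a treatment schedule (modality, dose per fraction,
fraction count, timing), a chemotherapy category, the number of patients, and
the 1-year overall-survival fraction. Survivor counts are not printed in the
source tables; they are reconstructed by rounding the printed percentage times
the cohort size, which is what the Poisson error weighting downstream needs.

The packaged fixtures (``chemorad/data/table*.csv``) transcribe the published
tables of X-ray-alone, X-ray+chemotherapy, and charged-particle cohorts.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

__all__ = [
    "Modality",
    "ChemoCategory",
    "SchemaError",
    "ValidationError",
    "TreatmentSchedule",
    "TrialCohort",
    "CohortTable",
    "derive_survivor_count",
    "read_cohorts",
    "write_cohorts",
    "load_table",
    "load_fixtures",
    "FIXTURE_TABLES",
    "CSV_COLUMNS",
    "SCHEMA_LINE",
]


class Modality(str, Enum):
    """Radiation quality of a schedule; decides the dose unit (Gy vs Gy(RBE))."""

    XRAY = "xray"
    PROTON = "proton"
    CARBON = "carbon"


class ChemoCategory(str, Enum):
    NONE = "none"
    GEMCITABINE = "gemcitabine"
    OTHER = "other"
    GEM_PLUS_OTHER = "gemcitabine_plus_other"


class SchemaError(ValueError):
    """CSV header or schema-version line does not match the documented schema."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


_REL_TOL_TOTAL_DOSE = 0.005  # total_dose vs d*n consistency


@dataclass(frozen=True)
class TreatmentSchedule:
    """One arm's physical prescription.

    ``dose_per_fraction`` and ``total_dose`` are in Gy for X-rays and Gy(RBE)
    for protons and carbon ions. Exactly one of ``fractions_per_week`` or
    ``overall_time_days`` fixes the treatment-time convention; ranged source
    rows keep their printed bounds in ``dose_low``/``dose_high`` while the
    midpoint is used as the working schedule.
    """

    modality: Modality
    dose_per_fraction: float
    n_fractions: int
    total_dose: Optional[float] = None
    dose_low: Optional[float] = None
    dose_high: Optional[float] = None
    fractions_per_week: Optional[float] = None
    overall_time_days: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "modality", Modality(self.modality))
        if self.dose_per_fraction <= 0:
            raise ValidationError("dose_per_fraction must be positive")
        if int(self.n_fractions) != self.n_fractions or self.n_fractions < 1:
            raise ValidationError("n_fractions must be a positive integer")
        object.__setattr__(self, "n_fractions", int(self.n_fractions))
        if self.total_dose is None:
            object.__setattr__(
                self, "total_dose", self.dose_per_fraction * self.n_fractions
            )
        implied = self.dose_per_fraction * self.n_fractions
        if not math.isclose(self.total_dose, implied, rel_tol=_REL_TOL_TOTAL_DOSE):
            raise ValidationError(
                f"total_dose {self.total_dose} inconsistent with "
                f"dose_per_fraction*n_fractions = {implied:.4g}"
            )
        if (self.dose_low is None) != (self.dose_high is None):
            raise ValidationError("dose_low and dose_high must be given together")
        if self.dose_low is not None:
            if not (self.dose_low <= self.total_dose <= self.dose_high):
                raise ValidationError(
                    f"total_dose {self.total_dose} outside printed range "
                    f"[{self.dose_low}, {self.dose_high}]"
                )
        has_fpw = self.fractions_per_week is not None
        has_time = self.overall_time_days is not None
        if has_fpw == has_time:
            raise ValidationError(
                "exactly one of fractions_per_week or overall_time_days required"
            )
        if has_fpw and self.fractions_per_week <= 0:
            raise ValidationError("fractions_per_week must be positive")
        if has_time and self.overall_time_days < 1:
            raise ValidationError("overall_time_days must be a positive integer")


def derive_survivor_count(os1y_fraction: float, n_total: int) -> int:
    """Reconstruct the 1-year survivor count from a printed survival fraction.

    Returns ``round(os1y_fraction * n_total)`` with ties rounded half away
    from zero, the nearest integer consistent with the printed percentage.
    """
    if not 0.0 <= os1y_fraction <= 1.0:
        raise ValidationError("os1y_fraction must lie in [0, 1]")
    if n_total < 1:
        raise ValidationError("n_total must be positive")
    return int(math.floor(os1y_fraction * n_total + 0.5))


@dataclass(frozen=True)
class TrialCohort:
    """One published cohort: schedule, chemotherapy category and 1-year outcome."""

    study_label: str
    year: int
    schedule: TreatmentSchedule
    chemo_category: ChemoCategory
    n_total: int
    os1y_fraction: float
    n_survivors_1y: Optional[int] = None
    os2y_fraction: Optional[float] = None
    median_os_months: Optional[float] = None
    included_in_fit: bool = True
    exclusion_reason: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "chemo_category", ChemoCategory(self.chemo_category))
        if not self.study_label:
            raise ValidationError("study_label must be non-empty")
        if self.n_total < 1:
            raise ValidationError("n_total must be positive")
        if not 0.0 <= self.os1y_fraction <= 1.0:
            raise ValidationError("os1y_fraction must lie in [0, 1]")
        if self.n_survivors_1y is None:
            object.__setattr__(
                self,
                "n_survivors_1y",
                derive_survivor_count(self.os1y_fraction, self.n_total),
            )
        if not 0 <= self.n_survivors_1y <= self.n_total:
            raise ValidationError("n_survivors_1y must lie in [0, n_total]")
        # survivor count must be the nearest integer to the printed fraction
        if (
            abs(self.n_survivors_1y / self.n_total - self.os1y_fraction)
            > 0.5 / self.n_total + 1e-12
        ):
            raise ValidationError(
                f"{self.study_label}: n_survivors_1y={self.n_survivors_1y} "
                f"inconsistent with os1y_fraction={self.os1y_fraction}"
            )
        if self.os2y_fraction is not None and not 0.0 <= self.os2y_fraction <= 1.0:
            raise ValidationError("os2y_fraction must lie in [0, 1]")
        if not self.included_in_fit and not self.exclusion_reason:
            raise ValidationError(
                f"{self.study_label}: excluded cohorts need an exclusion_reason"
            )


@dataclass(frozen=True)
class CohortTable:
    """Ordered collection of cohorts transcribed from one source table."""

    cohorts: tuple
    source_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "cohorts", tuple(self.cohorts))
        labels = [c.study_label for c in self.cohorts]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(
                f"{self.source_label or 'table'}: duplicate study labels {dupes}"
            )

    def __iter__(self) -> Iterator[TrialCohort]:
        return iter(self.cohorts)

    def __len__(self) -> int:
        return len(self.cohorts)

    def included(self) -> "CohortTable":
        return CohortTable(
            tuple(c for c in self.cohorts if c.included_in_fit), self.source_label
        )

    def to_frame(self):
        """Flat :class:`pandas.DataFrame` view (one row per cohort)."""
        import pandas as pd

        return pd.DataFrame([_cohort_to_row(c) for c in self.cohorts])


# ---------------------------------------------------------------------------
# CSV schema (comma-separated, UTF-8, schema-version line + one header row)

SCHEMA_LINE = "# cohort-csv v1"

CSV_COLUMNS = [
    "study_label",
    "year",
    "modality",
    "dose_per_fraction",
    "n_fractions",
    "total_dose",
    "dose_low",
    "dose_high",
    "fractions_per_week",
    "overall_time_days",
    "chemo_category",
    "n_total",
    "os1y_percent",
    "os2y_percent",
    "median_os_months",
    "included_in_fit",
    "exclusion_reason",
]


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _opt_float(cell: str) -> Optional[float]:
    cell = cell.strip()
    return float(cell) if cell else None


def _opt_int(cell: str) -> Optional[int]:
    cell = cell.strip()
    return int(cell) if cell else None


def _cohort_to_row(c: TrialCohort) -> dict:
    s = c.schedule
    return {
        "study_label": c.study_label,
        "year": c.year,
        "modality": s.modality.value,
        "dose_per_fraction": s.dose_per_fraction,
        "n_fractions": s.n_fractions,
        "total_dose": s.total_dose,
        "dose_low": s.dose_low,
        "dose_high": s.dose_high,
        "fractions_per_week": s.fractions_per_week,
        "overall_time_days": s.overall_time_days,
        "chemo_category": c.chemo_category.value,
        "n_total": c.n_total,
        "os1y_percent": round(c.os1y_fraction * 100.0, 10),
        "os2y_percent": None
        if c.os2y_fraction is None
        else round(c.os2y_fraction * 100.0, 10),
        "median_os_months": c.median_os_months,
        "included_in_fit": c.included_in_fit,
        "exclusion_reason": c.exclusion_reason,
    }


def _row_to_cohort(row: dict) -> TrialCohort:
    schedule = TreatmentSchedule(
        modality=Modality(row["modality"].strip()),
        dose_per_fraction=float(row["dose_per_fraction"]),
        n_fractions=int(row["n_fractions"]),
        total_dose=_opt_float(row["total_dose"]),
        dose_low=_opt_float(row["dose_low"]),
        dose_high=_opt_float(row["dose_high"]),
        fractions_per_week=_opt_float(row["fractions_per_week"]),
        overall_time_days=_opt_int(row["overall_time_days"]),
    )
    included_cell = row["included_in_fit"].strip().lower()
    if included_cell not in {"true", "false"}:
        raise ValidationError(f"included_in_fit must be true/false, got {included_cell!r}")
    os2y = _opt_float(row["os2y_percent"])
    return TrialCohort(
        study_label=row["study_label"].strip(),
        year=int(row["year"]),
        schedule=schedule,
        chemo_category=ChemoCategory(row["chemo_category"].strip()),
        n_total=int(row["n_total"]),
        os1y_fraction=float(row["os1y_percent"]) / 100.0,
        os2y_fraction=None if os2y is None else os2y / 100.0,
        median_os_months=_opt_float(row["median_os_months"]),
        included_in_fit=included_cell == "true",
        exclusion_reason=row["exclusion_reason"].strip() or None,
    )


def read_cohorts(path: Union[str, Path], source_label: str = "") -> CohortTable:
    """Read a cohort CSV, validating every row; raises with row diagnostics."""
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        first = fh.readline().rstrip("\r\n")
        if first != SCHEMA_LINE:
            raise SchemaError(
                f"{path}: expected schema line {SCHEMA_LINE!r}, got {first!r}"
            )
        reader = csv.DictReader(fh)
        if reader.fieldnames != CSV_COLUMNS:
            missing = set(CSV_COLUMNS) - set(reader.fieldnames or [])
            raise SchemaError(
                f"{path}: header mismatch; missing columns {sorted(missing)}"
                if missing
                else f"{path}: header column order does not match schema"
            )
        cohorts = []
        problems = []
        for lineno, row in enumerate(reader, start=3):  # line 1 schema, 2 header
            try:
                cohorts.append(_row_to_cohort(row))
            except (ValidationError, ValueError) as exc:
                problems.append(f"line {lineno}: {exc}")
        if problems:
            raise ValidationError(f"{path}: invalid rows:\n" + "\n".join(problems))
    return CohortTable(tuple(cohorts), source_label or path.stem)


def write_cohorts(table: CohortTable, path: Union[str, Path]) -> Path:
    """Write a cohort table; ``read_cohorts(write_cohorts(t))`` round-trips."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(SCHEMA_LINE + "\n")
        writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS)
        writer.writeheader()
        for cohort in table:
            writer.writerow({k: _fmt(v) for k, v in _cohort_to_row(cohort).items()})
    return path


# ---------------------------------------------------------------------------
# Packaged fixtures

FIXTURE_TABLES = ("table1", "table2", "table4", "table5", "table6")

_SOURCE_LABELS = {
    "table1": "Table 1 (X-rays alone)",
    "table2": "Table 2 (X-rays + gemcitabine)",
    "table4": "Table 4 (X-rays + other chemotherapy)",
    "table5": "Table 5 (X-rays + gemcitabine cocktail)",
    "table6": "Table 6 (charged particle therapy)",
}


def load_table(name: str) -> CohortTable:
    """Load one packaged fixture table by short name (``table1`` ... ``table6``)."""
    if name not in FIXTURE_TABLES:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_TABLES}")
    ref = resources.files("chemorad").joinpath(f"data/{name}.csv")
    with resources.as_file(ref) as path:
        return read_cohorts(path, source_label=_SOURCE_LABELS[name])


def load_fixtures() -> dict:
    """All packaged fixture tables, keyed by short name."""
    return {name: load_table(name) for name in FIXTURE_TABLES}
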