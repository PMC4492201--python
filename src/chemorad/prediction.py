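"""Scenario tables: expected 1-year survival for candidate dose-escalation
schedules.

Each scenario pairs a treatment schedule with a fitted parameter set (the
X-ray chemoradiation curve for photon schedules, the charged-particle curve
for proton/carbon schedules). The table reports BED and the model's expected
1-year overall survival. For charged-particle scenarios the published
reference table's survival percentages are not reproducible from the rounded
published parameters, so those rows carry a divergence flag: the numbers are
this model's own output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .bed import DEFAULT_CONSTANTS, RadiobiologicalConstants, compute_bed
from .dose_response import ModelParameters, bed_for_overall_survival, overall_survival
from .trial_data import Modality, TreatmentSchedule, ValidationError

__all__ = [
    "Scenario",
    "ConfigurationError",
    "PARAM_SET_XRAY_CHEMO",
    "PARAM_SET_CPT_CHEMO",
    "published_parameter_sets",
    "reference_scenarios",
    "predict_scenarios",
    "os_doubling_bed",
    "round_percent",
]

PARAM_SET_XRAY_CHEMO = "xray_chemo"
PARAM_SET_CPT_CHEMO = "cpt_chemo"

_DEFAULT_SET_FOR_MODALITY = {
    Modality.XRAY: PARAM_SET_XRAY_CHEMO,
    Modality.PROTON: PARAM_SET_CPT_CHEMO,
    Modality.CARBON: PARAM_SET_CPT_CHEMO,
}


class ConfigurationError(KeyError):
    """A scenario references a parameter set that was not provided."""


def published_parameter_sets() -> dict:
    """The published fitted curves: X-ray+chemo (D50 in Gy) and CPT+chemo
    (D50 in Gy(RBE)), sharing gamma50 = 1.2 and CS = 0.36."""
    return {
        PARAM_SET_XRAY_CHEMO: ModelParameters(gamma50=1.2, d50=107.0, cs=0.36),
        PARAM_SET_CPT_CHEMO: ModelParameters(gamma50=1.2, d50=75.0, cs=0.36),
    }


@dataclass(frozen=True)
class Scenario:
    """One candidate schedule to evaluate under a named parameter set.

    ``parameter_set=None`` selects the conventional set for the modality
    (X-ray schedules -> X-ray curve, charged particles -> CPT curve).
    """

    label: str
    schedule: TreatmentSchedule
    parameter_set: Optional[str] = None
    comment: str = ""

    def resolved_set(self) -> str:
        if self.parameter_set is not None:
            return self.parameter_set
        return _DEFAULT_SET_FOR_MODALITY[self.schedule.modality]


def _sched(modality, d, n, fractions_per_week=None, overall_time_days=None):
    return TreatmentSchedule(
        modality=modality,
        dose_per_fraction=d,
        n_fractions=n,
        fractions_per_week=fractions_per_week,
        overall_time_days=overall_time_days,
    )


def reference_scenarios() -> list:
    """The reference escalation table: standard X-ray fractionation, proposed
    X-ray escalation, SBRT, and charged-particle hypofractionation rows.

    X-ray and proton schedules use the weekday (5/week) convention; the
    12-fraction carbon schedules use the NIRS 3-week course (21 days), the
    single fraction 1 day, and the 18-fraction extension 30 days (4/week).
    """
    return [
        Scenario(
            "X-rays 28 x 1.8 Gy",
            _sched(Modality.XRAY, 1.8, 28, fractions_per_week=5),
            comment="current standard fractionation scheme",
        ),
        Scenario(
            "X-rays 33 x 2.25 Gy",
            _sched(Modality.XRAY, 2.25, 33, fractions_per_week=5),
            comment="proposed dose-escalation trial",
        ),
        Scenario(
            "X-rays 5 x 6.6 Gy",
            _sched(Modality.XRAY, 6.6, 5, fractions_per_week=5),
            comment="SBRT standard in adjuvant settings",
        ),
        Scenario(
            "Protons 26 x 2.7 Gy(RBE)",
            _sched(Modality.PROTON, 2.7, 26, fractions_per_week=5),
            comment="maximum proton dose reached at Hyogo",
        ),
        Scenario(
            "C-ions 12 x 4.6 Gy(RBE)",
            _sched(Modality.CARBON, 4.6, 12, overall_time_days=21),
            comment="maximum carbon-ion dose reached at NIRS",
        ),
        Scenario(
            "C-ions 12 x 5.85 Gy(RBE)",
            _sched(Modality.CARBON, 5.85, 12, overall_time_days=21),
            comment="Hyogo total dose in 12 NIRS fractions",
        ),
        Scenario(
            "Single fraction 25 Gy(RBE)",
            _sched(Modality.CARBON, 25.0, 1, overall_time_days=1),
            comment="single-fraction radiosurgery dose",
        ),
        Scenario(
            "C-ions 18 x 4.6 Gy(RBE)",
            _sched(Modality.CARBON, 4.6, 18, overall_time_days=30),
            comment="NIRS dose/fraction over 18 fractions; aims to double "
            "survival vs standard X-ray fractionation",
        ),
    ]


def round_percent(fraction: float) -> int:
    """Proportion -> whole percent, ties rounded half up."""
    return int(math.floor(fraction * 100.0 + 0.5))


def predict_scenarios(
    scenarios: Sequence[Scenario],
    params_by_set: Optional[Mapping[str, ModelParameters]] = None,
    constants: RadiobiologicalConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Deterministic scenario table: BED and expected 1-year OS per schedule.

    Charged-particle rows are flagged ``model_output_diverges`` because their
    published reference survival values cannot be reproduced from the rounded
    published parameters.
    """
    if params_by_set is None:
        params_by_set = published_parameter_sets()
    rows = []
    for sc in scenarios:
        set_name = sc.resolved_set()
        if set_name not in params_by_set:
            raise ConfigurationError(
                f"scenario {sc.label!r} needs parameter set {set_name!r}"
            )
        params = params_by_set[set_name]
        bed = compute_bed(sc.schedule, constants)
        os1y = overall_survival(bed, params)
        rows.append(
            {
                "label": sc.label,
                "modality": sc.schedule.modality.value,
                "dose_per_fraction": sc.schedule.dose_per_fraction,
                "n_fractions": sc.schedule.n_fractions,
                "total_dose": sc.schedule.total_dose,
                "bed": bed,
                "expected_os1y": os1y,
                "expected_os1y_percent": round_percent(os1y),
                "parameter_set": set_name,
                "model_output_diverges": sc.schedule.modality is not Modality.XRAY,
                "comment": sc.comment,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "label",
            "modality",
            "dose_per_fraction",
            "n_fractions",
            "total_dose",
            "bed",
            "expected_os1y",
            "expected_os1y_percent",
            "parameter_set",
            "model_output_diverges",
            "comment",
        ],
    )


def os_doubling_bed(reference_os: float, params: ModelParameters) -> float:
    """BED needed to double a reference 1-year overall survival.

    Solves the combined survival model for BED at 2 x ``reference_os``; the
    target must fall inside the model's attainable range (cs, 1).
    """
    target = 2.0 * reference_os
    if target >= 1.0 or target <= params.cs:
        raise ValidationError(
            f"doubled survival {target} outside attainable range ({params.cs}, 1)"
        )
    return bed_for_overall_survival(target, params)
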