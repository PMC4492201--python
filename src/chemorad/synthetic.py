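"""Virtual-trial simulator for parameter-recovery studies.

Cohorts are generated under the package's own survival model: each simulated
arm has a treatment schedule, a cohort size and a chemotherapy category; the
true 1-year survival probability is the combined logistic model evaluated at
the schedule's BED, and the survivor count is drawn Binomial(n_total, p).
The fit downstream weights points with the Poisson approximation to that
counting error, so the generator/fit pair deliberately mirrors the
approximation used on the real published tables.

Randomness is fully determined by (seed, replicate, arm index) through a
counter-based sub-seed scheme (``numpy.random.SeedSequence`` with spawn key
``(replicate, arm_index)``), so replicates are independent and arm order is
irrelevant: permuting the arms of a design yields the same multiset of
simulated cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .bed import DEFAULT_CONSTANTS, RadiobiologicalConstants, compute_bed
from .dose_response import ModelParameters, overall_survival
from .fitting import FitError, run_full_protocol
from .trial_data import (
    ChemoCategory,
    CohortTable,
    Modality,
    TreatmentSchedule,
    TrialCohort,
    ValidationError,
    load_fixtures,
)

__all__ = [
    "DesignArm",
    "SimulationDesign",
    "simulate_cohort",
    "simulate_study_set",
    "mirrored_fixture_design",
    "default_truth",
    "parameter_recovery_study",
    "recovery_rates",
]


@dataclass(frozen=True)
class DesignArm:
    """One simulated trial arm; ``index`` keys its sub-seed, so a permuted
    design reproduces the identical cohorts."""

    schedule: TreatmentSchedule
    n_total: int
    chemo_category: ChemoCategory
    index: int

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValidationError("n_total must be positive")


@dataclass(frozen=True)
class SimulationDesign:
    """A virtual multi-trial study: truth per modality set, arms, replicates.

    ``truth`` maps ``"xray"`` and ``"cpt"`` to the generating survival curves;
    arms without chemotherapy use the matching curve with cs set to 0.
    """

    truth: Mapping[str, ModelParameters]
    arms: tuple
    n_replicates: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        missing = {"xray", "cpt"} - set(self.truth)
        if missing:
            raise ValidationError(f"truth missing parameter sets: {sorted(missing)}")
        object.__setattr__(self, "arms", tuple(self.arms))

    @classmethod
    def from_lists(
        cls,
        truth: Mapping[str, ModelParameters],
        schedules: Sequence[TreatmentSchedule],
        cohort_sizes: Sequence[int],
        chemo_categories: Sequence[ChemoCategory],
        n_replicates: int,
        seed: int,
    ) -> "SimulationDesign":
        if not (len(schedules) == len(cohort_sizes) == len(chemo_categories)):
            raise ValidationError(
                "schedules, cohort_sizes and chemo_categories must have equal length"
            )
        arms = tuple(
            DesignArm(s, n, ChemoCategory(c), i)
            for i, (s, n, c) in enumerate(zip(schedules, cohort_sizes, chemo_categories))
        )
        return cls(truth=dict(truth), arms=arms, n_replicates=n_replicates, seed=seed)

    def permuted(self, order: Sequence[int]) -> "SimulationDesign":
        """Same design with arms reordered (sub-seed mapping preserved)."""
        return replace(self, arms=tuple(self.arms[i] for i in order))


def _truth_for_arm(arm: DesignArm, truth: Mapping[str, ModelParameters]) -> ModelParameters:
    key = "xray" if arm.schedule.modality is Modality.XRAY else "cpt"
    params = truth[key]
    if arm.chemo_category is ChemoCategory.NONE and params.cs != 0.0:
        params = replace(params, cs=0.0)
    return params


def simulate_cohort(
    schedule: TreatmentSchedule,
    n_total: int,
    truth: ModelParameters,
    constants: RadiobiologicalConstants = DEFAULT_CONSTANTS,
    rng: Optional[np.random.Generator] = None,
    label: str = "sim",
    chemo_category: ChemoCategory = ChemoCategory.NONE,
    year: int = 2015,
) -> TrialCohort:
    """Draw one virtual cohort: p from the survival model, count ~ Binomial."""
    if n_total < 1:
        raise ValidationError("n_total must be positive")
    if rng is None:
        rng = np.random.default_rng()
    p = overall_survival(compute_bed(schedule, constants), truth)
    n_survivors = int(rng.binomial(n_total, p))
    return TrialCohort(
        study_label=label,
        year=year,
        schedule=schedule,
        chemo_category=chemo_category,
        n_total=n_total,
        os1y_fraction=n_survivors / n_total,
        n_survivors_1y=n_survivors,
    )


def _arm_rng(seed: int, replicate: int, arm_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(replicate, arm_index))
    return np.random.default_rng(ss)


def simulate_study_set(
    design: SimulationDesign,
    constants: RadiobiologicalConstants = DEFAULT_CONSTANTS,
) -> list:
    """One :class:`CohortTable` per replicate, deterministically sub-seeded."""
    tables = []
    for r in range(design.n_replicates):
        cohorts = []
        for arm in design.arms:
            rng = _arm_rng(design.seed, r, arm.index)
            cohorts.append(
                simulate_cohort(
                    arm.schedule,
                    arm.n_total,
                    _truth_for_arm(arm, design.truth),
                    constants,
                    rng=rng,
                    label=f"sim-{arm.index:03d} ({arm.schedule.modality.value}, "
                    f"{arm.chemo_category.value})",
                    chemo_category=arm.chemo_category,
                )
            )
        tables.append(CohortTable(tuple(cohorts), source_label=f"replicate-{r}"))
    return tables


def default_truth() -> dict:
    """Generating curves matching the fitted study conditions: gamma50 = 1.2,
    D50 = 107 Gy (X-rays) / 75 Gy(RBE) (CPT), CS = 0.36."""
    return {
        "xray": ModelParameters(gamma50=1.2, d50=107.0, cs=0.36),
        "cpt": ModelParameters(gamma50=1.2, d50=75.0, cs=0.36),
    }


def mirrored_fixture_design(
    n_replicates: int,
    seed: int,
    truth: Optional[Mapping[str, ModelParameters]] = None,
) -> SimulationDesign:
    """Design mirroring the packaged fixture layout: the same schedules,
    cohort sizes and chemotherapy categories as the transcribed trial tables
    (radiotherapy-alone, X-ray chemoradiation, and charged-particle chemo
    arms; particle-monotherapy arms are not simulated)."""
    schedules, sizes, cats = [], [], []
    for table in load_fixtures().values():
        for c in table:
            if not c.included_in_fit:
                continue
            schedules.append(c.schedule)
            sizes.append(c.n_total)
            cats.append(c.chemo_category)
    return SimulationDesign.from_lists(
        truth or default_truth(), schedules, sizes, cats, n_replicates, seed
    )


def parameter_recovery_study(
    n_replicates: int = 200,
    seed: int = 0,
    truth: Optional[Mapping[str, ModelParameters]] = None,
    constants: RadiobiologicalConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Run the full staged protocol on simulated replicates of the mirrored
    design; one row per replicate with estimates and standard errors.

    Replicates where a stage fails to converge are kept with NaN entries.
    """
    truth = dict(truth or default_truth())
    design = mirrored_fixture_design(n_replicates, seed, truth)
    rows = []
    for r, table in enumerate(simulate_study_set(design, constants)):
        row = {"replicate": r}
        try:
            protocol = run_full_protocol(table, constants, subsets=False)
            s1 = protocol.stages["rt_alone"]
            row["gamma50"] = s1.free_params["gamma50"].value
            row["gamma50_se"] = s1.free_params["gamma50"].stderr
            row["d50"] = s1.free_params["d50"].value
            row["d50_se"] = s1.free_params["d50"].stderr
            s2 = protocol.stages.get("chemo_all")
            if s2 is not None:
                row["cs"] = s2.free_params["cs"].value
                row["cs_se"] = s2.free_params["cs"].stderr
            s3 = protocol.stages.get("cpt")
            if s3 is not None:
                row["d50_cpt"] = s3.free_params["d50"].value
                row["d50_cpt_se"] = s3.free_params["d50"].stderr
        except FitError:
            pass
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["truth"] = {
        "gamma50": truth["xray"].gamma50,
        "d50": truth["xray"].d50,
        "cs": truth["xray"].cs,
        "d50_cpt": truth["cpt"].d50,
    }
    return df


def recovery_rates(study: pd.DataFrame, k: float = 2.0) -> pd.Series:
    """Fraction of replicates whose estimate lies within k standard errors of
    the generating value, per parameter (failed replicates count as misses)."""
    truth = study.attrs["truth"]
    out = {}
    n = len(study)
    for name, true_value in truth.items():
        est = study.get(name)
        se = study.get(f"{name}_se")
        if est is None or se is None:
            out[name] = 0.0
            continue
        hit = (np.abs(est - true_value) <= k * se) & np.isfinite(est) & np.isfinite(se)
        out[name] = float(hit.sum()) / n
    return pd.Series(out)
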