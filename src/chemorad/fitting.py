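"""Poisson-weighted staged fitting of the chemoradiation survival model.

The published survival fractions carry a counting error approximated by
Poisson statistics, SD = sqrt(n_s)/n_tot with n_s the 1-year survivor count.
Fitting is weighted nonlinear least squares on the proportion scale with
weights 1/SD^2, run in three stages with parameters frozen forward:

1. radiotherapy-alone cohorts -> gamma50 and D50 of the logistic RS curve;
2. X-ray chemoradiation cohorts -> chemotherapy survival CS, with gamma50 and
   D50 fixed from stage 1 (optionally on drug-category subsets);
3. charged-particle chemoradiation cohorts -> a particle-specific D50 in
   Gy(RBE), with gamma50 and CS fixed from the X-ray stages.

Standard errors come from the Jacobian covariance scaled by the reduced
chi-square, with the scale floored at 1: the Poisson weights are absolute
counting errors, so the covariance is inflated when the data are overdispersed
but never deflated on the small residual degrees of freedom of these fits.
When a stage runs inside the full protocol, the covariance of the parameters
frozen from earlier stages is propagated into the later stage's standard
errors by the delta method (finite-difference sensitivity of the one-parameter
estimate to the frozen values); a standalone fit against externally fixed
values reports the fit-only error. Optimisation uses derivative-based least
squares with a documented multi-start (five starting points), an iteration cap
of 500 and tolerance 1e-10, keeping the start with the lowest weighted RSS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .bed import DEFAULT_CONSTANTS, RadiobiologicalConstants, compute_bed
from .dose_response import ModelParameters, overall_survival, radiotherapy_survival
from .trial_data import (
    ChemoCategory,
    CohortTable,
    Modality,
    TrialCohort,
    ValidationError,
    load_fixtures,
)

__all__ = [
    "FitError",
    "ParamEstimate",
    "FixedParam",
    "PointFit",
    "FitResult",
    "ProtocolResult",
    "poisson_sd",
    "fit_rt_alone",
    "fit_chemo_rt",
    "fit_cpt",
    "run_full_protocol",
]

MAX_NFEV = 500
TOL = 1e-10

# documented multi-start grids (best weighted RSS wins)
STARTS_RT_ALONE = ((0.5, 60.0), (1.0, 85.0), (1.5, 110.0), (2.0, 140.0), (3.0, 180.0))
STARTS_CS = (0.1, 0.25, 0.4, 0.55, 0.7)
STARTS_D50_CPT = (50.0, 65.0, 80.0, 95.0, 110.0)


class FitError(RuntimeError):
    """Optimiser failure; carries the per-start trace for diagnosis."""

    def __init__(self, message: str, trace: Optional[list] = None):
        super().__init__(message)
        self.trace = trace or []


@dataclass(frozen=True)
class ParamEstimate:
    """Point estimate with its standard error.

    ``stderr`` includes propagated uncertainty of frozen upstream parameters
    when the fit ran inside the staged protocol; ``stderr_fit`` is the
    fit-only (conditional) error.
    """

    value: float
    stderr: float
    stderr_fit: Optional[float] = None


@dataclass(frozen=True)
class FixedParam:
    value: float
    provenance: str


@dataclass(frozen=True)
class PointFit:
    study_label: str
    bed: float
    observed_os: float
    sd: float
    fitted_os: float
    residual: float  # weighted: (obs - fit)/sd


@dataclass(frozen=True)
class FitResult:
    """Outcome of one fitting stage.

    ``covariance`` is the (scaled) covariance of the free parameters in their
    listed order; ``fixed_sensitivity`` maps each free parameter to the
    derivative of its estimate with respect to each fixed parameter (filled
    when a fixed covariance was propagated).
    """

    stage: str
    free_params: Mapping[str, ParamEstimate]
    fixed_params: Mapping[str, FixedParam]
    weighted_rss: float
    n_points: int
    per_point: tuple
    covariance: Optional[np.ndarray] = None
    fixed_sensitivity: Optional[Mapping[str, Mapping[str, float]]] = None

    def __post_init__(self) -> None:
        overlap = set(self.free_params) & set(self.fixed_params)
        if overlap:
            raise ValidationError(f"parameters both free and fixed: {sorted(overlap)}")

    def value(self, name: str) -> float:
        if name in self.free_params:
            return self.free_params[name].value
        return self.fixed_params[name].value

    @property
    def params(self) -> ModelParameters:
        """Assembled survival-curve parameters (cs defaults to 0 if absent)."""
        names = set(self.free_params) | set(self.fixed_params)
        cs = self.value("cs") if "cs" in names else 0.0
        return ModelParameters(
            gamma50=self.value("gamma50"), d50=self.value("d50"), cs=cs
        )


def poisson_sd(cohort: TrialCohort) -> float:
    """Poisson SD of a cohort's survival fraction, sqrt(n_s)/n_tot.

    The survivor count is floored at 1 so a printed 0% cohort still gets a
    finite weight.
    """
    if cohort.n_total < 1:
        raise ValidationError("n_total must be positive")
    n_s = max(1, cohort.n_survivors_1y)
    return math.sqrt(n_s) / cohort.n_total


def _as_cohorts(data) -> tuple:
    if isinstance(data, CohortTable):
        return tuple(data)
    return tuple(data)


def _design(
    cohorts: Iterable[TrialCohort], constants: RadiobiologicalConstants
) -> tuple:
    labels, beds, obs, sds = [], [], [], []
    for c in cohorts:
        labels.append(c.study_label)
        beds.append(compute_bed(c.schedule, constants))
        obs.append(c.os1y_fraction)
        sds.append(poisson_sd(c))
    return labels, np.array(beds), np.array(obs), np.array(sds)


def _multistart_ls(residual, starts, bounds):
    best = None
    trace = []
    for x0 in starts:
        try:
            res = least_squares(
                residual,
                np.atleast_1d(np.asarray(x0, dtype=float)),
                bounds=bounds,
                xtol=TOL,
                ftol=TOL,
                gtol=TOL,
                max_nfev=MAX_NFEV,
            )
        except Exception as exc:  # pragma: no cover - defensive
            trace.append((x0, None, f"raised {exc!r}"))
            continue
        trace.append((x0, float(res.cost), res.message))
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitError("no optimiser start converged within the iteration cap", trace)
    return best


def _covariance(res, n_points: int) -> np.ndarray:
    """Jacobian covariance, inflated by reduced chi-square when > 1."""
    n_free = res.x.size
    dof = n_points - n_free
    jtj = res.jac.T @ res.jac
    try:
        cov = np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        return np.full((n_free, n_free), np.nan)
    scale = max(1.0, 2.0 * res.cost / dof) if dof > 0 else 1.0
    return cov * scale


def _per_point(labels, beds, obs, sds, fitted) -> tuple:
    return tuple(
        PointFit(l, float(b), float(o), float(s), float(f), float((o - f) / s))
        for l, b, o, s, f in zip(labels, beds, obs, sds, fitted)
    )


def fit_rt_alone(
    data: Union[CohortTable, Sequence[TrialCohort]],
    constants: RadiobiologicalConstants = DEFAULT_CONSTANTS,
    init: Optional[ModelParameters] = None,
) -> FitResult:
    """Stage 1: fit gamma50 and D50 to radiotherapy-alone cohorts."""
    cohorts = [
        c
        for c in _as_cohorts(data)
        if c.included_in_fit and c.chemo_category is ChemoCategory.NONE
    ]
    if len(cohorts) < 3:
        raise FitError(
            f"stage 1 needs at least 3 radiotherapy-alone cohorts, got {len(cohorts)}"
        )
    labels, beds, obs, sds = _design(cohorts, constants)

    def residual(theta):
        params = ModelParameters(gamma50=theta[0], d50=theta[1])
        return (obs - radiotherapy_survival(beds, params)) / sds

    starts = list(STARTS_RT_ALONE)
    if init is not None:
        starts.insert(0, (init.gamma50, init.d50))
    res = _multistart_ls(residual, starts, bounds=([1e-3, 1.0], [np.inf, np.inf]))
    cov = _covariance(res, len(cohorts))
    se = np.sqrt(np.diag(cov))
    params = ModelParameters(gamma50=res.x[0], d50=res.x[1])
    fitted = radiotherapy_survival(beds, params)
    return FitResult(
        stage="rt_alone",
        free_params={
            "gamma50": ParamEstimate(float(res.x[0]), float(se[0]), float(se[0])),
            "d50": ParamEstimate(float(res.x[1]), float(se[1]), float(se[1])),
        },
        fixed_params={},
        weighted_rss=float(2.0 * res.cost),
        n_points=len(cohorts),
        per_point=_per_point(labels, beds, obs, sds, fitted),
        covariance=cov,
    )


def _refit_scalar(residual_at, estimate: float, bounds) -> float:
    """Re-solve a one-parameter fit (used for finite-difference sensitivity)."""
    res = least_squares(
        residual_at,
        np.atleast_1d(estimate),
        bounds=bounds,
        xtol=TOL,
        ftol=TOL,
        gtol=TOL,
        max_nfev=MAX_NFEV,
    )
    return float(res.x[0])


def _propagated_variance(
    make_residual,
    fixed_values: Sequence[float],
    fixed_cov: np.ndarray,
    estimate: float,
    bounds,
) -> tuple:
    """Delta-method variance contribution of frozen upstream parameters.

    ``make_residual(values)`` builds the residual function for perturbed fixed
    values; the sensitivity of the one-parameter estimate is taken by central
    finite differences (1% relative step).
    """
    fixed_values = np.asarray(fixed_values, dtype=float)
    grad = np.zeros_like(fixed_values)
    for j, v in enumerate(fixed_values):
        step = max(1e-6, 0.01 * abs(v))
        hi = fixed_values.copy()
        lo = fixed_values.copy()
        hi[j] += step
        lo[j] -= step
        est_hi = _refit_scalar(make_residual(hi), estimate, bounds)
        est_lo = _refit_scalar(make_residual(lo), estimate, bounds)
        grad[j] = (est_hi - est_lo) / (2.0 * step)
    return float(grad @ fixed_cov @ grad), grad


def fit_chemo_rt(
    data: Union[CohortTable, Sequence[TrialCohort]],
    gamma50: float,
    d50: float,
    constants: RadiobiologicalConstants = DEFAULT_CONSTANTS,
    init_cs: Optional[float] = None,
    subset: Optional[ChemoCategory] = None,
    provenance: str = "stage 1 (radiotherapy-alone fit)",
    fixed_covariance: Optional[np.ndarray] = None,
) -> FitResult:
    """Stage 2: fit CS to X-ray chemoradiation cohorts, gamma50/D50 fixed.

    ``subset`` optionally restricts to one chemotherapy category.
    ``fixed_covariance`` (2x2, order gamma50/d50) propagates the stage-1
    uncertainty into the reported CS standard error.
    """
    cohorts = [
        c
        for c in _as_cohorts(data)
        if c.included_in_fit
        and c.schedule.modality is Modality.XRAY
        and c.chemo_category is not ChemoCategory.NONE
        and (subset is None or c.chemo_category is subset)
    ]
    if not cohorts:
        raise FitError("stage 2 needs at least one chemoradiation cohort")
    labels, beds, obs, sds = _design(cohorts, constants)

    def make_residual(fixed):
        g, d = fixed

        def residual(theta):
            params = ModelParameters(gamma50=g, d50=d, cs=theta[0])
            return (obs - overall_survival(beds, params)) / sds

        return residual

    bounds = ([0.0], [1.0 - 1e-9])
    starts = list(STARTS_CS)
    if init_cs is not None:
        starts.insert(0, init_cs)
    res = _multistart_ls(make_residual((gamma50, d50)), starts, bounds=bounds)
    cov = _covariance(res, len(cohorts))
    se_fit = float(np.sqrt(cov[0, 0]))
    estimate = float(res.x[0])
    se_total = se_fit
    sensitivity = None
    if fixed_covariance is not None:
        extra, grad = _propagated_variance(
            make_residual, (gamma50, d50), np.asarray(fixed_covariance), estimate, bounds
        )
        se_total = math.sqrt(se_fit**2 + extra)
        cov = np.array([[se_total**2]])
        sensitivity = {"cs": {"gamma50": float(grad[0]), "d50": float(grad[1])}}
    params = ModelParameters(gamma50=gamma50, d50=d50, cs=estimate)
    fitted = overall_survival(beds, params)
    return FitResult(
        stage="chemo_rt",
        free_params={"cs": ParamEstimate(estimate, se_total, se_fit)},
        fixed_params={
            "gamma50": FixedParam(gamma50, provenance),
            "d50": FixedParam(d50, provenance),
        },
        weighted_rss=float(2.0 * res.cost),
        n_points=len(cohorts),
        per_point=_per_point(labels, beds, obs, sds, fitted),
        covariance=cov,
        fixed_sensitivity=sensitivity,
    )


def fit_cpt(
    data: Union[CohortTable, Sequence[TrialCohort]],
    gamma50: float,
    cs: float,
    constants: RadiobiologicalConstants = DEFAULT_CONSTANTS,
    init_d50: Optional[float] = None,
    provenance: str = "stages 1-2 (X-ray fits)",
    fixed_covariance: Optional[np.ndarray] = None,
) -> FitResult:
    """Stage 3: fit the charged-particle D50 (Gy(RBE)), gamma50/CS fixed.

    Only proton/carbon arms *with* chemotherapy enter; particle-monotherapy
    arms are excluded upstream via ``included_in_fit``. ``fixed_covariance``
    (2x2, order gamma50/cs) propagates upstream uncertainty into the D50
    standard error.
    """
    cohorts = [
        c
        for c in _as_cohorts(data)
        if c.included_in_fit
        and c.schedule.modality in (Modality.PROTON, Modality.CARBON)
        and c.chemo_category is not ChemoCategory.NONE
    ]
    if not cohorts:
        raise FitError("stage 3 needs at least one charged-particle chemo cohort")
    labels, beds, obs, sds = _design(cohorts, constants)

    def make_residual(fixed):
        g, c = fixed

        def residual(theta):
            params = ModelParameters(gamma50=g, d50=theta[0], cs=c)
            return (obs - overall_survival(beds, params)) / sds

        return residual

    bounds = ([1.0], [1e4])
    starts = list(STARTS_D50_CPT)
    if init_d50 is not None:
        starts.insert(0, init_d50)
    res = _multistart_ls(make_residual((gamma50, cs)), starts, bounds=bounds)
    cov = _covariance(res, len(cohorts))
    se_fit = float(np.sqrt(cov[0, 0]))
    estimate = float(res.x[0])
    se_total = se_fit
    sensitivity = None
    if fixed_covariance is not None:
        extra, grad = _propagated_variance(
            make_residual, (gamma50, cs), np.asarray(fixed_covariance), estimate, bounds
        )
        se_total = math.sqrt(se_fit**2 + extra)
        cov = np.array([[se_total**2]])
        sensitivity = {"d50": {"gamma50": float(grad[0]), "cs": float(grad[1])}}
    params = ModelParameters(gamma50=gamma50, d50=estimate, cs=cs)
    fitted = overall_survival(beds, params)
    return FitResult(
        stage="cpt",
        free_params={"d50": ParamEstimate(estimate, se_total, se_fit)},
        fixed_params={
            "gamma50": FixedParam(gamma50, provenance),
            "cs": FixedParam(cs, provenance),
        },
        weighted_rss=float(2.0 * res.cost),
        n_points=len(cohorts),
        per_point=_per_point(labels, beds, obs, sds, fitted),
        covariance=cov,
        fixed_sensitivity=sensitivity,
    )


@dataclass
class ProtocolResult:
    """Ordered results of the three-stage protocol plus a summary table."""

    stages: dict
    statuses: dict
    summary: pd.DataFrame


_SUMMARY_DATASETS = {
    "rt_alone": "Radiotherapy (X-rays) alone",
    "chemo_gem": "Radiotherapy (X-rays) + gemcitabine",
    "chemo_other": "Radiotherapy (X-rays) + other chemotherapy",
    "chemo_all": "Radiotherapy (X-rays) + chemotherapy (all protocols)",
    "cpt": "Charged particle therapy + chemotherapy",
}


def _summary_row(key: str, fit: FitResult) -> dict:
    def cell(name):
        if name in fit.free_params:
            p = fit.free_params[name]
            return p.value, p.stderr, False
        if name in fit.fixed_params:
            return fit.fixed_params[name].value, None, True
        return None, None, None

    row = {"dataset": _SUMMARY_DATASETS[key], "stage": fit.stage}
    for name in ("gamma50", "d50", "cs"):
        value, se, fixed = cell(name)
        row[name] = value
        row[f"{name}_se"] = se
        row[f"{name}_fixed"] = fixed
    row["n_cohorts"] = fit.n_points
    row["weighted_rss"] = fit.weighted_rss
    return row


def run_full_protocol(
    data=None,
    constants: RadiobiologicalConstants = DEFAULT_CONSTANTS,
    subsets: bool = True,
) -> ProtocolResult:
    """Run stages 1 -> 2 -> 3 with parameter passing between stages.

    ``data`` may be a :class:`CohortTable`, an iterable of cohorts, or ``None``
    to pool the packaged fixture tables. With ``subsets=True`` stage 2 is also
    run on the gemcitabine-only and other-drug subsets (reported alongside the
    pooled fit; the pooled CS feeds stage 3).
    """
    if data is None:
        cohorts = tuple(c for table in load_fixtures().values() for c in table)
    else:
        cohorts = _as_cohorts(data)

    stages: dict = {}
    statuses: dict = {}

    try:
        stages["rt_alone"] = fit_rt_alone(cohorts, constants)
        statuses["rt_alone"] = "ok"
    except FitError as exc:
        statuses["rt_alone"] = f"failed: {exc}"
        raise FitError(f"stage rt_alone failed: {exc}", getattr(exc, "trace", None))

    stage1 = stages["rt_alone"]
    g50 = stage1.free_params["gamma50"].value
    d50 = stage1.free_params["d50"].value
    cov1 = stage1.covariance  # order (gamma50, d50)

    stage2_specs = [("chemo_all", None)]
    if subsets:
        stage2_specs += [
            ("chemo_gem", ChemoCategory.GEMCITABINE),
            ("chemo_other", ChemoCategory.OTHER),
        ]
    for key, subset in stage2_specs:
        try:
            stages[key] = fit_chemo_rt(
                cohorts, g50, d50, constants, subset=subset, fixed_covariance=cov1
            )
            statuses[key] = "ok"
        except FitError as exc:
            statuses[key] = f"skipped: {exc}"

    if "chemo_all" in stages:
        stage2 = stages["chemo_all"]
        cs_all = stage2.free_params["cs"].value
        # joint covariance of the frozen (gamma50, cs): gamma50 variance from
        # stage 1, total cs variance from stage 2, and their covariance via
        # the cs sensitivity to the stage-1 parameters
        grad_cs = np.array(
            [
                stage2.fixed_sensitivity["cs"]["gamma50"],
                stage2.fixed_sensitivity["cs"]["d50"],
            ]
        )
        cov_g_cs = float(grad_cs @ cov1[:, 0])
        v_fixed = np.array(
            [
                [cov1[0, 0], cov_g_cs],
                [cov_g_cs, stage2.free_params["cs"].stderr ** 2],
            ]
        )
        try:
            stages["cpt"] = fit_cpt(
                cohorts,
                g50,
                cs_all,
                constants,
                provenance="stage 1 (gamma50) / stage 2 pooled (cs)",
                fixed_covariance=v_fixed,
            )
            statuses["cpt"] = "ok"
        except FitError as exc:
            statuses["cpt"] = f"skipped: {exc}"
    else:
        statuses["cpt"] = "skipped: stage 2 unavailable"

    order = ["rt_alone", "chemo_gem", "chemo_other", "chemo_all", "cpt"]
    summary = pd.DataFrame(
        [_summary_row(k, stages[k]) for k in order if k in stages]
    )
    return ProtocolResult(stages=stages, statuses=statuses, summary=summary)
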