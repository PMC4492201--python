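"""Staged Poisson-weighted fitting: weights, recovery, oracles, protocol."""

import numpy as np
import pytest

import chemorad as cr
from chemorad.bed import DEFAULT_CONSTANTS, compute_bed
from chemorad.dose_response import ModelParameters, overall_survival, radiotherapy_survival
from chemorad.fitting import (
    FitError,
    fit_chemo_rt,
    fit_cpt,
    fit_rt_alone,
    poisson_sd,
    run_full_protocol,
)
from chemorad.trial_data import (
    ChemoCategory,
    CohortTable,
    Modality,
    TreatmentSchedule,
    TrialCohort,
)


def _cohort(label, d, n_fx, n_total, os1y, chemo=ChemoCategory.NONE, modality=Modality.XRAY):
    s = TreatmentSchedule(modality, d, n_fx, fractions_per_week=5)
    return TrialCohort(label, 2010, s, chemo, n_total, os1y)


class TestPoissonSD:
    def test_hand_values(self):
        assert poisson_sd(_cohort("a", 2.0, 25, 100, 0.25)) == pytest.approx(0.05)
        assert poisson_sd(_cohort("b", 2.0, 25, 1, 1.0)) == pytest.approx(1.0)
        # the oldest radiotherapy-alone cohort: 2 survivors of 28
        assert poisson_sd(_cohort("c", 2.0, 25, 28, 0.07)) == pytest.approx(
            0.0505, abs=1e-4
        )

    def test_zero_survivors_floored_for_weighting(self):
        c = _cohort("z", 2.0, 25, 40, 0.0)
        assert poisson_sd(c) == pytest.approx(np.sqrt(1) / 40)

    def test_all_fixture_rows_have_finite_positive_weights(self, pooled_cohorts):
        for c in pooled_cohorts:
            sd = poisson_sd(c)
            assert np.isfinite(sd) and sd > 0


def _noise_free_cohorts(params, schedules, n_total=1000, chemo=ChemoCategory.NONE,
                        modality=Modality.XRAY):
    """Cohorts lying exactly on the survival curve (survivor counts rounded to
    the nearest patient of a large cohort, so the rounding error is <=5e-4)."""
    cohorts = []
    for i, (d, n_fx) in enumerate(schedules):
        s = TreatmentSchedule(modality, d, n_fx, fractions_per_week=5)
        p = overall_survival(compute_bed(s), params)
        ns = round(p * n_total)
        cohorts.append(
            TrialCohort(f"sim-{i}", 2010, s, chemo, n_total, ns / n_total)
        )
    return cohorts


class TestStageOne:
    def test_recovers_noise_free_truth(self):
        truth = ModelParameters(gamma50=1.5, d50=90.0)
        cohorts = _noise_free_cohorts(
            truth, [(1.8, 20), (2.0, 30), (2.5, 30), (3.0, 30), (4.0, 25)],
            n_total=10**6,
        )
        fit = fit_rt_alone(cohorts)
        assert fit.free_params["gamma50"].value == pytest.approx(1.5, rel=1e-3)
        assert fit.free_params["d50"].value == pytest.approx(90.0, rel=1e-3)

    def test_two_cohorts_underdetermined(self):
        truth = ModelParameters(gamma50=1.5, d50=90.0)
        cohorts = _noise_free_cohorts(truth, [(2.0, 30), (3.0, 30)])
        with pytest.raises(FitError):
            fit_rt_alone(cohorts)

    def test_fixture_fit_matches_published_parameters(self, fixtures):
        fit = fit_rt_alone(fixtures["table1"])
        assert fit.free_params["gamma50"].value == pytest.approx(1.2, abs=0.5)
        assert fit.free_params["d50"].value == pytest.approx(107.0, abs=16.0)
        assert fit.n_points == 5

    def test_result_invariant_to_cohort_order(self, fixtures):
        cohorts = list(fixtures["table1"])
        a = fit_rt_alone(cohorts)
        b = fit_rt_alone(cohorts[::-1])
        # summation order inside the optimiser differs, so agreement is to
        # optimiser tolerance rather than bitwise
        assert a.free_params["d50"].value == pytest.approx(
            b.free_params["d50"].value, rel=1e-6
        )
        assert a.free_params["gamma50"].value == pytest.approx(
            b.free_params["gamma50"].value, rel=1e-6
        )

    def test_local_optimality_against_random_perturbations(self, fixtures):
        fit = fit_rt_alone(fixtures["table1"])
        g, d = fit.free_params["gamma50"].value, fit.free_params["d50"].value
        labels = [p.study_label for p in fit.per_point]
        beds = np.array([p.bed for p in fit.per_point])
        obs = np.array([p.observed_os for p in fit.per_point])
        sds = np.array([p.sd for p in fit.per_point])

        def wrss(gamma, d50):
            rs = radiotherapy_survival(beds, ModelParameters(gamma, d50))
            return float(np.sum(((obs - rs) / sds) ** 2))

        best = wrss(g, d)
        rng = np.random.default_rng(0)
        for _ in range(100):
            dg, dd = rng.normal(0, 0.05), rng.normal(0, 2.0)
            assert wrss(max(g + dg, 1e-3), max(d + dd, 1.0)) >= best - 1e-9


class TestStageTwo:
    def test_pooled_cs_matches_published(self, pooled_cohorts):
        fit = fit_chemo_rt(pooled_cohorts, 1.2, 107.0)
        assert fit.free_params["cs"].value == pytest.approx(0.36, abs=0.03)
        assert fit.n_points == 55

    def test_gemcitabine_subset(self, pooled_cohorts):
        fit = fit_chemo_rt(
            pooled_cohorts, 1.2, 107.0, subset=ChemoCategory.GEMCITABINE
        )
        assert fit.free_params["cs"].value == pytest.approx(0.39, abs=0.06)
        assert fit.n_points == 18

    def test_other_drug_subset(self, pooled_cohorts):
        fit = fit_chemo_rt(pooled_cohorts, 1.2, 107.0, subset=ChemoCategory.OTHER)
        assert fit.free_params["cs"].value == pytest.approx(0.32, abs=0.05)
        assert fit.n_points == 27

    def test_grid_search_oracle_agrees(self, pooled_cohorts):
        """Dense 1000-point grid over CS in [0, 0.999] brackets the optimum."""
        fit = fit_chemo_rt(pooled_cohorts, 1.2, 107.0)
        beds = np.array([p.bed for p in fit.per_point])
        obs = np.array([p.observed_os for p in fit.per_point])
        sds = np.array([p.sd for p in fit.per_point])
        grid = np.linspace(0.0, 0.999, 1000)
        wrss = [
            float(
                np.sum(
                    (
                        (obs - overall_survival(beds, ModelParameters(1.2, 107.0, c)))
                        / sds
                    )
                    ** 2
                )
            )
            for c in grid
        ]
        best_grid = grid[int(np.argmin(wrss))]
        assert fit.free_params["cs"].value == pytest.approx(
            best_grid, abs=grid[1] - grid[0]
        )


class TestStageThree:
    def test_fixture_fit_matches_published(self, pooled_cohorts):
        fit = fit_cpt(pooled_cohorts, 1.2, 0.36)
        assert fit.free_params["d50"].value == pytest.approx(75.0, abs=9.0)
        assert fit.n_points == 4  # particle-monotherapy arms stay out

    def test_recovers_noise_free_truth_from_single_cohort(self):
        truth = ModelParameters(gamma50=1.2, d50=80.0, cs=0.36)
        cohorts = _noise_free_cohorts(
            truth, [(2.7, 25)], n_total=10**6,
            chemo=ChemoCategory.GEMCITABINE, modality=Modality.PROTON,
        )
        fit = fit_cpt(cohorts, 1.2, 0.36)
        assert fit.free_params["d50"].value == pytest.approx(80.0, rel=1e-3)

    def test_grid_search_oracle_agrees(self, pooled_cohorts):
        fit = fit_cpt(pooled_cohorts, 1.2, 0.36)
        beds = np.array([p.bed for p in fit.per_point])
        obs = np.array([p.observed_os for p in fit.per_point])
        sds = np.array([p.sd for p in fit.per_point])
        grid = np.linspace(30.0, 150.0, 1000)
        wrss = [
            float(
                np.sum(
                    (
                        (obs - overall_survival(beds, ModelParameters(1.2, d, 0.36)))
                        / sds
                    )
                    ** 2
                )
            )
            for d in grid
        ]
        best_grid = grid[int(np.argmin(wrss))]
        assert fit.free_params["d50"].value == pytest.approx(
            best_grid, abs=grid[1] - grid[0]
        )


class TestFullProtocol:
    def test_summary_mirrors_published_parameter_table(self):
        res = run_full_protocol()
        assert list(res.summary["dataset"]) == [
            "Radiotherapy (X-rays) alone",
            "Radiotherapy (X-rays) + gemcitabine",
            "Radiotherapy (X-rays) + other chemotherapy",
            "Radiotherapy (X-rays) + chemotherapy (all protocols)",
            "Charged particle therapy + chemotherapy",
        ]
        s1 = res.stages["rt_alone"]
        assert s1.free_params["gamma50"].value == pytest.approx(1.2, abs=0.5)
        assert s1.free_params["d50"].value == pytest.approx(107.0, abs=16.0)
        assert res.stages["chemo_all"].free_params["cs"].value == pytest.approx(
            0.36, abs=0.03
        )
        assert res.stages["cpt"].free_params["d50"].value == pytest.approx(
            75.0, abs=9.0
        )
        # parameter passing: stage 2/3 fixed values come from earlier stages
        assert res.stages["chemo_all"].fixed_params["d50"].value == pytest.approx(
            s1.free_params["d50"].value
        )
        assert res.stages["cpt"].fixed_params["cs"].value == pytest.approx(
            res.stages["chemo_all"].free_params["cs"].value
        )

    def test_rt_alone_only_input_skips_later_stages(self, fixtures):
        res = run_full_protocol(fixtures["table1"])
        assert res.statuses["rt_alone"] == "ok"
        assert res.statuses["chemo_all"].startswith("skipped")
        assert res.statuses["cpt"].startswith("skipped")
        assert set(res.stages) == {"rt_alone"}

    def test_propagated_errors_exceed_conditional_errors(self):
        res = run_full_protocol()
        cs = res.stages["chemo_all"].free_params["cs"]
        d50c = res.stages["cpt"].free_params["d50"]
        assert cs.stderr > cs.stderr_fit
        assert d50c.stderr > d50c.stderr_fit
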