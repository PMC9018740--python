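import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import c14turnover as ct
from c14turnover.atmosphere import CoverageError
from c14turnover.forward import CohortSolver

from oracles import mc_cohort_mean_age


class TestRate:
    def test_constant_scenario(self):
        p = ct.ScenarioAParams(beta=0.07)
        assert p.rate(0.0) == 0.07
        assert p.rate(80.0) == 0.07

    def test_lin_flat_line(self):
        p = ct.ScenarioLINParams(beta0=0.1, beta10=0.1)
        assert p.rate(37.0) == pytest.approx(0.1)

    def test_lin_clamp_ceiling(self):
        # raw line 0.01 + 0.049·t exceeds 0.5 past t = 10
        p = ct.ScenarioLINParams(beta0=0.01, beta10=0.5)
        assert p.rate(10.0) == pytest.approx(0.5)
        assert p.rate(30.0) == 0.5

    def test_lin_clamp_floor(self):
        p = ct.ScenarioLINParams(beta0=0.2, beta10=0.0)
        # raw value at age 15 is −0.1, clamped to 0
        assert p.rate(15.0) == 0.0

    def test_2pop_rate_is_renewing_rate(self):
        p = ct.Scenario2POPParams(beta=0.12, f=0.3)
        assert p.rate(5.0) == 0.12

    def test_negative_age_rejected(self):
        for p in (
            ct.ScenarioAParams(beta=0.1),
            ct.ScenarioLINParams(beta0=0.1, beta10=0.1),
            ct.Scenario2POPParams(beta=0.1, f=0.5),
        ):
            with pytest.raises(ValueError, match="age"):
                p.rate(-1.0)


class TestSolveMeanC14:
    def test_no_turnover_freezes_birth_value(self, bomb_record):
        s = ct.SubjectSample("x", 1940.0, 2000.0, "neuronal", 0.0)
        tr = ct.solve_mean_c14(ct.ScenarioAParams(beta=0.0), s, bomb_record)
        assert tr.prediction == pytest.approx(bomb_record.lagged_lookup(1940.0), abs=1e-9)

    def test_initial_condition_is_lagged_birth_value(self, bomb_record):
        s = ct.SubjectSample("x", 1958.0, 2000.0, "neuronal", 0.0)
        tr = ct.solve_mean_c14(ct.ScenarioAParams(beta=0.1), s, bomb_record)
        assert tr.ages[0] == 0.0
        assert tr.cbar[0] == pytest.approx(bomb_record.lagged_lookup(1958.0))

    def test_unlagged_initial_condition_switch(self, bomb_record):
        s = ct.SubjectSample("x", 1958.0, 2000.0, "neuronal", 0.0)
        tr = ct.solve_mean_c14(
            ct.ScenarioAParams(beta=0.0), s, bomb_record, lag_initial_condition=False
        )
        assert tr.prediction == pytest.approx(bomb_record.lookup(1958.0), abs=1e-9)

    def test_closed_form_constant_source(self, flat_record, subject_1950):
        # dc/dt = β(K − c) with c(0) = 800 has c(t) = K + (c0−K)e^{−βt};
        # elapsed 20 y at β = 0.1 from 800 toward K = 100 gives ≈ 194.74
        solver = CohortSolver(
            [ct.SubjectSample("x", 1950.0, 1970.0, "neuronal", 0.0)],
            flat_record,
            max_step=np.inf,
        )
        solver.c0 = np.array([800.0])
        pred = solver.predict(ct.ScenarioAParams(beta=0.1))[0]
        expected = 100.0 + 700.0 * np.exp(-2.0)
        assert pred == pytest.approx(expected, rel=1e-12)

    @given(
        beta=st.floats(1e-4, 0.5),
        elapsed=st.floats(1.0, 80.0),
    )
    def test_closed_form_equivalence_property(self, beta, elapsed, flat_record):
        solver = CohortSolver(
            [ct.SubjectSample("x", 1930.0, 1930.0 + elapsed, "neuronal", 0.0)],
            flat_record,
        )
        solver.c0 = np.array([650.0])
        pred = solver.predict(ct.ScenarioAParams(beta=beta))[0]
        expected = 100.0 + 550.0 * np.exp(-beta * elapsed)
        assert pred == pytest.approx(expected, rel=1e-6)

    def test_2pop_equilibrium_splits_mixture(self, flat_record):
        # large β, long time: renewing half reaches K, quiescent half keeps c0
        solver = CohortSolver(
            [ct.SubjectSample("x", 1910.0, 2010.0, "neuronal", 0.0)], flat_record
        )
        solver.c0 = np.array([800.0])
        pred = solver.predict(ct.Scenario2POPParams(beta=0.5, f=0.5))[0]
        assert pred == pytest.approx((800.0 + 100.0) / 2.0, rel=1e-9)

    def test_2pop_is_f_weighted_mixture_exactly(self, bomb_record):
        s = ct.SubjectSample("x", 1945.0, 2015.0, "neuronal", 0.0)
        f, beta = 0.37, 0.08
        p_mix = ct.predict_cohort(ct.Scenario2POPParams(beta=beta, f=f), [s], bomb_record)
        p_renew = ct.predict_cohort(ct.ScenarioAParams(beta=beta), [s], bomb_record)
        c0 = bomb_record.lagged_lookup(1945.0)
        assert p_mix[0] == pytest.approx((1 - f) * c0 + f * p_renew[0], rel=1e-12)

    @given(
        beta=st.floats(0.0, 0.5),
        birth=st.floats(1925.0, 1990.0),
    )
    def test_convexity_bound(self, beta, birth, bomb_record):
        s = ct.SubjectSample("x", birth, 2015.0, "neuronal", 0.0)
        tr = ct.solve_mean_c14(ct.ScenarioAParams(beta=beta), s, bomb_record)
        window = bomb_record.lagged_lookup(birth + tr.ages)
        lo = min(window.min(), tr.cbar[0])
        hi = max(window.max(), tr.cbar[0])
        assert np.all(tr.cbar >= lo - 1e-9)
        assert np.all(tr.cbar <= hi + 1e-9)

    def test_coverage_violation(self, bomb_record):
        s = ct.SubjectSample("x", 1919.0, 2000.0, "neuronal", 0.0)
        with pytest.raises(CoverageError, match="x"):
            ct.solve_mean_c14(ct.ScenarioAParams(beta=0.1), s, bomb_record)

    def test_lin_grid_refinement_converges(self, bomb_record):
        # halving the step changes the LIN solution far below noise scale
        s = ct.SubjectSample("x", 1940.0, 2015.0, "neuronal", 0.0)
        p = ct.ScenarioLINParams(beta0=0.3, beta10=0.01)
        coarse = ct.predict_cohort(p, [s], bomb_record, max_step=0.25)[0]
        fine = ct.predict_cohort(p, [s], bomb_record, max_step=0.03125)[0]
        assert coarse == pytest.approx(fine, abs=0.05)


class TestPredictCohort:
    def test_empty_list(self, bomb_record):
        assert ct.predict_cohort(ct.ScenarioAParams(beta=0.1), [], bomb_record).size == 0

    def test_single_sample_consistency(self, bomb_record):
        s = ct.SubjectSample("x", 1952.0, 2012.0, "neuronal", 0.0)
        p = ct.ScenarioLINParams(beta0=0.05, beta10=0.01)
        tr = ct.solve_mean_c14(p, s, bomb_record)
        pred = ct.predict_cohort(p, [s], bomb_record)
        assert pred[0] == pytest.approx(tr.prediction, rel=1e-12)

    def test_identical_samples_identical_predictions(self, bomb_record):
        s1 = ct.SubjectSample("a", 1952.0, 2012.0, "neuronal", 0.0)
        s2 = ct.SubjectSample("b", 1952.0, 2012.0, "neuronal", 5.0)
        pred = ct.predict_cohort(ct.ScenarioAParams(beta=0.04), [s1, s2], bomb_record)
        assert pred[0] == pred[1]

    def test_batched_predictions_match_scalar(self, bomb_record, cohort_2pop):
        samples, _ = cohort_2pop
        solver = CohortSolver(samples, bomb_record)
        betas = np.array([0.01, 0.1, 0.4])
        batch = solver.final_const(betas)
        for i, b in enumerate(betas):
            np.testing.assert_allclose(
                batch[i], solver.predict(ct.ScenarioAParams(beta=b)), rtol=1e-12
            )


class TestMeanCellAge:
    def test_no_turnover_is_bisector(self):
        assert ct.mean_cell_age(ct.Scenario2POPParams(beta=0.3, f=0.0), 62.0) == 62.0
        assert ct.mean_cell_age(ct.ScenarioAParams(beta=0.0), 47.5) == 47.5

    def test_constant_rate_closed_form(self):
        got = ct.mean_cell_age(ct.ScenarioAParams(beta=0.1), 50.0)
        assert got == pytest.approx((1 - np.exp(-5.0)) / 0.1, rel=1e-9)

    def test_2pop_f1_reduces_to_constant(self):
        a = ct.mean_cell_age(ct.ScenarioAParams(beta=0.07), 40.0)
        two = ct.mean_cell_age(ct.Scenario2POPParams(beta=0.07, f=1.0), 40.0)
        assert two == pytest.approx(a, rel=1e-12)

    def test_lin_flat_matches_constant(self):
        lin = ct.mean_cell_age(ct.ScenarioLINParams(beta0=0.1, beta10=0.1), 50.0)
        const = ct.mean_cell_age(ct.ScenarioAParams(beta=0.1), 50.0)
        assert lin == pytest.approx(const, rel=1e-6)

    def test_monte_carlo_validation(self):
        mean, sd, n = mc_cohort_mean_age(0.1, 50.0, seed=42)
        got = ct.mean_cell_age(ct.ScenarioAParams(beta=0.1), 50.0)
        assert abs(got - mean) < 3.0 * sd / np.sqrt(n)

    @pytest.mark.parametrize(
        "params",
        [
            ct.ScenarioAParams(beta=0.05),
            ct.ScenarioLINParams(beta0=0.08, beta10=0.01),
            ct.Scenario2POPParams(beta=0.1, f=0.29),
        ],
    )
    def test_monotone_and_bounded(self, params):
        ages = np.linspace(0.0, 90.0, 19)
        vals = [ct.mean_cell_age(params, a) for a in ages]
        assert np.all(np.diff(vals) >= -1e-9)
        assert np.all(np.asarray(vals) <= ages + 1e-9)

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            ct.mean_cell_age(ct.ScenarioAParams(beta=0.1), -3.0)
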