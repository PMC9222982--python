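import math

import numpy as np
import pytest
from scipy.optimize import minimize

from roicox import (
    LinearCoxModel,
    OptimizerConfig,
    SurvivalTask,
    concordance_index,
    cph_loss,
    fit_cph,
    fit_cph_roi,
    linear_hazard,
    neg_log_partial_likelihood,
    predict_risk,
    roi_loss,
)
from roicox.exceptions import ShapeError, UndefinedLikelihoodError


def npll_brute(h, t, e):
    """Independent risk-set enumeration oracle, no log-sum-exp."""
    total = 0.0
    for i in range(len(h)):
        if e[i] == 1:
            denom = sum(math.exp(h[j]) for j in range(len(h)) if t[j] >= t[i])
            total -= h[i] - math.log(denom)
    return total


class TestLinearHazard:
    def test_zero_model_gives_zero(self):
        assert np.array_equal(linear_hazard(np.ones((3, 2)), np.zeros(2), 0.0), np.zeros(3))

    def test_arithmetic_identity(self):
        h = linear_hazard(np.array([[3.0, 1.0]]), np.array([1.0, -1.0]), 2.0)
        assert h[0] == 4.0

    def test_matches_dot_product_oracle(self, rng):
        X = rng.normal(size=(5, 3))
        beta = rng.normal(size=3)
        expected = [sum(X[i, j] * beta[j] for j in range(3)) + 0.7 for i in range(5)]
        assert np.allclose(linear_hazard(X, beta, 0.7), expected, atol=1e-12)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ShapeError):
            linear_hazard(rng.normal(size=(4, 3)), np.zeros(2), 0.0)


class TestNegLogPartialLikelihood:
    def test_all_events_zero_hazard_is_log_factorial(self):
        v = neg_log_partial_likelihood(np.zeros(3), np.array([1.0, 2.0, 3.0]), np.ones(3))
        assert abs(v - math.log(6)) < 1e-12

    def test_bias_invariance(self, rng):
        for _ in range(20):
            n = rng.integers(3, 10)
            h = rng.normal(0, 3, n)
            t = rng.uniform(1, 10, n)
            e = rng.integers(0, 2, n)
            if e.sum() == 0:
                e[0] = 1
            c = rng.normal(0, 50)
            v0 = neg_log_partial_likelihood(h, t, e)
            v1 = neg_log_partial_likelihood(h + c, t, e)
            assert abs(v0 - v1) < 1e-9 * max(1.0, abs(v0))

    def test_tie_and_censoring_against_brute_force(self):
        h = np.array([0.4, -1.2, 0.9, 0.0, 2.1])
        t = np.array([3.0, 3.0, 1.0, 5.0, 2.0])  # tie at t=3
        e = np.array([1, 1, 1, 0, 0])
        assert abs(neg_log_partial_likelihood(h, t, e) - npll_brute(h, t, e)) < 1e-10

    def test_oracle_equivalence_all_small_instances(self, rng):
        for _ in range(300):
            n = int(rng.integers(2, 9))
            h = rng.normal(0, 2, n)
            t = np.round(rng.uniform(1, 4, n), 0) + 1  # frequent ties
            e = rng.integers(0, 2, n)
            if e.sum() == 0:
                continue
            v = neg_log_partial_likelihood(h, t, e)
            assert abs(v - npll_brute(h, t, e)) < 1e-10

    def test_zero_events_raise(self):
        with pytest.raises(UndefinedLikelihoodError):
            neg_log_partial_likelihood(np.zeros(3), np.arange(1.0, 4.0), np.zeros(3))

    def test_extreme_hazards_stay_finite(self):
        v = neg_log_partial_likelihood(
            np.array([500.0, -500.0, 0.0]), np.array([1.0, 2.0, 3.0]), np.ones(3)
        )
        assert np.isfinite(v)


class TestLossFunctions:
    def test_zero_parameters_no_penalty(self, small_task):
        assert cph_loss(np.zeros(2), 0.0, small_task, 0.5) == pytest.approx(
            neg_log_partial_likelihood(np.zeros(6), small_task.t, small_task.e)
        )

    def test_zero_weight_reduces_to_likelihood(self, small_task, rng):
        beta = rng.normal(size=2)
        h = linear_hazard(small_task.X, beta, 0.3)
        assert cph_loss(beta, 0.3, small_task, 0.0) == pytest.approx(
            neg_log_partial_likelihood(h, small_task.t, small_task.e)
        )

    def test_penalty_arithmetic(self, small_task):
        with_pen = cph_loss(np.array([1.0, 2.0]), 3.0, small_task, 1e-4)
        without = cph_loss(np.array([1.0, 2.0]), 3.0, small_task, 0.0)
        assert with_pen - without == pytest.approx(0.0014)  # 1e-4 * (1 + 4 + 9)

    @pytest.mark.parametrize("lam,expect_outcome", [(0.0, "base"), (1.0, "aux")])
    def test_roi_lambda_limits(self, small_paired, rng, lam, expect_outcome):
        b1, b2 = rng.normal(size=2), rng.normal(size=2)
        joint = roi_loss(b1, b2, 0.1, small_paired, roi_weight=lam)
        if expect_outcome == "base":
            assert joint == pytest.approx(cph_loss(b1, 0.1, small_paired.base))
        else:
            assert joint == pytest.approx(cph_loss(b2, 0.1, small_paired.aux_task()))

    def test_identical_outcomes_convex_identity(self, small_task, rng):
        from roicox import PairedSurvivalTask

        paired = PairedSurvivalTask(small_task, small_task.t.copy(), small_task.e.copy())
        beta = rng.normal(size=2)
        for lam in (0.0, 0.2, 0.7, 1.0):
            assert roi_loss(beta, beta, 0.4, paired, lam) == pytest.approx(
                cph_loss(beta, 0.4, small_task)
            )

    def test_zero_event_outcome_named(self, small_task):
        from roicox import PairedSurvivalTask

        paired = PairedSurvivalTask(small_task, small_task.t.copy(), np.zeros(6, int))
        with pytest.raises(UndefinedLikelihoodError, match="auxiliary"):
            roi_loss(np.zeros(2), np.zeros(2), 0.0, paired)


class TestFitCph:
    def test_pure_noise_with_strong_penalty_shrinks(self, rng):
        n = 40
        X = rng.normal(size=(n, 3))
        task = SurvivalTask(
            list(range(n)), X, rng.uniform(1, 100, n), rng.integers(0, 2, n) | 1
        )
        model = fit_cph(task, l2_weight=1000.0)
        assert np.all(np.abs(model.beta) < 0.05)

    def test_agrees_with_independent_numeric_oracle(self, rng):
        # second implementation: BFGS with numeric gradient on the
        # brute-force objective, nothing shared with the fitter's path
        n, p = 20, 2
        X = rng.normal(size=(n, p))
        beta_true = np.array([1.0, -0.5])
        t = rng.exponential(scale=np.exp(-X @ beta_true))
        e = np.ones(n, int)
        task = SurvivalTask(list(range(n)), X, t, e)

        def objective(theta):
            h = [sum(X[i, j] * theta[j] for j in range(p)) + theta[p] for i in range(n)]
            return npll_brute(np.array(h), t, e) + 1e-4 * sum(th**2 for th in theta)

        oracle = minimize(objective, np.zeros(p + 1), method="BFGS",
                          options={"gtol": 1e-10}).x
        model = fit_cph(task)
        assert np.max(np.abs(model.beta - oracle[:p])) < 1e-4

    def test_bias_pinned_near_zero_by_penalty(self, mid_paired):
        model = fit_cph(mid_paired[0].base)
        assert abs(model.bias) < 1e-3

    def test_monotone_shrinkage(self, mid_paired):
        norms = [
            np.linalg.norm(fit_cph(mid_paired[0].base, l2_weight=lw).beta)
            for lw in (1e-4, 1e-2, 1e-1, 1.0)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_deterministic_given_seed(self, mid_paired):
        m1 = fit_cph(mid_paired[0].base, opt=OptimizerConfig(seed=3))
        m2 = fit_cph(mid_paired[0].base, opt=OptimizerConfig(seed=3))
        assert np.array_equal(m1.beta, m2.beta) and m1.bias == m2.bias

    def test_matches_lifelines_reference(self, mid_paired):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        base = mid_paired[0].base
        df = pd.DataFrame(base.X)
        df["T"], df["E"] = base.t, base.e
        ll = lifelines.CoxPHFitter(penalizer=1e-4)
        ll.fit(df, duration_col="T", event_col="E")
        ours = fit_cph(base)
        r = np.corrcoef(ours.beta, ll.params_.values)[0, 1]
        assert r > 0.999


class TestFitCphRoi:
    def test_lambda_zero_reduces_to_single_fit(self, mid_paired):
        paired = mid_paired[0]
        single = fit_cph(paired.base, opt=OptimizerConfig(seed=9))
        joint = fit_cph_roi(paired, roi_weight=0.0, opt=OptimizerConfig(seed=9))
        assert np.max(np.abs(single.beta - joint.beta)) < 1e-4

    def test_duplicated_outcome_symmetry(self, mid_paired):
        from roicox import PairedSurvivalTask

        base = mid_paired[0].base
        dup = PairedSurvivalTask(base, base.t.copy(), base.e.copy())
        joint = fit_cph_roi(dup, roi_weight=0.5)
        single = fit_cph(base)
        assert np.max(np.abs(joint.beta - joint.beta_aux)) < 1e-3
        assert np.max(np.abs(joint.beta - single.beta)) < 1e-3

    def test_primary_coefficients_equal_plain_fit(self, mid_paired):
        # The shared bias cancels in both partial likelihoods, so the joint
        # objective is block-separable and the primary solution coincides
        # with the plain fit at any mixing weight.
        paired = mid_paired[0]
        plain = fit_cph(paired.base, opt=OptimizerConfig(seed=4))
        joint = fit_cph_roi(paired, roi_weight=0.2, opt=OptimizerConfig(seed=4))
        assert np.max(np.abs(plain.beta - joint.beta)) < 1e-4


class TestPredictRisk:
    def test_zero_model(self, small_task):
        model = LinearCoxModel(beta=np.zeros(2), bias=0.0)
        assert np.array_equal(predict_risk(model, small_task.X), np.zeros(6))

    def test_bias_shift_leaves_cindex_unchanged(self, small_task, rng):
        beta = rng.normal(size=2)
        m1 = LinearCoxModel(beta=beta, bias=0.0)
        m2 = LinearCoxModel(beta=beta, bias=13.7)
        c1 = concordance_index(predict_risk(m1, small_task.X), small_task.t, small_task.e)
        c2 = concordance_index(predict_risk(m2, small_task.X), small_task.t, small_task.e)
        assert c1.c_index == c2.c_index

    def test_json_round_trip(self, mid_paired):
        model = fit_cph_roi(mid_paired[0])
        back = LinearCoxModel.from_json(model.to_json())
        assert np.array_equal(model.beta, back.beta)
        assert np.array_equal(model.beta_aux, back.beta_aux)
        assert model.bias == back.bias
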