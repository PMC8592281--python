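"""Estimator battery: worked examples, oracle checks, invariances."""

import numpy as np
import pytest

from dietmr.estimators import (
    EstimatorConfig,
    EstimatorError,
    egger,
    ivw,
    radial_filter,
    raps,
    run_estimators,
    wald_ratio,
    weighted_median,
)
from dietmr.simulate import simulate_instrument_set

from conftest import make_instrument_set


def brute_force_ivw(bx, by, sy, lo=-10.0, hi=10.0, tol=1e-9):
    """Independent oracle: bisection on the derivative of the weighted SSE
    sum w_j (by_j - beta*bx_j)^2 (convex in beta)."""
    w = 1.0 / np.asarray(sy, float) ** 2

    def dsse(beta):
        return float(np.sum(-2.0 * w * np.asarray(bx) * (np.asarray(by) - beta * np.asarray(bx))))

    a, b = lo, hi
    for _ in range(200):
        m = 0.5 * (a + b)
        if dsse(m) > 0:
            b = m
        else:
            a = m
        if b - a < tol:
            break
    return 0.5 * (a + b)


class TestWaldRatio:
    @pytest.mark.parametrize(
        "bx,by,sy,beta,se",
        [(1.0, 0.5, 0.1, 0.5, 0.1), (2.0, 1.0, 0.2, 0.5, 0.1), (-1.0, 0.5, 0.1, -0.5, 0.1)],
    )
    def test_ratio_and_delta_se(self, bx, by, sy, beta, se):
        r = wald_ratio(make_instrument_set([bx], [by], [sy]))
        assert r.beta == pytest.approx(beta)
        assert r.se == pytest.approx(se)
        assert r.method == "wald_ratio"

    def test_zero_exposure_effect_is_error(self):
        with pytest.raises(EstimatorError):
            wald_ratio(make_instrument_set([0.0], [0.5], [0.1]))


class TestIvw:
    def test_worked_example(self):
        iset = make_instrument_set([1.0, 1.0], [0.5, 0.7], [0.1, 0.1])
        r = ivw(iset)
        assert r.beta == pytest.approx(0.6)
        assert r.se == pytest.approx(0.070711, abs=1e-6)
        assert r.Q == pytest.approx(2.0)
        assert r.Q_df == 1
        assert r.Q_pvalue == pytest.approx(0.15730, abs=1e-4)
        assert r.variance_model == "fixed"          # 0.157 > 0.05/123

    def test_perfect_fit_has_zero_q(self):
        iset = make_instrument_set([1.0, 2.0, 3.0], [0.5, 1.0, 1.5], [0.1, 0.1, 0.1])
        r = ivw(iset)
        assert r.beta == pytest.approx(0.5)
        assert r.Q == pytest.approx(0.0, abs=1e-20)
        assert r.variance_model == "fixed"

    def test_heterogeneity_triggers_random_effects_inflation(self):
        iset = make_instrument_set(
            [1.0] * 4, [0.0, 0.0, 2.0, 2.0], [0.01] * 4
        )
        r = ivw(iset)
        assert r.variance_model == "random"
        fixed_se = (np.sum(1 / 0.01**2 * np.ones(4))) ** -0.5
        assert r.se == pytest.approx(fixed_se * np.sqrt(r.Q / 3))

    def test_ci_is_symmetric_wald(self):
        r = ivw(make_instrument_set([1.0, 1.0], [0.5, 0.7], [0.1, 0.1]))
        assert r.ci_low == pytest.approx(r.beta - 1.96 * r.se, abs=1e-9)
        assert r.ci_high == pytest.approx(r.beta + 1.96 * r.se, abs=1e-9)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            k = rng.integers(2, 6)
            bx = rng.normal(0.2, 0.1, k)
            by = rng.normal(0.1, 0.2, k)
            sy = rng.uniform(0.05, 0.3, k)
            r = ivw(make_instrument_set(bx, by, sy))
            assert r.beta == pytest.approx(brute_force_ivw(bx, by, sy), abs=1e-6)


class TestEgger:
    def test_exact_line_through_origin(self):
        iset = make_instrument_set([1, 2, 3], [0.5, 1.0, 1.5], [0.1, 0.1, 0.1])
        r = egger(iset)
        assert r.beta == pytest.approx(0.5, abs=1e-12)
        assert r.egger_intercept == pytest.approx(0.0, abs=1e-12)
        assert r.Q_df == 1

    def test_constant_offset_appears_in_intercept(self):
        iset = make_instrument_set([1, 2, 3], [0.6, 1.1, 1.6], [0.1, 0.1, 0.1])
        r = egger(iset)
        assert r.beta == pytest.approx(0.5, abs=1e-12)
        assert r.egger_intercept == pytest.approx(0.1, abs=1e-12)

    def test_orientation_flip_leaves_fit_invariant(self):
        plain = make_instrument_set([1, 2, 3], [0.6, 1.1, 1.6], [0.1, 0.1, 0.1])
        flipped = make_instrument_set([1, -2, 3], [0.6, -1.1, 1.6], [0.1, 0.1, 0.1])
        assert egger(flipped).beta == pytest.approx(egger(plain).beta)
        assert egger(flipped).egger_intercept == pytest.approx(egger(plain).egger_intercept)


class TestWeightedMedian:
    def test_symmetric_ratios(self):
        iset = make_instrument_set([1, 1, 1], [0.4, 0.5, 0.6], [0.1, 0.1, 0.1])
        assert weighted_median(iset, n_boot=50).beta == pytest.approx(0.5)

    def test_majority_weight_defeats_outlier(self):
        # weights proportional to {0.45, 0.45, 0.10}
        w = np.array([0.45, 0.45, 0.10])
        bx = np.sqrt(w)
        by = bx * np.array([0.5, 0.5, 5.0])
        iset = make_instrument_set(bx, by, [1.0, 1.0, 1.0])
        assert weighted_median(iset, n_boot=50).beta == pytest.approx(0.5)

    def test_dominating_weight_pins_estimate(self):
        w = np.array([0.005, 0.99, 0.005])
        bx = np.sqrt(w)
        by = bx * np.array([0.5, 0.7, 0.9])
        iset = make_instrument_set(bx, by, [1.0, 1.0, 1.0])
        assert weighted_median(iset, n_boot=50).beta == pytest.approx(0.7, abs=1e-6)

    def test_order_invariant_including_bootstrap_se(self, rng):
        iset = simulate_instrument_set(8, 0.3, seed=3)
        perm = rng.permutation(len(iset))
        shuffled = iset.subset(perm)
        a = weighted_median(iset, n_boot=100, seed=5)
        b = weighted_median(shuffled, n_boot=100, seed=5)
        assert a.beta == b.beta
        assert a.se == b.se


class TestRaps:
    def test_reduces_to_ivw_when_exposure_error_vanishes(self):
        iset = simulate_instrument_set(10, 0.3, seed=2, se_exposure=1e-12)
        assert raps(iset).beta == pytest.approx(ivw(iset).beta, abs=1e-6)
        assert raps(iset).se == pytest.approx(ivw(iset).se, rel=1e-3)

    def test_zero_outcome_effects_give_zero_estimate(self):
        iset = make_instrument_set([0.1, 0.2, 0.3], [0.0, 0.0, 0.0], [0.1, 0.1, 0.1],
                                   sx=[0.01, 0.01, 0.01])
        assert raps(iset).beta == pytest.approx(0.0, abs=1e-6)

    def test_recovers_truth_with_exposure_noise(self):
        reps = 60
        ests = []
        for s in range(reps):
            iset = simulate_instrument_set(
                30, 0.3, seed=1000 + s, se_exposure=0.02, se_outcome=0.02
            )
            ests.append(raps(iset).beta)
        mc_se = np.std(ests, ddof=1) / np.sqrt(reps)
        assert np.mean(ests) == pytest.approx(0.3, abs=3 * mc_se + 1e-3)


class TestRadialFilter:
    def test_homogeneous_set_unchanged(self):
        iset = simulate_instrument_set(20, 0.5, seed=4)
        filtered, removed = radial_filter(iset)
        assert removed == []
        assert len(filtered) == 20

    def test_planted_outlier_removed(self):
        iset = simulate_instrument_set(
            21, 0.5, seed=9, outlier_ratio=5.0, outlier_se=0.005
        )
        filtered, removed = radial_filter(iset)
        assert iset.snp_ids[-1] in removed
        assert len(filtered) == 20

    def test_two_discordant_snps_stop_at_guard(self):
        iset = make_instrument_set([1.0, 1.0], [5.0, -5.0], [0.01, 0.01])
        filtered, removed = radial_filter(iset)
        assert len(removed) <= 1
        assert len(filtered) >= 1


class TestScaleAndPermutationInvariance:
    @pytest.mark.parametrize("c", [0.5, 2.0, -3.0])
    def test_outcome_scale_equivariance(self, c):
        iset = simulate_instrument_set(12, 0.3, seed=6)
        scaled = make_instrument_set(
            iset.beta_exposure, c * iset.beta_outcome, abs(c) * iset.se_outcome,
            sx=iset.se_exposure, snp_ids=iset.snp_ids,
        )
        assert ivw(scaled).beta == pytest.approx(c * ivw(iset).beta, rel=1e-9)
        assert egger(scaled).beta == pytest.approx(c * egger(iset).beta, rel=1e-9)
        assert raps(scaled).beta == pytest.approx(c * raps(iset).beta, abs=1e-5)

    def test_permutation_invariance(self, rng):
        iset = simulate_instrument_set(15, 0.3, seed=8)
        perm = rng.permutation(len(iset))
        shuffled = iset.subset(perm)
        assert ivw(shuffled).beta == pytest.approx(ivw(iset).beta, rel=1e-12)
        assert egger(shuffled).beta == pytest.approx(egger(iset).beta, rel=1e-12)
        assert raps(shuffled).beta == pytest.approx(raps(iset).beta, abs=1e-8)


class TestRunEstimators:
    def test_single_instrument_routes_to_wald(self):
        iset = simulate_instrument_set(1, 0.3, seed=1)
        results = run_estimators(iset)
        assert [r.method for r in results] == ["wald_ratio"]

    def test_two_instruments_yield_ivw_only(self):
        iset = simulate_instrument_set(2, 0.3, seed=1)
        results = run_estimators(iset)
        assert [r.method for r in results] == ["ivw"]

    def test_clean_thirty_instrument_set_runs_full_battery(self):
        iset = simulate_instrument_set(30, 0.3, seed=1)
        results = run_estimators(iset, EstimatorConfig(median_n_boot=50))
        assert [r.method for r in results] == ["ivw", "egger", "weighted_median", "raps"]
        assert len({r.nsnp for r in results}) == 1  # all carry post-radial nsnp

    def test_empty_set_not_analyzed(self):
        iset = simulate_instrument_set(3, 0.3, seed=1).subset(np.zeros(3, dtype=bool))
        assert run_estimators(iset) == []
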