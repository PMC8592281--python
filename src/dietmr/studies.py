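"""Seeded validation studies: estimator calibration, robustness, FDR control.

Each function runs a self-contained simulation study against the package's
own estimators and returns the measured operating characteristics.  These
are the quantitative claims the package makes about itself; the test suite
asserts them and ``scripts/acceptance.py`` reports them.

Study design notes
------------------
* The pleiotropy-contamination and Egger-recovery studies draw all true
  SNP→exposure effects positive.  With signed effects, orienting
  instruments (or forming ratios) turns directional pleiotropy into
  balanced pleiotropy and the contamination washes out; the positive-effect
  design is the standard way to exercise the InSIDE scenario.
* The contamination study uses strong instruments (outcome SE 0.002 against
  exposure effects of 0.05–0.2) so that per-SNP ratio noise is small and
  the measured weighted-median bias isolates the contamination effect
  rather than finite-sample quantile noise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cur import compute_cur_records, filter_by_cur, stepwise_mvmr
from .estimators import egger, ivw, radial_filter, weighted_median
from .pc import fit_pc_model, project_effects
from .pipeline import PipelineData, PipelineSettings, run_pipeline
from .report import storey_qvalues
from .simulate import (
    null_grid_config,
    simulate_cur_scenario,
    simulate_grid,
    simulate_instrument_set,
)
from .sumstats import GroupSpec


def _spawn(seed: int, offset: int) -> int:
    return (int(seed) * 7919 + offset) % (2**31 - 1)


# ---------------------------------------------------------------------------
# IVW against an independent brute-force minimizer


def brute_force_ivw(bx, by, sy, lo=-10.0, hi=10.0) -> float:
    """Minimize Σ w_j (β_Yj − β β_Xj)² by coarse grid + interval refinement.

    Deliberately avoids the closed form: this is the independent oracle the
    analytic IVW estimate is checked against.
    """
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    w = 1.0 / np.asarray(sy, float) ** 2

    def sse(beta: np.ndarray) -> np.ndarray:
        return np.sum(w * (by[None, :] - beta[:, None] * bx[None, :]) ** 2, axis=1)

    a, b = lo, hi
    for _ in range(40):  # each pass shrinks the bracket 10x around the best grid point
        grid = np.linspace(a, b, 41)
        best = grid[int(np.argmin(sse(grid)))]
        step = (b - a) / 40.0
        a, b = best - step, best + step
        if b - a < 1e-12:
            break
    return float(0.5 * (a + b))


def ivw_oracle_agreement(n_sets: int = 100, seed: int = 0) -> dict:
    """Max |IVW − brute force| over random instrument sets of size 2–5."""
    from .harmonize import InstrumentSet

    rng = np.random.default_rng(_spawn(seed, 1))
    worst = 0.0
    for _ in range(n_sets):
        k = int(rng.integers(2, 6))
        bx = rng.normal(0.2, 0.1, k)
        bx[np.abs(bx) < 0.01] = 0.01
        by = rng.normal(0.1, 0.2, k)
        sy = rng.uniform(0.05, 0.3, k)
        iset = InstrumentSet(
            exposure_name="exp", outcome_name="out",
            snp_ids=np.array([f"rs{i}" for i in range(k)], dtype=object),
            beta_exposure=bx, se_exposure=np.full(k, 1e-6),
            beta_outcome=by, se_outcome=sy,
            pvalue_exposure=np.full(k, 1e-10), eaf_exposure=np.full(k, 0.3),
        )
        worst = max(worst, abs(ivw(iset).beta - brute_force_ivw(bx, by, sy)))
    return {"max_abs_difference": worst, "n": n_sets}


# ---------------------------------------------------------------------------
# coverage / type-I calibration


def ivw_coverage(n_sims: int = 1000, k: int = 30, beta_true: float = 0.3,
                 seed: int = 0) -> dict:
    """Fraction of 95% IVW confidence intervals covering the true effect."""
    covered = 0
    for s in range(n_sims):
        iset = simulate_instrument_set(k, beta_true, seed=_spawn(seed, 100 + s))
        r = ivw(iset)
        covered += r.ci_low <= beta_true <= r.ci_high
    return {"coverage": covered / n_sims, "n": n_sims}


def ivw_type1_error(n_sims: int = 2000, k: int = 30, seed: int = 0) -> dict:
    """Fraction of IVW p-values below 0.05 when the true effect is zero."""
    hits = 0
    for s in range(n_sims):
        iset = simulate_instrument_set(k, 0.0, seed=_spawn(seed, 5_000_000 + s))
        hits += ivw(iset).pvalue < 0.05
    return {"type1_error": hits / n_sims, "n": n_sims}


# ---------------------------------------------------------------------------
# robustness to invalid instruments


def pleiotropy_contamination(n_runs: int = 500, k: int = 30,
                             invalid_fraction: float = 0.4,
                             beta_true: float = 0.3, seed: int = 0) -> dict:
    """Weighted-median vs naive IVW bias with directional pleiotropy.

    ``invalid_fraction`` of instruments carry an extra outcome effect of
    mean 0.1 (all in one direction); instruments carrying the remaining
    >50% of the weight stay valid, so the weighted median should hold while
    IVW is dragged.
    """
    n_invalid = int(round(invalid_fraction * k))
    ivw_est, med_est = [], []
    for s in range(n_runs):
        iset = simulate_instrument_set(
            k, beta_true, seed=_spawn(seed, 10_000_000 + s),
            n_invalid=n_invalid, pleiotropy_mean=0.1, pleiotropy_sd=0.05,
            se_outcome=0.002, signed_gamma=False,
        )
        ivw_est.append(ivw(iset).beta)
        med_est.append(weighted_median(iset, n_boot=50, seed=s).beta)
    return {
        "ivw_bias": float(np.mean(ivw_est) - beta_true),
        "weighted_median_bias": float(np.mean(med_est) - beta_true),
        "n": n_runs,
    }


def egger_intercept_recovery(n_runs: int = 500, k: int = 30,
                             pleiotropy_mean: float = 0.05, seed: int = 0) -> dict:
    """Mean MR-Egger intercept when every instrument carries directional
    pleiotropy of the given mean (InSIDE holds by construction)."""
    intercepts = []
    for s in range(n_runs):
        iset = simulate_instrument_set(
            k, 0.3, seed=_spawn(seed, 20_000_000 + s),
            n_invalid=k, pleiotropy_mean=pleiotropy_mean, pleiotropy_sd=0.02,
            signed_gamma=False,
        )
        intercepts.append(egger(iset).egger_intercept)
    return {
        "mean_intercept": float(np.mean(intercepts)),
        "true_intercept": pleiotropy_mean,
        "mc_se": float(np.std(intercepts, ddof=1) / np.sqrt(n_runs)),
        "n": n_runs,
    }


def radial_outlier_study(n_runs: int = 500, k: int = 20, seed: int = 0) -> dict:
    """Detection and false-alarm rates of the radial outlier filter.

    A planted instrument with a 10x causal ratio (5.0 against a true 0.5)
    and small SE should be removed; fully homogeneous sets should pass
    untouched.
    """
    detected = clean = 0
    for s in range(n_runs):
        planted = simulate_instrument_set(
            k + 1, 0.5, seed=_spawn(seed, 30_000_000 + s),
            outlier_ratio=5.0, outlier_se=0.005,
        )
        _, removed = radial_filter(planted)
        detected += list(removed) == [planted.snp_ids[-1]]

        homogeneous = simulate_instrument_set(k, 0.5, seed=_spawn(seed, 40_000_000 + s))
        _, removed = radial_filter(homogeneous)
        clean += len(removed) == 0
    return {
        "outlier_removal_rate": detected / n_runs,
        "clean_no_removal_rate": clean / n_runs,
        "n": n_runs,
    }


# ---------------------------------------------------------------------------
# CUR filter operating characteristics


def cur_filter_performance(n_direct: int = 50, n_mediated: int = 50,
                           alpha: float = 0.5, se: float = 0.01,
                           seed: int = 0) -> dict:
    """Sensitivity (mediated SNPs dropped) and specificity (direct SNPs kept)."""
    food, conf, roles = simulate_cur_scenario(
        n_direct=n_direct, n_mediated=n_mediated, alpha=alpha, se=se,
        seed=_spawn(seed, 50),
    )
    ids = list(food.df.index)
    fit = stepwise_mvmr(food, [conf], ids)
    records = compute_cur_records(food, fit, [conf], ids)
    kept = set(filter_by_cur(records, window=0.05))
    direct = set(roles.index[roles == "direct"])
    mediated = set(roles.index[roles == "confounder_mediated"])
    return {
        "sensitivity": len(mediated - kept) / max(1, len(mediated)),
        "specificity": len(direct & kept) / max(1, len(direct)),
        "alpha_estimate": fit.alpha.get(conf.trait_name, (np.nan, np.nan))[0],
        "n": n_direct + n_mediated,
    }


# ---------------------------------------------------------------------------
# PC projection error propagation


def pc_projection_check(n_draws: int = 1_000_000, seed: int = 0) -> dict:
    """Propagated se_pc against the Monte-Carlo SD of projected betas, and
    eigendecomposition variance conservation, on a 5-item group."""
    items = [f"item{i}" for i in range(5)]
    rng = np.random.default_rng(_spawn(seed, 60))
    # a valid random correlation pair
    A = rng.normal(size=(5, 8))
    G = np.corrcoef(A @ A.T + 2 * np.eye(5))
    B = rng.normal(size=(5, 8))
    P = np.corrcoef(B @ B.T + 3 * np.eye(5))
    G_df = pd.DataFrame(G, index=items, columns=items)
    P_df = pd.DataFrame(P, index=items, columns=items)
    model = fit_pc_model(GroupSpec("group-PC1", items, 1), G_df, P_df)

    betas = rng.normal(0.1, 0.05, 5)
    ses = rng.uniform(0.02, 0.08, 5)
    eff = project_effects("rs1", betas, ses, model)

    cov = np.diag(ses) @ P @ np.diag(ses)
    draws = rng.multivariate_normal(betas, cov, size=n_draws)
    mc_sd = float(np.std(draws @ model.loadings))
    return {
        "se_ratio": mc_sd / eff.se_pc,
        "eigenvalue_sum_error": float(abs(model.eigenvalues.sum() - len(items))),
        "n": n_draws,
    }


# ---------------------------------------------------------------------------
# Storey q-values


def storey_null_calibration(m: int = 5000, seed: int = 0) -> dict:
    """π̂0 on uniform null p-values, and the worked 4-value q-vector."""
    rng = np.random.default_rng(_spawn(seed, 70))
    qs = storey_qvalues(rng.uniform(0, 1, m))
    small = storey_qvalues([0.001, 0.002, 0.8, 0.9])
    return {
        "pi0_uniform": qs.pi0,
        "q_small_example": [float(q) for q in small.qvalues],
        "n": m,
    }


# ---------------------------------------------------------------------------
# end-to-end FDR on fully-null grids


def null_grid_fdr(n_seeds: int = 50, seed: int = 0,
                  n_metabolites: int = 123) -> dict:
    """Mean false-positive proportion at q < 0.05 over fully-null grids.

    Each replicate simulates the full 40-exposure × ``n_metabolites`` grid
    with no causal pair, runs the complete pipeline (selection, pruning,
    CUR, harmonization, radial, IVW, pooled Storey q), and counts the
    proportion of analyzed pairs declared significant — all of which are
    false positives by construction.
    """
    props = []
    for s in range(n_seeds):
        cfg = null_grid_config(seed=_spawn(seed, 80_000_000 + s),
                               n_metabolites=n_metabolites)
        exposures, outcomes, confounders, ld, truth = simulate_grid(cfg)
        data = PipelineData(
            exposures=exposures, outcomes=outcomes, confounders=confounders,
            ld=ld, groups=truth.groups,
            genetic_corr=truth.item_genetic_corr,
            phenotypic_corr=truth.item_phenotypic_corr,
        )
        settings = PipelineSettings(run_sensitivity=False, seed=cfg.seed)
        res = run_pipeline(data, settings)
        m = res.summary["pairs_analyzed"]
        props.append(res.summary["pairs_significant"] / m if m else 0.0)
    props = np.asarray(props)
    return {
        "mean_false_positive_proportion": float(props.mean()),
        "mc_se": float(props.std(ddof=1) / np.sqrt(n_seeds)) if n_seeds > 1 else 0.0,
        "n": n_seeds,
    }
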