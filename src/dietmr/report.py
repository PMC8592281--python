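"""Grid-level inference and reporting.

All food–metabolite main-analysis p-values are pooled into one Storey
q-value computation; pairs with q < 0.05 are declared significant.
Sensitivity concordance is flagged (opposite effect direction, or a
sensitivity beta less than half the main beta in magnitude) but never used
to auto-drop a result.  For display, causal estimates are shrunk with a
normal–normal empirical-Bayes posterior mean under a N(0, τ²) prior
(τ = 0.1), which pulls imprecise estimates toward zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .estimators import MrResult
from .sumstats import InputError

LAMBDA_GRID = np.arange(0.05, 0.96, 0.05)
PI0_MIN_TESTS = 100


@dataclass
class QvalueSet:
    pvalues: np.ndarray
    pi0: float
    qvalues: np.ndarray
    lambda_grid: np.ndarray = field(default_factory=lambda: LAMBDA_GRID.copy())


@dataclass
class ConcordanceFlags:
    exposure: str
    outcome: str
    opposite_direction: bool
    attenuated: bool
    methods_flagged: list[str] = field(default_factory=list)


@dataclass
class ShrinkageConfig:
    prior_mean: float = 0.0
    prior_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.prior_sd <= 0:
            raise ValueError("prior_sd must be positive")


def estimate_pi0(pvalues: np.ndarray, lambda_grid: np.ndarray = LAMBDA_GRID) -> float:
    """Storey's smoothed estimate of the null proportion π0.

    π̂0(λ) = #{p > λ} / (m(1−λ)) on the λ grid, smoothed with a cubic
    (degree-3 least-squares) fit and evaluated at the largest λ, then
    clipped to (0, 1].  With fewer than 100 tests the estimator is unstable
    and π0 = 1 is returned.
    """
    p = np.asarray(pvalues, float)
    m = len(p)
    if m < PI0_MIN_TESTS:
        return 1.0
    pi0_lambda = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambda_grid])
    coeffs = np.polyfit(lambda_grid, pi0_lambda, deg=3)
    pi0 = float(np.polyval(coeffs, lambda_grid.max()))
    return float(np.clip(pi0, np.finfo(float).tiny, 1.0))


def storey_qvalues(pvalues: Sequence[float]) -> QvalueSet:
    """Storey q-values for a pooled p-value vector.

    q(i) = min_{j ≥ i} π̂0 · m · p(j) / j over the sorted p-values, mapped
    back to input order.  Equals π0-scaled Benjamini–Hochberg step-up values;
    with π0 = 1 they coincide exactly.
    """
    p = np.asarray(pvalues, float)
    if p.ndim != 1 or len(p) == 0:
        raise InputError("storey_qvalues: need a non-empty 1-d p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise InputError("storey_qvalues: p-values must lie in (0, 1]")

    m = len(p)
    pi0 = estimate_pi0(p)
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return QvalueSet(pvalues=p, pi0=pi0, qvalues=q)


def concordance_flags(main: MrResult, sensitivity: Sequence[MrResult]) -> ConcordanceFlags:
    """Flag disagreement between the main estimate and sensitivity estimates.

    ``opposite_direction`` when any sensitivity beta has a different sign
    from the main beta (zero sensitivity betas are ignored);
    ``attenuated`` when any sensitivity |beta| falls below half the main
    |beta| (a >50% effect-size difference).  Flags carry the method names.
    """
    flagged: list[str] = []
    opposite = False
    attenuated = False
    for r in sensitivity:
        if (r.exposure, r.outcome) != (main.exposure, main.outcome):
            raise InputError(
                f"concordance_flags: {r.method} result is for a different pair"
            )
        hit = False
        if r.beta != 0.0 and np.sign(r.beta) != np.sign(main.beta):
            opposite = True
            hit = True
        if abs(r.beta) < 0.5 * abs(main.beta):
            attenuated = True
            hit = True
        if hit:
            flagged.append(r.method)
    return ConcordanceFlags(
        exposure=main.exposure,
        outcome=main.outcome,
        opposite_direction=opposite,
        attenuated=attenuated,
        methods_flagged=flagged,
    )


def shrink_beta(beta: float, se: float, cfg: ShrinkageConfig | None = None) -> float:
    """Normal–normal posterior mean under a mean-zero prior.

    shrunk = β · τ² / (τ² + se²): estimates with larger standard errors are
    pulled harder toward zero.  se = 0 returns β unchanged.
    """
    cfg = cfg or ShrinkageConfig()
    if se < 0:
        raise ValueError("se must be non-negative")
    t2 = cfg.prior_sd**2
    return float(beta) * t2 / (t2 + float(se) ** 2)


def build_heatmap_matrix(
    results: Sequence[MrResult],
    qvalues: Mapping[tuple[str, str], float],
    cfg: ShrinkageConfig | None = None,
    q_threshold: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exposure × metabolite matrices of shrunk betas and FDR significance.

    ``results`` holds one *main* result per analyzed pair; cells of pairs
    never analyzed stay NaN (mask False).  The mask is True where the
    pooled Storey q is strictly below ``q_threshold`` (the "*" cells of the
    published heatmaps).
    """
    cfg = cfg or ShrinkageConfig()
    seen = set()
    for r in results:
        key = (r.exposure, r.outcome)
        if key in seen:
            raise InputError(f"duplicate main result for pair {key}")
        seen.add(key)
    exposures = sorted({r.exposure for r in results})
    outcomes = sorted({r.outcome for r in results})
    values = pd.DataFrame(np.nan, index=exposures, columns=outcomes)
    mask = pd.DataFrame(False, index=exposures, columns=outcomes)
    for r in results:
        values.at[r.exposure, r.outcome] = shrink_beta(r.beta, r.se, cfg)
        q = qvalues.get((r.exposure, r.outcome), np.nan)
        mask.at[r.exposure, r.outcome] = bool(np.isfinite(q) and q < q_threshold)
    return values, mask


def flags_to_frame(flags: Sequence[ConcordanceFlags]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "exposure": f.exposure,
                "outcome": f.outcome,
                "opposite_direction": f.opposite_direction,
                "attenuated": f.attenuated,
                "methods_flagged": ",".join(f.methods_flagged),
            }
            for f in flags
        ],
        columns=["exposure", "outcome", "opposite_direction", "attenuated", "methods_flagged"],
    )


def plot_heatmap(values: pd.DataFrame, mask: pd.DataFrame, path: str | Path) -> None:
    """Optional rendering of the shrunk-beta grid with '*' on FDR hits."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(6, 0.25 * values.shape[1]), max(4, 0.3 * values.shape[0]))
    )
    vmax = np.nanmax(np.abs(values.to_numpy())) or 1.0
    im = ax.imshow(values.to_numpy(float), cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(values.shape[1]), values.columns, rotation=90, fontsize=5)
    ax.set_yticks(range(values.shape[0]), values.index, fontsize=6)
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            if mask.iat[i, j]:
                ax.text(j, i, "*", ha="center", va="center", fontsize=6)
    fig.colorbar(im, ax=ax, label="shrunk beta")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
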