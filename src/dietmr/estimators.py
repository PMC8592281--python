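"""The Mendelian-randomization estimator battery.

Main analysis: inverse-variance-weighted (IVW) regression through the origin
of SNP→outcome on SNP→exposure effects, with a fixed-effect standard error
unless Cochran's Q signals heterogeneity (Q p-value below 0.05/123 by
default), in which case the SE is inflated by sqrt(Q/df) (floored at 1) —
the multiplicative random-effects convention.  When a single instrument is
available the Wald ratio β_Y/β_X is used instead.

Sensitivity battery: MR-Egger (weighted regression with an intercept that
estimates average directional pleiotropy), the weighted median (consistent
when instruments carrying >50% of the weight are valid), and MR-RAPS (a
profile-score estimator that also accounts for uncertainty in the
SNP→exposure effects).

Before any estimation the instrument set passes through a radial filter that
iteratively removes SNPs contributing outlying Cochran-Q components
(heterogeneity outliers, i.e. likely horizontal pleiotropy).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .harmonize import InstrumentSet

logger = logging.getLogger(__name__)

Z95 = 1.96
DEFAULT_HET_P_THRESHOLD = 0.05 / 123


class EstimatorError(ValueError):
    """An estimator's precondition is violated for this instrument set."""


class RapsNonConvergence(RuntimeError):
    """MR-RAPS found no interior optimum within the search bracket."""


@dataclass
class MrResult:
    """One estimator's causal estimate for one exposure-outcome pair."""

    exposure: str
    outcome: str
    method: str               # wald_ratio | ivw | egger | weighted_median | raps
    nsnp: int
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    Q: float | None = None
    Q_df: int | None = None
    Q_pvalue: float | None = None
    variance_model: str = "fixed"
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    removed_snps: tuple = ()


@dataclass
class EstimatorConfig:
    het_p_threshold: float = DEFAULT_HET_P_THRESHOLD
    radial_alpha: float = 0.05
    radial_correction: str = "bonferroni"   # or "none"
    radial_max_iter: int = 10
    median_n_boot: int = 1000
    seed: int = 0
    run_sensitivity: bool = True


def _wald_p(beta: float, se: float) -> float:
    # floored away from 0 so downstream FDR machinery keeps its (0,1] domain
    p = 2.0 * special.ndtr(-abs(beta) / se)
    return float(min(1.0, max(p, np.finfo(float).tiny)))


def _result(exposure, outcome, method, nsnp, beta, se, **kw) -> MrResult:
    return MrResult(
        exposure=exposure,
        outcome=outcome,
        method=method,
        nsnp=nsnp,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - Z95 * se),
        ci_high=float(beta + Z95 * se),
        pvalue=_wald_p(beta, se),
        **kw,
    )


def wald_ratio(instruments: InstrumentSet) -> MrResult:
    """Single-instrument ratio estimate β_Y/β_X with first-order delta SE."""
    if len(instruments) != 1:
        raise EstimatorError(f"wald_ratio needs exactly 1 instrument, got {len(instruments)}")
    bx = float(instruments.beta_exposure[0])
    if bx == 0.0:
        raise EstimatorError("wald_ratio: zero SNP-exposure effect")
    by = float(instruments.beta_outcome[0])
    sy = float(instruments.se_outcome[0])
    return _result(
        instruments.exposure_name,
        instruments.outcome_name,
        "wald_ratio",
        1,
        by / bx,
        sy / abs(bx),
    )


def _ivw_core(bx, by, sy):
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by)) / denom
    se_fixed = denom ** -0.5
    Q = float(np.sum(w * (by - beta * bx) ** 2))
    return beta, se_fixed, Q


def ivw(
    instruments: InstrumentSet,
    het_p_threshold: float = DEFAULT_HET_P_THRESHOLD,
) -> MrResult:
    """Inverse-variance-weighted estimate with the heterogeneity SE rule.

    Fixed-effect SE by default; when Cochran's Q has p < ``het_p_threshold``
    the SE is multiplied by sqrt(max(1, Q/(nsnp−1))) and the result is
    labelled ``variance_model='random'``.
    """
    k = len(instruments)
    if k < 2:
        raise EstimatorError(f"ivw needs >= 2 instruments, got {k}")
    beta, se, Q = _ivw_core(
        instruments.beta_exposure, instruments.beta_outcome, instruments.se_outcome
    )
    df = k - 1
    q_p = float(special.chdtrc(df, Q))
    model = "fixed"
    if q_p < het_p_threshold:
        se *= np.sqrt(max(1.0, Q / df))
        model = "random"
    return _result(
        instruments.exposure_name,
        instruments.outcome_name,
        "ivw",
        k,
        beta,
        se,
        Q=Q,
        Q_df=df,
        Q_pvalue=q_p,
        variance_model=model,
    )


def egger(
    instruments: InstrumentSet,
    het_p_threshold: float = DEFAULT_HET_P_THRESHOLD,
) -> MrResult:
    """MR-Egger: weighted regression with an intercept.

    Instruments are first oriented so every SNP-exposure effect is positive
    (the InSIDE convention); the slope estimates the causal effect and the
    intercept the average directional pleiotropy.  The same multiplicative
    heterogeneity SE rule as IVW is applied, with nsnp − 2 df.
    """
    k = len(instruments)
    if k < 3:
        raise EstimatorError(f"egger needs >= 3 instruments, got {k}")
    flip = np.sign(instruments.beta_exposure)
    flip[flip == 0] = 1.0
    bx = instruments.beta_exposure * flip
    by = instruments.beta_outcome * flip
    sy = instruments.se_outcome

    w = 1.0 / sy**2
    X = np.column_stack([np.ones(k), bx])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    cov = np.linalg.inv(xtwx)
    coef = cov @ (WX.T @ by)
    intercept, slope = float(coef[0]), float(coef[1])
    resid = by - X @ coef
    Q = float(np.sum(w * resid**2))
    df = k - 2
    q_p = float(special.chdtrc(df, Q))
    se_slope = float(np.sqrt(cov[1, 1]))
    se_int = float(np.sqrt(cov[0, 0]))
    model = "fixed"
    if q_p < het_p_threshold:
        infl = np.sqrt(max(1.0, Q / df))
        se_slope *= infl
        se_int *= infl
        model = "random"
    return _result(
        instruments.exposure_name,
        instruments.outcome_name,
        "egger",
        k,
        slope,
        se_slope,
        Q=Q,
        Q_df=df,
        Q_pvalue=q_p,
        variance_model=model,
        egger_intercept=intercept,
        egger_intercept_se=se_int,
    )


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weight-interpolated median: cumulative weight midpoint crossing 0.5."""
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, cum, r))


def _boot_seed(instruments: InstrumentSet, seed: int) -> int:
    """Stable bootstrap seed from the sorted snp_id set and the global seed."""
    key = ",".join(sorted(map(str, instruments.snp_ids)))
    return (int(seed) * 1_000_003 + zlib.crc32(key.encode())) % (2**31 - 1)


def weighted_median(
    instruments: InstrumentSet,
    n_boot: int = 1000,
    seed: int = 0,
) -> MrResult:
    """Weighted-median estimator with parametric-bootstrap SE.

    Per-SNP ratios β_Yj/β_Xj carry weights β_Xj²/se_Yj² (normalized); the
    estimate interpolates the ratio at cumulative weight 0.5.  The SE is the
    SD of the estimate over ``n_boot`` parametric resamples of (β_Xj, β_Yj)
    from their stated normal errors.  Instruments are sorted by snp_id and
    the resampling seed derives from the snp_id set, so the result is
    invariant to input order.
    """
    if len(instruments) < 3:
        raise EstimatorError(f"weighted_median needs >= 3 instruments, got {len(instruments)}")
    inst = instruments.sorted_by_snp()
    nz = inst.beta_exposure != 0.0
    if nz.sum() < 3:
        raise EstimatorError("weighted_median: fewer than 3 instruments with nonzero beta_exposure")
    inst = inst.subset(nz)
    bx, by = inst.beta_exposure, inst.beta_outcome
    sx, sy = inst.se_exposure, inst.se_outcome

    ratios = by / bx
    weights = bx**2 / sy**2
    est = _weighted_median(ratios, weights)

    rng = np.random.default_rng(_boot_seed(inst, seed))
    k = len(inst)
    bxs = rng.normal(bx, sx, size=(n_boot, k))
    bys = rng.normal(by, sy, size=(n_boot, k))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxb = bxs[b]
        ok = bxb != 0.0
        boots[b] = _weighted_median(bys[b][ok] / bxb[ok], bxb[ok] ** 2 / sy[ok] ** 2)
    se = float(np.std(boots, ddof=1))
    return _result(
        inst.exposure_name,
        inst.outcome_name,
        "weighted_median",
        k,
        est,
        se,
    )


def raps(instruments: InstrumentSet, bracket: float = 10.0, tol: float = 1e-8) -> MrResult:
    """MR-RAPS profile-score estimate.

    Minimizes the sum of squared standardized residuals
    t_j(β) = (β_Yj − β β_Xj)/sqrt(se_Yj² + β² se_Xj²) over β ∈ [−bracket,
    bracket]; the SE comes from the numerical curvature of the objective at
    the optimum (sqrt(2/f'')), which reduces exactly to the IVW fixed SE
    when all se_X vanish.

    Raises RapsNonConvergence when the optimum sits on the bracket edge.
    """
    if len(instruments) < 3:
        raise EstimatorError(f"raps needs >= 3 instruments, got {len(instruments)}")
    bx, by = instruments.beta_exposure, instruments.beta_outcome
    sx, sy = instruments.se_exposure, instruments.se_outcome

    def objective(beta: float) -> float:
        var = sy**2 + beta**2 * sx**2
        return float(np.sum((by - beta * bx) ** 2 / var))

    res = optimize.minimize_scalar(
        objective, bounds=(-bracket, bracket), method="bounded",
        options={"xatol": tol},
    )
    beta = float(res.x)
    if abs(abs(beta) - bracket) < 1e-6:
        raise RapsNonConvergence(
            f"{instruments.exposure_name}->{instruments.outcome_name}: "
            f"no interior optimum in [-{bracket}, {bracket}]"
        )
    h = 1e-4 * (1.0 + abs(beta))
    curv = (objective(beta + h) - 2.0 * objective(beta) + objective(beta - h)) / h**2
    if curv <= 0:
        raise RapsNonConvergence("non-positive curvature at optimum")
    se = float(np.sqrt(2.0 / curv))
    return _result(
        instruments.exposure_name,
        instruments.outcome_name,
        "raps",
        len(instruments),
        beta,
        se,
    )


def radial_filter(
    instruments: InstrumentSet,
    per_snp_alpha: float = 0.05,
    max_iter: int = 10,
    correction: str = "bonferroni",
) -> tuple[InstrumentSet, list[str]]:
    """Iteratively remove heterogeneity outliers (radial MR outlier step).

    Each round fits IVW, computes every SNP's Cochran-Q contribution
    Q_j = w_j (β_Yj − β̂ β_Xj)² and removes the *largest* contribution whose
    chi-square(1) tail probability falls below the per-SNP threshold
    (``per_snp_alpha / nsnp`` under the default Bonferroni correction,
    matching radial-MR software convention; ``correction='none'`` uses the
    raw level).  Removing one SNP per round and refitting protects against
    outlier masking: a strong outlier drags the pooled slope and can make
    every concordant instrument look heterogeneous in the first fit.  Stops
    when no SNP is flagged, fewer than 2 remain, or after ``max_iter``
    rounds.
    """
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    current = instruments
    removed: list[str] = []
    for _ in range(max_iter):
        k = len(current)
        if k < 2:
            break
        beta, _, _ = _ivw_core(
            current.beta_exposure, current.beta_outcome, current.se_outcome
        )
        w = 1.0 / current.se_outcome**2
        qj = w * (current.beta_outcome - beta * current.beta_exposure) ** 2
        pj = special.chdtrc(1, qj)
        threshold = per_snp_alpha / k if correction == "bonferroni" else per_snp_alpha
        flagged = pj < threshold
        if not flagged.any():
            break
        worst = int(np.argmax(qj))
        removed.append(current.snp_ids[worst])
        keep = np.ones(k, dtype=bool)
        keep[worst] = False
        current = current.subset(keep)
    return current, removed


def run_estimators(
    instruments: InstrumentSet,
    config: EstimatorConfig | None = None,
) -> list[MrResult]:
    """Full battery for one harmonized, CUR-filtered instrument set.

    Radial outlier removal first; then the main analysis (IVW with ≥2
    surviving instruments, otherwise the Wald ratio) and — where their
    minimum-instrument preconditions hold and sensitivity is enabled —
    MR-Egger, the weighted median and MR-RAPS.  An empty set yields no
    results (the pair is recorded as not analyzed by the caller).
    """
    config = config or EstimatorConfig()
    if len(instruments) == 0:
        return []
    if len(instruments) >= 2:
        filtered, removed = radial_filter(
            instruments,
            per_snp_alpha=config.radial_alpha,
            max_iter=config.radial_max_iter,
            correction=config.radial_correction,
        )
    else:
        filtered, removed = instruments, []

    results: list[MrResult] = []
    k = len(filtered)
    if k == 0:
        return results
    if k == 1:
        try:
            main = wald_ratio(filtered)
        except EstimatorError as exc:
            logger.info("%s", exc)
            return results
        main.removed_snps = tuple(removed)
        results.append(main)
        return results

    main = ivw(filtered, het_p_threshold=config.het_p_threshold)
    main.removed_snps = tuple(removed)
    results.append(main)

    if config.run_sensitivity and k >= 3:
        for fn in (
            lambda s: egger(s, het_p_threshold=config.het_p_threshold),
            lambda s: weighted_median(s, n_boot=config.median_n_boot, seed=config.seed),
            raps,
        ):
            try:
                r = fn(filtered)
            except RapsNonConvergence as exc:
                logger.warning("raps non-convergence: %s", exc)
                continue
            except EstimatorError as exc:
                logger.info("%s", exc)
                continue
            r.removed_snps = tuple(removed)
            results.append(r)
    return results
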