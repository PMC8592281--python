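"""Corrected-to-Uncorrected Ratio (CUR) instrument filtering.

Food-frequency GWAS signals are contaminated by heritable confounders (BMI,
lipids, blood pressure, disease status, educational attainment): a SNP may
associate with reported food intake only because it changes a health trait
that changes behaviour or reporting.  CUR keeps a SNP as an instrument only
if its food-trait effect is essentially *direct*:

1. multivariable MR of the food trait on a stepwise-selected subset of
   candidate confounders gives per-confounder causal effects α_c;
2. each SNP's *expected* (confounder-mediated) effect is Σ_c α_c · b_{j,c};
3. the *corrected* effect is observed − expected, and the SNP is kept when
   CUR = corrected / observed lies within 1 ± window (default ±0.05,
   boundary inclusive).

The multivariable MR is a no-intercept weighted regression of SNP→food betas
on SNP→confounder beta columns, weights 1/se_food²; forward selection adds
the candidate with the smallest coefficient p while it is below the
criterion (default 0.05), or the candidate that lowers AIC most under the
``aic`` criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .sumstats import SumStats

logger = logging.getLogger(__name__)

#: the candidate confounder battery used throughout the analysis
DEFAULT_CONFOUNDERS = (
    "bmi",
    "ldl_cholesterol",
    "hdl_cholesterol",
    "triglycerides",
    "diastolic_bp",
    "systolic_bp",
    "type2_diabetes",
    "coronary_artery_disease",
    "crohns_disease",
    "ulcerative_colitis",
    "educational_attainment",
)

_RANK_TOL = 1e-10


@dataclass
class MvmrFit:
    food_trait: str
    selected_confounders: list[str]
    alpha: dict[str, tuple[float, float]]  # name -> (estimate, se)
    selection_trace: list[dict] = field(default_factory=list)

    def expected_effects(self, confounder_betas: dict[str, np.ndarray]) -> np.ndarray:
        """Σ_c α̂_c · b_{j,c} for each SNP j (zero when nothing was selected)."""
        if not self.selected_confounders:
            any_col = next(iter(confounder_betas.values()), np.zeros(0))
            return np.zeros_like(np.asarray(any_col, float))
        return np.sum(
            [self.alpha[c][0] * np.asarray(confounder_betas[c], float)
             for c in self.selected_confounders],
            axis=0,
        )


@dataclass
class CurRecord:
    snp_id: str
    observed: float
    expected: float
    corrected: float
    ratio: float          # NaN when observed == 0 (undefined)
    keep: bool = False


def stepwise_mvmr(
    food: SumStats,
    confounders: Sequence[SumStats],
    instrument_ids: Sequence[str],
    criterion_alpha: float = 0.05,
    criterion: str = "pvalue",
) -> MvmrFit:
    """Forward-stepwise multivariable MR with the food trait as outcome.

    Requires instruments harmonized across the food trait and every
    candidate confounder (same SNPs, same effect alleles) and at least
    ``len(confounders) + 2`` instruments.  Collinear candidates (those not
    raising the design-matrix rank) are dropped with a logged warning.
    """
    if criterion not in ("pvalue", "aic"):
        raise ValueError(f"unknown stepwise criterion {criterion!r}")
    instrument_ids = list(instrument_ids)
    names = [c.trait_name for c in confounders]
    if len(instrument_ids) < len(names) + 2:
        raise ValueError(
            f"stepwise_mvmr: need >= {len(names) + 2} instruments, "
            f"got {len(instrument_ids)}"
        )

    y = food.df.loc[instrument_ids, "beta"].to_numpy(float)
    w = 1.0 / food.df.loc[instrument_ids, "se"].to_numpy(float) ** 2
    cols = {}
    for c in confounders:
        missing = [s for s in instrument_ids if s not in c.df.index]
        if missing:
            raise ValueError(
                f"stepwise_mvmr: confounder {c.trait_name} lacks instrument(s) "
                f"{missing[:3]}"
            )
        cols[c.trait_name] = c.df.loc[instrument_ids, "beta"].to_numpy(float)

    selected: list[str] = []
    trace: list[dict] = []
    remaining = list(names)
    sw = np.sqrt(w)

    def _rank_ok(candidate: str) -> bool:
        X = np.column_stack([cols[c] for c in selected + [candidate]]) * sw[:, None]
        return np.linalg.matrix_rank(X, tol=_RANK_TOL * max(1.0, np.abs(X).max())) == len(
            selected
        ) + 1

    current_aic = None
    if criterion == "aic":
        # null model: no regressors, no intercept
        rss = float(np.sum(w * y**2))
        current_aic = len(y) * np.log(rss / len(y))

    while remaining:
        # drop candidates that would make the design rank-deficient
        collinear = [c for c in remaining if not _rank_ok(c)]
        for cand in collinear:
            logger.warning(
                "%s: dropping collinear confounder candidate %s",
                food.trait_name,
                cand,
            )
            trace.append({"candidate": cand, "criterion": np.nan, "kept": False,
                          "reason": "collinear"})
            remaining.remove(cand)
        if not remaining:
            break

        best = None
        for cand in remaining:
            X = np.column_stack([cols[c] for c in selected + [cand]])
            fit = sm.WLS(y, X, weights=w).fit()
            score = float(fit.pvalues[-1]) if criterion == "pvalue" else float(fit.aic)
            if best is None or score < best[1]:
                best = (cand, score)
        cand, score = best
        admit = score < criterion_alpha if criterion == "pvalue" else score < current_aic
        trace.append({"candidate": cand, "criterion": score, "kept": bool(admit)})
        if not admit:
            break
        selected.append(cand)
        remaining.remove(cand)
        if criterion == "aic":
            current_aic = score

    alpha: dict[str, tuple[float, float]] = {}
    if selected:
        X = np.column_stack([cols[c] for c in selected])
        fit = sm.WLS(y, X, weights=w).fit()
        for i, c in enumerate(selected):
            alpha[c] = (float(fit.params[i]), float(fit.bse[i]))

    return MvmrFit(
        food_trait=food.trait_name,
        selected_confounders=selected,
        alpha=alpha,
        selection_trace=trace,
    )


def cur_ratio(snp_id: str, observed: float, expected: float) -> CurRecord:
    """corrected = observed − expected; ratio = corrected / observed.

    A zero observed effect leaves the ratio undefined (NaN) and the record
    excluded (keep stays False through filtering).
    """
    if not np.isfinite(observed):
        raise ValueError(f"{snp_id}: observed effect must be finite")
    corrected = observed - expected
    ratio = corrected / observed if observed != 0.0 else np.nan
    return CurRecord(
        snp_id=snp_id,
        observed=float(observed),
        expected=float(expected),
        corrected=float(corrected),
        ratio=float(ratio),
    )


def compute_cur_records(
    food: SumStats,
    fit: MvmrFit,
    confounders: Sequence[SumStats],
    instrument_ids: Sequence[str],
) -> list[CurRecord]:
    """CUR records for each instrument from a fitted multivariable MR."""
    instrument_ids = list(instrument_ids)
    betas = {
        c.trait_name: c.df.loc[instrument_ids, "beta"].to_numpy(float)
        for c in confounders
        if c.trait_name in fit.selected_confounders
    }
    if fit.selected_confounders:
        expected = fit.expected_effects(betas)
    else:
        expected = np.zeros(len(instrument_ids))
    observed = food.df.loc[instrument_ids, "beta"].to_numpy(float)
    return [
        cur_ratio(snp, float(o), float(e))
        for snp, o, e in zip(instrument_ids, observed, expected)
    ]


def filter_by_cur(records: Sequence[CurRecord], window: float = 0.05) -> list[str]:
    """Keep SNPs with CUR in [1 − window, 1 + window] (boundary inclusive).

    Sets ``keep`` on each record in place and returns the kept snp_ids.
    Records with undefined ratio (observed = 0) are never kept.
    """
    if window <= 0:
        raise ValueError(f"window must be positive, got {window}")
    kept = []
    for rec in records:
        rec.keep = bool(
            np.isfinite(rec.ratio) and (1.0 - window) <= rec.ratio <= (1.0 + window)
        )
        if rec.keep:
            kept.append(rec.snp_id)
    return kept
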