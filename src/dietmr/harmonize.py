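"""Instrument selection and exposure/outcome harmonization.

Implements the standard two-sample MR preprocessing chain: pick genome-wide
significant SNPs for the exposure, greedily prune them to an independent set
under a pairwise r² threshold, then align outcome effects onto the exposure's
effect allele (sign-flipping swapped orientations, strand-flipping where the
complement resolves the match, and dropping palindromic SNPs whose strand
cannot be resolved from allele frequencies).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .sumstats import LdTable, SumStats

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PALINDROMES = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class InstrumentSet:
    """Harmonized per-SNP effect pairs for one exposure-outcome analysis.

    Arrays are aligned: entry j of every array refers to ``snp_ids[j]``, and
    ``beta_outcome`` is already re-signed onto the exposure's effect allele.
    """

    exposure_name: str
    outcome_name: str
    snp_ids: np.ndarray
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    pvalue_exposure: np.ndarray
    eaf_exposure: np.ndarray
    counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        for name in ("beta_exposure", "se_exposure", "beta_outcome",
                     "se_outcome", "pvalue_exposure", "eaf_exposure"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("InstrumentSet: duplicate snp_id")
        if np.any(self.se_exposure <= 0) or np.any(self.se_outcome <= 0):
            raise ValueError("InstrumentSet: non-positive standard error")

    def __len__(self) -> int:
        return len(self.snp_ids)

    def subset(self, mask: np.ndarray) -> "InstrumentSet":
        return InstrumentSet(
            exposure_name=self.exposure_name,
            outcome_name=self.outcome_name,
            snp_ids=self.snp_ids[mask],
            beta_exposure=self.beta_exposure[mask],
            se_exposure=self.se_exposure[mask],
            beta_outcome=self.beta_outcome[mask],
            se_outcome=self.se_outcome[mask],
            pvalue_exposure=self.pvalue_exposure[mask],
            eaf_exposure=self.eaf_exposure[mask],
            counts=dict(self.counts),
        )

    def sorted_by_snp(self) -> "InstrumentSet":
        order = np.argsort(self.snp_ids.astype(str))
        return self.subset(order)


def select_significant(
    exposure: SumStats, p_threshold: float = 5e-8
) -> list[str]:
    """SNPs with exposure p strictly below ``p_threshold``.

    Returned in ascending-p order with lexicographic snp_id tie-break, the
    order later used for greedy LD pruning.
    """
    if not 0 < p_threshold < 1:
        raise ValueError(f"p_threshold must be in (0,1), got {p_threshold}")
    p = exposure.df["pvalue"]
    hits = p[p < p_threshold]
    order = sorted(hits.items(), key=lambda kv: (kv[1], kv[0]))
    if not order:
        logger.info("%s: no SNP below p < %.3g", exposure.trait_name, p_threshold)
    return [snp for snp, _ in order]


def ld_prune(
    candidates: Sequence[str],
    pvalues: Mapping[str, float],
    ld: LdTable,
    r2_threshold: float = 0.001,
) -> list[str]:
    """Greedy clumping: keep a SNP iff its r² with every kept SNP is < threshold.

    Candidates are visited in ascending-p order (snp_id tie-break), so the
    strongest association in each LD block survives.
    """
    if not 0 < r2_threshold <= 1:
        raise ValueError(f"r2_threshold must be in (0,1], got {r2_threshold}")
    ordered = sorted(candidates, key=lambda s: (pvalues[s], s))
    kept: list[str] = []
    for snp in ordered:
        if all(ld.r2(snp, k) < r2_threshold for k in kept):
            kept.append(snp)
    return kept


def _orientation(ea_x: str, oa_x: str, ea_y: str, oa_y: str) -> str | None:
    """How the outcome alleles relate to the exposure alleles.

    Returns 'same', 'swapped', 'flipped' (strand complement), 'flipped_swapped',
    or None when no orientation matches.
    """
    if (ea_y, oa_y) == (ea_x, oa_x):
        return "same"
    if (ea_y, oa_y) == (oa_x, ea_x):
        return "swapped"
    c_ea, c_oa = COMPLEMENT[ea_y], COMPLEMENT[oa_y]
    if (c_ea, c_oa) == (ea_x, oa_x):
        return "flipped"
    if (c_ea, c_oa) == (oa_x, ea_x):
        return "flipped_swapped"
    return None


def harmonize(
    exposure: SumStats,
    outcome: SumStats,
    instrument_ids: Sequence[str],
    palindrome_eaf_window: float = 0.08,
) -> InstrumentSet:
    """Align outcome effects onto the exposure's effect allele.

    Rules, applied per SNP:

    * absent from the outcome GWAS → dropped (``missing_in_outcome``);
    * swapped alleles → outcome beta negated, eaf complemented;
    * strand-complement match (non-palindromic) → resolved silently;
    * palindromic (A/T, C/G) → kept only when both allele frequencies are
      available and both fall outside ``0.5 ± palindrome_eaf_window`` on the
      same side after alignment (``palindromic_dropped`` otherwise);
    * allele sets matching neither orientation → dropped
      (``allele_mismatch``).

    The returned set may be empty; callers skip the pair in that case.
    Drop/flip counts are stored in ``InstrumentSet.counts``.
    """
    counts = {
        "input": len(instrument_ids),
        "missing_in_outcome": 0,
        "allele_mismatch": 0,
        "palindromic_dropped": 0,
        "sign_flipped": 0,
        "strand_flipped": 0,
        "kept": 0,
    }
    w = palindrome_eaf_window

    instrument_ids = list(instrument_ids)
    e_pos_map = exposure.positions()
    o_pos_map = outcome.positions()
    missing_exp = [s for s in instrument_ids if s not in e_pos_map]
    if missing_exp:
        raise KeyError(
            f"instrument(s) {missing_exp[:3]} absent from exposure {exposure.trait_name}"
        )
    present = [s for s in instrument_ids if s in o_pos_map]
    counts["missing_in_outcome"] = len(instrument_ids) - len(present)
    e_pos = np.array([e_pos_map[s] for s in present], dtype=int)
    o_pos = np.array([o_pos_map[s] for s in present], dtype=int)

    ea_xs = exposure.column("effect_allele")[e_pos]
    oa_xs = exposure.column("other_allele")[e_pos]
    bx_arr = exposure.column("beta")[e_pos].astype(float)
    sx_arr = exposure.column("se")[e_pos].astype(float)
    px_arr = exposure.column("pvalue")[e_pos].astype(float)
    fx_arr = exposure.column("eaf")[e_pos].astype(float)
    ea_ys = outcome.column("effect_allele")[o_pos]
    oa_ys = outcome.column("other_allele")[o_pos]
    by_arr = outcome.column("beta")[o_pos].astype(float)
    sy_arr = outcome.column("se")[o_pos].astype(float)
    fy_arr = outcome.column("eaf")[o_pos].astype(float)

    rows = {k: [] for k in ("snp", "bx", "sx", "by", "sy", "px", "fx")}
    lo, hi = 0.5 - w, 0.5 + w
    for i, snp in enumerate(present):
        ea_x, oa_x = ea_xs[i], oa_xs[i]
        orient = _orientation(ea_x, oa_x, ea_ys[i], oa_ys[i])
        if orient is None:
            counts["allele_mismatch"] += 1
            continue

        by = by_arr[i]
        fy = fy_arr[i]
        if orient in ("swapped", "flipped_swapped"):
            by = -by
            fy = 1.0 - fy if np.isfinite(fy) else np.nan
            counts["sign_flipped"] += 1
        if orient in ("flipped", "flipped_swapped"):
            counts["strand_flipped"] += 1

        if (ea_x, oa_x) in PALINDROMES:
            fx = fx_arr[i]
            if not (np.isfinite(fx) and np.isfinite(fy)):
                counts["palindromic_dropped"] += 1
                continue
            both_low = fx < lo and fy < lo
            both_high = fx > hi and fy > hi
            if not (both_low or both_high):
                counts["palindromic_dropped"] += 1
                continue

        rows["snp"].append(snp)
        rows["bx"].append(bx_arr[i])
        rows["sx"].append(sx_arr[i])
        rows["by"].append(by)
        rows["sy"].append(sy_arr[i])
        rows["px"].append(px_arr[i])
        rows["fx"].append(fx_arr[i])
        counts["kept"] += 1

    if counts["kept"] == 0:
        logger.info(
            "%s -> %s: no instrument survived harmonization",
            exposure.trait_name,
            outcome.trait_name,
        )
    return InstrumentSet(
        exposure_name=exposure.trait_name,
        outcome_name=outcome.trait_name,
        snp_ids=np.array(rows["snp"], dtype=object),
        beta_exposure=np.array(rows["bx"]),
        se_exposure=np.array(rows["sx"]),
        beta_outcome=np.array(rows["by"]),
        se_outcome=np.array(rows["sy"]),
        pvalue_exposure=np.array(rows["px"]),
        eaf_exposure=np.array(rows["fx"]),
        counts=counts,
    )


def f_statistic(instruments: InstrumentSet) -> tuple[np.ndarray, float]:
    """Per-instrument strength F_j = (beta_X / se_X)² and the mean F."""
    if len(instruments) == 0:
        raise ValueError("f_statistic: empty instrument set")
    f = (instruments.beta_exposure / instruments.se_exposure) ** 2
    return f, float(np.mean(f))
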