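"""Principal-component dietary traits.

A PC-trait summarizes a group of genetically correlated food items (e.g.
oily + non-oily fish → Fish-PC1).  The rotation comes from an
eigendecomposition of the items' *genetic* correlation matrix G; per-SNP item
effects are projected through the selected eigenvector, and the projected
standard error is propagated through the *phenotypic* correlation matrix P:

    beta_pc = Lᵀ b,    se_pc² = Σᵢ Σⱼ Lᵢ Lⱼ seᵢ seⱼ Pᵢⱼ

with L the loadings (eigenvector of G for the chosen component).  The Wald
p-value of beta_pc/se_pc is the SNP's p "in the rotated space".

Eigenvectors are oriented so their largest-magnitude entry is positive;
without a fixed convention every downstream causal estimate would flip sign
arbitrarily between runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sumstats import GroupSpec, InputError, SumStats

logger = logging.getLogger(__name__)

_ORTHO_TOL = 1e-10
_PSD_TOL = -1e-8


@dataclass
class PcModel:
    """Rotation and correlation matrices for one PC-trait."""

    group: GroupSpec
    genetic_corr: pd.DataFrame
    phenotypic_corr: pd.DataFrame
    rotation: np.ndarray          # columns = eigenvectors of G, eigenvalues descending
    eigenvalues: np.ndarray

    @property
    def loadings(self) -> np.ndarray:
        """The eigenvector column for this trait's pc_index (1-based)."""
        return self.rotation[:, self.group.pc_index - 1]

    @property
    def members(self) -> list[str]:
        return self.group.member_items


@dataclass
class PcSnpEffect:
    snp_id: str
    beta_pc: float
    se_pc: float
    pvalue_pc: float
    source_min_item_p: float


def _check_corr(mat: pd.DataFrame, members: list[str], label: str) -> np.ndarray:
    try:
        sub = mat.loc[members, members]
    except KeyError as exc:
        raise InputError(f"{label}: missing member trait {exc}") from exc
    a = sub.to_numpy(float)
    if not np.allclose(a, a.T, atol=1e-8):
        raise InputError(f"{label}: matrix is not symmetric")
    if not np.allclose(np.diag(a), 1.0, atol=1e-6):
        raise InputError(f"{label}: diagonal must be 1")
    return (a + a.T) / 2.0


def fit_pc_model(
    group: GroupSpec,
    genetic_corr: pd.DataFrame,
    phenotypic_corr: pd.DataFrame,
) -> PcModel:
    """Eigendecompose the genetic correlation matrix of the group's members.

    Raises InputError when either matrix is asymmetric, lacks a unit
    diagonal, or is indefinite beyond tolerance.
    """
    G = _check_corr(genetic_corr, group.member_items, f"{group.group_name} genetic_corr")
    P = _check_corr(
        phenotypic_corr, group.member_items, f"{group.group_name} phenotypic_corr"
    )
    evals, evecs = np.linalg.eigh(G)
    if evals.min() < _PSD_TOL:
        raise InputError(
            f"{group.group_name}: genetic correlation matrix indefinite "
            f"(min eigenvalue {evals.min():.3g})"
        )
    if np.linalg.eigvalsh(P).min() < _PSD_TOL:
        raise InputError(f"{group.group_name}: phenotypic correlation matrix indefinite")

    order = np.argsort(-evals, kind="stable")   # ties keep eigh's order
    evals = evals[order]
    evecs = evecs[:, order]
    # deterministic orientation: largest-|entry| of each eigenvector positive
    for k in range(evecs.shape[1]):
        col = evecs[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            evecs[:, k] = -col

    if not np.allclose(evecs.T @ evecs, np.eye(len(evals)), atol=_ORTHO_TOL):
        raise InputError(f"{group.group_name}: rotation not orthonormal")

    m = group.member_items
    return PcModel(
        group=group,
        genetic_corr=pd.DataFrame(G, index=m, columns=m),
        phenotypic_corr=pd.DataFrame(P, index=m, columns=m),
        rotation=evecs,
        eigenvalues=evals,
    )


def propagate_se(loadings: np.ndarray, item_ses: np.ndarray, phen_corr: np.ndarray) -> float:
    """sqrt(Lᵀ diag(se) P diag(se) L) — SE of the projected effect."""
    d = loadings * item_ses
    return float(np.sqrt(d @ phen_corr @ d))


def project_effects(
    snp_id: str,
    item_betas: np.ndarray,
    item_ses: np.ndarray,
    model: PcModel,
    source_min_item_p: float = np.nan,
) -> PcSnpEffect:
    """Project one SNP's item-level effects onto the PC-trait.

    Raises InputError when any beta or se is missing/non-finite: such SNPs
    are excluded from the PC trait by the caller.
    """
    b = np.asarray(item_betas, float)
    s = np.asarray(item_ses, float)
    if b.shape != s.shape or b.shape != (len(model.members),):
        raise InputError(f"{snp_id}: need one beta and se per member item")
    if not (np.all(np.isfinite(b)) and np.all(np.isfinite(s)) and np.all(s > 0)):
        raise InputError(f"{snp_id}: missing or invalid item-level effect")

    L = model.loadings
    beta_pc = float(L @ b)
    se_pc = propagate_se(L, s, model.phenotypic_corr.to_numpy())
    z = beta_pc / se_pc
    pvalue = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    pvalue = max(pvalue, np.finfo(float).tiny)
    return PcSnpEffect(
        snp_id=snp_id,
        beta_pc=beta_pc,
        se_pc=se_pc,
        pvalue_pc=pvalue,
        source_min_item_p=float(source_min_item_p),
    )


def _wald_p_matrix(betas: np.ndarray, ses: np.ndarray) -> np.ndarray:
    p = 2.0 * sps.norm.sf(np.abs(betas / ses))
    return np.clip(p, np.finfo(float).tiny, 1.0)


def select_pc_instruments(
    item_sumstats: dict[str, SumStats],
    model: PcModel,
    p_threshold: float = 5e-8,
    pvalue_rule: str = "wald",
) -> list[PcSnpEffect]:
    """Candidate instruments for a PC-trait.

    A SNP qualifies when it is associated (p < ``p_threshold``) with *any*
    member item; its assigned p-value then comes from the rotated space:
    either the Wald p of this trait's projected effect (``pvalue_rule =
    'wald'``, default) or the minimum Wald p across all components of the
    group (``'min_pc'``).  The assigned p may exceed the threshold; it is
    kept as-is and only orders downstream LD pruning.

    SNPs missing an effect estimate in any member item are excluded (logged).
    """
    if pvalue_rule not in ("wald", "min_pc"):
        raise ValueError(f"unknown pvalue_rule {pvalue_rule!r}")
    members = model.members
    missing = [m for m in members if m not in item_sumstats]
    if missing:
        raise InputError(f"{model.group.group_name}: missing item sumstats {missing}")

    frames = {m: item_sumstats[m].df for m in members}
    candidates: set[str] = set()
    for m in members:
        p = frames[m]["pvalue"]
        candidates.update(p.index[p < p_threshold])

    out: list[PcSnpEffect] = []
    n_excluded = 0
    for snp in sorted(candidates):
        try:
            b = np.array([float(frames[m].at[snp, "beta"]) for m in members])
            s = np.array([float(frames[m].at[snp, "se"]) for m in members])
            item_p = np.array([float(frames[m].at[snp, "pvalue"]) for m in members])
        except KeyError:
            n_excluded += 1
            continue
        if not (np.all(np.isfinite(b)) and np.all(np.isfinite(s)) and np.all(s > 0)):
            n_excluded += 1
            continue
        eff = project_effects(snp, b, s, model, source_min_item_p=item_p.min())
        if pvalue_rule == "min_pc":
            P = model.phenotypic_corr.to_numpy()
            betas = model.rotation.T @ b
            ses = np.array(
                [propagate_se(model.rotation[:, k], s, P) for k in range(len(members))]
            )
            eff.pvalue_pc = float(_wald_p_matrix(betas, ses).min())
        out.append(eff)
    if n_excluded:
        logger.info(
            "%s: excluded %d candidate SNP(s) with missing item effects",
            model.group.group_name,
            n_excluded,
        )
    return out


def build_pc_sumstats(
    item_sumstats: dict[str, SumStats],
    model: PcModel,
    p_threshold: float = 5e-8,
    pvalue_rule: str = "wald",
) -> SumStats | None:
    """Package a PC-trait's candidate instruments as a SumStats.

    Alleles (and eaf) are taken from the first member item; member GWAS are
    assumed to share allele coding per SNP (true when items come from one
    study, as here).  SNPs whose allele coding differs between members are
    excluded.  Returns None when no candidate qualifies.
    """
    effects = select_pc_instruments(item_sumstats, model, p_threshold, pvalue_rule)
    if not effects:
        return None
    members = model.members
    ref = item_sumstats[members[0]].df
    rows = []
    for eff in effects:
        alleles = {
            (item_sumstats[m].df.at[eff.snp_id, "effect_allele"],
             item_sumstats[m].df.at[eff.snp_id, "other_allele"])
            for m in members
            if eff.snp_id in item_sumstats[m].df.index
        }
        if len(alleles) != 1:
            logger.warning(
                "%s: %s has inconsistent allele coding across items; excluded",
                model.group.group_name,
                eff.snp_id,
            )
            continue
        rows.append(
            {
                "snp_id": eff.snp_id,
                "effect_allele": ref.at[eff.snp_id, "effect_allele"],
                "other_allele": ref.at[eff.snp_id, "other_allele"],
                "eaf": ref.at[eff.snp_id, "eaf"],
                "beta": eff.beta_pc,
                "se": eff.se_pc,
                "pvalue": eff.pvalue_pc,
                "n": ref.at[eff.snp_id, "n"],
            }
        )
    if not rows:
        return None
    df = pd.DataFrame(rows).set_index("snp_id")
    return SumStats(trait_name=model.group.group_name, df=df, trait_kind="pc_trait")
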