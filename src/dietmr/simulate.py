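"""Synthetic GWAS summary statistics with known ground truth.

The generator emulates the structural features the pipeline is built around:

* a two-sample design — SNP→exposure and SNP→outcome effects carry
  *independent* sampling noise with SE = 1/sqrt(N) on the standardized
  scale, with the exposure study much larger than the outcome study
  (defaults mirror a 445,799-person food-frequency GWAS and a 24,925-person
  NMR metabolomics GWAS);
* food items clustered into groups sharing a latent genetic factor, so the
  item effect vectors realize a declared within-group genetic correlation
  (these groups feed the PC-trait machinery);
* four SNP roles: ``direct`` instruments acting on the food items,
  ``confounder_mediated`` SNPs whose food association runs entirely through
  a heritable confounder (CUR's quarry), ``pleiotropic`` instruments with
  additional direct outcome effects (balanced or directional), and ``null``
  SNPs;
* a full many-exposure × many-metabolite causal grid with a sparse true
  effect matrix (or an entirely null one).

Every output is reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .harmonize import InstrumentSet
from .sumstats import ConfigError, GroupSpec, LdTable, SumStats

P_FLOOR = 1e-300

#: the 25 food-consumption items of the exposure GWAS
FOOD_ITEMS = [
    "beef",
    "beer",
    "bread",
    "white_wine",
    "cheese",
    "cooked_vegetables",
    "decaf_coffee",
    "dried_fruit",
    "fresh_fruit",
    "ground_coffee",
    "instant_coffee",
    "lamb",
    "nonoily_fish",
    "oily_fish",
    "pork",
    "poultry",
    "processed_meat",
    "red_wine",
    "salad",
    "salt",
    "spirits",
    "tea",
    "water",
    "vegetarianism",
    "drink_temperature",
]

CONFOUNDER_NAMES = [
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
]

#: named NMR metabolite measures heading the outcome panel; the remainder of
#: the 123 outcomes are filled programmatically
METABOLITE_SEED_NAMES = [
    "ApoB",
    "ApoA1",
    "VLDL_D",
    "IDL_C",
    "LDL_C",
    "HDL_C",
    "Serum_TG",
    "DHA",
    "Omega3",
    "Omega6",
    "LA",
    "Glucose",
    "Creatinine",
    "Albumin",
    "Citrate",
]


def default_metabolite_names(n: int = 123) -> list[str]:
    names = list(METABOLITE_SEED_NAMES[:n])
    names += [f"met_{i:03d}" for i in range(len(names) + 1, n + 1)]
    return names


def default_groups() -> list[GroupSpec]:
    """The 15 dietary-pattern (PC) traits of the default scenario."""
    alcohol = ["beer", "red_wine", "white_wine", "spirits"]
    coffee = ["ground_coffee", "instant_coffee", "decaf_coffee"]
    meat = ["beef", "lamb", "pork", "poultry", "processed_meat"]
    broad = [
        "beef",
        "processed_meat",
        "oily_fish",
        "nonoily_fish",
        "fresh_fruit",
        "dried_fruit",
        "salad",
        "cooked_vegetables",
        "beer",
        "red_wine",
        "ground_coffee",
        "tea",
    ]
    psycho = alcohol + ["ground_coffee", "instant_coffee", "tea"]
    return [
        GroupSpec("Fruit-PC1", ["dried_fruit", "fresh_fruit"], 1),
        GroupSpec("Fish-PC1", ["oily_fish", "nonoily_fish"], 1),
        GroupSpec("Vegetables-PC1", ["cooked_vegetables", "salad"], 1),
        GroupSpec("Meat-PC1", meat, 1),
        GroupSpec("Meat-PC2", meat, 2),
        GroupSpec("Coffee-PC1", coffee, 1),
        GroupSpec("Coffee-PC2", coffee, 2),
        GroupSpec("Alcohol-PC1", alcohol, 1),
        GroupSpec("Alcohol-PC2", alcohol, 2),
        GroupSpec("Psychoactive-PC1", psycho, 1),
        GroupSpec("Psychoactive-PC2", psycho, 2),
        GroupSpec("Hot-drinks-PC1", ["tea", "ground_coffee", "instant_coffee", "decaf_coffee"], 1),
        GroupSpec("All-PC1", broad, 1),
        GroupSpec("All-PC2", broad, 2),
        GroupSpec("All-PC3", broad, 3),
    ]


@dataclass
class SimConfig:
    """Generative settings; the defaults are the package's study conditions."""

    n_snps: int = 2000
    n_food_items: int = 25
    n_metabolites: int = 123
    sample_size_exposure: int = 445_799
    sample_size_outcome: int = 24_925
    sample_size_confounder: int = 1_000_000
    n_confounders: int = 11
    prop_pleiotropic: float = 0.05
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.05
    pleiotropy_prob: float = 0.2    # chance a pleiotropic SNP hits a given outcome
    prop_confounder_mediated: float = 0.05
    prop_null: float = 0.75
    effect_size_sd: float = 0.1
    within_group_genetic_corr: float = 0.6
    within_group_phenotypic_corr: float = 0.4
    confounder_alpha: float = 0.5
    n_causal_confounders: int = 11
    confounder_outcome_sd: float = 0.3
    prop_nonnull_pairs: float = 0.10
    causal_effect_sd: float = 0.4
    ld_block_size: int = 1
    ld_within_r2: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("prop_pleiotropic", "prop_confounder_mediated", "prop_null",
                     "prop_nonnull_pairs"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        if self.prop_pleiotropic + self.prop_confounder_mediated + self.prop_null > 1.0:
            raise ConfigError("SNP role proportions exceed 1")
        for name in ("n_snps", "n_food_items", "n_metabolites",
                     "sample_size_exposure", "sample_size_outcome"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_food_items > len(FOOD_ITEMS):
            raise ConfigError(f"n_food_items > {len(FOOD_ITEMS)} not supported")
        if self.n_confounders > len(CONFOUNDER_NAMES):
            raise ConfigError(f"n_confounders > {len(CONFOUNDER_NAMES)} not supported")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)


@dataclass
class SimTruth:
    """Ground truth behind one simulated grid."""

    causal_beta: pd.DataFrame            # exposures (items + PC traits) x metabolites
    snp_roles: pd.Series                 # snp_id -> direct|confounder_mediated|pleiotropic|null
    confounder_alpha: pd.Series          # confounder -> true effect on every food item
    item_genetic_corr: pd.DataFrame
    item_phenotypic_corr: pd.DataFrame
    item_effects: pd.DataFrame | None = None   # true SNP -> item effects (incl. mediated part)
    groups: list[GroupSpec] = field(default_factory=list)
    seed: int = 0


def _wald_p(beta: np.ndarray, se: float | np.ndarray) -> np.ndarray:
    p = 2.0 * sps.norm.sf(np.abs(beta) / se)
    return np.clip(p, P_FLOOR, 1.0)


def _sumstats_frame(snp_ids, ea, oa, eaf, beta, se, n) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pvalue": _wald_p(beta, se),
            "n": float(n),
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )


def _block_corr(items: Sequence[str], groups: Sequence[GroupSpec], rho: float) -> pd.DataFrame:
    """Within-group constant-correlation blocks, identity elsewhere."""
    mat = pd.DataFrame(np.eye(len(items)), index=items, columns=items)
    for g in groups:
        members = [m for m in g.member_items if m in items]
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                mat.loc[a, b] = mat.loc[b, a] = rho
    return mat


def _primary_groups(items: Sequence[str], groups: Sequence[GroupSpec]) -> list[GroupSpec]:
    """Disjoint item partition used for the latent-factor structure.

    Overlapping / hierarchical group specs share the correlation blocks of
    the first group each item appears in.
    """
    taken: set[str] = set()
    primary = []
    for g in groups:
        members = [m for m in g.member_items if m in items and m not in taken]
        if len(members) >= 2:
            primary.append(GroupSpec(g.group_name, members, 1))
            taken.update(members)
    return primary


def simulate_grid(
    cfg: SimConfig,
    groups: Sequence[GroupSpec] | None = None,
) -> tuple[dict[str, SumStats], dict[str, SumStats], dict[str, SumStats], LdTable, SimTruth]:
    """Simulate a full exposure × metabolite grid of summary statistics.

    Returns (food-item SumStats by name, metabolite SumStats by name,
    confounder SumStats by name, LdTable, SimTruth).  PC-trait summary
    statistics are *not* pre-built: the pipeline derives them from the
    item-level tables and the returned correlation matrices, exactly as for
    real data.
    """
    rng = np.random.default_rng(cfg.seed)
    items = FOOD_ITEMS[: cfg.n_food_items]
    metabolites = default_metabolite_names(cfg.n_metabolites)
    conf_names = CONFOUNDER_NAMES[: cfg.n_confounders]
    groups = list(groups) if groups is not None else [
        g for g in default_groups()
        if all(m in items for m in g.member_items)
    ]

    n = cfg.n_snps
    snp_ids = np.array([f"rs{i + 1:07d}" for i in range(n)], dtype=object)
    bases = np.array(list("ACGT"))
    ea_idx = rng.integers(0, 4, size=n)
    shift = rng.integers(1, 4, size=n)
    ea = bases[ea_idx]
    oa = bases[(ea_idx + shift) % 4]
    eaf = rng.uniform(0.05, 0.95, size=n)

    # SNP roles
    n_pleio = int(round(cfg.prop_pleiotropic * n))
    n_med = int(round(cfg.prop_confounder_mediated * n))
    n_null = int(round(cfg.prop_null * n))
    n_direct = n - n_pleio - n_med - n_null
    if n_direct < 0:
        raise ConfigError("role proportions leave no direct instruments")
    roles = np.array(
        ["pleiotropic"] * n_pleio
        + ["confounder_mediated"] * n_med
        + ["null"] * n_null
        + ["direct"] * n_direct,
        dtype=object,
    )
    rng.shuffle(roles)
    is_instr = (roles == "direct") | (roles == "pleiotropic")
    is_med = roles == "confounder_mediated"
    is_pleio = roles == "pleiotropic"

    # --- true SNP -> food-item effects ---------------------------------
    # Items are partitioned into clusters (the disjoint cores of the PC
    # groups, plus singletons for uncovered items).  Each instrument SNP
    # acts on one cluster; within the cluster a shared latent factor
    # induces the declared within-group genetic correlation.
    rho_g = cfg.within_group_genetic_corr
    prim = _primary_groups(items, groups)
    covered = {m for g in prim for m in g.member_items}
    clusters: list[list[str]] = [g.member_items for g in prim] + [
        [it] for it in items if it not in covered
    ]
    item_col = {it: j for j, it in enumerate(items)}

    gamma = np.zeros((n, len(items)))
    instr_rows = np.where(is_instr)[0]
    assignment = rng.integers(0, len(clusters), size=len(instr_rows))
    for c, members in enumerate(clusters):
        rows = instr_rows[assignment == c]
        if len(rows) == 0:
            continue
        f = rng.normal(size=len(rows))
        for item in members:
            idio = rng.normal(size=len(rows))
            z = np.sqrt(rho_g) * f + np.sqrt(1.0 - rho_g) * idio
            gamma[rows, item_col[item]] = cfg.effect_size_sd * z

    # confounder-mediated component
    alpha = pd.Series(0.0, index=conf_names)
    causal_conf = conf_names[: cfg.n_causal_confounders]
    alpha[causal_conf] = cfg.confounder_alpha
    delta = np.zeros((n, len(conf_names)))
    if is_med.any():
        # each mediated SNP hits one causal confounder
        which = rng.integers(0, max(1, len(causal_conf)), size=int(is_med.sum()))
        effects = rng.normal(0.0, cfg.effect_size_sd, size=int(is_med.sum()))
        for row, (k, d) in zip(np.where(is_med)[0], zip(which, effects)):
            delta[row, k] = d
    gamma_total = gamma + delta @ np.diag(alpha.to_numpy()) @ np.ones((len(conf_names), len(items)))

    # --- true exposure -> metabolite grid ------------------------------
    all_exposures = items + [g.group_name for g in groups]
    causal_beta = pd.DataFrame(0.0, index=all_exposures, columns=metabolites)
    if cfg.prop_nonnull_pairs > 0:
        nonnull = rng.random((len(items), len(metabolites))) < cfg.prop_nonnull_pairs
        effects = rng.normal(0.0, cfg.causal_effect_sd, size=nonnull.sum())
        vals = np.zeros((len(items), len(metabolites)))
        vals[nonnull] = effects
        causal_beta.loc[items, :] = vals

    # PC-trait rows of the truth grid: loadings-weighted item effects
    G = _block_corr(items, prim, rho_g)
    P = _block_corr(items, prim, cfg.within_group_phenotypic_corr)
    for g in groups:
        sub = G.loc[g.member_items, g.member_items].to_numpy()
        evals, evecs = np.linalg.eigh(sub)
        order = np.argsort(-evals, kind="stable")
        load = evecs[:, order[g.pc_index - 1]]
        if load[np.argmax(np.abs(load))] < 0:
            load = -load
        causal_beta.loc[g.group_name, :] = load @ causal_beta.loc[g.member_items, :].to_numpy()

    # --- true SNP -> metabolite effects --------------------------------
    B = causal_beta.loc[items, :].to_numpy()          # items x metabolites
    phi = rng.normal(0.0, cfg.confounder_outcome_sd, size=(len(conf_names), len(metabolites)))
    big_gamma = gamma_total @ B + delta @ phi
    if is_pleio.any():
        shape = (int(is_pleio.sum()), len(metabolites))
        hits = rng.random(shape) < cfg.pleiotropy_prob
        big_gamma[is_pleio, :] += np.where(
            hits, rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=shape), 0.0
        )

    # --- observed summary statistics (two-sample: independent noise) ----
    se_x = 1.0 / np.sqrt(cfg.sample_size_exposure)
    se_y = 1.0 / np.sqrt(cfg.sample_size_outcome)
    se_c = 1.0 / np.sqrt(cfg.sample_size_confounder)

    exposures: dict[str, SumStats] = {}
    for j, item in enumerate(items):
        beta_hat = gamma_total[:, j] + rng.normal(0.0, se_x, size=n)
        exposures[item] = SumStats(
            item,
            _sumstats_frame(snp_ids, ea, oa, eaf, beta_hat, se_x, cfg.sample_size_exposure),
            trait_kind="food_item",
        )

    outcomes: dict[str, SumStats] = {}
    for j, met in enumerate(metabolites):
        beta_hat = big_gamma[:, j] + rng.normal(0.0, se_y, size=n)
        outcomes[met] = SumStats(
            met,
            _sumstats_frame(snp_ids, ea, oa, eaf, beta_hat, se_y, cfg.sample_size_outcome),
            trait_kind="metabolite",
        )

    confounders: dict[str, SumStats] = {}
    for j, name in enumerate(conf_names):
        beta_hat = delta[:, j] + rng.normal(0.0, se_c, size=n)
        confounders[name] = SumStats(
            name,
            _sumstats_frame(snp_ids, ea, oa, eaf, beta_hat, se_c, cfg.sample_size_confounder),
            trait_kind="confounder",
        )

    ld = make_ld_blocks(n, cfg.ld_block_size, cfg.ld_within_r2, snp_ids=snp_ids)

    truth = SimTruth(
        causal_beta=causal_beta,
        snp_roles=pd.Series(roles, index=snp_ids),
        confounder_alpha=alpha,
        item_genetic_corr=G,
        item_phenotypic_corr=P,
        item_effects=pd.DataFrame(gamma_total, index=snp_ids, columns=items),
        groups=groups,
        seed=cfg.seed,
    )
    return exposures, outcomes, confounders, ld, truth


def make_ld_blocks(
    n_snps: int,
    block_size: int,
    within_r2: float,
    seed: int = 0,
    snp_ids: Sequence[str] | None = None,
) -> LdTable:
    """Consecutive SNPs form blocks with constant within-block r².

    Cross-block pairs are absent (independent).  ``block_size = 1`` yields
    an empty table.
    """
    if block_size < 1:
        raise ConfigError(f"block_size must be >= 1, got {block_size}")
    ids = (
        list(snp_ids)
        if snp_ids is not None
        else [f"rs{i + 1:07d}" for i in range(n_snps)]
    )
    table = LdTable()
    if block_size == 1 or within_r2 <= 0:
        return table
    for start in range(0, n_snps, block_size):
        block = ids[start : start + block_size]
        for i, a in enumerate(block):
            for b in block[i + 1:]:
                table.set(a, b, within_r2)
    return table


def simulate_instrument_set(
    k: int,
    beta_true: float,
    seed: int,
    gamma_low: float = 0.05,
    gamma_high: float = 0.2,
    se_exposure: float = 0.0015,
    se_outcome: float = 0.02,
    n_invalid: int = 0,
    pleiotropy_mean: float = 0.0,
    pleiotropy_sd: float = 0.0,
    outlier_ratio: float | None = None,
    outlier_se: float | None = None,
    signed_gamma: bool = True,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
) -> InstrumentSet:
    """A single harmonized instrument set with known truth — the workhorse
    of estimator calibration studies.

    True SNP→exposure effects have magnitudes ~ U(gamma_low, gamma_high)
    with random sign; the first ``n_invalid`` instruments receive an extra
    direct outcome effect ~ N(pleiotropy_mean, pleiotropy_sd²) (directional
    when the mean is nonzero).  When ``outlier_ratio`` is given the last
    instrument's outcome effect is generated under that per-SNP causal ratio
    instead of ``beta_true`` (optionally with its own smaller SE), planting
    a heterogeneity outlier.
    """
    rng = np.random.default_rng(seed)
    gamma = rng.uniform(gamma_low, gamma_high, size=k)
    if signed_gamma:
        gamma *= rng.choice([-1.0, 1.0], size=k)
    pleio = np.zeros(k)
    if n_invalid > 0:
        pleio[:n_invalid] = rng.normal(pleiotropy_mean, pleiotropy_sd, size=n_invalid)
    mu_y = beta_true * gamma + pleio
    sy = np.full(k, se_outcome)
    if outlier_ratio is not None:
        mu_y[-1] = outlier_ratio * gamma[-1]
        if outlier_se is not None:
            sy[-1] = outlier_se
    bx = rng.normal(gamma, se_exposure)
    by = rng.normal(mu_y, sy)
    sx = np.full(k, se_exposure)
    return InstrumentSet(
        exposure_name=exposure_name,
        outcome_name=outcome_name,
        snp_ids=np.array([f"rs{i + 1:05d}" for i in range(k)], dtype=object),
        beta_exposure=bx,
        se_exposure=sx,
        beta_outcome=by,
        se_outcome=sy,
        pvalue_exposure=_wald_p(bx, se_exposure),
        eaf_exposure=np.full(k, 0.3),
    )


def simulate_cur_scenario(
    n_direct: int = 50,
    n_mediated: int = 50,
    alpha: float = 0.5,
    se: float = 0.01,
    seed: int = 0,
    direct_low: float = 0.2,
    direct_high: float = 0.4,
    mediated_low: float = 0.3,
    mediated_high: float = 0.6,
    confounder_name: str = "bmi",
) -> tuple[SumStats, SumStats, pd.Series]:
    """A food trait instrumented by direct and confounder-mediated SNPs.

    Direct SNPs carry food effects of magnitude U(direct_low, direct_high)
    (random sign) and no confounder effect; mediated SNPs act on the food
    only through the confounder (food effect = alpha × confounder effect,
    confounder effects of magnitude U(mediated_low, mediated_high)).  Both
    observed tables carry independent N(0, se²) noise.  Effect magnitudes
    are sized so the CUR window (±5% of the observed effect) comfortably
    exceeds the sampling noise of the estimated mediated component — the
    regime in which the filter is designed to operate.

    Returns (food SumStats, confounder SumStats, true role per SNP).
    """
    rng = np.random.default_rng(seed)
    n = n_direct + n_mediated
    snp_ids = np.array([f"rs{i + 1:05d}" for i in range(n)], dtype=object)
    roles = np.array(["direct"] * n_direct + ["confounder_mediated"] * n_mediated,
                     dtype=object)

    sign_d = rng.choice([-1.0, 1.0], size=n_direct)
    gamma_direct = rng.uniform(direct_low, direct_high, size=n_direct) * sign_d
    sign_m = rng.choice([-1.0, 1.0], size=n_mediated)
    delta = rng.uniform(mediated_low, mediated_high, size=n_mediated) * sign_m

    food_true = np.concatenate([gamma_direct, alpha * delta])
    conf_true = np.concatenate([np.zeros(n_direct), delta])
    food_hat = rng.normal(food_true, se)
    conf_hat = rng.normal(conf_true, se)

    bases = np.array(list("ACGT"))
    ea_idx = rng.integers(0, 4, size=n)
    shift = rng.integers(1, 4, size=n)
    ea, oa = bases[ea_idx], bases[(ea_idx + shift) % 4]
    eaf = rng.uniform(0.05, 0.95, size=n)

    food = SumStats(
        "food", _sumstats_frame(snp_ids, ea, oa, eaf, food_hat, se, 1.0 / se**2),
        trait_kind="food_item",
    )
    conf = SumStats(
        confounder_name,
        _sumstats_frame(snp_ids, ea, oa, eaf, conf_hat, se, 1.0 / se**2),
        trait_kind="confounder",
    )
    return food, conf, pd.Series(roles, index=snp_ids)


def null_grid_config(seed: int, n_snps: int = 400, n_metabolites: int = 123) -> SimConfig:
    """The fully-null grid scenario used for end-to-end FDR checks: no
    causal pairs, no pleiotropy, no confounder mediation."""
    return SimConfig(
        n_snps=n_snps,
        n_metabolites=n_metabolites,
        prop_pleiotropic=0.0,
        prop_confounder_mediated=0.0,
        prop_null=0.85,
        prop_nonnull_pairs=0.0,
        seed=seed,
    )
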