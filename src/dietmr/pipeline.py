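"""End-to-end orchestration of the diet → metabolite MR workflow.

Per exposure: genome-wide-significant instrument selection (for PC traits,
union-over-items selection followed by projection into the rotated space),
greedy LD pruning, CUR confounder filtering; then per outcome: allele
harmonization, radial outlier removal and the estimator battery.  Grid-level:
pooled Storey q-values over the main-analysis p-values, sensitivity
concordance flags, and the shrunk-beta heatmap matrices.

A failing exposure-outcome pair is logged and skipped; it never aborts the
grid.  Given a seed the whole run is deterministic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import cur as cur_mod
from . import pc as pc_mod
from .estimators import DEFAULT_HET_P_THRESHOLD, EstimatorConfig, MrResult, run_estimators
from .harmonize import _orientation, harmonize, ld_prune, select_significant
from .report import (
    ConcordanceFlags,
    QvalueSet,
    ShrinkageConfig,
    build_heatmap_matrix,
    concordance_flags,
    flags_to_frame,
    storey_qvalues,
)
from .sumstats import (
    ConfigError,
    GroupSpec,
    LdTable,
    SumStats,
    read_correlation_matrix,
    read_groups_yaml,
    read_ld_table,
    read_sumstats,
    results_to_frame,
)

logger = logging.getLogger(__name__)

MAIN_METHODS = ("ivw", "wald_ratio")


@dataclass
class PipelineSettings:
    """All thresholds and knobs of one run (defaults = the study settings)."""

    p_instrument: float = 5e-8
    r2_threshold: float = 0.001
    palindrome_eaf_window: float = 0.08
    cur_window: float = 0.05
    use_cur: bool = True
    stepwise_alpha: float = 0.05
    stepwise_criterion: str = "pvalue"
    pc_pvalue_rule: str = "wald"
    het_p_threshold: float = DEFAULT_HET_P_THRESHOLD
    q_significance: float = 0.05
    radial_alpha: float = 0.05
    radial_correction: str = "bonferroni"
    radial_max_iter: int = 10
    median_n_boot: int = 1000
    run_sensitivity: bool = True
    prior_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("p_instrument", 0.0, 1.0),
            ("r2_threshold", 0.0, 1.0),
            ("cur_window", 0.0, np.inf),
            ("het_p_threshold", 0.0, 1.0),
            ("q_significance", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo < v <= hi:
                raise ConfigError(f"{name} out of range: {v}")

    def estimator_config(self) -> EstimatorConfig:
        return EstimatorConfig(
            het_p_threshold=self.het_p_threshold,
            radial_alpha=self.radial_alpha,
            radial_correction=self.radial_correction,
            radial_max_iter=self.radial_max_iter,
            median_n_boot=self.median_n_boot,
            seed=self.seed,
            run_sensitivity=self.run_sensitivity,
        )


@dataclass
class PipelineData:
    """In-memory inputs of one run."""

    exposures: dict[str, SumStats]              # food items (and any pre-built traits)
    outcomes: dict[str, SumStats]
    confounders: dict[str, SumStats] = field(default_factory=dict)
    ld: LdTable = field(default_factory=LdTable)
    groups: list[GroupSpec] = field(default_factory=list)
    genetic_corr: pd.DataFrame | None = None
    phenotypic_corr: pd.DataFrame | None = None


@dataclass
class PipelineResult:
    results: list[MrResult]
    qvalues: QvalueSet | None
    qvalue_by_pair: dict[tuple[str, str], float]
    flags: list[ConcordanceFlags]
    heatmap_values: pd.DataFrame | None
    heatmap_mask: pd.DataFrame | None
    summary: dict

    def main_results(self) -> list[MrResult]:
        return [r for r in self.results if r.method in MAIN_METHODS]


def _align_trait(exposure: SumStats, other: SumStats, ids: Sequence[str]) -> SumStats | None:
    """Re-sign another trait's betas onto the exposure's effect alleles.

    Used to put confounder GWAS on the exposure's allele frame before the
    multivariable MR.  Both GWAS are assumed strand-consistent (palindromic
    SNPs in the nominal orientation are taken at face value, as for traits
    measured on one platform/panel).  SNPs missing or allele-mismatched in
    ``other`` are dropped.
    """
    rows = []
    exp = exposure.df
    oth = other.df
    for snp in ids:
        if snp not in oth.index:
            continue
        e, o = exp.loc[snp], oth.loc[snp]
        orient = _orientation(
            e["effect_allele"], e["other_allele"], o["effect_allele"], o["other_allele"]
        )
        if orient is None:
            continue
        beta = float(o["beta"])
        if orient in ("swapped", "flipped_swapped"):
            beta = -beta
        rows.append(
            {
                "snp_id": snp,
                "effect_allele": e["effect_allele"],
                "other_allele": e["other_allele"],
                "eaf": o["eaf"],
                "beta": beta,
                "se": float(o["se"]),
                "pvalue": float(o["pvalue"]),
                "n": o["n"],
            }
        )
    if not rows:
        return None
    return SumStats(other.trait_name, pd.DataFrame(rows).set_index("snp_id"),
                    trait_kind=other.trait_kind)


def _cur_stage(
    exposure: SumStats,
    pruned: list[str],
    confounders: dict[str, SumStats],
    settings: PipelineSettings,
    stage: dict,
) -> list[str]:
    """Run CUR filtering; on precondition failure keep all instruments."""
    n_conf = len(confounders)
    if n_conf == 0:
        stage["cur_applied"] = False
        return pruned
    if len(pruned) < n_conf + 2:
        logger.info(
            "%s: %d instruments < %d needed for stepwise MVMR; CUR skipped",
            exposure.trait_name, len(pruned), n_conf + 2,
        )
        stage["cur_applied"] = False
        return pruned

    aligned = []
    common = set(pruned)
    for conf in confounders.values():
        a = _align_trait(exposure, conf, pruned)
        if a is None:
            logger.warning(
                "%s: confounder %s shares no instrument; CUR skipped",
                exposure.trait_name, conf.trait_name,
            )
            stage["cur_applied"] = False
            return pruned
        aligned.append(a)
        common &= set(a.df.index)
    ids = [s for s in pruned if s in common]
    if len(ids) < n_conf + 2:
        stage["cur_applied"] = False
        return pruned

    fit = cur_mod.stepwise_mvmr(
        exposure, aligned, ids,
        criterion_alpha=settings.stepwise_alpha,
        criterion=settings.stepwise_criterion,
    )
    records = cur_mod.compute_cur_records(exposure, fit, aligned, ids)
    kept = cur_mod.filter_by_cur(records, window=settings.cur_window)
    # instruments outside the harmonized-common set never reached CUR; drop them too
    stage["cur_applied"] = True
    stage["cur_selected_confounders"] = fit.selected_confounders
    stage["dropped_cur"] = len(pruned) - len(kept)
    return kept


def prepare_exposures(
    data: PipelineData, settings: PipelineSettings
) -> dict[str, tuple[SumStats, dict[str, float]]]:
    """Instrument-candidate summary statistics and pruning p-values per exposure.

    Food items pass through unchanged (item p-values); PC traits are built
    by projecting item effects, carrying rotated-space p-values.
    """
    out: dict[str, tuple[SumStats, dict[str, float]]] = {}
    for name, ss in data.exposures.items():
        out[name] = (ss, ss.df["pvalue"].to_dict())

    if data.groups:
        if data.genetic_corr is None or data.phenotypic_corr is None:
            raise ConfigError("PC groups given without correlation matrices")
        built: dict[str, SumStats] = dict(data.exposures)
        for g in data.groups:
            missing = [m for m in g.member_items if m not in built]
            if missing:
                raise ConfigError(f"{g.group_name}: member trait(s) {missing} unavailable")
            model = pc_mod.fit_pc_model(g, data.genetic_corr, data.phenotypic_corr)
            pc_ss = pc_mod.build_pc_sumstats(
                {m: built[m] for m in g.member_items},
                model,
                p_threshold=settings.p_instrument,
                pvalue_rule=settings.pc_pvalue_rule,
            )
            if pc_ss is None:
                logger.info("%s: no candidate instrument; exposure skipped", g.group_name)
                continue
            built[g.group_name] = pc_ss
            out[g.group_name] = (pc_ss, pc_ss.df["pvalue"].to_dict())
    return out


def run_pipeline(
    data: PipelineData,
    settings: PipelineSettings | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full grid and (optionally) write the result tables.

    Output files (when ``out_dir`` is given): ``results_all.tsv``,
    ``results_significant.tsv``, ``heatmap_values.tsv``, ``heatmap_mask.tsv``,
    ``flags.tsv`` and a JSON ``run_manifest.json`` with per-stage counters.
    """
    settings = settings or PipelineSettings()
    est_cfg = settings.estimator_config()

    exposures = prepare_exposures(data, settings)
    all_results: list[MrResult] = []
    flags: list[ConcordanceFlags] = []
    stages: dict[str, dict] = {}
    pair_log: list[dict] = []

    for name, (ss, pvals) in exposures.items():
        stage: dict = {"exposure": name}
        stages[name] = stage
        # PC-trait candidate tables contain only qualifying SNPs already
        if ss.trait_kind == "pc_trait":
            candidates = sorted(ss.df.index, key=lambda s: (pvals[s], s))
        else:
            candidates = select_significant(ss, settings.p_instrument)
        stage["candidates"] = len(candidates)
        if not candidates:
            stage["status"] = "no_instruments"
            continue

        pruned = ld_prune(candidates, pvals, data.ld, settings.r2_threshold)
        stage["after_ld_prune"] = len(pruned)

        stage["dropped_cur"] = 0
        if settings.use_cur:
            kept = _cur_stage(ss, pruned, data.confounders, settings, stage)
        else:
            stage["cur_applied"] = False
            kept = pruned
        stage["after_cur"] = len(kept)
        if not kept:
            stage["status"] = "no_instruments_after_cur"
            continue
        stage["status"] = "analyzed"

        for out_name, out_ss in data.outcomes.items():
            entry = {
                "exposure": name,
                "outcome": out_name,
                "instruments_in": len(pruned),
                "dropped_cur": stage["dropped_cur"],
            }
            try:
                iset = harmonize(
                    ss, out_ss, kept,
                    palindrome_eaf_window=settings.palindrome_eaf_window,
                )
                entry["dropped_harmonization"] = len(kept) - iset.counts["kept"]
                if len(iset) == 0:
                    entry["status"] = "no_instruments_after_harmonization"
                    entry["dropped_radial"] = 0
                    entry["kept"] = 0
                    pair_log.append(entry)
                    continue
                results = run_estimators(iset, est_cfg)
            except Exception:
                logger.exception("pair %s -> %s failed; skipped", name, out_name)
                entry["status"] = "error"
                pair_log.append(entry)
                continue
            if not results:
                entry["status"] = "not_analyzed"
                entry["dropped_radial"] = len(iset)
                entry["kept"] = 0
                pair_log.append(entry)
                continue
            main = results[0]
            entry["dropped_radial"] = len(main.removed_snps)
            entry["kept"] = main.nsnp
            entry["status"] = "analyzed"
            pair_log.append(entry)
            all_results.extend(results)
            sens = [r for r in results[1:]]
            if sens:
                flags.append(concordance_flags(main, sens))

    # ---- grid-level inference -----------------------------------------
    main_results = [r for r in all_results if r.method in MAIN_METHODS]
    qset = None
    q_by_pair: dict[tuple[str, str], float] = {}
    heat_vals = heat_mask = None
    if main_results:
        qset = storey_qvalues([r.pvalue for r in main_results])
        q_by_pair = {
            (r.exposure, r.outcome): float(q)
            for r, q in zip(main_results, qset.qvalues)
        }
        heat_vals, heat_mask = build_heatmap_matrix(
            main_results,
            q_by_pair,
            ShrinkageConfig(prior_sd=settings.prior_sd),
            q_threshold=settings.q_significance,
        )

    n_sig = sum(1 for q in q_by_pair.values() if q < settings.q_significance)
    summary = {
        "n_exposures": len(exposures),
        "n_outcomes": len(data.outcomes),
        "pairs_analyzed": len(main_results),
        "pairs_significant": n_sig,
        "pi0": qset.pi0 if qset else None,
        "exposure_stages": stages,
        "pairs": pair_log,
        "settings": asdict(settings),
    }

    result = PipelineResult(
        results=all_results,
        qvalues=qset,
        qvalue_by_pair=q_by_pair,
        flags=flags,
        heatmap_values=heat_vals,
        heatmap_mask=heat_mask,
        summary=summary,
    )
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def write_outputs(result: PipelineResult, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    q_all = {
        (r.exposure, r.outcome, r.method): result.qvalue_by_pair.get((r.exposure, r.outcome), np.nan)
        for r in result.results
        if r.method in MAIN_METHODS
    }
    frame = results_to_frame(result.results, q_all)
    frame.to_csv(out_dir / "results_all.tsv", sep="\t", index=False, float_format="%.12g")
    sig = frame[(frame["method"].isin(MAIN_METHODS)) & (frame["qvalue"] < 0.05)]
    sig.to_csv(out_dir / "results_significant.tsv", sep="\t", index=False,
               float_format="%.12g")
    if result.heatmap_values is not None:
        result.heatmap_values.to_csv(out_dir / "heatmap_values.tsv", sep="\t",
                                     float_format="%.12g")
        result.heatmap_mask.to_csv(out_dir / "heatmap_mask.tsv", sep="\t")
    flags_to_frame(result.flags).to_csv(out_dir / "flags.tsv", sep="\t", index=False)
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# file-based configuration


def load_pipeline_config(path: str | Path) -> tuple[PipelineData, PipelineSettings, str | None]:
    """Build PipelineData + PipelineSettings from a YAML run config.

    Schema::

        exposures:    [{path, name?, kind?, column_map?}, ...]
        outcomes:     [{path, name?}, ...]
        confounders:  [{path, name?}, ...]
        ld_table: path
        groups: path            # YAML list of GroupSpec
        genetic_corr: path      # TSV matrix
        phenotypic_corr: path
        thresholds: {p_instrument, r2_threshold, cur_window, het_p_threshold, q_significance, ...}
        out_dir: path
    """
    import yaml

    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: not a mapping")
    base = path.parent

    def _resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    def _load_set(entries, kind) -> dict[str, SumStats]:
        out = {}
        for e in entries or []:
            ss = read_sumstats(
                _resolve(e["path"]),
                column_map=e.get("column_map"),
                trait_name=e.get("name"),
                trait_kind=e.get("kind", kind),
            )
            out[ss.trait_name] = ss
        return out

    data = PipelineData(
        exposures=_load_set(raw.get("exposures"), "food_item"),
        outcomes=_load_set(raw.get("outcomes"), "metabolite"),
        confounders=_load_set(raw.get("confounders"), "confounder"),
        ld=read_ld_table(_resolve(raw["ld_table"])) if raw.get("ld_table") else LdTable(),
        groups=read_groups_yaml(_resolve(raw["groups"])) if raw.get("groups") else [],
        genetic_corr=(
            read_correlation_matrix(_resolve(raw["genetic_corr"]))
            if raw.get("genetic_corr") else None
        ),
        phenotypic_corr=(
            read_correlation_matrix(_resolve(raw["phenotypic_corr"]))
            if raw.get("phenotypic_corr") else None
        ),
    )
    if not data.exposures:
        raise ConfigError(f"{path}: no exposures configured")
    if not data.outcomes:
        raise ConfigError(f"{path}: no outcomes configured")
    settings = PipelineSettings(**(raw.get("thresholds") or {}))
    out_dir = raw.get("out_dir")
    return data, settings, str(_resolve(out_dir)) if out_dir else None
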