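#!/usr/bin/env python
"""Run the full MR grid on the simulated study from 01_simulate.py and
report how well the pipeline recovers the planted causal structure.

Reads results/sim/, runs instrument selection -> LD pruning -> CUR ->
harmonization -> radial filtering -> estimator battery -> pooled Storey
q-values, writes the standard output tables to results/run/, and then
scores the q < 0.05 calls against the known truth grid (item-level and
PC-trait exposures separately).

Usage: python analysis/02_run_pipeline.py [--sim results/sim] [--out results/run]
"""

import argparse
from pathlib import Path

import pandas as pd

from dietmr.pipeline import PipelineData, PipelineSettings, run_pipeline
from dietmr.sumstats import (
    read_correlation_matrix,
    read_groups_yaml,
    read_ld_table,
    read_sumstats,
)


def _load_dir(d: Path, kind: str) -> dict:
    out = {}
    for path in sorted(d.glob("*.tsv")):
        ss = read_sumstats(path, trait_kind=kind)
        out[ss.trait_name] = ss
    return out


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--sim", type=Path, default=Path("results/sim"))
    ap.add_argument("--out", type=Path, default=Path("results/run"))
    ap.add_argument("--median-boot", type=int, default=200)
    args = ap.parse_args()

    data = PipelineData(
        exposures=_load_dir(args.sim / "exposures", "food_item"),
        outcomes=_load_dir(args.sim / "outcomes", "metabolite"),
        confounders=_load_dir(args.sim / "confounders", "confounder"),
        ld=read_ld_table(args.sim / "ld.tsv"),
        groups=read_groups_yaml(args.sim / "groups.yaml"),
        genetic_corr=read_correlation_matrix(args.sim / "genetic_corr.tsv"),
        phenotypic_corr=read_correlation_matrix(args.sim / "phenotypic_corr.tsv"),
    )
    settings = PipelineSettings(median_n_boot=args.median_boot, seed=7)
    result = run_pipeline(data, settings, out_dir=args.out)

    s = result.summary
    print(f"pairs analyzed: {s['pairs_analyzed']}, significant (q<0.05): "
          f"{s['pairs_significant']}, pi0-hat: {s['pi0']:.3f}")

    truth = pd.read_csv(args.sim / "truth_causal_beta.tsv", sep="\t", index_col=0)
    G = data.genetic_corr
    members = {g.group_name: g.member_items for g in data.groups}

    def genetically_related(exposure: str) -> set[str]:
        """Items genetically correlated with this exposure (or its members)."""
        if exposure in G.index:
            return set(G.index[G.loc[exposure] > 0.01])
        related: set[str] = set()
        for m in members.get(exposure, []):
            related |= set(G.index[G.loc[m] > 0.01])
        return related

    tp = fp_sibling = fp_other = fn = 0
    for r in result.main_results():
        sig = result.qvalue_by_pair[(r.exposure, r.outcome)] < 0.05
        true_nonzero = abs(truth.loc[r.exposure, r.outcome]) > 1e-12
        tp += sig and true_nonzero
        fn += (not sig) and true_nonzero
        if sig and not true_nonzero:
            # a genetically correlated item with a true effect on this
            # metabolite makes the call expected (correlated-exposure MR
            # signal), not a clean false positive
            if any(abs(truth.loc[i, r.outcome]) > 1e-12
                   for i in genetically_related(r.exposure) if i in truth.index):
                fp_sibling += 1
            else:
                fp_other += 1
    fp = fp_sibling + fp_other
    print(f"against the truth grid: {tp} true positives, {fn} missed, "
          f"{fp} calls with a zero direct effect")
    print(f"  of those, {fp_sibling} trace to a genetically correlated item "
          f"with a true effect (the dietary-pattern entanglement PC-traits "
          f"address); {fp_other} are residual (pleiotropy/mediation leakage)")
    print(f"  strict FDP {fp / max(1, tp + fp):.3f}; excluding "
          f"correlated-item calls {fp_other / max(1, tp + fp_other):.3f}; "
          f"power {tp / max(1, tp + fn):.3f}")

    flagged = [f for f in result.flags if f.opposite_direction or f.attenuated]
    print(f"concordance flags on {len(flagged)} / {len(result.flags)} pairs "
          f"with sensitivity estimates")


if __name__ == "__main__":
    main()
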