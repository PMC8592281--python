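"""Synthetic-data generator: determinism, calibration, structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dietmr.estimators import egger, ivw
from dietmr.harmonize import harmonize, ld_prune, select_significant
from dietmr.simulate import (
    SimConfig,
    make_ld_blocks,
    simulate_grid,
    simulate_instrument_set,
)
from dietmr.sumstats import ConfigError


def _small_cfg(**kw):
    base = dict(n_snps=300, n_food_items=6, n_metabolites=3, seed=1)
    base.update(kw)
    return SimConfig(**base)


class TestDeterminism:
    def test_same_config_same_seed_bit_identical(self):
        a = simulate_grid(_small_cfg())
        b = simulate_grid(_small_cfg())
        for ta, tb in zip(a[0].values(), b[0].values()):
            pd.testing.assert_frame_equal(ta.df, tb.df)
        for ta, tb in zip(a[1].values(), b[1].values()):
            pd.testing.assert_frame_equal(ta.df, tb.df)
        pd.testing.assert_frame_equal(a[4].causal_beta, b[4].causal_beta)

    def test_different_seed_differs(self):
        a = simulate_grid(_small_cfg(seed=1))
        b = simulate_grid(_small_cfg(seed=2))
        name = next(iter(a[0]))
        assert not np.allclose(a[0][name].df["beta"], b[0][name].df["beta"])


class TestNoiseModel:
    def test_vanishing_noise_limit_recovers_truth(self):
        """With astronomically large samples the observed betas equal the
        true effects and IVW recovers the planted causal slope."""
        cfg = _small_cfg(
            n_snps=200,
            sample_size_exposure=10**12,
            sample_size_outcome=10**12,
            prop_pleiotropic=0.0,
            prop_confounder_mediated=0.0,
            prop_nonnull_pairs=1.0,
            seed=3,
        )
        exposures, outcomes, _, _, truth = simulate_grid(cfg, groups=[])
        item = truth.item_effects.columns[0]
        obs = exposures[item].df["beta"].to_numpy()
        np.testing.assert_allclose(obs, truth.item_effects[item].to_numpy(), atol=1e-4)

        met = truth.causal_beta.columns[0]
        ids = select_significant(exposures[item], 5e-8)
        iset = harmonize(exposures[item], outcomes[met], ids)
        r = ivw(iset)
        assert r.beta == pytest.approx(truth.causal_beta.loc[item, met], abs=1e-3)

    def test_exposure_noise_sd_matches_declared_se(self):
        """Empirical SD of (observed - true) beta equals 1/sqrt(N) within 2%."""
        cfg = SimConfig(n_snps=100_000, n_food_items=2, n_metabolites=1,
                        n_confounders=1, prop_null=0.5, seed=4)
        exposures, _, _, _, truth = simulate_grid(cfg, groups=[])
        item = truth.item_effects.columns[0]
        resid = exposures[item].df["beta"].to_numpy() - truth.item_effects[item].to_numpy()
        declared = 1.0 / np.sqrt(cfg.sample_size_exposure)
        assert np.std(resid) == pytest.approx(declared, rel=0.02)

    def test_null_snp_pvalues_uniform(self):
        cfg = SimConfig(n_snps=20_000, n_food_items=2, n_metabolites=1,
                        n_confounders=1, prop_null=0.6, seed=5)
        exposures, _, _, _, truth = simulate_grid(cfg, groups=[])
        item = truth.item_effects.columns[0]
        null_ids = truth.snp_roles[truth.snp_roles == "null"].index
        p = exposures[item].df.loc[null_ids, "pvalue"].to_numpy()
        assert len(p) >= 10_000
        ks = sps.kstest(p[:10_000], "uniform")
        assert ks.pvalue > 0.01

    def test_item_effect_correlation_matches_declared_matrix(self):
        """Correlation of true item effect vectors reproduces the declared
        genetic correlation within 0.02 (no mediation in this check)."""
        cfg = SimConfig(n_snps=100_000, n_food_items=25, n_metabolites=1,
                        prop_pleiotropic=0.0, prop_confounder_mediated=0.0,
                        prop_null=0.0, seed=6)
        _, _, _, _, truth = simulate_grid(cfg)
        eff = truth.item_effects
        G = truth.item_genetic_corr
        for g in truth.groups[:4]:
            a, b = g.member_items[0], g.member_items[1]
            emp = np.corrcoef(eff[a], eff[b])[0, 1]
            assert emp == pytest.approx(G.loc[a, b], abs=0.02)

    def test_two_sample_noise_independent(self):
        cfg = _small_cfg(n_snps=5000, prop_null=1.0, prop_pleiotropic=0.0,
                         prop_confounder_mediated=0.0, seed=7)
        exposures, outcomes, _, _, truth = simulate_grid(cfg, groups=[])
        ex = next(iter(exposures.values())).df["beta"]
        out = next(iter(outcomes.values())).df["beta"]
        # all-null: residual noise of the two studies is uncorrelated
        assert abs(np.corrcoef(ex, out)[0, 1]) < 0.05


class TestCleanModelBehaviour:
    def test_egger_intercept_covers_zero_without_pleiotropy(self):
        covered = 0
        reps = 200
        for s in range(reps):
            iset = simulate_instrument_set(30, 0.3, seed=20_000 + s)
            r = egger(iset)
            lo = r.egger_intercept - 1.96 * r.egger_intercept_se
            hi = r.egger_intercept + 1.96 * r.egger_intercept_se
            covered += lo <= 0.0 <= hi
        assert covered / reps >= 0.90


class TestLdBlocks:
    def test_block_size_one_is_empty(self):
        assert len(make_ld_blocks(10, 1, 0.9)) == 0

    def test_pair_count_in_blocks(self):
        table = make_ld_blocks(10, 5, 0.9)
        assert len(table) == 2 * 10  # 2 blocks x C(5,2)

    def test_prune_keeps_one_per_block(self):
        table = make_ld_blocks(10, 5, 0.9)
        ids = [f"rs{i + 1:07d}" for i in range(10)]
        pvals = {s: 1e-9 * (i + 1) for i, s in enumerate(ids)}
        kept = ld_prune(ids, pvals, table, 0.001)
        assert len(kept) == 2

    def test_bad_block_size_rejected(self):
        with pytest.raises(ConfigError):
            make_ld_blocks(10, 0, 0.5)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"prop_pleiotropic": 1.2},
            {"prop_pleiotropic": 0.6, "prop_confounder_mediated": 0.6},
            {"n_snps": 0},
            {"n_food_items": 26},
        ],
    )
    def test_inconsistent_config_rejected(self, kw):
        with pytest.raises(ConfigError):
            SimConfig(**kw)

    def test_yaml_round_trip(self, tmp_path):
        cfg = _small_cfg(seed=9)
        path = tmp_path / "scenario.yaml"
        cfg.to_yaml(path)
        assert SimConfig.from_yaml(path) == cfg
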