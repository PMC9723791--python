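"""Generator contracts: determinism, latent structure, environment shifts."""

import numpy as np
import pandas as pd
import pytest

import traitscape as ts
from traitscape.covariation import correlation_matrix


class TestTraitTable:
    def test_zero_noise_replicates_identical(self):
        cfg = ts.default_config(seed=3, replicate_noise_sd=np.zeros(9))
        table, truth = ts.simulate_trait_table(cfg)
        for _, grp in table.groupby("strain_id"):
            assert np.allclose(grp[list(cfg.trait_names)].to_numpy().std(axis=0), 0.0)
        # and the values equal the noiseless culture means
        traits = list(cfg.trait_names)
        assert np.allclose(table[traits].to_numpy(), truth.culture_means[traits].to_numpy())

    def test_default_shape_and_size_group_correlation(self, default_cfg, std_table):
        table, _ = std_table
        assert len(table) == default_cfg.n_strains * default_cfg.n_replicates == 39
        r = np.corrcoef(table["cell_size"], table["chl_a"])[0, 1]
        assert r > 0.8

    def test_standard_environment_has_zero_shift(self, default_cfg, std_table):
        table, truth = std_table
        assert set(table["environment"]) == {default_cfg.standard_environment}
        # noiseless means carry only the factor signal: strain means of the
        # truth table equal trait_means + scales * (loadings @ f)
        f = truth.strain_factor_means.loc["s01"].to_numpy()
        expected = default_cfg.trait_means + default_cfg.trait_scales * (
            default_cfg.factor_loadings @ f
        )
        got = truth.culture_means[truth.culture_means.strain_id == "s01"][
            list(default_cfg.trait_names)
        ].iloc[0]
        assert np.allclose(got.to_numpy(), expected)

    def test_determinism_byte_identical(self, default_cfg):
        t1, _ = ts.simulate_trait_table(default_cfg)
        t2, _ = ts.simulate_trait_table(ts.default_config(seed=1))
        assert t1.to_csv(index=False) == t2.to_csv(index=False)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="2 strains"):
            ts.default_config(n_strains=1)
        with pytest.raises(ValueError, match="non-negative"):
            ts.default_config(replicate_noise_sd=np.full(9, -0.1))
        with pytest.raises(ValueError, match="orthogonal"):
            ts.default_config(factor_loadings=np.ones((9, 2)))

    def test_correlation_converges_to_implied(self):
        """With many strains and small replicate noise the sample trait
        correlation matrix approaches the factor-model one.  Per-entry
        sampling error scales as 1/sqrt(n_strains), so the matrix-level
        (mean absolute) deviation is the convergent quantity."""
        prev = None
        for n in (200, 800):
            cfg = ts.default_config(n_strains=n, seed=7, replicate_noise_sd=np.full(9, 0.01))
            table, _ = ts.simulate_trait_table(cfg)
            sample = np.corrcoef(table[list(cfg.trait_names)].to_numpy(), rowvar=False)
            dev = np.mean(np.abs(sample - cfg.implied_correlation()))
            assert dev < 0.05
            if prev is not None:
                assert dev < prev
            prev = dev


class TestPlasticityShift:
    def test_zero_noise_mean_change_equals_shift(self):
        cfg = ts.default_config(
            seed=5, replicate_noise_sd=np.zeros(9), env_shift_noise_sd=0.0
        )
        base, _ = ts.simulate_trait_table(cfg)
        full = ts.simulate_plasticity_shift(cfg, base)
        traits = list(cfg.trait_names)
        for env, shift in cfg.env_shift_vectors.items():
            trt = full[full.environment == env]
            for sid in trt.strain_id.unique():
                delta_nat = (
                    trt[trt.strain_id == sid][traits].mean()
                    - base[base.strain_id == sid][traits].mean()
                )
                delta_std = delta_nat.to_numpy() / cfg.trait_scales
                assert np.allclose(delta_std, shift, atol=1e-10)

    def test_low_nutrient_sign_reversal(self, default_cfg, full_table):
        """Within every shifted strain, chlorophyll decreases and lipids
        increase under low nutrients, while the across-strain correlation of
        the two traits stays positive."""
        base = full_table[full_table.environment == "standard"]
        ln = full_table[full_table.environment == "LN"]
        for sid in ln.strain_id.unique():
            d_chl = ln[ln.strain_id == sid]["chl_a"].mean() - base[base.strain_id == sid]["chl_a"].mean()
            d_lip = ln[ln.strain_id == sid]["lipids"].mean() - base[base.strain_id == sid]["lipids"].mean()
            assert d_chl < 0 and d_lip > 0
        means = base.groupby("strain_id")[["chl_a", "lipids"]].mean()
        assert np.corrcoef(means["chl_a"], means["lipids"])[0, 1] > 0

    def test_zero_shift_vector_appends_standard_law_rows(self):
        cfg = ts.default_config(
            seed=2, env_shift_vectors={"null_env": np.zeros(9)}, env_shift_noise_sd=0.0
        )
        base, _ = ts.simulate_trait_table(cfg)
        full = ts.simulate_plasticity_shift(cfg, base, environments=["null_env"])
        added = full[full.environment == "null_env"]
        assert len(added) == 5 * cfg.n_replicates
        # same generative law: pooled mean within sampling error of standard
        traits = list(cfg.trait_names)
        sub = base[base.strain_id.isin(added.strain_id.unique())]
        z = (added[traits].mean() - sub[traits].mean()) / sub[traits].std()
        assert np.all(np.abs(z) < 1.5)

    def test_unknown_environment_rejected(self, default_cfg, std_table):
        table, _ = std_table
        with pytest.raises(ValueError, match="unknown environment"):
            ts.simulate_plasticity_shift(default_cfg, table, environments=["mars"])


class TestGrowthSeries:
    def test_exact_exponential_values(self):
        s = ts.simulate_growth_series(mu=0.5, f0=100.0, days=5, noise_sd=0.0)
        expected = [100.0, 164.87212707, 271.82818285, 448.16890703, 738.90560989, 1218.24939607]
        assert np.allclose(s.fluorescence, expected)

    def test_zero_growth_constant(self):
        s = ts.simulate_growth_series(mu=0.0, f0=50.0, days=4)
        assert np.allclose(s.fluorescence, 50.0)

    def test_seed_determinism_and_lag_plateau(self):
        a = ts.simulate_growth_series(mu=0.4, noise_sd=0.1, seed=9)
        b = ts.simulate_growth_series(mu=0.4, noise_sd=0.1, seed=9)
        assert np.array_equal(a.fluorescence, b.fluorescence)
        lagged = ts.simulate_growth_series(mu=0.4, days=6, lag_days=2.0)
        assert np.allclose(lagged.fluorescence[:3][:2], 100.0)
        capped = ts.simulate_growth_series(mu=1.0, days=6, plateau=500.0)
        assert capped.fluorescence.max() == 500.0

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            ts.simulate_growth_series(mu=0.5, days=1)


class TestLightCurves:
    def test_small_irradiance_slope_is_alpha(self):
        e = np.array([1e-6, 1e-5, 1e-4, 1.0, 10.0, 50.0, 100.0, 200.0])
        c = ts.simulate_light_curves(alpha=0.3, etrmax=60.0, irradiances=e)
        assert c.etr[0] / e[0] == pytest.approx(0.3, rel=1e-9)

    def test_saturation_limit_and_closed_form(self):
        e = np.array([20.0, 50.0, 100.0, 200.0, 500.0, 1000.0, 5000.0, 20000.0])
        c = ts.simulate_light_curves(alpha=0.3, etrmax=60.0, irradiances=e)
        assert c.etr[-1] == pytest.approx(60.0, rel=1e-6)
        at200 = np.interp(200.0, c.irradiance, c.etr)
        assert at200 == pytest.approx(60.0 * np.tanh(1.0), abs=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ts.simulate_light_curves(alpha=-0.1, etrmax=60.0)
        with pytest.raises(ValueError):
            ts.simulate_light_curves(alpha=0.3, etrmax=0.0)


class TestIdentityMatrix:
    def test_diagonal_and_symmetry(self, default_cfg):
        m = ts.simulate_identity_matrix(default_cfg)
        assert np.allclose(np.diag(m.to_numpy()), 100.0)
        assert np.allclose(m.to_numpy(), m.to_numpy().T)
        off = m.to_numpy()[~np.eye(len(m), dtype=bool)]
        lo, hi = default_cfg.identity_range
        assert off.min() >= lo and off.max() <= hi

    def test_coupled_mode_decreasing_in_factor_distance(self, default_cfg):
        m = ts.simulate_identity_matrix(default_cfg, mode="coupled", coupled_noise_sd=0.0)
        from traitscape.synthetic import _strain_factors

        f = _strain_factors(default_cfg).to_numpy()
        ids = list(m.index)
        pairs = []
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                d = np.linalg.norm(f[i] - f[j])
                pairs.append((d, m.iloc[i, j]))
        pairs.sort()
        idents = [p[1] for p in pairs]
        assert all(a >= b - 1e-9 for a, b in zip(idents, idents[1:]))

    def test_needs_three_strains(self):
        with pytest.raises(ValueError, match="at least 3"):
            ts.simulate_identity_matrix(ts.default_config(n_strains=2))


def test_instrument_round_trip():
    """Noise-free instrument emission inverts to the generating trait table;
    the derived Ik is exactly ETRmax/alpha."""
    from traitscape.traits import derive_trait_table

    cfg = ts.default_config(n_strains=3, seed=2, growth_noise_sd=0.0, light_noise_sd=0.0)
    table, _ = ts.simulate_trait_table(cfg)
    data = ts.synthetic.emit_instrument_data(table, cfg)
    derived = derive_trait_table(**data).sort_values(["strain_id", "replicate"]).reset_index(drop=True)
    ref = table.sort_values(["strain_id", "replicate"]).reset_index(drop=True)
    for trait in ["growth_rate", "cell_size", "chl_a", "granularity", "lipids", "ros", "alpha", "etrmax"]:
        assert np.allclose(derived[trait], ref[trait], rtol=1e-8), trait
    assert np.allclose(derived["ik"], derived["etrmax"] / derived["alpha"])
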