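"""Correlation matrices, trait groups, centroid distances, recovery and
genotype-phenotype regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import traitscape as ts
from traitscape import covariation as cov
from traitscape.scape import trait_columns
from tests.conftest import random_trait_table

finite = st.floats(-100.0, 100.0, allow_nan=False)


class TestCorrelationMatrix:
    def test_diagonal_and_exact_linearity(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        df["y"] = 2 * df["x"]
        c = cov.correlation_matrix(df)
        assert c.r.loc["x", "x"] == 1.0
        assert c.r.loc["x", "y"] == pytest.approx(1.0)
        assert c.p.loc["x", "y"] < 1e-10
        assert bool(c.significant.loc["x", "y"])

    def test_matches_brute_force_oracle(self, rng):
        df = random_trait_table(rng)
        c = cov.correlation_matrix(df)
        traits = trait_columns(df)
        for i, a in enumerate(traits):
            for b in traits[i + 1 :]:
                r_ref, p_ref = stats.pearsonr(df[a], df[b])
                assert c.r.loc[a, b] == pytest.approx(r_ref, abs=1e-12)
                assert c.p.loc[a, b] == pytest.approx(p_ref, rel=1e-8)

    def test_constant_trait_reported_missing(self, rng):
        df = random_trait_table(rng)
        df["t0"] = 3.0
        c = cov.correlation_matrix(df)
        assert np.isnan(c.r.loc["t0", "t1"])
        assert not bool(c.significant.loc["t0", "t1"])

    def test_holm_is_conservative(self, rng):
        df = random_trait_table(rng)
        raw = cov.correlation_matrix(df)
        adj = cov.correlation_matrix(df, holm=True)
        iu = np.triu_indices(9, 1)
        assert np.all(adj.p.to_numpy()[iu] >= raw.p.to_numpy()[iu] - 1e-15)


def four_block_table(seed=0, n_strains=30):
    """Table with two latent blocks plus two independent traits: the
    generative partition has exactly four groups."""
    loadings = np.zeros((9, 4))
    for i, t in enumerate(ts.TRAIT_NAMES):
        g = ts.synthetic.DEFAULT_GROUP_ASSIGNMENT[t]
        loadings[i, ["size", "photophysiology", "growth", "ros"].index(g)] = 0.95
    cfg = ts.default_config(
        n_strains=n_strains,
        seed=seed,
        factor_loadings=loadings,
        strain_factor_sd=np.ones(4),
        replicate_noise_sd=np.full(9, 0.25),
    )
    table, truth = ts.simulate_trait_table(cfg)
    return table, truth


class TestTraitGroups:
    def test_block_structure_recovers_generative_partition(self):
        table, truth = four_block_table(seed=11)
        scape = ts.build_traitscape(table)
        c = cov.correlation_matrix(table)
        groups = cov.identify_trait_groups(c, scape)
        got = {frozenset(v) for v in groups.groups.values()}
        want = {
            frozenset(t for t, g in truth.group_assignment.items() if g == lab)
            for lab in set(truth.group_assignment.values())
        }
        assert got == want

    def test_extreme_thresholds(self, rng):
        df = random_trait_table(rng)
        scape = ts.build_traitscape(df)
        c = cov.correlation_matrix(df)
        singletons = cov.identify_trait_groups(c, scape, threshold=0.999)
        assert all(len(m) == 1 for m in singletons.groups.values())
        dup = pd.DataFrame({f"t{i}": df["t0"] * (i + 1) for i in range(9)})
        c2 = cov.correlation_matrix(dup)
        one = cov.identify_trait_groups(c2, ts.build_traitscape(dup), threshold=0.7)
        assert len(one.groups) == 1

    def test_threshold_bounds(self, rng):
        df = random_trait_table(rng)
        scape = ts.build_traitscape(df)
        c = cov.correlation_matrix(df)
        with pytest.raises(ValueError):
            cov.identify_trait_groups(c, scape, threshold=1.5)


class TestCentroidDistance:
    def test_examples(self):
        assert cov.centroid_distance((1.0, 2.0), (1.0, 2.0), 58.3, 19.4) == 0.0
        assert cov.centroid_distance((1.0, 0.0), (0.0, 0.0), 58.3, 19.4) == pytest.approx(58.3)
        assert cov.centroid_distance((1.0, 1.0), (0.0, 0.0), 58.3, 19.4) == pytest.approx(
            np.sqrt(58.3**2 + 19.4**2)
        )

    @given(
        st.tuples(finite, finite),
        st.tuples(finite, finite),
        st.tuples(finite, finite),
        st.floats(0.1, 100.0),
        st.floats(0.1, 100.0),
    )
    @settings(max_examples=300, deadline=None)
    def test_metric_axioms(self, p, q, r, a, b):
        d_pq = cov.centroid_distance(p, q, a, b)
        d_qp = cov.centroid_distance(q, p, a, b)
        assert d_pq == pytest.approx(d_qp)
        assert d_pq >= 0.0
        if p == q:
            assert d_pq == 0.0
        d_pr = cov.centroid_distance(p, r, a, b)
        d_rq = cov.centroid_distance(r, q, a, b)
        assert d_pq <= d_pr + d_rq + 1e-9 * max(1.0, d_pq)

    def test_positive_weights_required(self):
        with pytest.raises(ValueError):
            cov.centroid_distance((0, 0), (1, 1), 0.0, 19.4)


class TestDistanceRegression:
    def test_exact_linearity(self, rng):
        d = pd.Series(rng.uniform(1, 10, size=20))
        res = cov.distance_regression(d, 3.0 * d)
        assert res.r2 == pytest.approx(1.0)
        assert res.slope == pytest.approx(3.0)

    def test_weight_scale_invariance(self, std_table):
        table, _ = std_table
        scape = ts.build_traitscape(table)
        cents = cov.strain_centroids(scape.scores)
        a, b = scape.variance_pct(1), scape.variance_pct(2)
        d_pct = cov.pairwise_centroid_distances(cents, a, b)
        d_prop = cov.pairwise_centroid_distances(cents, a / 100, b / 100)
        other = ts.build_traitscape(table[["strain_id", "replicate", "environment",
                                           "cell_size", "etrmax", "growth_rate"]])
        d_alt = cov.pairwise_centroid_distances(
            cov.strain_centroids(other.scores), other.variance_pct(1), other.variance_pct(2)
        )
        r2_pct = cov.distance_regression(d_pct, d_alt).r2
        r2_prop = cov.distance_regression(d_prop, d_alt).r2
        assert r2_pct == pytest.approx(r2_prop, abs=1e-12)

    def test_null_mean_r2_close_to_one_over_m_minus_one(self):
        """Permuted distances: E[R^2] = 1/(m-1) under independence."""
        rng = np.random.default_rng(0)
        m = 78
        x = rng.uniform(size=m)
        vals = []
        for _ in range(500):
            y = rng.permutation(x)
            vals.append(cov.distance_regression(x, y).r2)
        assert np.mean(vals) == pytest.approx(1.0 / (m - 1), abs=0.01)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            cov.distance_regression(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestReducedRecovery:
    def test_full_subset_recovers_exactly(self, std_table):
        table, _ = std_table
        _, reg = cov.reduced_traitscape_recovery(table, list(ts.TRAIT_NAMES))
        assert reg.r2 == pytest.approx(1.0, abs=1e-10)

    def test_representative_subset_beats_no_size_subset(self, std_table):
        table, _ = std_table
        _, rep = cov.reduced_traitscape_recovery(
            table, ["growth_rate", "cell_size", "ros", "etrmax"]
        )
        _, nosize = cov.reduced_traitscape_recovery(
            table, ["growth_rate", "ros", "etrmax", "ik"]
        )
        assert rep.adj_r2 > nosize.adj_r2

    def test_subset_validation(self, std_table):
        table, _ = std_table
        with pytest.raises(ValueError, match="not in table"):
            cov.reduced_traitscape_recovery(table, ["cell_size", "nope"])
        with pytest.raises(ValueError, match="at least 2"):
            cov.reduced_traitscape_recovery(table, ["cell_size"])


class TestGenotypeRegression:
    def test_constant_identity_flagged(self, scape):
        cents = cov.strain_centroids(scape.scores)
        ident = pd.DataFrame(100.0, index=cents.index, columns=cents.index)
        with pytest.raises(ValueError, match="constant"):
            cov.genotype_phenotype_regression(ident, cents, 50.0, 25.0)

    def test_coupled_identity_strongly_predictive(self):
        cfg = ts.default_config(seed=3)
        table, _ = ts.simulate_trait_table(cfg)
        scape = ts.build_traitscape(table)
        ident = ts.simulate_identity_matrix(cfg, mode="coupled", coupled_noise_sd=0.0)
        reg = cov.genotype_phenotype_regression(
            ident, cov.strain_centroids(scape.scores),
            scape.variance_pct(1), scape.variance_pct(2),
        )
        assert reg.r2 > 0.7

    def test_strain_mismatch_rejected(self, scape, default_cfg):
        ident = ts.simulate_identity_matrix(default_cfg)
        cents = cov.strain_centroids(scape.scores)
        cents = cents.rename(index={"s01": "sXX"})
        with pytest.raises(ValueError, match="missing"):
            cov.genotype_phenotype_regression(ident, cents, 50.0, 25.0)
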