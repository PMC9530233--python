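"""JSD metric properties and the age-heteroskedasticity test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import jensenshannon

from agexpr.containers import ExpressionMatrix, SampleMetadata
from agexpr.heterogeneity import (
    bh_fdr,
    heteroskedasticity_scan,
    heteroskedasticity_test,
    jsd,
    jsd_age_slope,
    jsd_group_contrast,
    pairwise_jsd,
    shannon_entropy,
)
from agexpr.preprocess import split_age_groups
from agexpr.simulate import default_architectures, simulate_cohort, simulate_tissue


def random_distribution(rng, k):
    p = rng.random(k)
    return p / p.sum()


class TestEntropy:
    def test_uniform_two_outcomes(self):
        assert shannon_entropy(np.array([0.5, 0.5])) == pytest.approx(1.0)

    def test_point_mass(self):
        assert shannon_entropy(np.array([1.0, 0.0])) == 0.0

    def test_skewed_pair_closed_form(self):
        # direct evaluation: -(1/4 log2 1/4 + 3/4 log2 3/4)
        expected = -(0.25 * np.log2(0.25) + 0.75 * np.log2(0.75))
        assert shannon_entropy(np.array([0.25, 0.75])) == pytest.approx(expected)

    def test_negative_entry_errors(self):
        with pytest.raises(ValueError):
            shannon_entropy(np.array([-0.1, 1.1]))


class TestJsd:
    def test_identity_is_zero(self, rng):
        p = random_distribution(rng, 20)
        d, sd = jsd(p, p)
        assert d == 0.0 and sd == 0.0

    def test_disjoint_supports_maximal(self):
        d, sd = jsd(np.array([1.0, 0.0]), np.array([0.0, 1.0]))
        assert d == pytest.approx(1.0) and sd == pytest.approx(1.0)

    def test_matches_independent_oracle(self, rng):
        # scipy's jensenshannon returns sqrt(JSD) in the chosen base
        for _ in range(200):
            k = rng.integers(2, 30)
            p, q = random_distribution(rng, k), random_distribution(rng, k)
            d, sd = jsd(p, q)
            ref = jensenshannon(p, q, base=2)
            assert abs(d - ref**2) < 1e-10
            assert abs(sd - ref) < 1e-10

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            jsd(np.array([0.5, 0.5]), np.array([1 / 3] * 3))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_sqrt_jsd_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 15))
        a, b, c = (random_distribution(rng, k) for _ in range(3))
        _, ab = jsd(a, b)
        _, bc = jsd(b, c)
        _, ac = jsd(a, c)
        assert ac <= ab + bc + 1e-12

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 15))
        p, q = random_distribution(rng, k), random_distribution(rng, k)
        assert jsd(p, q)[0] == pytest.approx(jsd(q, p)[0], abs=1e-14)


def _tpm_matrix(values, sample_ids=None):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        [f"g{i}" for i in range(values.shape[0])],
        sample_ids or [f"s{j}" for j in range(values.shape[1])],
        scale="tpm",
    )


class TestPairwise:
    def test_pair_count(self, rng):
        expr = _tpm_matrix(rng.exponential(1, size=(10, 6)))
        assert len(pairwise_jsd(expr)) == 15

    def test_duplicate_profiles_zero(self, rng):
        col = rng.exponential(1, size=10)
        expr = _tpm_matrix(np.column_stack([col, col, 2 * col]))
        res = {(r.sample_a, r.sample_b): r.jsd for r in pairwise_jsd(expr)}
        assert res[("s0", "s1")] == 0.0
        # scaling a profile leaves its normalized distribution unchanged
        assert res[("s0", "s2")] == 0.0

    def test_all_zero_sample_excluded(self, rng, caplog):
        vals = rng.exponential(1, size=(5, 3))
        vals[:, 1] = 0
        with caplog.at_level("WARNING"):
            res = pairwise_jsd(_tpm_matrix(vals))
        assert len(res) == 1  # only the s0-s2 pair remains


def _het_tissue(n, het_slope, n_genes, seed, r2_age=0.1):
    archs = default_architectures(
        n_genes, h2=0.0, r2_age=r2_age, het_slope=het_slope, seed=seed
    )
    return simulate_tissue(
        n_samples=n, architectures=archs, n_snps_per_gene=2, seed=seed
    )


class TestGroupContrast:
    def test_doubled_old_noise_positive_contrast(self):
        # old group with inflated noise variance: positive sqrt-JSD contrast
        hits = 0
        for rep in range(10):
            sim = _het_tissue(120, 1.2, 200, 50 + rep, r2_age=0.0)
            expr = ExpressionMatrix(
                np.exp(sim.expr.values),
                list(sim.expr.gene_ids),
                list(sim.expr.sample_ids),
                scale="tpm",
            )
            meta = split_age_groups(sim.meta, 50)
            hits += jsd_group_contrast(expr, meta)["contrast"] > 0
        assert hits >= 9

    def test_replicate_profiles_group_mean_zero(self, rng):
        col = rng.exponential(1, size=8)
        vals = np.column_stack([col, col, col, rng.exponential(1, (8, 2))])
        expr = _tpm_matrix(vals)
        meta = SampleMetadata(
            pd.DataFrame(
                {"age": [30, 35, 40, 70, 75], "sex": [0] * 5},
                index=[f"s{j}" for j in range(5)],
            )
        )
        meta = split_age_groups(meta, 55)
        out = jsd_group_contrast(expr, meta)
        assert out["mean_sqrt_jsd_young"] == 0.0

    def test_small_group_errors(self, rng):
        expr = _tpm_matrix(rng.exponential(1, size=(4, 3)))
        meta = SampleMetadata(
            pd.DataFrame(
                {"age": [30, 40, 70], "sex": [0] * 3},
                index=["s0", "s1", "s2"],
            )
        )
        meta = split_age_groups(meta, 55)
        with pytest.raises(ValueError):
            jsd_group_contrast(expr, meta)


class TestAgeSlope:
    def test_age_dependent_noise_positive_slope(self):
        sim = _het_tissue(400, 1.0, 150, 77, r2_age=0.0)
        expr = ExpressionMatrix(
            np.exp(sim.expr.values),
            list(sim.expr.gene_ids),
            list(sim.expr.sample_ids),
            scale="tpm",
        )
        out = jsd_age_slope(expr, sim.meta)
        assert out["slope"] > 0 and out["p"] < 0.05
        assert out["n_bins"] == 6

    def test_single_bin_errors(self, rng):
        expr = _tpm_matrix(rng.exponential(1, size=(5, 4)))
        meta = SampleMetadata(
            pd.DataFrame(
                {"age": [21.0, 22, 23, 24], "sex": [0] * 4},
                index=[f"s{j}" for j in range(4)],
            )
        )
        with pytest.raises(ValueError):
            jsd_age_slope(expr, meta)


class TestHetTest:
    def test_power_under_generator_heteroskedasticity(self):
        sim = _het_tissue(600, 1.0, 100, 13)
        scan = heteroskedasticity_scan(sim.expr, sim.meta)
        power = ((scan["beta_het"] > 0) & (scan["p"] < 0.05)).mean()
        assert power >= 0.8

    def test_exactly_linear_expression_degenerate(self):
        meta = simulate_cohort(100, seed=5)
        res = heteroskedasticity_test(3.0 * meta.age - 1, meta)
        assert res.degenerate and res.p == 1.0

    def test_beta_het_sign_tracks_generator(self):
        up = _het_tissue(500, 1.0, 60, 21)
        down = _het_tissue(500, -0.6, 60, 22)
        b_up = heteroskedasticity_scan(up.expr, up.meta)["beta_het"].mean()
        b_down = heteroskedasticity_scan(down.expr, down.meta)["beta_het"].mean()
        assert b_up > 0 > b_down


class TestBhFdr:
    def test_all_equal(self):
        np.testing.assert_allclose(bh_fdr(np.full(5, 0.03)), 0.03)

    def test_matches_brute_force_definition(self, rng):
        def brute(p):
            m = len(p)
            order = np.argsort(p)
            q = np.empty(m)
            prev = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                prev = min(prev, p[i] * m / rank)
                q[i] = prev
            return q

        p = np.array([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(bh_fdr(p), brute(p), atol=1e-12)
        for _ in range(50):
            p = rng.uniform(1e-6, 1, size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_fdr(p), brute(p), atol=1e-12)

    def test_single_p(self):
        np.testing.assert_allclose(bh_fdr(np.array([0.2])), [0.2])

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.0, 0.5]))
        with pytest.raises(ValueError):
            bh_fdr(np.array([1.5]))
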