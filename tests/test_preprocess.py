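"""Filters, age-group construction, latent-factor correction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from agexpr.containers import ExpressionMatrix, GenotypeMatrix, SampleMetadata
from agexpr.preprocess import (
    age_independent_factors,
    downsample_balance,
    filter_genes,
    filter_snps,
    hwe_chisq_p,
    residualize,
    split_age_groups,
)
from agexpr.simulate import default_architectures, simulate_cohort, simulate_tissue


def _expr(values, scale="tpm"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        [f"g{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
        scale=scale,
    )


class TestFilterGenes:
    def test_low_tpm_excluded_high_retained(self):
        tpm = _expr([[0.05] * 10, [1.0] * 10])
        reads = _expr([[100] * 10, [10] * 10], scale="counts")
        out = filter_genes(tpm, reads)
        assert out.gene_ids == ["g1"]

    def test_read_boundary_inclusive(self):
        # 6 reads in exactly 20% of samples passes the >= criterion
        tpm = _expr([[1.0] * 10])
        reads = _expr([[6, 6] + [0] * 8], scale="counts")
        out = filter_genes(tpm, reads)
        assert out.gene_ids == ["g0"]

    def test_tpm_boundary_strict(self):
        # exactly 0.1 TPM everywhere fails the > criterion
        tpm = _expr([[0.1] * 10])
        out = filter_genes(tpm, None)
        assert out.gene_ids == []

    def test_missing_counts_skips_read_criterion(self, caplog):
        tpm = _expr([[1.0] * 10])
        with caplog.at_level("WARNING"):
            out = filter_genes(tpm, None)
        assert out.gene_ids == ["g0"]

    def test_filter_commutes_with_sample_subset(self):
        rng = np.random.default_rng(0)
        tpm = _expr(rng.exponential(0.2, size=(30, 40)))
        ids = tpm.sample_ids
        a = filter_genes(tpm.subset_samples(ids), None)
        b = filter_genes(tpm, None).subset_samples(ids)
        # same sample set: filtering and id-subsetting commute
        assert a.gene_ids == b.gene_ids


class TestFilterSnps:
    @staticmethod
    def _geno(columns):
        d = np.array(columns, dtype=float).T
        return GenotypeMatrix(
            d,
            [f"snp{i}" for i in range(d.shape[1])],
            np.arange(1, d.shape[1] + 1),
            [f"s{j}" for j in range(d.shape[0])],
        )

    def test_rare_snp_removed(self):
        col = [1.0] + [0.0] * 99  # MAF 0.005
        out = filter_snps(self._geno([col]))
        assert out.n_snps == 0

    def test_exact_hwe_retained(self):
        # counts (25, 50, 25) sit exactly at HWE for p=0.5 -> chi2=0, p=1
        col = [0.0] * 25 + [1.0] * 50 + [2.0] * 25
        assert hwe_chisq_p(np.array(col)) == pytest.approx(1.0)
        out = filter_snps(self._geno([col]))
        assert out.n_snps == 1

    def test_extreme_hwe_violation_removed(self):
        # (50, 0, 50): no hets at p=0.5; chi-square oracle via scipy
        col = [0.0] * 50 + [2.0] * 50
        exp = np.array([25.0, 50.0, 25.0])
        obs = np.array([50.0, 0.0, 50.0])
        chi2 = ((obs - exp) ** 2 / exp).sum()
        assert hwe_chisq_p(np.array(col)) == pytest.approx(
            stats.chi2.sf(chi2, 1), rel=1e-12
        )
        out = filter_snps(self._geno([col]))
        assert out.n_snps == 0

    def test_monomorphic_excluded_not_error(self):
        out = filter_snps(self._geno([[0.0] * 50]))
        assert out.n_snps == 0


class TestAgeGroups:
    def test_cutoff_tie_goes_old(self):
        meta = SampleMetadata(
            pd.DataFrame(
                {"age": [54.9, 55.0], "sex": [0, 1]}, index=["a", "b"]
            )
        )
        out = split_age_groups(meta, 55)
        assert list(out.age_group) == ["young", "old"]

    def test_lower_cutoff_monotone(self):
        meta = simulate_cohort(500, seed=1)
        n55 = (split_age_groups(meta, 55).age_group == "old").sum()
        n45 = (split_age_groups(meta, 45).age_group == "old").sum()
        assert n45 > n55

    def test_empty_metadata(self):
        meta = SampleMetadata(pd.DataFrame({"age": [], "sex": []}))
        out = split_age_groups(meta, 55)
        assert len(out) == 0


class TestDownsample:
    def _grouped(self, n_young, n_old):
        ages = [30.0] * n_young + [70.0] * n_old
        meta = SampleMetadata(
            pd.DataFrame(
                {"age": ages, "sex": [0] * len(ages)},
                index=[f"s{i}" for i in range(len(ages))],
            )
        )
        return split_age_groups(meta, 55)

    def test_balances_and_preserves_smaller_group(self):
        meta = self._grouped(120, 100)
        out = downsample_balance(meta, seed=0)
        counts = out.age_group.value_counts()
        assert counts["young"] == counts["old"] == 100
        # smaller group untouched
        old_ids = {s for s, g in zip(meta.sample_ids, meta.age_group) if g == "old"}
        assert old_ids <= set(out.sample_ids)

    def test_already_balanced_identity(self):
        meta = self._grouped(50, 50)
        out = downsample_balance(meta, seed=1)
        assert out.sample_ids == meta.sample_ids

    def test_seed_determinism(self):
        meta = self._grouped(80, 40)
        a = downsample_balance(meta, seed=9).sample_ids
        b = downsample_balance(meta, seed=9).sample_ids
        assert a == b

    def test_empty_group_errors(self):
        meta = self._grouped(10, 0)
        with pytest.raises(ValueError):
            downsample_balance(meta, seed=0)


class TestFactors:
    def test_factors_orthogonal_to_age(self, small_tissue):
        fm = age_independent_factors(small_tissue.expr, small_tissue.meta, k=5)
        age = small_tissue.meta.age
        for j in range(fm.k):
            r = np.corrcoef(fm.scores[:, j], age)[0, 1]
            assert abs(r) < 1e-8

    def test_recovers_injected_batch_factor(self):
        archs = default_architectures(60, h2=0.0, r2_age=0.1, seed=2)
        sim = simulate_tissue(
            n_samples=500,
            architectures=archs,
            n_snps_per_gene=2,
            seed=3,
            batch_variance=0.5,
        )
        fm = age_independent_factors(sim.expr, sim.meta, k=1)
        # reconstruct the latent batch vector the generator used
        from agexpr.simulate import simulate_cohort  # noqa: F401

        # factor 1 should align with the dominant shared component
        resid = sim.expr.values - sim.expr.values.mean(axis=1, keepdims=True)
        consensus = resid.mean(axis=0)  # with equal loadings, mean ~ batch
        r = np.corrcoef(fm.scores[:, 0], consensus)[0, 1]
        assert abs(r) > 0.9

    def test_perfectly_age_explained_flags_degenerate(self):
        meta = simulate_cohort(50, seed=4)
        values = np.vstack([2.0 * meta.age, -1.5 * meta.age + 3])
        expr = ExpressionMatrix(values, ["g0", "g1"], meta.sample_ids)
        fm = age_independent_factors(expr, meta, k=1)
        assert fm.degenerate

    def test_k_too_large(self, small_tissue):
        with pytest.raises(ValueError):
            age_independent_factors(
                small_tissue.expr, small_tissue.meta, k=small_tissue.meta.n_samples
            )


class TestResidualize:
    def test_intercept_only_centers(self, rng):
        expr = _expr(rng.normal(5, 1, size=(3, 20)), scale="normalized")
        out = residualize(expr, np.empty((20, 0)))
        np.testing.assert_allclose(out.values.mean(axis=1), 0, atol=1e-10)
        assert out.scale == "residual"

    def test_residuals_orthogonal_to_covariates(self, rng):
        expr = _expr(rng.normal(size=(5, 40)), scale="normalized")
        cov = rng.normal(size=(40, 3))
        out = residualize(expr, cov)
        for j in range(3):
            dots = out.values @ cov[:, j]
            np.testing.assert_allclose(dots, 0, atol=1e-8)

    def test_expression_equal_to_covariate(self, rng):
        cov = rng.normal(size=(30, 1))
        expr = _expr(cov.T.copy(), scale="normalized")
        out = residualize(expr, cov)
        np.testing.assert_allclose(out.values, 0, atol=1e-10)

    def test_collinear_columns_dropped_with_warning(self, rng, caplog):
        expr = _expr(rng.normal(size=(2, 25)), scale="normalized")
        x = rng.normal(size=25)
        cov = np.column_stack([x, 2 * x])
        with caplog.at_level("WARNING"):
            out = residualize(expr, cov)
        assert "rank-deficient" in caplog.text
        np.testing.assert_allclose(out.values @ x, 0, atol=1e-8)
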