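"""Sample, gene and SNP filters; age groups; latent-factor correction.

Implements the cohort-preparation conventions of GTEx-style eQTL studies:
expression filters on TPM and read support, common-SNP filters on minor
allele frequency and Hardy-Weinberg equilibrium, a median-age split into
young/old groups with downsampling to equal size, and hidden-factor
correction in which latent expression factors are computed on
age-residualized expression so they are orthogonal to age by construction
(principal components stand in for PEER; see docs/methods.md).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from .containers import ExpressionMatrix, GenotypeMatrix, SampleMetadata

__all__ = [
    "filter_genes",
    "filter_snps",
    "split_age_groups",
    "downsample_balance",
    "age_independent_factors",
    "residualize",
    "FactorMatrix",
]

logger = logging.getLogger(__name__)


class FactorMatrix:
    """Samples x k latent factor scores, orthogonal to age by construction."""

    def __init__(self, scores: np.ndarray, sample_ids: list[str], degenerate: bool = False):
        self.scores = np.asarray(scores, dtype=float)
        self.sample_ids = sample_ids
        self.degenerate = degenerate

    @property
    def k(self) -> int:
        return self.scores.shape[1]


def filter_genes(
    expr: ExpressionMatrix,
    reads: ExpressionMatrix | None = None,
    tpm_thresh: float = 0.1,
    read_thresh: float = 6,
    frac: float = 0.2,
) -> ExpressionMatrix:
    """Keep genes expressed above threshold in enough samples.

    A gene is retained when its TPM exceeds ``tpm_thresh`` (strict) in at
    least ``frac`` of samples AND its read count is at least ``read_thresh``
    (inclusive) in at least ``frac`` of samples. When no counts matrix is
    available (synthetic cohorts have none) the read criterion is skipped
    with a warning.
    """
    n = expr.n_samples
    ok_tpm = (expr.values > tpm_thresh).sum(axis=1) >= frac * n
    if reads is not None:
        if reads.gene_ids != expr.gene_ids or reads.sample_ids != expr.sample_ids:
            raise ValueError("TPM and counts matrices have mismatched ids")
        ok_reads = (reads.values >= read_thresh).sum(axis=1) >= frac * n
    else:
        logger.warning("no counts matrix supplied; read-support filter skipped")
        ok_reads = np.ones(expr.n_genes, dtype=bool)
    keep = [g for g, a, b in zip(expr.gene_ids, ok_tpm, ok_reads) if a and b]
    return expr.subset_genes(keep)


def hwe_chisq_p(dosages: np.ndarray) -> float:
    """Hardy-Weinberg chi-square p for one SNP from (rounded) hard calls.

    1 degree of freedom over the three genotype classes; monomorphic SNPs
    return p = 1 (the HWE null is vacuous there and the MAF filter removes
    them anyway).
    """
    calls = np.rint(dosages).astype(int)
    n = len(calls)
    n_aa = int((calls == 0).sum())
    n_ab = int((calls == 1).sum())
    n_bb = int((calls == 2).sum())
    p = (2 * n_bb + n_ab) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
    obs = np.array([n_aa, n_ab, n_bb])
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, df=1))


def filter_snps(
    geno: GenotypeMatrix,
    maf_min: float = 0.05,
    hwe_p_min: float = 0.05,
) -> GenotypeMatrix:
    """Keep common SNPs: MAF > ``maf_min`` (strict) and HWE p > ``hwe_p_min``."""
    maf = geno.maf
    keep = np.zeros(geno.n_snps, dtype=bool)
    for j in range(geno.n_snps):
        if maf[j] <= maf_min:
            continue
        if hwe_chisq_p(geno.dosages[:, j]) <= hwe_p_min:
            continue
        keep[j] = True
    return geno.subset_snps(keep)


def split_age_groups(meta: SampleMetadata, cutoff: float = 55.0) -> SampleMetadata:
    """Label samples old (age >= cutoff) or young (age < cutoff)."""
    out = meta.copy()
    out.table["age_group"] = np.where(out.age >= cutoff, "old", "young")
    return out


def downsample_balance(meta: SampleMetadata, seed: int | None = None) -> SampleMetadata:
    """Equalize young/old group sizes by downsampling the larger group.

    Selection is uniform without replacement and seed-deterministic; the
    smaller group is untouched. Row order of the surviving samples is
    preserved.
    """
    groups = meta.age_group
    young = [s for s, g in zip(meta.sample_ids, groups) if g == "young"]
    old = [s for s, g in zip(meta.sample_ids, groups) if g == "old"]
    if not young or not old:
        raise ValueError("both age groups must be non-empty before balancing")
    rng = np.random.default_rng(seed)
    target = min(len(young), len(old))
    keep = set()
    for members in (young, old):
        if len(members) > target:
            keep.update(rng.choice(members, size=target, replace=False))
        else:
            keep.update(members)
    kept_ids = [s for s in meta.sample_ids if s in keep]
    return meta.subset(kept_ids)


def age_independent_factors(
    expr: ExpressionMatrix,
    meta: SampleMetadata,
    k: int = 15,
) -> FactorMatrix:
    """Latent expression factors orthogonal to age.

    Each gene is regressed on age (with intercept); the top-``k`` right
    singular vectors of the residual matrix are returned as sample-space
    factor scores. Every factor lies in the row space of the residuals and
    is therefore exactly uncorrelated with age. When the residual matrix is
    numerically zero (expression perfectly explained by age) the factors
    are zero-filled and flagged degenerate.
    """
    if expr.sample_ids != meta.sample_ids:
        raise ValueError("expression and metadata sample ids differ")
    n = expr.n_samples
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    age = meta.age
    X = np.column_stack([np.ones(n), age - age.mean()])
    coef, *_ = np.linalg.lstsq(X, expr.values.T, rcond=None)
    resid = expr.values.T - X @ coef  # samples x genes
    if np.allclose(resid, 0, atol=1e-10):
        logger.warning("residual matrix ~0: expression fully explained by age")
        return FactorMatrix(np.zeros((n, k)), list(meta.sample_ids), degenerate=True)
    u, s, _ = np.linalg.svd(resid, full_matrices=False)
    scores = u[:, :k] * s[:k]
    if scores.shape[1] < k:
        scores = np.pad(scores, ((0, 0), (0, k - scores.shape[1])))
    return FactorMatrix(scores, list(meta.sample_ids))


def _orth(X: np.ndarray) -> np.ndarray:
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    tol = max(X.shape) * np.finfo(float).eps * (s[0] if s.size else 1.0)
    return u[:, s > tol]


def residualize(
    expr: ExpressionMatrix,
    covariates: np.ndarray,
) -> ExpressionMatrix:
    """Per-gene OLS residuals against a covariate matrix (intercept added).

    Collinear covariate columns are dropped via a rank-revealing QR with a
    warning rather than failing the whole run.
    """
    n = expr.n_samples
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim == 1:
        covariates = covariates[:, None]
    if covariates.shape[0] != n:
        raise ValueError("covariate rows must match sample count")
    X = np.column_stack([np.ones(n), covariates])
    # SVD-based orthonormal basis of the column space absorbs collinearity
    Q = _orth(X)
    if Q.shape[1] < X.shape[1]:
        logger.warning(
            "covariate matrix rank-deficient (%d < %d); collinear columns dropped",
            Q.shape[1],
            X.shape[1],
        )
    proj = Q @ (Q.T @ expr.values.T)
    resid = (expr.values.T - proj).T
    return ExpressionMatrix(
        values=resid,
        gene_ids=list(expr.gene_ids),
        sample_ids=list(expr.sample_ids),
        scale="residual",
    )
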