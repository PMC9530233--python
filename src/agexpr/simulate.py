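"""Synthetic cohort generator with known genetic/age architecture.

Generates GTEx-like cohorts in which every downstream statistic has a
known ground truth: dosage genotypes under Hardy-Weinberg equilibrium,
uniform adult ages, and per-gene expression assembled from a cis-genetic
block, a linear age trend, an optional age-by-sex interaction, optional
shared latent (batch-like) factors and Gaussian noise whose variance may
itself drift with age (heteroskedasticity).

Coefficients are scaled against *realized* sample variances of the
predictors, so the requested variance fractions are met tightly even at
moderate sample sizes; the realized values are recorded in a
:class:`~agexpr.containers.TruthTable` for parameter-recovery tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    ExpressionMatrix,
    GeneArchitecture,
    GenotypeMatrix,
    SampleMetadata,
    TruthTable,
)

__all__ = [
    "simulate_genotypes",
    "simulate_cohort",
    "simulate_expression",
    "simulate_constraint",
    "simulate_tissue",
    "default_architectures",
    "SimulatedTissue",
]

# Residual variance never drops below this fraction of its baseline, so a
# strong heteroskedasticity slope cannot produce zero- or negative-variance
# samples at the young end of the cohort.
NOISE_FLOOR = 0.05

# cis-window half-width used when placing SNPs around a nominal TSS.
CIS_WINDOW_BP = 1_000_000


def simulate_genotypes(
    n_samples: int,
    n_snps: int,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    seed: int | None = None,
    tss: int = 2_000_000,
    chrom: str = "1",
) -> GenotypeMatrix:
    """Draw HWE dosage genotypes for ``n_snps`` SNPs on one chromosome.

    Per-SNP allele frequencies are uniform on ``[maf_low, maf_high]`` and
    dosages are binomial(2, maf) draws, i.e. unlinked sites in
    Hardy-Weinberg equilibrium. Positions are placed within +/-1 Mb of
    ``tss`` and returned strictly increasing.
    """
    if not (0 < maf_low <= maf_high <= 0.5):
        raise ValueError("require 0 < maf_low <= maf_high <= 0.5")
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(maf_low, maf_high, size=n_snps)
    dosages = rng.binomial(2, mafs, size=(n_samples, n_snps)).astype(float)
    lo = max(1, tss - CIS_WINDOW_BP + 1)
    hi = tss + CIS_WINDOW_BP
    positions = np.unique(rng.integers(lo, hi, size=n_snps))
    while len(positions) < n_snps:  # rare collision top-up
        extra = rng.integers(lo, hi, size=n_snps - len(positions))
        positions = np.unique(np.concatenate([positions, extra]))
    return GenotypeMatrix(
        dosages=dosages,
        snp_ids=[f"snp_{chrom}_{p}" for p in positions],
        positions=positions,
        sample_ids=[f"S{i:05d}" for i in range(n_samples)],
        chrom=chrom,
    )


def simulate_cohort(
    n_samples: int,
    age_low: float = 20.0,
    age_high: float = 80.0,
    sex_ratio: float = 0.5,
    seed: int | None = None,
    n_batch_covariates: int = 0,
) -> SampleMetadata:
    """Sample a cohort with uniform ages and Bernoulli sexes.

    ``sex_ratio`` is the probability of sex = 1. Optional standard-normal
    batch covariates are attached as ``cov_0 .. cov_{k-1}``.
    """
    if not age_low < age_high:
        raise ValueError("age_low must be < age_high")
    rng = np.random.default_rng(seed)
    ages = rng.uniform(age_low, age_high, size=n_samples)
    sexes = rng.binomial(1, sex_ratio, size=n_samples)
    table = pd.DataFrame(
        {"age": ages, "sex": sexes},
        index=pd.Index([f"S{i:05d}" for i in range(n_samples)], name="sample_id"),
    )
    for k in range(n_batch_covariates):
        table[f"cov_{k}"] = rng.standard_normal(n_samples)
    return SampleMetadata(table)


def _scaled_component(raw: np.ndarray, target_var: float) -> tuple[np.ndarray, float]:
    """Rescale ``raw`` to have sample variance ``target_var``.

    Returns the scaled component and the multiplier; a constant ``raw``
    with nonzero target is a degenerate request and raises.
    """
    sd = raw.std(ddof=0)
    if target_var == 0:
        return np.zeros_like(raw), 0.0
    if sd == 0:
        raise ValueError("constant predictor cannot carry variance")
    scale = np.sqrt(target_var) / sd
    return raw * scale, scale


def simulate_expression(
    geno: GenotypeMatrix,
    meta: SampleMetadata,
    architectures: list[GeneArchitecture],
    seed: int | None = None,
    batch_loadings: np.ndarray | None = None,
    batch_variance: float = 0.0,
    gene_windows: dict[str, np.ndarray] | None = None,
) -> tuple[ExpressionMatrix, TruthTable]:
    """Generate expression with requested per-gene variance fractions.

    For gene ``g`` with architecture ``(h2, r2_age, r2_agesex, het_slope)``
    and total variance normalized to 1::

        y = sum_i beta_i x_i + beta_age * A + beta_agesex * A * S + eps

    where ``A`` is cohort-standardized age, ``S`` binary sex, the causal
    dosages are drawn from ``geno`` and each block is rescaled so its
    realized sample variance equals the requested fraction. The noise is
    Gaussian with per-sample variance
    ``resid * max(1 + het_slope * A, NOISE_FLOOR)`` where
    ``resid = 1 - h2 - r2_age - r2_agesex``.

    When ``batch_variance > 0`` a shared standard-normal latent factor is
    added to every gene with that variance fraction (taken out of the
    residual), emulating a technical batch effect; per-gene loadings may
    be supplied explicitly via ``batch_loadings``. ``gene_windows`` limits
    each gene's causal-SNP pool to its own cis window (column indices into
    ``geno``).
    """
    if geno.sample_ids != meta.sample_ids:
        raise ValueError("genotype and metadata sample ids differ")
    rng = np.random.default_rng(seed)
    n = meta.n_samples
    a_std = meta.standardized_age()
    sex = meta.sex

    batch = rng.standard_normal(n) if batch_variance > 0 else None

    values = np.empty((len(architectures), n))
    causal_snps: dict[str, list[str]] = {}
    causal_betas: dict[str, np.ndarray] = {}
    beta_age: dict[str, float] = {}
    beta_agesex: dict[str, float] = {}
    realized_h2: dict[str, float] = {}
    realized_r2_age: dict[str, float] = {}
    realized_r2_agesex: dict[str, float] = {}

    for j, arch in enumerate(architectures):
        g = arch.gene_id
        pool = (
            np.asarray(gene_windows[g])
            if gene_windows is not None
            else np.arange(geno.n_snps)
        )
        if arch.h2_true > 0 and arch.n_causal_snps > len(pool):
            raise ValueError(
                f"{g}: {arch.n_causal_snps} causal SNPs requested, "
                f"only {len(pool)} available"
            )

        # genetic block
        if arch.h2_true > 0 and arch.n_causal_snps > 0:
            idx = rng.choice(pool, size=arch.n_causal_snps, replace=False)
            raw_w = rng.standard_normal(arch.n_causal_snps)
            raw_g = geno.dosages[:, idx] @ raw_w
            genetic, scale = _scaled_component(raw_g, arch.h2_true)
            causal_snps[g] = [geno.snp_ids[i] for i in idx]
            causal_betas[g] = raw_w * scale
        else:
            genetic = np.zeros(n)
            causal_snps[g] = []
            causal_betas[g] = np.empty(0)

        # age trend; sign 0 with nonzero fraction means "random sign"
        if arch.r2_age_true > 0:
            sign = arch.beta_age_sign or rng.choice([-1, 1])
            b_age = sign * np.sqrt(arch.r2_age_true) / a_std.std(ddof=0)
            age_comp = b_age * a_std
        else:
            b_age = 0.0
            age_comp = np.zeros(n)

        # age x sex interaction
        if arch.r2_agesex_true > 0:
            inter = a_std * sex
            inter_comp, b_inter = _scaled_component(inter, arch.r2_agesex_true)
        else:
            b_inter = 0.0
            inter_comp = np.zeros(n)

        resid = arch.residual_fraction
        if batch is not None:
            loading = (
                batch_loadings[j] if batch_loadings is not None else 1.0
            ) * np.sqrt(batch_variance)
            resid = max(resid - batch_variance, 0.0)
            batch_comp = loading * batch
        else:
            batch_comp = 0.0

        noise_var = resid * np.maximum(1.0 + arch.het_slope * a_std, NOISE_FLOOR)
        eps = rng.standard_normal(n) * np.sqrt(noise_var)

        y = genetic + age_comp + inter_comp + batch_comp + eps
        values[j] = y

        beta_age[g] = float(b_age)
        beta_agesex[g] = float(b_inter)
        realized_h2[g] = _sq_corr(y, genetic)
        realized_r2_age[g] = _sq_corr(y, age_comp)
        realized_r2_agesex[g] = _sq_corr(y, inter_comp)

    expr = ExpressionMatrix(
        values=values,
        gene_ids=[a.gene_id for a in architectures],
        sample_ids=list(meta.sample_ids),
        scale="normalized",
    )
    truth = TruthTable(
        architectures={a.gene_id: a for a in architectures},
        causal_snps=causal_snps,
        causal_betas=causal_betas,
        beta_age=beta_age,
        beta_agesex=beta_agesex,
        realized_h2=realized_h2,
        realized_r2_age=realized_r2_age,
        realized_r2_agesex=realized_r2_agesex,
    )
    return expr, truth


def _sq_corr(y: np.ndarray, component: np.ndarray) -> float:
    if component.std(ddof=0) == 0 or y.std(ddof=0) == 0:
        return 0.0
    r = np.corrcoef(y, component)[0, 1]
    return float(r * r)


def simulate_constraint(
    truth: TruthTable,
    target_correlation: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate a pLI-like constraint score per gene.

    Uses a Gaussian copula on the rank-normal scores of the generative age
    slopes, so the Spearman correlation between constraint and ``beta_age``
    approximates ``target_correlation``; at +/-1 the constraint is an exact
    monotone transform. Values are mapped to [0, 1] via the normal CDF.

    Returns a DataFrame indexed by gene_id with columns ``pLI`` and
    ``degenerate`` (True when fewer than 2 genes make correlation moot).
    """
    if not -1 <= target_correlation <= 1:
        raise ValueError("target_correlation must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    genes = truth.gene_ids
    beta = np.array([truth.beta_age[g] for g in genes])
    m = len(genes)
    degenerate = m < 2
    if degenerate:
        z = rng.standard_normal(m)
    else:
        # rank-normal scores of beta_age; random ranks break ties so a
        # constant beta vector still yields a valid score
        jitter = rng.uniform(0, 1e-12, size=m)
        ranks = stats.rankdata(beta + jitter, method="ordinal")
        z_beta = stats.norm.ppf(ranks / (m + 1))
        rho = target_correlation
        z = rho * z_beta + np.sqrt(max(1 - rho**2, 0.0)) * rng.standard_normal(m)
    pli = stats.norm.cdf(z)
    return pd.DataFrame(
        {"pLI": pli, "degenerate": degenerate},
        index=pd.Index(genes, name="gene_id"),
    )


def default_architectures(
    n_genes: int,
    h2: float | None = None,
    r2_age: float | None = None,
    r2_agesex: float = 0.0,
    het_slope: float = 0.0,
    n_causal_snps: int = 3,
    seed: int | None = None,
) -> list[GeneArchitecture]:
    """Convenience factory for gene panels.

    When ``h2`` / ``r2_age`` are None, fractions are drawn uniformly on
    realistic ranges (h2 in [0, 0.4], r2_age in [0, 0.3]) subject to the
    sum-below-1 invariant; age-slope signs alternate at random.
    """
    rng = np.random.default_rng(seed)
    archs = []
    for i in range(n_genes):
        h = rng.uniform(0, 0.4) if h2 is None else h2
        ra = rng.uniform(0, 0.3) if r2_age is None else r2_age
        sign = int(rng.choice([-1, 1]))
        archs.append(
            GeneArchitecture(
                gene_id=f"gene_{i:04d}",
                n_causal_snps=n_causal_snps,
                h2_true=h,
                r2_age_true=ra,
                r2_agesex_true=r2_agesex,
                beta_age_sign=sign if ra > 0 else 0,
                het_slope=het_slope,
            )
        )
    return archs


from dataclasses import dataclass


@dataclass
class SimulatedTissue:
    """One synthetic tissue: aligned genotype/expression/metadata plus
    per-gene TSS positions and cis-window column indices."""

    geno: GenotypeMatrix
    expr: ExpressionMatrix
    meta: SampleMetadata
    truth: TruthTable
    gene_tss: dict[str, int]
    gene_windows: dict[str, np.ndarray]
    constraint: pd.DataFrame | None = None


def simulate_tissue(
    n_samples: int = 600,
    architectures: list[GeneArchitecture] | None = None,
    n_genes: int = 200,
    n_snps_per_gene: int = 20,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    age_low: float = 20.0,
    age_high: float = 80.0,
    sex_ratio: float = 0.5,
    seed: int | None = None,
    batch_variance: float = 0.0,
    constraint_correlation: float | None = None,
    meta: SampleMetadata | None = None,
) -> SimulatedTissue:
    """Simulate a full tissue with per-gene cis windows.

    Each gene receives its own nominal TSS on one synthetic chromosome
    (genes spaced 4 Mb apart so cis windows never overlap) and a block of
    ``n_snps_per_gene`` HWE SNPs within +/-1 Mb of that TSS; causal SNPs
    are drawn only from the gene's own window. A shared cohort is drawn
    once (or passed in via ``meta`` to reuse across tissues).
    """
    rng = np.random.default_rng(seed)
    if architectures is None:
        architectures = default_architectures(
            n_genes, seed=int(rng.integers(2**31))
        )
    if meta is None:
        meta = simulate_cohort(
            n_samples, age_low, age_high, sex_ratio, seed=int(rng.integers(2**31))
        )
    blocks, positions, snp_ids = [], [], []
    gene_tss: dict[str, int] = {}
    gene_windows: dict[str, np.ndarray] = {}
    col = 0
    for i, arch in enumerate(architectures):
        tss = 2_000_000 + i * 4_000_000
        block = simulate_genotypes(
            meta.n_samples,
            n_snps_per_gene,
            maf_low,
            maf_high,
            seed=int(rng.integers(2**31)),
            tss=tss,
        )
        blocks.append(block.dosages)
        positions.append(block.positions)
        snp_ids.extend(block.snp_ids)
        gene_tss[arch.gene_id] = tss
        gene_windows[arch.gene_id] = np.arange(col, col + n_snps_per_gene)
        col += n_snps_per_gene
    geno = GenotypeMatrix(
        dosages=np.hstack(blocks) if blocks else np.empty((meta.n_samples, 0)),
        snp_ids=snp_ids,
        positions=np.concatenate(positions) if positions else np.empty(0, dtype=int),
        sample_ids=list(meta.sample_ids),
    )
    expr, truth = simulate_expression(
        geno,
        meta,
        architectures,
        seed=int(rng.integers(2**31)),
        batch_variance=batch_variance,
        gene_windows=gene_windows,
    )
    truth.tss = dict(gene_tss)
    constraint = None
    if constraint_correlation is not None:
        constraint = simulate_constraint(
            truth, constraint_correlation, seed=int(rng.integers(2**31))
        )
    return SimulatedTissue(geno, expr, meta, truth, gene_tss, gene_windows, constraint)
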