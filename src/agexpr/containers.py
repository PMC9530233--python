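"""Core in-memory containers shared across the pipeline.

The pipeline moves three aligned objects between stages: a dosage matrix
(samples x SNPs), an expression matrix (genes x samples) and a per-sample
metadata table. Each is a thin dataclass around numpy/pandas so that
downstream code can rely on consistent axis conventions and id alignment
without repeatedly re-validating raw arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "ExpressionMatrix",
    "SampleMetadata",
    "GeneArchitecture",
    "TruthTable",
    "GeneModelFit",
]


@dataclass
class GenotypeMatrix:
    """Dosage genotypes for one cohort.

    Parameters
    ----------
    dosages
        ``(n_samples, n_snps)`` array of allelic dosages in ``[0, 2]``.
    snp_ids
        SNP identifiers, one per column.
    positions
        1-based basepair positions, strictly increasing within ``chrom``.
    sample_ids
        Sample identifiers, one per row.
    chrom
        Chromosome name shared by all SNPs (single synthetic chromosome).
    """

    dosages: np.ndarray
    snp_ids: list[str]
    positions: np.ndarray
    sample_ids: list[str]
    chrom: str = "1"

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.positions = np.asarray(self.positions, dtype=int)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x SNPs)")
        if self.dosages.shape[1] != len(self.snp_ids):
            raise ValueError("snp_ids length does not match dosage columns")
        if self.dosages.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length does not match dosage rows")
        if len(self.positions) != len(self.snp_ids):
            raise ValueError("positions length does not match snp_ids")
        if self.dosages.size and (self.dosages.min() < 0 or self.dosages.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def maf(self) -> np.ndarray:
        """Empirical minor-allele frequency per SNP."""
        if self.n_samples == 0:
            return np.zeros(self.n_snps)
        af = self.dosages.mean(axis=0) / 2.0
        return np.minimum(af, 1.0 - af)

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            snp_ids=[self.snp_ids[i] for i in idx],
            positions=self.positions[idx],
            sample_ids=list(self.sample_ids),
            chrom=self.chrom,
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        order = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [order[s] for s in sample_ids]
        return GenotypeMatrix(
            dosages=self.dosages[idx, :],
            snp_ids=list(self.snp_ids),
            positions=self.positions.copy(),
            sample_ids=list(sample_ids),
            chrom=self.chrom,
        )


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance matrix with an explicit scale tag.

    ``scale`` is one of ``"tpm"`` (non-negative abundances), ``"normalized"``
    (arbitrary real values, e.g. inverse-normal transformed) or ``"residual"``
    (covariate-adjusted residuals).
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    scale: str = "normalized"

    VALID_SCALES = ("tpm", "counts", "normalized", "residual")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (genes x samples)")
        if self.values.shape[0] != len(self.gene_ids):
            raise ValueError("gene_ids length does not match value rows")
        if self.values.shape[1] != len(self.sample_ids):
            raise ValueError("sample_ids length does not match value columns")
        if self.scale not in self.VALID_SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale in ("tpm", "counts") and self.values.size and self.values.min() < 0:
            raise ValueError(f"{self.scale} expression must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def gene(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id), :]

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        order = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [order[g] for g in gene_ids]
        return ExpressionMatrix(
            values=self.values[idx, :],
            gene_ids=list(gene_ids),
            sample_ids=list(self.sample_ids),
            scale=self.scale,
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        order = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [order[s] for s in sample_ids]
        return ExpressionMatrix(
            values=self.values[:, idx],
            gene_ids=list(self.gene_ids),
            sample_ids=list(sample_ids),
            scale=self.scale,
        )


class SampleMetadata:
    """Per-sample metadata: age in years, binary sex, free covariates.

    Backed by a :class:`pandas.DataFrame` indexed by ``sample_id`` with at
    least ``age`` and ``sex`` columns; an ``age_group`` column holds
    ``young`` / ``old`` / ``unassigned`` labels once the cohort is split.
    """

    RESERVED = ("age", "sex", "age_group")

    def __init__(self, table: pd.DataFrame):
        if "age" not in table.columns or "sex" not in table.columns:
            raise ValueError("metadata needs 'age' and 'sex' columns")
        table = table.copy()
        if "age_group" not in table.columns:
            table["age_group"] = "unassigned"
        self.table = table

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def age(self) -> np.ndarray:
        return self.table["age"].to_numpy(dtype=float)

    @property
    def sex(self) -> np.ndarray:
        return self.table["sex"].to_numpy(dtype=float)

    @property
    def age_group(self) -> pd.Series:
        return self.table["age_group"]

    @property
    def n_samples(self) -> int:
        return len(self.table)

    def covariate_columns(self) -> list[str]:
        return [c for c in self.table.columns if c not in self.RESERVED]

    def covariates(self) -> np.ndarray:
        cols = self.covariate_columns()
        if not cols:
            return np.empty((self.n_samples, 0))
        return self.table[cols].to_numpy(dtype=float)

    def standardized_age(self) -> np.ndarray:
        """Cohort z-score of age; raises on a constant age column."""
        a = self.age
        sd = a.std(ddof=0)
        if sd == 0:
            raise ValueError("age has zero variance; cannot standardize")
        return (a - a.mean()) / sd

    def subset(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        return SampleMetadata(self.table.loc[list(sample_ids)])

    def copy(self) -> "SampleMetadata":
        return SampleMetadata(self.table.copy())

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GeneArchitecture:
    """Ground-truth generative architecture for one synthetic gene.

    Variance fractions are targets on the total-variance-1 scale:
    ``h2_true`` for the cis-genetic block, ``r2_age_true`` for the linear
    age trend and ``r2_agesex_true`` for the age-by-sex interaction; their
    sum must stay below 1 so residual variance is strictly positive.
    ``het_slope`` scales the residual variance linearly in standardized age.
    """

    gene_id: str
    n_causal_snps: int = 1
    h2_true: float = 0.0
    r2_age_true: float = 0.0
    r2_agesex_true: float = 0.0
    beta_age_sign: int = 0
    het_slope: float = 0.0
    constraint_true: float = 0.5

    def __post_init__(self) -> None:
        for name in ("h2_true", "r2_age_true", "r2_agesex_true"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        total = self.h2_true + self.r2_age_true + self.r2_agesex_true
        if total >= 1:
            raise ValueError("variance fractions must sum to < 1")
        if self.beta_age_sign not in (-1, 0, 1):
            raise ValueError("beta_age_sign must be -1, 0 or +1")

    @property
    def residual_fraction(self) -> float:
        return 1.0 - self.h2_true - self.r2_age_true - self.r2_agesex_true


@dataclass
class TruthTable:
    """Realized generative parameters per gene, for recovery diagnostics."""

    architectures: dict[str, GeneArchitecture]
    causal_snps: dict[str, list[str]]
    causal_betas: dict[str, np.ndarray]
    beta_age: dict[str, float]
    beta_agesex: dict[str, float]
    realized_h2: dict[str, float]
    realized_r2_age: dict[str, float]
    realized_r2_agesex: dict[str, float]
    tss: dict[str, int] = field(default_factory=dict)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.architectures)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g, arch in self.architectures.items():
            rows.append(
                {
                    "gene_id": g,
                    "h2_true": arch.h2_true,
                    "r2_age_true": arch.r2_age_true,
                    "r2_agesex_true": arch.r2_agesex_true,
                    "het_slope": arch.het_slope,
                    "constraint_true": arch.constraint_true,
                    "beta_age": self.beta_age[g],
                    "beta_agesex": self.beta_agesex[g],
                    "realized_h2": self.realized_h2[g],
                    "realized_r2_age": self.realized_r2_age[g],
                    "realized_r2_agesex": self.realized_r2_agesex[g],
                }
            )
        return pd.DataFrame(rows).set_index("gene_id")


@dataclass
class GeneModelFit:
    """Fitted joint model for one gene: coefficients and variance partition.

    ``r2_environment`` is defined by remainder -- every source of expression
    variance not captured by the genetic or age blocks -- floored at zero.
    """

    gene_id: str
    tissue_id: str = "tissue"
    intercept: float = 0.0
    snp_ids: list[str] = field(default_factory=list)
    beta_snps: np.ndarray = field(default_factory=lambda: np.empty(0))
    beta_age: float = 0.0
    beta_agesex: float = 0.0
    lambda_: float = float("nan")
    alpha: float = 0.5
    h2: float = 0.0
    r2_age: float = 0.0
    r2_agesex: float = 0.0
    r2_environment: float = 1.0

    @property
    def n_nonzero_snps(self) -> int:
        return int(np.count_nonzero(self.beta_snps))
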