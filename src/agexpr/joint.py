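"""Joint elastic-net model of expression on cis-SNP dosages and age.

Per gene, expression (already residualized against technical covariates)
is regressed on all common SNPs within +/-1 Mb of the TSS plus cohort
standardized age and, optionally, an age-by-sex interaction:

    y = b0 + sum_i b_i x_i + b_age * A (+ b_agesex * A*S) + eps

with an elastic-net penalty mixing L1 and L2 equally (alpha = 0.5) and
the overall strength lambda chosen by 10-fold cross-validation over a
100-value log-spaced path (minimum mean-squared error). The training-set
variance is then partitioned: h2 is the squared Pearson correlation
between y and the genetic block's linear predictor, R2_age likewise for
the age term, and R2_environment is the remainder, floored at zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

from .containers import ExpressionMatrix, GeneModelFit, GenotypeMatrix, SampleMetadata

__all__ = [
    "DesignMatrix",
    "build_design",
    "elastic_net_fit",
    "partition_variance",
    "fit_gene_joint_model",
    "fit_tissue",
    "age_group_h2_contrast",
]

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "alpha": 0.5,  # L1/L2 mixing weight
    "cv_folds": 10,
    "n_lambdas": 100,
    "window_bp": 1_000_000,
    "include_interaction": False,
    "r2_method": "corr",  # "corr" (squared Pearson) or "ratio" (var ratio)
}


@dataclass
class DesignMatrix:
    """Standardized predictor matrix with column-role tags."""

    X: np.ndarray
    roles: list[str]  # per column: "genetic" | "age" | "agesex"
    snp_ids: list[str] = field(default_factory=list)

    def block(self, role: str) -> np.ndarray:
        idx = [i for i, r in enumerate(self.roles) if r == role]
        return self.X[:, idx]

    def block_indices(self, role: str) -> list[int]:
        return [i for i, r in enumerate(self.roles) if r == role]


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=0)


def build_design(
    geno: GenotypeMatrix,
    gene_tss: int,
    meta: SampleMetadata,
    include_interaction: bool = False,
    window_bp: int = 1_000_000,
) -> DesignMatrix:
    """Assemble the per-gene design: cis SNPs, standardized age, interaction.

    SNPs strictly within ``window_bp`` of ``gene_tss`` are kept and
    z-scored (constant dosage columns are dropped). Age is cohort
    z-scored; the optional interaction column is standardized age times
    binary sex, itself re-standardized, and dropped with a warning when
    constant or collinear with age (single-sex cohorts).
    """
    in_window = np.abs(geno.positions - gene_tss) < window_bp
    cols, roles, snp_ids = [], [], []
    for j in np.flatnonzero(in_window):
        d = geno.dosages[:, j]
        if d.std(ddof=0) == 0:
            continue
        cols.append(_zscore(d))
        roles.append("genetic")
        snp_ids.append(geno.snp_ids[j])
    if not cols:
        logger.warning("no polymorphic SNPs in window around TSS %d", gene_tss)
    a_std = meta.standardized_age()
    cols.append(a_std)
    roles.append("age")
    if include_interaction:
        inter = a_std * meta.sex
        sd = inter.std(ddof=0)
        collinear = sd > 0 and abs(np.corrcoef(inter, a_std)[0, 1]) > 1 - 1e-10
        if sd == 0 or collinear:
            logger.warning("age*sex column constant or collinear with age; dropped")
        else:
            cols.append(_zscore(inter))
            roles.append("agesex")
    return DesignMatrix(X=np.column_stack(cols), roles=roles, snp_ids=snp_ids)


def elastic_net_fit(
    design: DesignMatrix,
    y: np.ndarray,
    alpha: float = 0.5,
    cv_folds: int = 10,
    seed: int | None = None,
    n_lambdas: int = 100,
    lambda_: float | None = None,
    gene_id: str = "gene",
    tissue_id: str = "tissue",
) -> GeneModelFit:
    """Fit the penalized model; lambda by CV unless fixed via ``lambda_``.

    The objective is ``1/(2n) * ||y - b0 - X b||^2 +
    lambda * (alpha * ||b||_1 + (1 - alpha)/2 * ||b||_2^2)``; fold
    assignment for cross-validation is shuffled with ``seed`` so fits are
    reproducible.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if lambda_ is None:
        if n <= cv_folds:
            raise ValueError("need more samples than CV folds")
        cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        model = ElasticNetCV(
            l1_ratio=alpha,
            alphas=n_lambdas,  # int: length of the automatic log-spaced path
            cv=cv,
            fit_intercept=True,
            max_iter=5000,
        )
        model.fit(design.X, y)
        chosen_lambda = float(model.alpha_)
        coef, intercept = model.coef_, float(model.intercept_)
    else:
        model = ElasticNet(
            alpha=max(lambda_, 1e-12),
            l1_ratio=alpha,
            fit_intercept=True,
            max_iter=50000,
            tol=1e-10,
        )
        model.fit(design.X, y)
        chosen_lambda = float(lambda_)
        coef, intercept = model.coef_, float(model.intercept_)

    gi = design.block_indices("genetic")
    ai = design.block_indices("age")
    ii = design.block_indices("agesex")
    return GeneModelFit(
        gene_id=gene_id,
        tissue_id=tissue_id,
        intercept=intercept,
        snp_ids=list(design.snp_ids),
        beta_snps=np.asarray(coef)[gi],
        beta_age=float(coef[ai[0]]) if ai else 0.0,
        beta_agesex=float(coef[ii[0]]) if ii else 0.0,
        lambda_=chosen_lambda,
        alpha=alpha,
    )


def _block_r2(y: np.ndarray, pred: np.ndarray, method: str) -> float:
    if pred.std(ddof=0) == 0 or y.std(ddof=0) == 0:
        return 0.0
    if method == "corr":
        r = np.corrcoef(y, pred)[0, 1]
        return float(r * r)
    if method == "ratio":
        return float(min(pred.var(ddof=0) / y.var(ddof=0), 1.0))
    raise ValueError("r2 method must be 'corr' or 'ratio'")


def partition_variance(
    fit: GeneModelFit,
    design: DesignMatrix,
    y: np.ndarray,
    method: str = "corr",
) -> GeneModelFit:
    """Fill the variance partition of a fitted model in place.

    Each role block's linear predictor is compared against observed y;
    ``method="corr"`` uses the squared Pearson correlation (default),
    ``"ratio"`` the predictor-to-total variance ratio. The environment
    component is the remainder, floored at zero.
    """
    y = np.asarray(y, dtype=float)
    preds = {
        "genetic": design.block("genetic") @ fit.beta_snps
        if fit.beta_snps.size
        else np.zeros(len(y)),
        "age": design.block("age").ravel() * fit.beta_age
        if design.block_indices("age")
        else np.zeros(len(y)),
        "agesex": design.block("agesex").ravel() * fit.beta_agesex
        if design.block_indices("agesex")
        else np.zeros(len(y)),
    }
    fit.h2 = _block_r2(y, preds["genetic"], method)
    fit.r2_age = _block_r2(y, preds["age"], method)
    fit.r2_agesex = _block_r2(y, preds["agesex"], method)
    rem = 1.0 - fit.h2 - fit.r2_age - fit.r2_agesex
    if rem < 0:
        logger.debug("negative environment remainder %.3g floored at 0", rem)
    fit.r2_environment = max(rem, 0.0)
    return fit


def fit_gene_joint_model(
    expr_gene: np.ndarray,
    geno: GenotypeMatrix,
    meta: SampleMetadata,
    gene_tss: int,
    config: dict | None = None,
    seed: int | None = None,
    gene_id: str = "gene",
    tissue_id: str = "tissue",
) -> GeneModelFit:
    """End-to-end per-gene pipeline: design -> penalized fit -> partition."""
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    design = build_design(
        geno,
        gene_tss,
        meta,
        include_interaction=cfg["include_interaction"],
        window_bp=cfg["window_bp"],
    )
    fit = elastic_net_fit(
        design,
        expr_gene,
        alpha=cfg["alpha"],
        cv_folds=cfg["cv_folds"],
        seed=seed,
        n_lambdas=cfg["n_lambdas"],
        gene_id=gene_id,
        tissue_id=tissue_id,
    )
    return partition_variance(fit, design, expr_gene, method=cfg["r2_method"])


def fit_tissue(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    meta: SampleMetadata,
    gene_tss: dict[str, int],
    gene_windows: dict[str, np.ndarray] | None = None,
    config: dict | None = None,
    seed: int | None = None,
    tissue_id: str = "tissue",
    min_group_size: int | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Fit the joint model for every gene in a tissue.

    ``gene_windows`` may pre-restrict each gene's SNP columns (index array
    into ``geno``); otherwise the TSS window rule applies to the full
    matrix. When ``min_group_size`` is set the tissue must have that many
    samples in both age groups, mirroring cohort-inclusion rules for
    group-wise analyses.

    Returns the per-gene fit table and tissue-level means with standard
    errors of h2 and R2_age.
    """
    if min_group_size is not None:
        counts = meta.age_group.value_counts()
        if (
            counts.get("young", 0) < min_group_size
            or counts.get("old", 0) < min_group_size
        ):
            raise ValueError(
                f"tissue {tissue_id!r} fails the >= {min_group_size}"
                " per-age-group inclusion check"
            )
    rows = []
    for i, gene in enumerate(expr.gene_ids):
        sub = geno.subset_snps(gene_windows[gene]) if gene_windows else geno
        fit = fit_gene_joint_model(
            expr.values[i],
            sub,
            meta,
            gene_tss.get(gene, 0),
            config=config,
            seed=seed,
            gene_id=gene,
            tissue_id=tissue_id,
        )
        rows.append(
            {
                "gene_id": gene,
                "tissue": tissue_id,
                "beta_age": fit.beta_age,
                "beta_agesex": fit.beta_agesex,
                "n_nonzero_snps": fit.n_nonzero_snps,
                "h2": fit.h2,
                "r2_age": fit.r2_age,
                "r2_agesex": fit.r2_agesex,
                "r2_env": fit.r2_environment,
                "lambda": fit.lambda_,
            }
        )
    table = pd.DataFrame(rows).set_index("gene_id")
    summary = {}
    for col in ("h2", "r2_age"):
        v = table[col].to_numpy()
        summary[f"mean_{col}"] = float(v.mean()) if v.size else float("nan")
        summary[f"se_{col}"] = (
            float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else float("nan")
        )
    return table, summary


def age_group_h2_contrast(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    meta: SampleMetadata,
    gene_tss: dict[str, int],
    gene_windows: dict[str, np.ndarray] | None = None,
    config: dict | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-gene h2_young - h2_old from independent genetics-only fits.

    Each age group gets its own elastic-net fit with no age column (age is
    near-constant within group and would absorb genetic signal); the
    difference in training-set h2 measures the age-dependence of genetic
    predictive power. Requires balanced groups from ``downsample_balance``.
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    groups = meta.age_group
    rows = []
    members = {
        label: [s for s, g in zip(meta.sample_ids, groups) if g == label]
        for label in ("young", "old")
    }
    for label, ids in members.items():
        if len(ids) <= cfg["cv_folds"]:
            raise ValueError(f"group {label!r} too small for CV")
    for i, gene in enumerate(expr.gene_ids):
        sub = geno.subset_snps(gene_windows[gene]) if gene_windows else geno
        h2 = {}
        for label, ids in members.items():
            g_sub = sub.subset_samples(ids)
            e_sub = expr.subset_samples(ids)
            in_window = np.abs(g_sub.positions - gene_tss.get(gene, 0)) < cfg["window_bp"]
            cols, snp_ids = [], []
            for j in np.flatnonzero(in_window):
                d = g_sub.dosages[:, j]
                if d.std(ddof=0) == 0:
                    continue
                cols.append(_zscore(d))
                snp_ids.append(g_sub.snp_ids[j])
            if not cols:
                h2[label] = 0.0
                continue
            design = DesignMatrix(
                X=np.column_stack(cols),
                roles=["genetic"] * len(cols),
                snp_ids=snp_ids,
            )
            fit = elastic_net_fit(
                design,
                e_sub.values[i],
                alpha=cfg["alpha"],
                cv_folds=cfg["cv_folds"],
                seed=seed,
                n_lambdas=cfg["n_lambdas"],
                gene_id=gene,
            )
            fit = partition_variance(fit, design, e_sub.values[i], cfg["r2_method"])
            h2[label] = fit.h2
        rows.append(
            {
                "gene_id": gene,
                "h2_young": h2["young"],
                "h2_old": h2["old"],
                "h2_diff": h2["young"] - h2["old"],
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")
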