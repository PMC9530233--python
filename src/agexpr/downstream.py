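"""Tissue specificity, constraint (Medawar) regressions, cancer mutation
frequency, and hallmark-pathway contrasts.

Built on the per-gene joint-model fits: the tissue-specificity score
summarizes how concentrated a gene's age (or genetic) variance explained
is across tissues; constraint regressions test Medawar's hypothesis that
late-expressed genes (positive age slope) are under weaker purifying
selection (lower pLI); mutation-frequency regressions relate the age of
expression to somatic mutational burden in matched cancers; and pathway
contrasts compare age slopes between Medawarian and non-Medawarian
tissues within each gene set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .heterogeneity import bh_fdr

__all__ = [
    "SpecificityScore",
    "ConstraintRegression",
    "specificity_score",
    "specificity_contrast",
    "constraint_regression",
    "mutation_frequency_regression",
    "pathway_beta_contrast",
]

logger = logging.getLogger(__name__)


@dataclass
class SpecificityScore:
    gene_id: str
    component: str  # "age" | "genetics"
    s_g: float
    n_tissues: int


@dataclass
class ConstraintRegression:
    tissue_id: str
    predictor: str  # "beta_age" | "h2"
    constraint_metric: str
    slope: float
    se: float
    p: float
    classification: str  # Medawarian | non-Medawarian | not-significant
    n_genes: int


def specificity_score(
    r2_by_tissue: np.ndarray,
    component: str = "age",
    gene_id: str = "gene",
) -> SpecificityScore:
    """Tissue-specificity S_g of a gene's variance-explained profile.

    S_g = sum_t (1 - R2_t / R2_max) / (n - 1): the mean relative shortfall
    from the best tissue. 0 for a flat profile (ubiquitous effect), 1 when
    only a single tissue has nonzero R2. An all-zero profile is undefined
    and raises.
    """
    r2 = np.asarray(r2_by_tissue, dtype=float)
    n = len(r2)
    if n < 2:
        raise ValueError("specificity needs at least 2 tissues")
    if (r2 < 0).any():
        raise ValueError("R2 values must be non-negative")
    mx = r2.max()
    if mx == 0:
        raise ValueError("all-zero R2 profile: specificity undefined")
    s = float((1.0 - r2 / mx).sum() / (n - 1))
    return SpecificityScore(gene_id, component, s, n)


def specificity_contrast(
    scores_age: dict[str, float],
    scores_genetics: dict[str, float],
) -> dict[str, float]:
    """Paired t-test of per-gene age vs genetic specificity scores."""
    shared = sorted(set(scores_age) & set(scores_genetics))
    if len(shared) < 2:
        raise ValueError("need at least 2 genes present in both components")
    a = np.array([scores_age[g] for g in shared])
    b = np.array([scores_genetics[g] for g in shared])
    if np.allclose(a, b):
        t, p = 0.0, 1.0  # zero paired differences: no evidence either way
    else:
        t, p = stats.ttest_rel(a, b)
    return {
        "t": float(t),
        "p": float(p),
        "n_genes": len(shared),
        "mean_age_specificity": float(a.mean()),
        "mean_genetic_specificity": float(b.mean()),
    }


def constraint_regression(
    per_gene: pd.DataFrame,
    predictor: str = "beta_age",
    constraint_metric: str = "pLI",
    min_r2: float = 0.0,
    r2_column: str | None = None,
    p_threshold: float = 1e-3,
    exclude_top_expression_quartile: bool = False,
    expression_column: str = "median_expression",
    tissue_id: str = "tissue",
) -> ConstraintRegression:
    """OLS of the age slope (or h2) on a gene-constraint metric.

    Genes enter only when the relevant component is predictive
    (R2 > ``min_r2``; age R2 for beta_age regressions, h2 for h2
    regressions by default). A significantly negative slope (p below
    ``p_threshold``) is classified Medawarian, significantly positive
    non-Medawarian, otherwise not-significant. Optionally excludes genes
    in the top quartile of median expression as a robustness variant.
    """
    df = per_gene.copy()
    if r2_column is None:
        r2_column = "r2_age" if predictor == "beta_age" else "h2"
    if r2_column in df.columns:
        df = df[df[r2_column] > min_r2]
    if exclude_top_expression_quartile:
        if expression_column not in df.columns:
            raise ValueError(f"missing {expression_column!r} for quartile filter")
        q3 = df[expression_column].quantile(0.75)
        df = df[df[expression_column] <= q3]
    if len(df) < 3:
        raise ValueError("fewer than 3 genes after filtering")
    x = df[constraint_metric].to_numpy(dtype=float)
    y = df[predictor].to_numpy(dtype=float)
    if x.std() == 0:
        raise ValueError("constraint metric is constant")
    res = stats.linregress(x, y)
    if res.pvalue < p_threshold and res.slope < 0:
        cls = "Medawarian"
    elif res.pvalue < p_threshold and res.slope > 0:
        cls = "non-Medawarian"
    else:
        cls = "not-significant"
    return ConstraintRegression(
        tissue_id=tissue_id,
        predictor=predictor,
        constraint_metric=constraint_metric,
        slope=float(res.slope),
        se=float(res.stderr),
        p=float(res.pvalue),
        classification=cls,
        n_genes=len(df),
    )


def mutation_frequency_regression(
    per_gene: pd.DataFrame,
    min_total: int = 200,
) -> dict[str, float]:
    """OLS of cancer somatic mutation frequency on the age slope.

    ``per_gene`` needs columns beta_age, mutated_samples, total_samples;
    frequency = mutated / total; genes with total strictly greater than
    ``min_total`` tumor samples enter the regression.
    """
    df = per_gene.copy()
    if (df["mutated_samples"] > df["total_samples"]).any():
        raise ValueError("mutated_samples cannot exceed total_samples")
    if (df["mutated_samples"] < 0).any() or (df["total_samples"] < 0).any():
        raise ValueError("counts must be non-negative")
    df = df[df["total_samples"] > min_total]
    if len(df) < 3:
        raise ValueError(f"no usable genes with > {min_total} tumor samples")
    freq = df["mutated_samples"] / df["total_samples"]
    res = stats.linregress(df["beta_age"].to_numpy(dtype=float), freq.to_numpy())
    return {
        "slope": float(res.slope),
        "se": float(res.stderr),
        "p": float(res.pvalue),
        "n_genes": len(df),
    }


def pathway_beta_contrast(
    beta_age: pd.DataFrame,
    tissue_classes: dict[str, str],
    gene_sets: dict[str, list[str]],
    fdr_threshold: float = 0.01,
) -> pd.DataFrame:
    """Per-pathway contrast of age slopes between tissue classes.

    ``beta_age`` is a long table with columns gene_id, tissue, beta_age;
    ``tissue_classes`` maps tissue -> "Medawarian" / "non-Medawarian".
    Within each gene set, beta_age values pooled over genes and tissues of
    each class are compared with a two-sided t-test; p-values are BH
    adjusted across pathways. Pathways with fewer than 2 observations in
    either class are skipped with a warning.
    """
    med = {t for t, c in tissue_classes.items() if c == "Medawarian"}
    non = {t for t, c in tissue_classes.items() if c == "non-Medawarian"}
    if not med or not non:
        raise ValueError("both tissue classes must be non-empty")
    rows = []
    for name, genes in gene_sets.items():
        sub = beta_age[beta_age["gene_id"].isin(genes)]
        x = sub[sub["tissue"].isin(med)]["beta_age"].to_numpy(dtype=float)
        y = sub[sub["tissue"].isin(non)]["beta_age"].to_numpy(dtype=float)
        if len(x) < 2 or len(y) < 2:
            logger.warning("pathway %s has < 2 observations in a class; skipped", name)
            continue
        t, p = stats.ttest_ind(x, y)
        rows.append(
            {
                "pathway": name,
                "t": float(t),
                "p": float(p),
                "mean_medawarian": float(x.mean()),
                "mean_non_medawarian": float(y.mean()),
                "n_medawarian": len(x),
                "n_non_medawarian": len(y),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "pathway",
                "t",
                "p",
                "q",
                "significant",
                "mean_medawarian",
                "mean_non_medawarian",
                "n_medawarian",
                "n_non_medawarian",
            ]
        ).set_index("pathway")
    out = pd.DataFrame(rows).set_index("pathway")
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["q"] < fdr_threshold
    return out
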