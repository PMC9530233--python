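"""Per-gene lead-SNP eQTL fits and the young/old predictive-power contrast.

For each gene the lead SNP is chosen on the full cohort (smallest marginal
p in the cis window, ties to the lower position), then the expression ~
dosage regression is refit separately within the young and old groups with
the same SNP so the contrast is paired on SNP identity. Tissue-level
differences in predictive power are tested by comparing the two groups'
p-value distributions on the -log10 scale with Welch's unequal-variance
t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, GenotypeMatrix, SampleMetadata

__all__ = [
    "EqtlResult",
    "GroupContrast",
    "lead_snp_scan",
    "eqtl_fit",
    "welch_t",
    "compare_pvalue_distributions",
    "tissue_contrast",
]

P_FLOOR = 1e-300  # avoid -log10 underflow


@dataclass
class EqtlResult:
    gene_id: str
    snp_id: str
    group: str
    slope: float
    se: float
    t: float
    p: float
    constant_dosage: bool = False


@dataclass
class GroupContrast:
    t_statistic: float
    dof: float
    p: float
    direction: str  # young_stronger | old_stronger
    n_genes: int
    mean_neglogp_young: float
    mean_neglogp_old: float


def _marginal_pvalues(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Two-sided p for each column's simple regression slope against y."""
    n = len(y)
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    sx = Xc.std(axis=0)
    sy = yc.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / (n * sx * sy)
    r = np.clip(np.nan_to_num(r), -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p[sx == 0] = 1.0  # constant dosage carries no signal
    return p


def lead_snp_scan(
    expr_gene: np.ndarray,
    geno_window: GenotypeMatrix,
    covariates: np.ndarray | None = None,
) -> str:
    """Lead SNP: minimal marginal p on the full cohort.

    Ties break to the lowest position, then lexicographic snp id. When
    covariates are given, expression is residualized against them first.
    """
    if geno_window.n_snps == 0:
        raise ValueError("empty cis window")
    y = np.asarray(expr_gene, dtype=float)
    if covariates is not None and covariates.size:
        X = np.column_stack([np.ones(len(y)), covariates])
        y = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    p = _marginal_pvalues(y, geno_window.dosages)
    order = sorted(
        range(geno_window.n_snps),
        key=lambda j: (p[j], geno_window.positions[j], geno_window.snp_ids[j]),
    )
    return geno_window.snp_ids[order[0]]


def eqtl_fit(
    expr_gene: np.ndarray,
    dosage: np.ndarray,
    covariates: np.ndarray | None = None,
    gene_id: str = "gene",
    snp_id: str = "snp",
    group: str = "all",
) -> EqtlResult:
    """OLS of expression on dosage (+ covariates + intercept).

    Returns slope, standard error, t and two-sided p for the dosage term.
    A constant dosage is flagged and reported with p = 1.
    """
    y = np.asarray(expr_gene, dtype=float)
    d = np.asarray(dosage, dtype=float)
    cov = (
        np.asarray(covariates, dtype=float).reshape(len(y), -1)
        if covariates is not None and np.size(covariates)
        else np.empty((len(y), 0))
    )
    n, k = len(y), cov.shape[1]
    if n <= k + 2:
        raise ValueError("not enough samples for the requested covariates")
    if d.std() == 0:
        return EqtlResult(gene_id, snp_id, group, 0.0, np.nan, 0.0, 1.0, True)
    X = np.column_stack([np.ones(n), d, cov])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = n - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = float(np.sqrt(sigma2 * XtX_inv[1, 1]))
    slope = float(coef[1])
    tval = slope / se if se > 0 else 0.0
    p = float(2 * stats.t.sf(abs(tval), df=dof)) if se > 0 else 1.0
    return EqtlResult(gene_id, snp_id, group, slope, se, tval, max(p, P_FLOOR), False)


def welch_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: (t, Welch-Satterthwaite dof, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs length >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("both samples have zero variance")
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    dof = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = float(2 * stats.t.sf(abs(t), df=dof))
    return float(t), float(dof), p


def compare_pvalue_distributions(
    p_young: np.ndarray,
    p_old: np.ndarray,
    transform: str = "neglog10",
) -> GroupContrast:
    """Welch contrast of young vs old eQTL p-value distributions.

    By default p-values are -log10 transformed (floored at 1e-300) before
    the test, mirroring QQ-plot practice for heavy-tailed p distributions;
    ``transform="raw"`` tests the raw p-values instead.
    """
    p_young = np.asarray(p_young, dtype=float)
    p_old = np.asarray(p_old, dtype=float)
    if transform == "neglog10":
        x = -np.log10(np.maximum(p_young, P_FLOOR))
        y = -np.log10(np.maximum(p_old, P_FLOOR))
    elif transform == "raw":
        # raw p is inversely ordered: small p = strong signal
        x = -p_young
        y = -p_old
    else:
        raise ValueError("transform must be 'neglog10' or 'raw'")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        # degenerate but well-defined cases: identical constants (no
        # evidence) or perfectly separated constants (infinite evidence)
        if x.mean() == y.mean():
            t, dof, p = 0.0, float(len(x) + len(y) - 2), 1.0
        else:
            t = float(np.inf) if x.mean() > y.mean() else float(-np.inf)
            dof, p = float(len(x) + len(y) - 2), 0.0
    else:
        t, dof, p = welch_t(x, y)
    direction = "young_stronger" if x.mean() >= y.mean() else "old_stronger"
    return GroupContrast(
        t_statistic=t,
        dof=dof,
        p=p,
        direction=direction,
        n_genes=len(p_young),
        mean_neglogp_young=float(x.mean()),
        mean_neglogp_old=float(y.mean()),
    )


def tissue_contrast(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    meta: SampleMetadata,
    gene_windows: dict[str, np.ndarray] | None = None,
    covariates: np.ndarray | None = None,
    transform: str = "neglog10",
) -> tuple[pd.DataFrame, GroupContrast]:
    """Full young/old eQTL contrast for one tissue.

    For each gene: pick the lead SNP on the full cohort (restricted to the
    gene's cis window when ``gene_windows`` maps gene_id -> SNP column
    indices), refit within each age group, then Welch-contrast the two
    p-value sets. Requires ``meta.age_group`` labels.
    """
    groups = meta.age_group.to_numpy()
    young_idx = np.flatnonzero(groups == "young")
    old_idx = np.flatnonzero(groups == "old")
    if len(young_idx) < 3 or len(old_idx) < 3:
        raise ValueError("each age group needs at least 3 samples")
    rows = []
    for gi, gene in enumerate(expr.gene_ids):
        window = (
            geno.subset_snps(gene_windows[gene]) if gene_windows is not None else geno
        )
        y = expr.values[gi]
        snp = lead_snp_scan(y, window, covariates)
        d = geno.dosages[:, geno.snp_ids.index(snp)]
        fits = {}
        for label, idx in (("young", young_idx), ("old", old_idx)):
            cov_g = covariates[idx] if covariates is not None else None
            fits[label] = eqtl_fit(y[idx], d[idx], cov_g, gene, snp, label)
        rows.append(
            {
                "gene_id": gene,
                "snp_id": snp,
                "slope_young": fits["young"].slope,
                "p_young": fits["young"].p,
                "slope_old": fits["old"].slope,
                "p_old": fits["old"].p,
            }
        )
    table = pd.DataFrame(rows)
    contrast = compare_pvalue_distributions(
        table["p_young"].to_numpy(), table["p_old"].to_numpy(), transform=transform
    )
    return table, contrast
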