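"""Transcriptome heterogeneity: Jensen-Shannon divergence and
age-heteroskedasticity.

Each sample's non-negative expression profile is normalized to a
probability distribution; pairwise dissimilarity between individuals is
the Jensen-Shannon divergence (base-2, so JSD is in [0, 1] bits) and its
square root, which is a true metric. Cohort-level age trends are
summarized two ways: a two-bin contrast (mean old minus mean young
within-group sqrt-JSD) and a six-bin slope (within-bin pairwise sqrt-JSD
regressed on the pair's mean age over decadal bins 20-80).

Per-gene age-dependence of residual variance is tested with a
Breusch-Pagan-style regression: residuals from the mean-trend fit are
squared, scaled by their mean, and regressed on standardized age; the
slope beta_het and its two-sided t-test p-value are reported, with
Benjamini-Hochberg adjustment across genes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, SampleMetadata

__all__ = [
    "shannon_entropy",
    "jsd",
    "pairwise_jsd",
    "jsd_group_contrast",
    "jsd_age_slope",
    "heteroskedasticity_test",
    "heteroskedasticity_scan",
    "bh_fdr",
    "JsdResult",
    "HetTestResult",
]

logger = logging.getLogger(__name__)

AGE_BINS = [(20, 30), (30, 40), (40, 50), (50, 60), (60, 70), (70, 80)]


@dataclass
class JsdResult:
    sample_a: str
    sample_b: str
    jsd: float
    sqrt_jsd: float
    bin_label: str = ""
    mean_age: float = float("nan")


@dataclass
class HetTestResult:
    gene_id: str
    beta_het: float
    se: float
    p: float
    q: float = float("nan")
    degenerate: bool = False


def _as_distribution(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty distribution")
    if (p < 0).any():
        raise ValueError("distribution entries must be non-negative")
    s = p.sum()
    if s <= 0:
        raise ValueError("distribution must have positive mass")
    if abs(s - 1) > 1e-12:
        raise ValueError("distribution must sum to 1")
    return p


def shannon_entropy(p: np.ndarray) -> float:
    """Shannon entropy in bits, with the 0*log2(0) = 0 convention."""
    p = _as_distribution(p)
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def jsd(p1: np.ndarray, p2: np.ndarray) -> tuple[float, float]:
    """Jensen-Shannon divergence in bits and its square root.

    JSD(P1, P2) = H(M) - (H(P1) + H(P2)) / 2 with M the equal mixture;
    symmetric, zero iff P1 = P2, and exactly 1 for disjoint supports.
    """
    p1 = _as_distribution(p1)
    p2 = _as_distribution(p2)
    if p1.shape != p2.shape:
        raise ValueError("distributions must share support length")
    m = 0.5 * (p1 + p2)
    d = shannon_entropy(m) - 0.5 * (shannon_entropy(p1) + shannon_entropy(p2))
    d = float(np.clip(d, 0.0, 1.0))  # clip tiny negative rounding
    return d, float(np.sqrt(d))


def _profiles(expr: ExpressionMatrix, sample_ids: list[str]) -> dict[str, np.ndarray]:
    """Normalize each sample's profile to sum 1, dropping all-zero samples."""
    out = {}
    for s in sample_ids:
        v = expr.values[:, expr.sample_ids.index(s)]
        if (v < 0).any():
            raise ValueError("JSD requires non-negative expression")
        tot = v.sum()
        if tot <= 0:
            logger.warning("sample %s has all-zero expression; excluded", s)
            continue
        out[s] = v / tot
    return out


def pairwise_jsd(
    expr: ExpressionMatrix,
    sample_ids: list[str] | None = None,
    bin_label: str = "",
    ages: dict[str, float] | None = None,
) -> list[JsdResult]:
    """sqrt-JSD for every unordered sample pair."""
    if sample_ids is None:
        sample_ids = list(expr.sample_ids)
    profiles = _profiles(expr, sample_ids)
    ids = list(profiles)
    if len(ids) < 2:
        raise ValueError("need at least 2 usable samples")
    results = []
    for a, b in itertools.combinations(ids, 2):
        d, sd = jsd(profiles[a], profiles[b])
        mean_age = (
            0.5 * (ages[a] + ages[b]) if ages is not None else float("nan")
        )
        results.append(JsdResult(a, b, d, sd, bin_label, mean_age))
    return results


def jsd_group_contrast(
    expr: ExpressionMatrix,
    meta: SampleMetadata,
) -> dict[str, float]:
    """Two-bin heterogeneity contrast: mean(old sqrt-JSD) - mean(young).

    Positive values mean old individuals' transcriptomes are more
    dissimilar to each other than young individuals' are.
    """
    groups = meta.age_group
    out = {}
    for label in ("young", "old"):
        ids = [s for s, g in zip(meta.sample_ids, groups) if g == label]
        if len(ids) < 2:
            raise ValueError(f"group {label!r} needs at least 2 samples")
        res = pairwise_jsd(expr, ids, bin_label=label)
        out[f"mean_sqrt_jsd_{label}"] = float(np.mean([r.sqrt_jsd for r in res]))
    out["contrast"] = out["mean_sqrt_jsd_old"] - out["mean_sqrt_jsd_young"]
    return out


def jsd_age_slope(
    expr: ExpressionMatrix,
    meta: SampleMetadata,
    bins: list[tuple[float, float]] | None = None,
) -> dict[str, float]:
    """Six-bin JSD-vs-age slope.

    Samples are binned by decade ([20,30) ... [70,80], last bin closed;
    samples outside are dropped with a warning); within each bin all
    pairwise sqrt-JSD values are computed and regressed on the pair's mean
    age by OLS. Returns slope, 95% CI, and two-sided p.
    """
    if bins is None:
        bins = AGE_BINS
    ages = dict(zip(meta.sample_ids, meta.age))
    xs, ys = [], []
    n_used_bins = 0
    last_hi = max(hi for _, hi in bins)
    for lo, hi in bins:
        ids = [
            s
            for s, a in ages.items()
            if (lo <= a < hi) or (hi == last_hi and a == hi)
        ]
        if len(ids) < 2:
            continue
        n_used_bins += 1
        for r in pairwise_jsd(expr, ids, bin_label=f"[{lo},{hi})", ages=ages):
            xs.append(r.mean_age)
            ys.append(r.sqrt_jsd)
    dropped = sum(
        1 for a in ages.values() if not (bins[0][0] <= a <= last_hi)
    )
    if dropped:
        logger.warning("%d samples outside the age-bin range dropped", dropped)
    if n_used_bins < 2:
        raise ValueError("need at least 2 bins with >= 2 samples")
    res = stats.linregress(xs, ys)
    # 95% CI from the slope's standard error
    dof = len(xs) - 2
    tcrit = stats.t.ppf(0.975, df=dof)
    return {
        "slope": float(res.slope),
        "ci_low": float(res.slope - tcrit * res.stderr),
        "ci_high": float(res.slope + tcrit * res.stderr),
        "p": float(res.pvalue),
        "n_pairs": len(xs),
        "n_bins": n_used_bins,
    }


def heteroskedasticity_test(
    expr_gene: np.ndarray,
    meta: SampleMetadata,
    covariates: np.ndarray | None = None,
    transform: str | None = None,
    gene_id: str = "gene",
) -> HetTestResult:
    """Breusch-Pagan-style test for age-dependent residual variance.

    Expression is regressed on intercept + age + covariates; the squared
    residuals, divided by their mean, are regressed on standardized age.
    The slope is beta_het (positive = variance grows with age); its
    two-sided t-test p-value is returned. ``transform="invlogit_ready"``
    applies a logit to proportion-valued inputs (cell-type compositions)
    before testing, mapping them to an approximately Gaussian scale.
    """
    y = np.asarray(expr_gene, dtype=float)
    if transform == "invlogit_ready":
        eps = 1e-6
        y = np.clip(y, eps, 1 - eps)
        y = np.log(y / (1 - y))
    elif transform is not None:
        raise ValueError("transform must be None or 'invlogit_ready'")
    n = len(y)
    age = meta.age
    cov = (
        np.asarray(covariates, dtype=float).reshape(n, -1)
        if covariates is not None and np.size(covariates)
        else np.empty((n, 0))
    )
    X = np.column_stack([np.ones(n), age, cov])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    if np.allclose(resid, 0, atol=1e-10):
        return HetTestResult(gene_id, 0.0, np.nan, 1.0, degenerate=True)
    u = resid**2
    u = u / u.mean()
    a_std = meta.standardized_age()
    res = stats.linregress(a_std, u)
    return HetTestResult(
        gene_id,
        beta_het=float(res.slope),
        se=float(res.stderr),
        p=float(res.pvalue),
    )


def heteroskedasticity_scan(
    expr: ExpressionMatrix,
    meta: SampleMetadata,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Run the per-gene test across a matrix and BH-adjust the p-values."""
    results = [
        heteroskedasticity_test(expr.values[i], meta, covariates, gene_id=g)
        for i, g in enumerate(expr.gene_ids)
    ]
    p = np.array([r.p for r in results])
    q = bh_fdr(p)
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "beta_het": [r.beta_het for r in results],
            "p": p,
            "q": q,
            "degenerate": [r.degenerate for r in results],
        }
    ).set_index("gene_id")


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
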