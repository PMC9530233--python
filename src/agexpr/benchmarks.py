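"""Self-validation benchmarks: parameter recovery, calibration and
oracle-equivalence measurements computed by running the package on
synthetic cohorts with known ground truth.

Each function simulates its own inputs from a seed, runs the relevant
pipeline operations, and returns summary metrics. These back both the
acceptance test suite and ``scripts/acceptance.py``; problem sizes are
chosen so the full set runs in minutes on one CPU (see docs/methods.md).
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.spatial.distance import jensenshannon

from .containers import GeneArchitecture, TruthTable
from .downstream import constraint_regression, specificity_score
from .eqtl import compare_pvalue_distributions, eqtl_fit, lead_snp_scan
from .heterogeneity import bh_fdr, heteroskedasticity_scan, jsd
from .joint import (
    DesignMatrix,
    age_group_h2_contrast,
    elastic_net_fit,
    fit_tissue,
)
from .preprocess import downsample_balance, split_age_groups
from .simulate import (
    default_architectures,
    simulate_cohort,
    simulate_constraint,
    simulate_expression,
    simulate_genotypes,
    simulate_tissue,
)

__all__ = [
    "variance_partition_recovery",
    "jsd_correctness",
    "specificity_correctness",
    "heteroskedasticity_calibration",
    "eqtl_contrast_benchmark",
    "medawar_recovery",
    "elastic_net_correctness",
    "bh_fdr_correctness",
    "model_consistency",
]


def _grid_architectures(n_genes: int, seed: int) -> list[GeneArchitecture]:
    """Gene panel over the (h2, r2_age) grid {0, 0.1, 0.3}^2, cycled."""
    rng = np.random.default_rng(seed)
    grid = list(itertools.product([0.0, 0.1, 0.3], repeat=2))
    archs = []
    for i in range(n_genes):
        h2, r2a = grid[i % len(grid)]
        archs.append(
            GeneArchitecture(
                gene_id=f"gene_{i:04d}",
                n_causal_snps=3,
                h2_true=h2,
                r2_age_true=r2a,
                beta_age_sign=int(rng.choice([-1, 1])) if r2a > 0 else 0,
            )
        )
    return archs


def variance_partition_recovery(
    seed: int, n_samples: int = 600, n_genes: int = 200, n_snps_per_gene: int = 20
) -> dict[str, float]:
    """Joint-model recovery of (h2, R2_age) over the {0, 0.1, 0.3}^2 grid.

    Returns Pearson r and mean absolute error between estimated and true
    components across genes.
    """
    archs = _grid_architectures(n_genes, seed)
    sim = simulate_tissue(
        n_samples=n_samples,
        architectures=archs,
        n_snps_per_gene=n_snps_per_gene,
        seed=seed,
    )
    fits, _ = fit_tissue(
        sim.expr, sim.geno, sim.meta, sim.gene_tss, sim.gene_windows, seed=seed
    )
    true_h2 = np.array([a.h2_true for a in archs])
    true_r2a = np.array([a.r2_age_true for a in archs])
    est_h2 = fits["h2"].to_numpy()
    est_r2a = fits["r2_age"].to_numpy()
    return {
        "h2_pearson_r": float(np.corrcoef(true_h2, est_h2)[0, 1]),
        "h2_mae": float(np.abs(true_h2 - est_h2).mean()),
        "r2_age_pearson_r": float(np.corrcoef(true_r2a, est_r2a)[0, 1]),
        "r2_age_mae": float(np.abs(true_r2a - est_r2a).mean()),
        "n_genes": n_genes,
        "n_samples": n_samples,
    }


def jsd_correctness(seed: int, n_pairs: int = 1000, n_triples: int = 1000) -> dict:
    """JSD oracle equivalence and metric properties.

    Compares the package's JSD against scipy's independent implementation
    (``jensenshannon`` returns sqrt-JSD in the chosen base) on random
    distribution pairs, counts sqrt-JSD triangle-inequality violations on
    random triples, and checks the identity and disjoint-support cases.
    """
    rng = np.random.default_rng(seed)

    def rand_dist(k):
        p = rng.random(k)
        return p / p.sum()

    max_dev = 0.0
    for _ in range(n_pairs):
        k = int(rng.integers(2, 50))
        p, q = rand_dist(k), rand_dist(k)
        d, _ = jsd(p, q)
        max_dev = max(max_dev, abs(d - jensenshannon(p, q, base=2) ** 2))
    violations = 0
    for _ in range(n_triples):
        k = int(rng.integers(2, 20))
        a, b, c = rand_dist(k), rand_dist(k), rand_dist(k)
        if jsd(a, c)[1] > jsd(a, b)[1] + jsd(b, c)[1] + 1e-12:
            violations += 1
    p = rand_dist(10)
    identity_jsd = jsd(p, p)[0]
    disjoint_jsd = jsd(np.array([1.0, 0.0]), np.array([0.0, 1.0]))[0]
    return {
        "max_abs_deviation": float(max_dev),
        "triangle_violations": violations,
        "identity_jsd": float(identity_jsd),
        "disjoint_jsd": float(disjoint_jsd),
        "n_pairs": n_pairs,
    }


def specificity_correctness(seed: int, n_profiles: int = 1000) -> dict:
    """Specificity-score agreement with direct formula evaluation."""
    rng = np.random.default_rng(seed)
    max_dev = 0.0
    for _ in range(n_profiles):
        n = int(rng.integers(2, 30))
        r2 = rng.uniform(0, 0.5, size=n)
        r2[rng.integers(n)] = rng.uniform(0.1, 0.5)  # ensure a nonzero max
        s = specificity_score(r2).s_g
        direct = float((1 - r2 / r2.max()).sum() / (n - 1))
        max_dev = max(max_dev, abs(s - direct))
    const = specificity_score(np.full(5, 0.2)).s_g
    single = specificity_score(np.array([0.4, 0.0, 0.0])).s_g
    return {
        "max_abs_deviation": float(max_dev),
        "constant_profile_score": float(const),
        "single_tissue_score": float(single),
        "n_profiles": n_profiles,
    }


def heteroskedasticity_calibration(
    seed: int,
    n_null: int = 2000,
    n_null_samples: int = 300,
    n_power: int = 200,
    n_power_samples: int = 600,
    het_slope: float = 1.0,
) -> dict:
    """Type-I error and power of the age-heteroskedasticity test.

    Null: homoskedastic genes with an age mean-trend (r2_age = 0.2) at
    n = 300; rejection rate at alpha = 0.05 should match 0.05. Power:
    genes with het_slope = 1 at n = 600.
    """
    rng = np.random.default_rng(seed)
    meta_null = simulate_cohort(n_null_samples, seed=int(rng.integers(2**31)))
    geno_null = simulate_genotypes(n_null_samples, 2, seed=int(rng.integers(2**31)))
    archs = default_architectures(
        n_null, h2=0.0, r2_age=0.2, het_slope=0.0, n_causal_snps=0,
        seed=int(rng.integers(2**31)),
    )
    expr, _ = simulate_expression(
        geno_null, meta_null, archs, seed=int(rng.integers(2**31))
    )
    scan = heteroskedasticity_scan(expr, meta_null)
    type1 = float((scan["p"] < 0.05).mean())

    meta_pow = simulate_cohort(n_power_samples, seed=int(rng.integers(2**31)))
    geno_pow = simulate_genotypes(n_power_samples, 2, seed=int(rng.integers(2**31)))
    archs_pow = default_architectures(
        n_power, h2=0.0, r2_age=0.2, het_slope=het_slope, n_causal_snps=0,
        seed=int(rng.integers(2**31)),
    )
    expr_pow, _ = simulate_expression(
        geno_pow, meta_pow, archs_pow, seed=int(rng.integers(2**31))
    )
    scan_pow = heteroskedasticity_scan(expr_pow, meta_pow)
    power = float(((scan_pow["p"] < 0.05) & (scan_pow["beta_het"] > 0)).mean())
    return {
        "type1_rate": type1,
        "type1_se": float(np.sqrt(0.05 * 0.95 / n_null)),
        "power": power,
        "n_null": n_null,
        "n_power": n_power,
    }


def _one_eqtl_tissue(
    rng: np.random.Generator,
    n_per_group: int,
    n_genes: int,
    h2_young: float,
    old_slope_factor: float,
    n_snps: int = 10,
):
    """Simulate one tissue where the genetic slope changes in old samples,
    then run the lead-SNP scan and per-group fits."""
    n = 2 * n_per_group
    meta = simulate_cohort(n, seed=int(rng.integers(2**31)))
    meta = split_age_groups(meta, np.median(meta.age))
    groups = meta.age_group.to_numpy()
    young = groups == "young"
    old = ~young
    a_is_old = old.astype(float)
    p_young_list, p_old_list = [], []
    for _ in range(n_genes):
        geno = simulate_genotypes(n, n_snps, seed=int(rng.integers(2**31)))
        causal = int(rng.integers(n_snps))
        x = geno.dosages[:, causal]
        xc = x - x.mean()
        if h2_young > 0 and xc.std() > 0:
            slope = np.sqrt(h2_young / (1 - h2_young)) / xc.std()
        else:
            slope = 0.0
        per_sample_slope = slope * (1 - (1 - old_slope_factor) * a_is_old)
        y = per_sample_slope * xc + rng.standard_normal(n)
        lead = lead_snp_scan(y, geno)
        d = geno.dosages[:, geno.snp_ids.index(lead)]
        p_young_list.append(eqtl_fit(y[young], d[young]).p)
        p_old_list.append(eqtl_fit(y[old], d[old]).p)
    return compare_pvalue_distributions(
        np.array(p_young_list), np.array(p_old_list)
    )


def eqtl_contrast_benchmark(
    seed: int,
    n_reps: int = 50,
    n_null_tissues: int = 200,
    n_per_group: int = 300,
    n_genes: int = 200,
    n_null_genes: int = 60,
) -> dict:
    """Power and null calibration of the young/old eQTL contrast.

    Power: genetic slopes halved in the old group (h2_young = 0.2); the
    Welch contrast should be significant with direction young_stronger.
    Null: no age effect on genetics; direction should be young_stronger
    in about half of simulated tissues.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        c = _one_eqtl_tissue(rng, n_per_group, n_genes, 0.2, 0.5)
        hits += (c.direction == "young_stronger") and (c.p < 0.05)
    power = hits / n_reps

    young_count = 0
    for _ in range(n_null_tissues):
        c = _one_eqtl_tissue(rng, 100, n_null_genes, 0.1, 1.0)
        young_count += c.direction == "young_stronger"
    return {
        "power": float(power),
        "null_young_fraction": young_count / n_null_tissues,
        "null_se": float(np.sqrt(0.25 / n_null_tissues)),
        "n_reps": n_reps,
        "n_null_tissues": n_null_tissues,
    }


def _beta_age_truth(rng: np.random.Generator, n_genes: int) -> TruthTable:
    """Minimal truth table with a continuous beta_age spectrum."""
    genes = [f"gene_{i:04d}" for i in range(n_genes)]
    beta = rng.normal(0, 0.3, size=n_genes)
    archs = {g: GeneArchitecture(gene_id=g) for g in genes}
    zero = {g: 0.0 for g in genes}
    return TruthTable(
        architectures=archs,
        causal_snps={g: [] for g in genes},
        causal_betas={g: np.empty(0) for g in genes},
        beta_age=dict(zip(genes, beta)),
        beta_agesex=dict(zero),
        realized_h2=dict(zero),
        realized_r2_age={g: 0.1 for g in genes},
        realized_r2_agesex=dict(zero),
    )


def medawar_recovery(seed: int, n_reps: int = 50, n_genes: int = 1000) -> dict:
    """Classification accuracy of the constraint (Medawar) regression.

    Constraint simulated at rank correlation -0.5 / +0.5 / 0 to the
    generative age slopes; the regression should classify Medawarian /
    non-Medawarian / not-significant respectively.
    """
    rng = np.random.default_rng(seed)
    match_neg = match_pos = null_ns = 0
    for _ in range(n_reps):
        truth = _beta_age_truth(rng, n_genes)
        df = truth.to_frame().reset_index()
        df = df.rename(columns={"realized_r2_age": "r2_age"})
        for rho, bucket in ((-0.5, "neg"), (0.5, "pos"), (0.0, "null")):
            constraint = simulate_constraint(truth, rho, seed=int(rng.integers(2**31)))
            merged = df.merge(constraint.reset_index(), on="gene_id")
            merged["pLI"] = merged["pLI"].astype(float)
            reg = constraint_regression(merged)
            if bucket == "neg":
                match_neg += reg.classification == "Medawarian"
            elif bucket == "pos":
                match_pos += reg.classification == "non-Medawarian"
            else:
                null_ns += reg.classification == "not-significant"
    return {
        "medawarian_match_rate": match_neg / n_reps,
        "non_medawarian_match_rate": match_pos / n_reps,
        "null_not_significant_rate": null_ns / n_reps,
        "n_reps": n_reps,
        "n_genes": n_genes,
    }


def elastic_net_correctness(seed: int) -> dict:
    """Closed-form checks of the penalized fit.

    On an orthonormal centered design the elastic-net solution is the
    soft-thresholded, ridge-shrunken OLS estimate per predictor; in the
    lambda -> 0 limit it matches OLS on a well-conditioned problem.
    """
    rng = np.random.default_rng(seed)
    n, p, lam, alpha = 400, 6, 0.1, 0.5
    raw = rng.normal(size=(n, p))
    raw -= raw.mean(axis=0)
    q, _ = np.linalg.qr(raw)
    X = q * np.sqrt(n)
    beta = np.array([0.9, -0.4, 0.2, 0.04, 0.0, -1.1])
    y = X @ beta + 0.3 * rng.normal(size=n)
    y -= y.mean()
    design = DesignMatrix(X, ["genetic"] * p, [f"s{i}" for i in range(p)])
    fit = elastic_net_fit(design, y, alpha=alpha, lambda_=lam)
    ols = X.T @ y / n
    closed = np.sign(ols) * np.maximum(np.abs(ols) - lam * alpha, 0)
    closed /= 1 + lam * (1 - alpha)
    ortho_dev = float(np.abs(fit.beta_snps - closed).max())

    X2 = rng.normal(size=(300, 5))
    y2 = X2 @ np.array([1.0, -2.0, 0.5, 0.0, 3.0]) + 0.2 * rng.normal(size=300)
    design2 = DesignMatrix(X2, ["genetic"] * 5, [f"t{i}" for i in range(5)])
    fit2 = elastic_net_fit(design2, y2, lambda_=1e-12)
    ols2 = np.linalg.lstsq(np.column_stack([np.ones(300), X2]), y2, rcond=None)[0][1:]
    ols_dev = float(np.abs(fit2.beta_snps - ols2).max())
    return {"orthonormal_max_dev": ortho_dev, "ols_limit_max_dev": ols_dev}


def bh_fdr_correctness(seed: int, n_vectors: int = 1000) -> dict:
    """BH step-up vs its brute-force definition on random p-vectors."""
    rng = np.random.default_rng(seed)

    def brute(p):
        m = len(p)
        order = np.argsort(p, kind="stable")
        q = np.empty(m)
        prev = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            prev = min(prev, p[i] * m / rank)
            q[i] = prev
        return q

    max_dev = 0.0
    for _ in range(n_vectors):
        m = int(rng.integers(1, 60))
        p = rng.uniform(1e-8, 1, size=m)
        max_dev = max(max_dev, float(np.abs(bh_fdr(p) - brute(p)).max()))
    return {"max_abs_deviation": max_dev, "n_vectors": n_vectors}


def model_consistency(
    seed: int, n_samples: int = 600, n_genes: int = 200, n_snps_per_gene: int = 12
) -> dict:
    """Internal consistency of the joint model.

    (a) Per-gene h2 from the joint model vs the mean of the two
    age-group genetics-only fits on a shared cohort; (b) R2_age with vs
    without the age-by-sex interaction term when no interaction was
    simulated.
    """
    archs = _grid_architectures(n_genes, seed)
    sim = simulate_tissue(
        n_samples=n_samples,
        architectures=archs,
        n_snps_per_gene=n_snps_per_gene,
        seed=seed,
    )
    fits, _ = fit_tissue(
        sim.expr, sim.geno, sim.meta, sim.gene_tss, sim.gene_windows, seed=seed
    )
    meta = split_age_groups(sim.meta, 50.0)
    meta_bal = downsample_balance(meta, seed=seed)
    expr_bal = sim.expr.subset_samples(meta_bal.sample_ids)
    geno_bal = sim.geno.subset_samples(meta_bal.sample_ids)
    group = age_group_h2_contrast(
        expr_bal, geno_bal, meta_bal, sim.gene_tss, sim.gene_windows, seed=seed
    )
    group_mean_h2 = 0.5 * (group["h2_young"] + group["h2_old"])
    r_h2 = float(np.corrcoef(fits["h2"], group_mean_h2.loc[fits.index])[0, 1])

    fits_inter, _ = fit_tissue(
        sim.expr,
        sim.geno,
        sim.meta,
        sim.gene_tss,
        sim.gene_windows,
        config={"include_interaction": True},
        seed=seed,
    )
    r_r2age = float(np.corrcoef(fits["r2_age"], fits_inter["r2_age"])[0, 1])
    return {
        "h2_joint_vs_group_r": r_h2,
        "r2_age_with_without_interaction_r": r_r2age,
        "n_genes": n_genes,
        "n_samples": n_samples,
    }
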