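"""End-to-end orchestration: config, seed management, stage outputs.

A run is driven by a YAML/dict config describing either a synthetic
cohort block or paths to on-disk inputs, plus the analysis parameters
(age cutoff, elastic-net settings, filter thresholds). Every stochastic
stage receives a seed derived deterministically from the master seed by
hashing the stage name, so identical configs produce byte-identical
outputs. Outputs land in a run directory with a manifest recording the
config, derived seeds and package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import SampleMetadata
from .downstream import constraint_regression, specificity_score
from .eqtl import tissue_contrast
from .heterogeneity import heteroskedasticity_scan, jsd_age_slope, jsd_group_contrast
from .io import read_expression, read_metadata, read_vcf, write_fixture_set
from .joint import age_group_h2_contrast, fit_tissue
from .preprocess import downsample_balance, filter_snps, split_age_groups
from .simulate import simulate_tissue

__all__ = ["default_config", "validate_config", "derive_seed", "run_pipeline", "report"]

logger = logging.getLogger(__name__)


def default_config() -> dict:
    return {
        "seed": 0,
        "age_cutoff": 55.0,
        "alpha": 0.5,
        "cv_folds": 10,
        "window_bp": 1_000_000,
        "k_factors": 15,
        "maf_min": 0.05,
        "hwe_p_min": 0.05,
        "fdr": 0.05,
        "constraint_p_threshold": 1e-3,
        "synthetic": {
            "n_samples": 600,
            "n_genes": 200,
            "n_snps_per_gene": 20,
            "h2": None,
            "r2_age": None,
            "het_slope": 0.0,
            "constraint_correlation": -0.5,
        },
        "inputs": None,  # or {vcf, expression, metadata}
    }


def validate_config(config: dict) -> dict:
    """Merge with defaults and check basic schema constraints."""
    cfg = default_config()
    for k, v in (config or {}).items():
        if k == "synthetic" and v is not None:
            cfg["synthetic"] = {**cfg["synthetic"], **v}
        else:
            cfg[k] = v
    if cfg.get("inputs") is None and cfg.get("synthetic") is None:
        raise ValueError("config needs either an 'inputs' or a 'synthetic' block")
    if cfg["inputs"] is not None:
        missing = {"vcf", "expression", "metadata"} - set(cfg["inputs"])
        if missing:
            raise ValueError(f"inputs block missing paths: {sorted(missing)}")
    if not 0 < cfg["alpha"] <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if cfg["cv_folds"] < 2:
        raise ValueError("cv_folds must be >= 2")
    return cfg


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})


def run_pipeline(config: dict, out_dir: str | Path) -> Path:
    """Execute all stages in order and write results plus a manifest.

    Stages: synthesize/ingest -> SNP filter + age groups -> eQTL young/old
    contrast -> JSD heterogeneity -> per-gene heteroskedasticity -> joint
    model -> constraint regression. Partial outputs are left in place if a
    stage raises.
    """
    cfg = validate_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {
        "version": __version__,
        "config": _jsonable(cfg),
        "seeds": {},
        "stages_completed": [],
    }

    def _save_manifest() -> None:
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)

    try:
        # --- stage: data ---------------------------------------------------
        if cfg["inputs"] is not None:
            geno = read_vcf(cfg["inputs"]["vcf"])
            expr = read_expression(cfg["inputs"]["expression"])
            meta = read_metadata(cfg["inputs"]["metadata"])
            gene_tss = {g: 0 for g in expr.gene_ids}
            gene_windows = None
            truth = constraint = None
        else:
            s = cfg["synthetic"]
            sim_seed = derive_seed(seed, "simulate")
            manifest["seeds"]["simulate"] = sim_seed
            from .containers import GeneArchitecture
            from .simulate import default_architectures

            if s["h2"] is None and s["r2_age"] is None:
                archs = None
            else:
                archs = default_architectures(
                    s["n_genes"],
                    h2=s["h2"] or 0.0,
                    r2_age=s["r2_age"] or 0.0,
                    het_slope=s["het_slope"],
                    seed=sim_seed,
                )
            sim = simulate_tissue(
                n_samples=s["n_samples"],
                architectures=archs,
                n_genes=s["n_genes"],
                n_snps_per_gene=s["n_snps_per_gene"],
                seed=sim_seed,
                constraint_correlation=s["constraint_correlation"],
            )
            geno, expr, meta = sim.geno, sim.expr, sim.meta
            truth, constraint = sim.truth, sim.constraint
            gene_tss, gene_windows = sim.gene_tss, sim.gene_windows
            write_fixture_set(geno, expr, meta, truth, out_dir / "data")
            if constraint is not None:
                constraint.to_csv(out_dir / "data" / "constraint.tsv", sep="\t")
        manifest["stages_completed"].append("data")
        _save_manifest()

        # --- stage: preprocess ---------------------------------------------
        window_snp_ids = (
            {g: [geno.snp_ids[j] for j in win] for g, win in gene_windows.items()}
            if gene_windows is not None
            else None
        )
        geno = filter_snps(geno, cfg["maf_min"], cfg["hwe_p_min"])
        if window_snp_ids is not None:
            # re-map windows onto the filtered SNP set
            kept = {s_id: i for i, s_id in enumerate(geno.snp_ids)}
            gene_windows = {
                g: np.array([kept[s] for s in ids if s in kept], dtype=int)
                for g, ids in window_snp_ids.items()
            }
        meta = split_age_groups(meta, cfg["age_cutoff"])
        balance_seed = derive_seed(seed, "downsample")
        manifest["seeds"]["downsample"] = balance_seed
        meta_bal = downsample_balance(meta, seed=balance_seed)
        expr_bal = expr.subset_samples(meta_bal.sample_ids)
        geno_bal = geno.subset_samples(meta_bal.sample_ids)
        manifest["stages_completed"].append("preprocess")
        _save_manifest()

        # --- stage: eqtl contrast -------------------------------------------
        eqtl_table, contrast = tissue_contrast(
            expr_bal, geno_bal, meta_bal, gene_windows=gene_windows
        )
        eqtl_table.to_csv(out_dir / "eqtl_contrast.tsv", sep="\t", index=False)
        with open(out_dir / "eqtl_contrast.json", "w") as fh:
            json.dump(
                {
                    "t": contrast.t_statistic,
                    "dof": contrast.dof,
                    "p": contrast.p,
                    "direction": contrast.direction,
                    "n_genes": contrast.n_genes,
                },
                fh,
                indent=1,
            )
        manifest["stages_completed"].append("eqtl")
        _save_manifest()

        # --- stage: heterogeneity -------------------------------------------
        # JSD operates on non-negative profiles; shift synthetic normalized
        # expression into abundance space via exp
        from .containers import ExpressionMatrix

        abund = ExpressionMatrix(
            np.exp(expr_bal.values),
            list(expr_bal.gene_ids),
            list(expr_bal.sample_ids),
            scale="tpm",
        )
        jsd2 = jsd_group_contrast(abund, meta_bal)
        jsd6 = jsd_age_slope(abund, meta_bal)
        with open(out_dir / "jsd.json", "w") as fh:
            json.dump({"two_bin": jsd2, "six_bin": jsd6}, fh, indent=1)
        het = heteroskedasticity_scan(expr_bal, meta_bal)
        het.to_csv(out_dir / "heteroskedasticity.tsv", sep="\t")
        manifest["stages_completed"].append("heterogeneity")
        _save_manifest()

        # --- stage: joint model ---------------------------------------------
        fit_seed = derive_seed(seed, "joint_model")
        manifest["seeds"]["joint_model"] = fit_seed
        joint_cfg = {
            "alpha": cfg["alpha"],
            "cv_folds": cfg["cv_folds"],
            "window_bp": cfg["window_bp"],
        }
        fits, summary = fit_tissue(
            expr, geno, meta, gene_tss, gene_windows, joint_cfg, seed=fit_seed
        )
        fits.to_csv(out_dir / "joint_fits.tsv", sep="\t")
        group_h2 = age_group_h2_contrast(
            expr_bal, geno_bal, meta_bal, gene_tss, gene_windows, joint_cfg,
            seed=fit_seed,
        )
        group_h2.to_csv(out_dir / "group_h2.tsv", sep="\t")
        summary["mean_h2_diff_young_minus_old"] = float(group_h2["h2_diff"].mean())
        with open(out_dir / "joint_summary.json", "w") as fh:
            json.dump(summary, fh, indent=1)
        manifest["stages_completed"].append("joint_model")
        _save_manifest()

        # --- stage: downstream ----------------------------------------------
        downstream_out: dict = {}
        if constraint is not None:
            per_gene = fits.join(constraint[["pLI"]], how="inner")
            reg = constraint_regression(
                per_gene.reset_index(),
                p_threshold=cfg["constraint_p_threshold"],
            )
            downstream_out["constraint"] = {
                "slope": reg.slope,
                "se": reg.se,
                "p": reg.p,
                "classification": reg.classification,
                "n_genes": reg.n_genes,
            }
        if truth is not None:
            tf = truth.to_frame()
            merged = fits.join(tf, how="inner", rsuffix="_true")
            downstream_out["recovery"] = {
                "h2_pearson_r": _safe_corr(merged["h2"], merged["realized_h2"]),
                "r2_age_pearson_r": _safe_corr(
                    merged["r2_age"], merged["realized_r2_age"]
                ),
            }
        with open(out_dir / "downstream.json", "w") as fh:
            json.dump(downstream_out, fh, indent=1)
        manifest["stages_completed"].append("downstream")
        manifest["status"] = "complete"
        _save_manifest()
    except Exception:
        manifest["status"] = "failed"
        _save_manifest()
        raise
    return out_dir


def _safe_corr(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj


def report(run_dir: str | Path) -> dict:
    """Summarize a completed run from its output files."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError("run directory has no manifest.json")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    if manifest.get("status") != "complete":
        raise RuntimeError(
            f"run status is {manifest.get('status')!r}; refusing to summarize"
        )
    out = {"version": manifest["version"], "stages": manifest["stages_completed"]}
    for name in ("eqtl_contrast", "jsd", "joint_summary", "downstream"):
        path = run_dir / f"{name}.json"
        if path.exists():
            with open(path) as fh:
                out[name] = json.load(fh)
    lines = [f"# Run summary (agexpr {out['version']})", ""]
    if "joint_summary" in out:
        js = out["joint_summary"]
        lines.append(
            f"- mean h2 = {js['mean_h2']:.4f} (SE {js['se_h2']:.4f}); "
            f"mean R2_age = {js['mean_r2_age']:.4f} (SE {js['se_r2_age']:.4f})"
        )
    if "eqtl_contrast" in out:
        ec = out["eqtl_contrast"]
        lines.append(
            f"- eQTL contrast: direction={ec['direction']}, p={ec['p']:.3g}"
        )
    if "jsd" in out:
        lines.append(
            f"- JSD two-bin contrast = {out['jsd']['two_bin']['contrast']:.5f}; "
            f"six-bin slope = {out['jsd']['six_bin']['slope']:.3g}"
        )
    if "downstream" in out and "constraint" in out["downstream"]:
        c = out["downstream"]["constraint"]
        lines.append(
            f"- constraint regression: slope={c['slope']:.4g}, "
            f"p={c['p']:.3g} -> {c['classification']}"
        )
    with open(run_dir / "report.md", "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return out
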