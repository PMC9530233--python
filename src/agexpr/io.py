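"""Readers and writers for the on-disk exchange formats.

Genotypes travel as VCF 4.2 with a ``DS`` (dosage) FORMAT field, read back
through cyvcf2; expression as a tab-separated genes x samples table (GCT's
two-line header is accepted on read); metadata as TSV keyed by
``sample_id``; the generator's ground truth as JSON keyed by gene id.
``write_fixture_set`` / ``read_fixture_set`` round-trip a full synthetic
cohort losslessly (dosages to 6 decimals).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import (
    ExpressionMatrix,
    GeneArchitecture,
    GenotypeMatrix,
    SampleMetadata,
    TruthTable,
)

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_expression_tsv",
    "read_expression",
    "write_metadata_tsv",
    "read_metadata",
    "write_truth_json",
    "read_truth_json",
    "write_fixture_set",
    "read_fixture_set",
    "read_gmt",
]

_VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID={chrom}>
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternate allele dosage">
"""


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> Path:
    """Write dosages as a plain-text VCF 4.2 with a DS FORMAT field."""
    path = Path(path)
    cols = "\t".join(
        ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        + list(geno.sample_ids)
    )
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(chrom=geno.chrom))
        fh.write(cols + "\n")
        for j in range(geno.n_snps):
            ds = "\t".join(f"{d:.6f}" for d in geno.dosages[:, j])
            fh.write(
                f"{geno.chrom}\t{geno.positions[j]}\t{geno.snp_ids[j]}"
                f"\tA\tG\t.\tPASS\t.\tDS\t{ds}\n"
            )
    return path


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a dosage VCF (DS FORMAT field) into a GenotypeMatrix."""
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    snp_ids, positions, rows = [], [], []
    chrom = "1"
    for var in vcf:
        chrom = var.CHROM
        snp_ids.append(var.ID if var.ID else f"snp_{var.CHROM}_{var.POS}")
        positions.append(var.POS)
        rows.append(np.asarray(var.format("DS"), dtype=float).ravel())
    vcf.close()
    if rows:
        dosages = np.vstack(rows).T
    else:
        dosages = np.empty((len(sample_ids), 0))
    return GenotypeMatrix(
        dosages=dosages,
        snp_ids=snp_ids,
        positions=np.asarray(positions, dtype=int),
        sample_ids=sample_ids,
        chrom=chrom,
    )


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> Path:
    """Write genes x samples expression as TSV; enforces the scale invariant."""
    if expr.scale in ("tpm", "counts") and expr.values.size and expr.values.min() < 0:
        raise ValueError(f"negative values are invalid on the {expr.scale} scale")
    path = Path(path)
    df = pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.sample_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.10g")
    return path


def read_expression(path: str | Path, scale: str = "normalized") -> ExpressionMatrix:
    """Read expression from TSV or GCT (detected by the ``#1.2`` magic)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#1.2"):
        df = pd.read_csv(path, sep="\t", skiprows=2, index_col=0)
        if "Description" in df.columns:
            df = df.drop(columns=["Description"])
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(
        values=df.to_numpy(dtype=float),
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        scale=scale,
    )


def write_metadata_tsv(meta: SampleMetadata, path: str | Path) -> Path:
    path = Path(path)
    out = meta.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")
    return path


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def write_truth_json(truth: TruthTable, path: str | Path) -> Path:
    path = Path(path)
    payload = {}
    for g, arch in truth.architectures.items():
        payload[g] = {
            "architecture": {
                "n_causal_snps": arch.n_causal_snps,
                "h2_true": arch.h2_true,
                "r2_age_true": arch.r2_age_true,
                "r2_agesex_true": arch.r2_agesex_true,
                "beta_age_sign": arch.beta_age_sign,
                "het_slope": arch.het_slope,
                "constraint_true": arch.constraint_true,
            },
            "causal_snps": truth.causal_snps[g],
            "causal_betas": [float(b) for b in truth.causal_betas[g]],
            "beta_age": truth.beta_age[g],
            "beta_agesex": truth.beta_agesex[g],
            "realized_h2": truth.realized_h2[g],
            "realized_r2_age": truth.realized_r2_age[g],
            "realized_r2_agesex": truth.realized_r2_agesex[g],
        }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
    return path


def read_truth_json(path: str | Path) -> TruthTable:
    with open(path) as fh:
        payload = json.load(fh)
    archs, snps, betas = {}, {}, {}
    b_age, b_as, r_h2, r_age, r_as = {}, {}, {}, {}, {}
    for g, rec in payload.items():
        a = rec["architecture"]
        archs[g] = GeneArchitecture(gene_id=g, **a)
        snps[g] = rec["causal_snps"]
        betas[g] = np.asarray(rec["causal_betas"], dtype=float)
        b_age[g] = rec["beta_age"]
        b_as[g] = rec["beta_agesex"]
        r_h2[g] = rec["realized_h2"]
        r_age[g] = rec["realized_r2_age"]
        r_as[g] = rec["realized_r2_agesex"]
    return TruthTable(
        architectures=archs,
        causal_snps=snps,
        causal_betas=betas,
        beta_age=b_age,
        beta_agesex=b_as,
        realized_h2=r_h2,
        realized_r2_age=r_age,
        realized_r2_agesex=r_as,
    )


def write_fixture_set(
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    meta: SampleMetadata,
    truth: TruthTable | None,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write a consistent cohort (VCF + expression TSV + metadata + truth)."""
    if geno.sample_ids != meta.sample_ids or expr.sample_ids != meta.sample_ids:
        raise ValueError("sample ids differ between genotype/expression/metadata")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": write_vcf(geno, out_dir / "genotypes.vcf"),
        "expression": write_expression_tsv(expr, out_dir / "expression.tsv"),
        "metadata": write_metadata_tsv(meta, out_dir / "metadata.tsv"),
    }
    if truth is not None:
        paths["truth"] = write_truth_json(truth, out_dir / "truth.json")
    return paths


def read_fixture_set(
    out_dir: str | Path, scale: str = "normalized"
) -> tuple[GenotypeMatrix, ExpressionMatrix, SampleMetadata, TruthTable | None]:
    out_dir = Path(out_dir)
    geno = read_vcf(out_dir / "genotypes.vcf")
    expr = read_expression(out_dir / "expression.tsv", scale=scale)
    meta = read_metadata(out_dir / "metadata.tsv")
    truth_path = out_dir / "truth.json"
    truth = read_truth_json(truth_path) if truth_path.exists() else None
    return geno, expr, meta, truth


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
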