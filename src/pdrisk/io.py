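"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as VCF 4.2 (GT field, missing ``./.``; REF = other allele,
ALT = effect allele, so the ALT dosage is the effect-allele count).  Summary
statistics, phenotypes and kinship are TSVs with headers; the simulation
manifest is JSON.  VCF parsing is delegated to cyvcf2.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .genotypes import GenotypeMatrix
from .simulate import SimulationConfig, SyntheticCohort

SUMSTAT_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "P", "FREQ"]

_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write the dosage matrix as a VCF 4.2 text file."""
    path = Path(path)
    v = genotypes.variants
    has_meta = {c: c in v.columns for c in ("maf", "info", "hwe_p")}
    order = np.lexsort((v["pos"].to_numpy(), v["chrom"].to_numpy()))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pdrisk\n")
        for c in sorted(v["chrom"].unique()):
            fh.write(f"##contig=<ID={c}>\n")
        if has_meta["maf"]:
            fh.write('##INFO=<ID=MAF,Number=1,Type=Float,Description="Minor allele frequency">\n')
        if has_meta["info"]:
            fh.write('##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation quality surrogate">\n')
        if has_meta["hwe_p"]:
            fh.write('##INFO=<ID=HWE,Number=1,Type=Float,Description="Hardy-Weinberg exact p">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.sample_ids)
            + "\n"
        )
        dos = genotypes.dosages
        for j in order:
            row = v.iloc[j]
            info_parts = []
            if has_meta["maf"]:
                info_parts.append(f"MAF={row['maf']:.6g}")
            if has_meta["info"]:
                info_parts.append(f"R2={row['info']:.6g}")
            if has_meta["hwe_p"]:
                info_parts.append(f"HWE={row['hwe_p']:.6g}")
            info_str = ";".join(info_parts) if info_parts else "."
            gts = "\t".join(
                "./." if np.isnan(d) else _GT[float(d)] for d in dos[:, j]
            )
            rsid = row["rsid"] if row["rsid"] not in ("", None) else "."
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{rsid}\t{row['a2']}\t{row['a1']}"
                f"\t.\tPASS\t{info_str}\tGT\t{gts}\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix (ALT-allele dosage; ``./.`` -> NaN)."""
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    records, columns = [], []
    for var in vcf:
        gt = np.asarray(var.gt_types, dtype=float)
        # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        dos = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        columns.append(dos.astype(np.float32))
        records.append(
            {
                "rsid": var.ID or "",
                "chrom": int(var.CHROM),
                "pos": int(var.POS),
                "a1": var.ALT[0] if var.ALT else "",
                "a2": var.REF,
                "maf": var.INFO.get("MAF"),
                "info": var.INFO.get("R2"),
                "hwe_p": var.INFO.get("HWE"),
            }
        )
    variants = pd.DataFrame.from_records(records)
    dosages = np.column_stack(columns) if columns else np.empty((len(sample_ids), 0))
    return GenotypeMatrix(sample_ids, variants, dosages)


def write_summary_stats(stats: pd.DataFrame, path: str | Path) -> None:
    stats.to_csv(path, sep="\t", index=False, columns=SUMSTAT_COLUMNS)


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary statistics file lacks columns: {missing}")
    return df


def write_phenotypes(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_kinship(kinship: pd.DataFrame, path: str | Path) -> None:
    kinship.to_csv(path, sep="\t", index=False)


def read_kinship(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("id1", "id2", "kinship") if c not in df.columns]
    if missing:
        raise ValueError(f"kinship file lacks columns: {missing}")
    return df


def write_cohort(bundle: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write all cohort components plus a manifest recording config and seed."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": directory / "genotypes.vcf",
        "summary_stats": directory / "summary_stats.tsv",
        "phenotypes": directory / "phenotypes.tsv",
        "kinship": directory / "kinship.tsv",
        "truth": directory / "truth.tsv",
        "manifest": directory / "manifest.json",
    }
    write_vcf(bundle.genotypes, paths["genotypes"])
    write_summary_stats(bundle.summary_stats, paths["summary_stats"])
    write_phenotypes(bundle.cohort, paths["phenotypes"])
    write_kinship(bundle.kinship, paths["kinship"])
    pd.DataFrame(
        {"SNP": bundle.genotypes.variants["rsid"], "BETA_TRUE": bundle.beta_true}
    ).to_csv(paths["truth"], sep="\t", index=False, float_format="%.17g")
    manifest = {"config": bundle.config.to_dict(), "seed": bundle.config.seed}
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return paths


def read_cohort(directory: str | Path) -> SyntheticCohort:
    """Round-trip reader for a directory written by :func:`write_cohort`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    config = SimulationConfig.from_dict(manifest["config"])
    genotypes = read_vcf(directory / "genotypes.vcf")
    truth = pd.read_csv(directory / "truth.tsv", sep="\t", float_precision="round_trip")
    beta_true = (
        truth.set_index("SNP")["BETA_TRUE"]
        .reindex(genotypes.variants["rsid"])
        .to_numpy()
    )
    return SyntheticCohort(
        config=config,
        genotypes=genotypes,
        beta_true=beta_true,
        summary_stats=read_summary_stats(directory / "summary_stats.tsv"),
        cohort=read_phenotypes(directory / "phenotypes.tsv"),
        kinship=read_kinship(directory / "kinship.tsv"),
    )
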