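"""Reading and writing the pipeline's on-disk formats.

Genotypes travel as GT-only VCF 4.2 (missing calls as ``./.``), phenotypes
and scoring files as tab-separated text.  VCF parsing uses cyvcf2; the
emitter writes the minimal conformant text directly.
"""
from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .containers import PHENO_COLUMNS, Cohort, GenotypeMatrix

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}

SCORING_COLUMNS = ["rsID", "chr", "pos", "effect_allele", "other_allele", "effect_weight"]


def write_vcf(path: str, geno: GenotypeMatrix) -> None:
    """Write a GT-only VCF 4.2 file; missing dosages become ``./.``."""
    v = geno.variants
    contigs = list(dict.fromkeys(v["chrom"].astype(str)))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=prs-interplay\n")
        fh.write('##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(s) for s in geno.samples) + "\n")
        dos = geno.dosages
        for j in range(geno.n_variants):
            row = v.iloc[j]
            gts = [
                "./." if np.isnan(d) else _GT[int(round(d))] for d in dos[:, j]
            ]
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{row['id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\tINFO={float(row['info']):.4f}\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a biallelic GT VCF into a dosage matrix (cyvcf2 backend)."""
    from cyvcf2 import VCF

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    vcf = VCF(path, gts012=True)
    samples = np.asarray(vcf.samples, dtype=object)
    rows = []
    dosage_rows = []
    for var in vcf:
        alt = var.ALT[0] if var.ALT else "."
        info = var.INFO.get("INFO")
        rows.append(
            {
                "chrom": var.CHROM,
                "pos": var.POS,
                "id": var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}",
                "ref": var.REF,
                "alt": alt,
                "info": float(info) if info is not None else 1.0,
            }
        )
        # gts012: 0/1/2 = ALT count, 3 = missing
        d = var.gt_types.astype(float)
        d[d == 3] = np.nan
        dosage_rows.append(d)
    vcf.close()
    if not rows:
        raise ValueError(f"no variants in {path}")
    dosages = np.vstack(dosage_rows).T
    return GenotypeMatrix(dosages, samples, pd.DataFrame(rows))


def write_pheno(path: str, pheno: pd.DataFrame) -> None:
    pheno.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_pheno(path: str) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file missing columns: {missing}")
    return df


def write_scoring_file(path: str, entries: pd.DataFrame, name: str = "score") -> None:
    """Write a PGS-Catalog-style scoring file (# header lines + TSV)."""
    with open(path, "w") as fh:
        fh.write(f"#pgs_name={name}\n")
        fh.write("#genome_build=NA\n")
        entries[SCORING_COLUMNS].to_csv(fh, sep="\t", index=False)


def read_scoring_file(path: str):
    """Read a PGS-Catalog-style scoring file; returns (name, entries)."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    name = os.path.splitext(os.path.basename(path))[0]
    with open(path) as fh:
        pos = 0
        while True:
            line = fh.readline()
            if line.startswith("#"):
                if line.startswith("#pgs_name="):
                    name = line.strip().split("=", 1)[1]
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    missing = [c for c in SCORING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"scoring file missing columns: {missing}")
    return name, df


def write_cohort(cohort: Cohort, out_dir: str) -> dict:
    """Emit a cohort as ``cohort.vcf`` + ``phenotypes.tsv`` (+ ``truth.json``).

    Returns the mapping of logical name -> path.  Read-back with
    :func:`read_cohort` reproduces the in-memory cohort.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "cohort.vcf"),
        "pheno": os.path.join(out_dir, "phenotypes.tsv"),
    }
    write_vcf(paths["vcf"], cohort.geno)
    write_pheno(paths["pheno"], cohort.pheno)
    if cohort.truth is not None:
        paths["truth"] = os.path.join(out_dir, "truth.json")
        cohort.truth.to_json(paths["truth"])
    return paths


def read_cohort(out_dir: str) -> Cohort:
    from .simulate import TruthRecord

    geno = read_vcf(os.path.join(out_dir, "cohort.vcf"))
    pheno = read_pheno(os.path.join(out_dir, "phenotypes.tsv"))
    truth_path = os.path.join(out_dir, "truth.json")
    truth = TruthRecord.from_json(truth_path) if os.path.exists(truth_path) else None
    return Cohort(geno, pheno, truth)
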