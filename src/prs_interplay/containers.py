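"""Core in-memory containers shared across the pipeline.

The pipeline works on a samples x variants dosage matrix (ALT-allele
counts 0/1/2 with NaN for missing calls), a per-variant metadata table
and a per-sample phenotype/covariate table.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: columns required in the per-variant metadata table
VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt", "info"]

#: columns required in the phenotype table (PC columns pc1..pcK optional)
PHENO_COLUMNS = ["sample_id", "status", "age", "sex", "bmi", "smoking"]


@dataclass
class GenotypeMatrix:
    """Dosage matrix with variant metadata.

    Parameters
    ----------
    dosages : ndarray, shape (n_samples, n_variants)
        ALT-allele counts as floats; missing genotypes are NaN.
    samples : ndarray of str
        Sample identifiers, row order of ``dosages``.
    variants : DataFrame
        One row per variant with columns ``chrom, pos, id, ref, alt, info``.
    """

    dosages: np.ndarray
    samples: np.ndarray
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.samples = np.asarray(self.samples, dtype=object)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        if self.dosages.shape[0] != len(self.samples):
            raise ValueError("sample count mismatch between dosages and samples")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("variant count mismatch between dosages and variants")
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table missing columns: {missing}")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def variant_call_rate(self) -> np.ndarray:
        """Fraction of non-missing genotypes per variant."""
        return 1.0 - np.mean(np.isnan(self.dosages), axis=0)

    def sample_call_rate(self) -> np.ndarray:
        """Fraction of non-missing genotypes per sample."""
        return 1.0 - np.mean(np.isnan(self.dosages), axis=1)

    def alt_freq(self) -> np.ndarray:
        """ALT-allele frequency per variant over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def subset(self, sample_idx=None, variant_idx=None) -> "GenotypeMatrix":
        d = self.dosages
        s = self.samples
        v = self.variants
        if sample_idx is not None:
            sample_idx = np.asarray(sample_idx)
            d = d[sample_idx, :]
            s = s[sample_idx]
        if variant_idx is not None:
            variant_idx = np.asarray(variant_idx)
            d = d[:, variant_idx]
            v = v.iloc[variant_idx]
        return GenotypeMatrix(d.copy(), s.copy(), v.reset_index(drop=True))

    def sample_index(self) -> dict:
        return {s: i for i, s in enumerate(self.samples)}


@dataclass
class Cohort:
    """A genotype matrix paired with its phenotype table and, for simulated
    cohorts, the ground-truth record."""

    geno: GenotypeMatrix
    pheno: pd.DataFrame
    truth: "object | None" = field(default=None)

    def __post_init__(self) -> None:
        missing = [c for c in PHENO_COLUMNS if c not in self.pheno.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns: {missing}")
        if list(self.pheno["sample_id"]) != list(self.geno.samples):
            raise ValueError("phenotype rows must align with genotype samples")
        self.pheno = self.pheno.reset_index(drop=True)

    @property
    def n_cases(self) -> int:
        return int((self.pheno["status"] == 1).sum())

    @property
    def n_controls(self) -> int:
        return int((self.pheno["status"] == 0).sum())
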