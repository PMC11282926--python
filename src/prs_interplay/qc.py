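"""Variant and sample quality control.

Default thresholds reproduce a standard array-genotyping QC: variant call
rate >= 0.97, Hardy-Weinberg exact P >= 1e-7 (computed in controls only,
since true associations can distort genotype frequencies in cases), MAF >=
1%, unique chrom:pos; sample call rate >= 0.95, inbreeding-coefficient
outliers beyond 10 SD of the cohort mean, duplicate/first-degree relative
removal by an IBS-based kinship estimate, and PC-score outliers.  The
post-imputation filter removes variants with INFO < 0.3, MAF < 0.001 or
MAF x INFO x n_cases < 10.

Exclusion reasons are assigned with fixed precedence (the order the rules
are listed in), so reports are deterministic and each excluded unit cites
exactly one primary reason.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

__all__ = [
    "QCThresholds",
    "PostImputationThresholds",
    "QCReport",
    "hwe_exact_test",
    "variant_qc",
    "inbreeding_f",
    "ibs_relatedness",
    "ibs_matrix",
    "king_kinship",
    "sample_qc",
    "post_imputation_filter",
]


@dataclass
class QCThresholds:
    variant_call_rate_min: float = 0.97
    hwe_p_min: float = 1e-7
    maf_min: float = 0.01
    sample_call_rate_min: float = 0.95
    inbreeding_sd_limit: float = 10.0
    #: KING-robust kinship above which a pair is treated as duplicate or
    #: first-degree (standard first-degree cutoff)
    relatedness_limit: float = 0.177
    pca_outlier_sd: float = 6.0

    def __post_init__(self) -> None:
        for name in ("variant_call_rate_min", "hwe_p_min", "maf_min",
                     "sample_call_rate_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class PostImputationThresholds:
    info_min: float = 0.3
    maf_min: float = 0.001
    maf_info_ncase_min: float = 10.0


@dataclass
class QCReport:
    """Per-unit pass/fail with the first failing rule."""

    unit: str  # "variant" or "sample"
    table: pd.DataFrame  # columns: id, pass, reason
    order: list = field(default_factory=list)

    @property
    def kept_ids(self) -> list:
        return list(self.table.loc[self.table["pass"], "id"])

    @property
    def kept_mask(self) -> np.ndarray:
        return self.table["pass"].to_numpy()

    def counts(self) -> pd.Series:
        """Exclusion counts by primary reason."""
        excl = self.table.loc[~self.table["pass"], "reason"]
        return excl.value_counts().reindex(self.order, fill_value=0)

    def to_tsv(self, path: str) -> None:
        out = self.table.copy()
        out.insert(0, "unit", self.unit)
        out.to_csv(path, sep="\t", index=False, na_rep="NA")


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy-Weinberg test conditional on the observed allele counts.

    Sums the probabilities of all heterozygote counts (with the parity
    forced by the rare-allele total) whose conditional probability does
    not exceed the observed one.  No mid-p correction.  Returns p in
    (0, 1]; monomorphic sites return 1.0.
    """
    for c in (n_AA, n_Aa, n_aa):
        if c < 0:
            raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotype required")
    n_rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if n_rare == 0:
        return 1.0

    # conditional pmf over het counts via the standard two-sided recurrence
    # from the mode (numerically stable: probabilities are normalized at
    # the end)
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    probs = np.zeros(len(hets))
    mode = int(round(n_rare * (2 * n - n_rare) / (2.0 * n - 1.0)))
    if mode % 2 != n_rare % 2:
        mode += 1
    mode = min(max(mode, hets[0]), hets[-1])
    idx = {h: i for i, h in enumerate(hets)}
    probs[idx[mode]] = 1.0
    # going down: P(h-2)/P(h) = h(h-1) / ((r-h+2)(c-h+2)) with
    # r = rare hom*2 relation; derive from hom counts at h
    h = mode
    while h >= hets[0] + 2:
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        ratio = h * (h - 1.0) / (4.0 * (hom_r + 1.0) * (hom_c + 1.0))
        probs[idx[h - 2]] = probs[idx[h]] * ratio
        h -= 2
    h = mode
    while h <= hets[-1] - 2:
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        ratio = 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
        probs[idx[h + 2]] = probs[idx[h]] * ratio
        h += 2
    probs /= probs.sum()
    p_obs = probs[idx[n_Aa]] if n_Aa in idx else 0.0
    if n_Aa not in idx:
        raise ValueError("heterozygote count inconsistent with allele totals")
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def variant_qc(geno: GenotypeMatrix, thr: QCThresholds | None = None,
               controls_mask: np.ndarray | None = None) -> QCReport:
    """Apply variant filters in order: call rate, HWE, MAF, duplicate position.

    HWE is computed in controls only when ``controls_mask`` is given;
    duplicated chrom:pos keeps the first occurrence.
    """
    if geno.n_variants == 0:
        raise ValueError("empty genotype matrix")
    thr = thr or QCThresholds()
    order = ["call_rate", "hwe", "maf", "duplicate_position"]
    call = geno.variant_call_rate()
    maf = geno.maf()

    d_hwe = geno.dosages if controls_mask is None else geno.dosages[controls_mask]
    hwe_p = np.ones(geno.n_variants)
    for j in range(geno.n_variants):
        col = d_hwe[:, j]
        col = col[~np.isnan(col)]
        if len(col) == 0:
            hwe_p[j] = 1.0
            continue
        n_aa = int((col == 0).sum())
        n_het = int((col == 1).sum())
        n_AA = int((col == 2).sum())
        hwe_p[j] = hwe_exact_test(n_AA, n_het, n_aa)

    key = geno.variants["chrom"].astype(str) + ":" + geno.variants["pos"].astype(str)
    dup = key.duplicated(keep="first").to_numpy()

    reason = np.full(geno.n_variants, "", dtype=object)
    fails = [
        ("call_rate", call < thr.variant_call_rate_min),
        ("hwe", hwe_p < thr.hwe_p_min),
        ("maf", maf < thr.maf_min),
        ("duplicate_position", dup),
    ]
    for name, mask in fails:
        sel = mask & (reason == "")
        reason[sel] = name
    table = pd.DataFrame(
        {"id": geno.variants["id"], "pass": reason == "", "reason":
         np.where(reason == "", None, reason)}
    )
    return QCReport("variant", table, order)


def inbreeding_f(dosages: np.ndarray, freqs: np.ndarray) -> float:
    """Inbreeding coefficient F = 1 - observed/expected heterozygosity.

    ``dosages`` is one sample's dosage vector (NaN = missing); ``freqs``
    the cohort ALT-allele frequencies at the same variants.
    """
    dosages = np.asarray(dosages, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    ok = ~np.isnan(dosages)
    exp_het = float(np.sum(2.0 * freqs[ok] * (1.0 - freqs[ok])))
    if exp_het == 0:
        raise ValueError("expected heterozygosity is zero")
    obs_het = float(np.sum(dosages[ok] == 1))
    return 1.0 - obs_het / exp_het


def ibs_relatedness(d_i: np.ndarray, d_j: np.ndarray) -> float:
    """Mean identity-by-state similarity over co-observed variants.

    IBS per site is (2 - |d_i - d_j|) / 2, i.e. 1 for identical
    genotypes, 0 for opposite homozygotes.
    """
    d_i = np.asarray(d_i, dtype=float)
    d_j = np.asarray(d_j, dtype=float)
    ok = ~(np.isnan(d_i) | np.isnan(d_j))
    if not ok.any():
        raise ValueError("no co-observed variants")
    return float(np.mean((2.0 - np.abs(d_i[ok] - d_j[ok])) / 2.0))


def ibs_matrix(dosages: np.ndarray) -> np.ndarray:
    """All-pairs mean IBS similarity (chunk-free; for moderate cohorts)."""
    n = dosages.shape[0]
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = ibs_relatedness(dosages[i], dosages[j])
    return out


def king_kinship(dosages: np.ndarray) -> np.ndarray:
    """KING-robust pairwise kinship from genotype counts.

    phi_ij = (N_het_both - 2 * N_opposite_hom) / (N_het_i + N_het_j),
    counting only co-observed sites.  Duplicates/MZ twins ~0.5, parent-
    offspring ~0.25, unrelated ~0; robust to allele-frequency spectrum.
    """
    d = np.asarray(dosages, dtype=float)
    obs = (~np.isnan(d)).astype(float)
    het = np.nan_to_num((d == 1).astype(float))
    hom0 = np.nan_to_num((d == 0).astype(float))
    hom2 = np.nan_to_num((d == 2).astype(float))
    n11 = het @ het.T
    nopp = hom0 @ hom2.T + hom2 @ hom0.T
    # het counts restricted to sites observed in the partner
    het_i = het @ obs.T
    denom = het_i + het_i.T
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (n11 - 2.0 * nopp) / denom
    phi[denom == 0] = 0.0
    np.fill_diagonal(phi, 0.5)
    return phi


def sample_qc(geno: GenotypeMatrix, thr: QCThresholds | None = None,
              pcs: np.ndarray | None = None) -> QCReport:
    """Sample filters in order: call rate, inbreeding outlier, relatedness,
    PC outlier.

    Relatedness removal keeps, from each flagged pair, the member with the
    higher call rate (ties broken by sample id).  PC outliers are samples
    whose score on any supplied component deviates from the component mean
    by more than ``pca_outlier_sd`` standard deviations.
    """
    if geno.n_samples == 0:
        raise ValueError("empty cohort")
    thr = thr or QCThresholds()
    order = ["call_rate", "inbreeding", "relatedness", "pc_outlier"]
    n = geno.n_samples
    reason = np.full(n, "", dtype=object)

    call = geno.sample_call_rate()
    reason[(call < thr.sample_call_rate_min) & (reason == "")] = "call_rate"

    freqs = geno.alt_freq()
    F = np.array([inbreeding_f(geno.dosages[i], freqs) for i in range(n)])
    mu, sd = F.mean(), F.std()
    if sd > 0:
        out = np.abs(F - mu) > thr.inbreeding_sd_limit * sd
        reason[out & (reason == "")] = "inbreeding"

    phi = king_kinship(geno.dosages)
    iu = np.triu_indices(n, k=1)
    flagged = phi[iu] > thr.relatedness_limit
    drop = set()
    pairs = sorted(zip(iu[0][flagged], iu[1][flagged]),
                   key=lambda ij: (str(geno.samples[ij[0]]), str(geno.samples[ij[1]])))
    for i, j in pairs:
        if i in drop or j in drop:
            continue
        ci, cj = call[i], call[j]
        if ci > cj:
            drop.add(j)
        elif cj > ci:
            drop.add(i)
        else:  # tie-break: keep the lexicographically smaller id
            drop.add(j if str(geno.samples[i]) < str(geno.samples[j]) else i)
    for i in drop:
        if reason[i] == "":
            reason[i] = "relatedness"

    if pcs is not None:
        pcs = np.asarray(pcs, dtype=float)
        mu = pcs.mean(axis=0)
        sd = pcs.std(axis=0)
        sd[sd == 0] = np.inf
        out = (np.abs(pcs - mu) > thr.pca_outlier_sd * sd).any(axis=1)
        reason[out & (reason == "")] = "pc_outlier"

    table = pd.DataFrame(
        {"id": geno.samples, "pass": reason == "",
         "reason": np.where(reason == "", None, reason)}
    )
    return QCReport("sample", table, order)


def post_imputation_filter(variants: pd.DataFrame, n_cases: int,
                           thr: PostImputationThresholds | None = None,
                           maf: np.ndarray | None = None) -> QCReport:
    """Post-imputation variant filter: INFO, MAF, and MAF x INFO x n_cases.

    ``variants`` must carry an ``info`` column; MAF is taken from the
    ``maf`` argument or a ``maf`` column.
    """
    thr = thr or PostImputationThresholds()
    if "info" not in variants.columns or variants["info"].isna().any():
        raise ValueError("INFO value required for every variant")
    if maf is None:
        if "maf" not in variants.columns:
            raise ValueError("MAF required (column or argument)")
        maf = variants["maf"].to_numpy(dtype=float)
    info = variants["info"].to_numpy(dtype=float)
    order = ["info", "maf", "maf_info_ncases"]
    reason = np.full(len(variants), "", dtype=object)
    fails = [
        ("info", info < thr.info_min),
        ("maf", maf < thr.maf_min),
        ("maf_info_ncases", maf * info * n_cases < thr.maf_info_ncase_min),
    ]
    for name, mask in fails:
        sel = mask & (reason == "")
        reason[sel] = name
    table = pd.DataFrame(
        {"id": variants["id"], "pass": reason == "",
         "reason": np.where(reason == "", None, reason)}
    )
    return QCReport("variant", table, order)
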