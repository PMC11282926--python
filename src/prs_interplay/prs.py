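"""Polygenic-score construction: weight harmonization, proxy lookup,
scoring, standardization and genetic-risk grouping.

Harmonization aligns each weight entry to the cohort's REF/ALT coding:

* effect allele equals ALT -> dosage used as-is;
* effect allele equals REF -> the contribution is weight * (2 - dosage);
* alleles match only after strand complement -> complemented, then the
  two cases above;
* palindromic entries (A/T, C/G) are dropped — their orientation cannot
  be resolved without frequency matching and the error mode is silent;
* otherwise an LD proxy may be searched in a reference panel (maximal
  squared Pearson dosage correlation above ``r2_min`` within a window).

Scores are the weighted [log(OR)] sum of harmonized dosages, or in
unweighted mode the plain sum of risk-allele counts (the risk allele is
the effect allele when the weight is positive, the other allele when
negative).  Missing dosages are imputed with twice the cohort
effect-allele frequency.  Standardization and all percentile groupings
use the combined cases+controls distribution: quintiles, low/
intermediate/high risk groups at the 20th/80th percentiles, and tail
flags at the 90th/95th/99th.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .io import SCORING_COLUMNS, read_scoring_file, write_scoring_file

__all__ = [
    "WeightSet",
    "HarmonizationLog",
    "ScoreResult",
    "harmonize_weights",
    "find_proxy",
    "merge_multi_reports",
    "compute_score",
    "standardize_and_group",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _complement(allele: str) -> str:
    try:
        return "".join(_COMPLEMENT[b] for b in allele.upper())
    except KeyError:
        raise ValueError(f"malformed allele: {allele!r}")


def _is_palindromic(ea: str, oa: str) -> bool:
    return ea.upper() == _complement(oa)


@dataclass
class WeightSet:
    """A named PRS definition.

    ``entries`` columns: ``rsID, chr, pos, effect_allele, other_allele,
    effect_weight`` (+ harmonization columns ``flip``/``matched_id`` once
    harmonized).  ``mode`` is ``"weighted"`` (sum of weight * dosage) or
    ``"unweighted"`` (sum of risk alleles).
    """

    name: str
    entries: pd.DataFrame
    mode: str = "weighted"

    def __post_init__(self) -> None:
        if self.mode not in ("weighted", "unweighted"):
            raise ValueError("mode must be 'weighted' or 'unweighted'")
        missing = [c for c in SCORING_COLUMNS if c not in self.entries.columns]
        if missing:
            raise ValueError(f"weight set missing columns: {missing}")
        if self.entries["rsID"].duplicated().any():
            raise ValueError("duplicate variant ids in weight set")
        if not np.isfinite(self.entries["effect_weight"].to_numpy(float)).all():
            raise ValueError("weights must be finite")
        self.entries = self.entries.reset_index(drop=True)

    @classmethod
    def from_file(cls, path: str, mode: str = "weighted") -> "WeightSet":
        name, entries = read_scoring_file(path)
        return cls(name, entries, mode)

    def to_file(self, path: str) -> None:
        write_scoring_file(path, self.entries, self.name)


@dataclass
class HarmonizationLog:
    """Per-entry harmonization outcome; every entry appears exactly once."""

    table: pd.DataFrame  # columns: rsID, action, detail

    def counts(self) -> pd.Series:
        return self.table["action"].value_counts()


@dataclass
class ScoreResult:
    """Per-sample scores and percentile groupings (combined-cohort reference)."""

    table: pd.DataFrame  # sample_id, status, raw, z, quintile, risk_group, tails

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False, na_rep="NA")


def harmonize_weights(ws: WeightSet, variants: pd.DataFrame,
                      reference: GenotypeMatrix | None = None,
                      r2_min: float = 0.5, window: int = 500_000,
                      drop_palindromic: bool = True):
    """Align a weight set to cohort variants; returns (WeightSet, log).

    Matching is by chrom:pos.  Harmonizing an already-harmonized set is a
    no-op (same actions, same output).
    """
    vkey = {}
    for idx, row in variants.iterrows():
        vkey[(str(row["chrom"]), int(row["pos"]))] = idx

    out_rows, log_rows = [], []
    for _, e in ws.entries.iterrows():
        ea = str(e["effect_allele"]).upper()
        oa = str(e["other_allele"]).upper()
        if not ea or not oa or any(b not in "ACGT" for b in ea + oa):
            raise ValueError(f"malformed alleles for {e['rsID']}: {ea}/{oa}")
        if drop_palindromic and _is_palindromic(ea, oa):
            log_rows.append({"rsID": e["rsID"], "action": "dropped",
                             "detail": "palindromic"})
            continue
        key = (str(e["chr"]), int(e["pos"]))
        resolved = None
        if key in vkey:
            v = variants.loc[vkey[key]]
            ref, alt = str(v["ref"]).upper(), str(v["alt"]).upper()
            if (ea, oa) == (alt, ref):
                resolved = (v, ea, oa, False, "matched", "")
            elif (ea, oa) == (ref, alt):
                resolved = (v, ea, oa, True, "sign-flipped", "")
            else:
                cea, coa = _complement(ea), _complement(oa)
                if (cea, coa) == (alt, ref):
                    resolved = (v, cea, coa, False, "strand-complemented", "")
                elif (cea, coa) == (ref, alt):
                    resolved = (v, cea, coa, True, "strand-complemented", "flipped")
        if resolved is None and reference is not None:
            try:
                proxy = find_proxy(e, reference, r2_min=r2_min, window=window)
            except ValueError:  # target absent from the panel: no proxy
                proxy = None
            if proxy is not None:
                pv, r2, sign = proxy
                w = float(e["effect_weight"]) * sign
                out_rows.append({
                    "rsID": e["rsID"], "chr": pv["chrom"], "pos": pv["pos"],
                    "effect_allele": pv["alt"], "other_allele": pv["ref"],
                    "effect_weight": w, "flip": False,
                    "matched_id": pv["id"],
                })
                log_rows.append({"rsID": e["rsID"], "action": "proxied",
                                 "detail": f"{pv['id']} r2={r2:.3f}"})
                continue
        if resolved is None:
            log_rows.append({"rsID": e["rsID"], "action": "dropped",
                             "detail": "unmatched"})
            continue
        v, ea2, oa2, flip, action, detail = resolved
        out_rows.append({
            "rsID": e["rsID"], "chr": v["chrom"], "pos": v["pos"],
            "effect_allele": ea2, "other_allele": oa2,
            "effect_weight": float(e["effect_weight"]), "flip": flip,
            "matched_id": v["id"],
        })
        log_rows.append({"rsID": e["rsID"], "action": action, "detail": detail})

    entries = pd.DataFrame(
        out_rows,
        columns=SCORING_COLUMNS[:1] + ["chr", "pos", "effect_allele",
                                       "other_allele", "effect_weight",
                                       "flip", "matched_id"],
    )
    log = HarmonizationLog(pd.DataFrame(
        log_rows, columns=["rsID", "action", "detail"]))
    return WeightSet(ws.name, entries, ws.mode), log


def find_proxy(target, reference: GenotypeMatrix, r2_min: float = 0.5,
               window: int = 500_000):
    """Best LD proxy for a target variant within a base-pair window.

    The target must be present in the reference panel (by chrom:pos).
    Returns ``(variant_row, r2, sign)`` for the in-window variant with the
    highest squared Pearson dosage correlation above ``r2_min`` (sign is
    the correlation's sign, used to re-orient the effect allele), or None.
    """
    v = reference.variants
    chrom, pos = str(target["chr"]), int(target["pos"])
    tmask = (v["chrom"].astype(str) == chrom) & (v["pos"].astype(int) == pos)
    if not tmask.any():
        raise ValueError(f"target {target['rsID']} absent from reference panel")
    tj = int(np.flatnonzero(tmask.to_numpy())[0])
    td = reference.dosages[:, tj]
    cand = np.flatnonzero(
        (v["chrom"].astype(str) == chrom).to_numpy()
        & (np.abs(v["pos"].astype(int) - pos) <= window).to_numpy()
    )
    best = None
    for j in cand:
        if j == tj:
            continue
        d = reference.dosages[:, j]
        ok = ~(np.isnan(td) | np.isnan(d))
        if ok.sum() < 2 or np.std(td[ok]) == 0 or np.std(d[ok]) == 0:
            continue
        r = float(np.corrcoef(td[ok], d[ok])[0, 1])
        if r * r > r2_min and (best is None or r * r > best[1]):
            best = (j, r * r, 1.0 if r >= 0 else -1.0)
    if best is None:
        return None
    j, r2, sign = best
    return v.iloc[j], r2, sign


def merge_multi_reports(effect_sizes) -> float:
    """Median reported odds ratio across studies (even count: mean of the
    middle two)."""
    arr = np.asarray(list(effect_sizes), dtype=float)
    if arr.size == 0:
        raise ValueError("at least one effect size required")
    return float(np.median(arr))


def compute_score(geno: GenotypeMatrix, ws: WeightSet) -> np.ndarray:
    """Raw PRS per sample from a harmonized weight set.

    Weighted: sum_j w_j * d_ij (with d flipped to 2-d where the effect
    allele is REF).  Unweighted: sum of risk-allele counts.  Missing
    dosages are imputed as 2 * effect-allele frequency.
    """
    if "matched_id" not in ws.entries.columns:
        raise ValueError("weight set must be harmonized before scoring")
    if len(ws.entries) == 0:
        raise ValueError("no overlapping variants between weights and cohort")
    vid_to_col = {vid: j for j, vid in enumerate(geno.variants["id"])}
    score = np.zeros(geno.n_samples)
    alt_freq = geno.alt_freq()
    for _, e in ws.entries.iterrows():
        j = vid_to_col[e["matched_id"]]
        d = geno.dosages[:, j].copy()
        d[np.isnan(d)] = 2.0 * alt_freq[j]
        if bool(e.get("flip", False)):
            d = 2.0 - d
        w = float(e["effect_weight"])
        if ws.mode == "weighted":
            score += w * d
        else:
            score += d if w >= 0 else (2.0 - d)
    return score


def _rank_groups(raw: np.ndarray):
    """Rank-based quintiles, 20/80 risk groups and tail flags.

    Boundaries use ranks so the partition is exact: with n samples the
    low and high groups hold ceil(0.2 n) samples each.
    """
    n = len(raw)
    order = np.argsort(raw, kind="stable")
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(1, n + 1)
    edges = [int(np.ceil(k * n / 5.0)) for k in range(1, 6)]
    quintile = np.searchsorted(edges, rank, side="left") + 1
    n_low = int(np.ceil(0.2 * n))
    risk = np.where(rank <= n_low, "low",
                    np.where(rank > n - n_low, "high", "intermediate"))
    tails = {
        f"tail{q}": rank > n - int(np.floor((1 - q / 100.0) * n))
        for q in (90, 95, 99)
    }
    return quintile, risk, tails


def standardize_and_group(raw: np.ndarray, status: np.ndarray,
                          sample_ids=None) -> ScoreResult:
    """Standardize scores and assign percentile groups on the combined cohort.

    z-scores use the combined cases+controls mean and SD (ddof=1);
    quintiles, the 20/80 risk groups and the 90/95/99th-percentile tail
    flags all use the combined distribution.
    """
    raw = np.asarray(raw, dtype=float)
    status = np.asarray(status)
    n = len(raw)
    if n < 2:
        raise ValueError("at least 2 samples required")
    sd = raw.std(ddof=1)
    if sd == 0:
        raise ValueError("zero score variance")
    z = (raw - raw.mean()) / sd
    quintile, risk, tails = _rank_groups(raw)
    if sample_ids is None:
        sample_ids = [f"S{i + 1:06d}" for i in range(n)]
    table = pd.DataFrame({
        "sample_id": sample_ids,
        "status": status,
        "raw": raw,
        "z": z,
        "quintile": quintile,
        "risk_group": pd.Categorical(
            risk, categories=["low", "intermediate", "high"]),
        **{k: v for k, v in tails.items()},
    })
    return ScoreResult(table)
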