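"""Ancestry principal components and 5:1 case-control matching.

PCs are computed from the standardized dosage matrix (columns centered by
twice the allele frequency and scaled by the binomial SD; missing dosages
mean-imputed), and controls are matched to cases by greedy nearest-
neighbour in PC1-PC2 Euclidean space without replacement.  Cases are
processed in descending order of local control density so cases in sparse
regions are not starved by earlier picks; ties break by case id, making
the assignment deterministic and invariant to input order.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .containers import GenotypeMatrix

__all__ = ["PCResult", "MatchResult", "compute_pcs", "match_controls"]


@dataclass
class PCResult:
    scores: np.ndarray  # (n_samples, n_components), zero mean per component
    eigenvalues: np.ndarray  # non-increasing
    loadings: np.ndarray  # (n_variants_used, n_components)
    sample_ids: np.ndarray
    variant_idx: np.ndarray  # indices of variants used (polymorphic)

    def to_tsv(self, path: str) -> None:
        cols = {f"pc{k + 1}": self.scores[:, k]
                for k in range(self.scores.shape[1])}
        pd.DataFrame({"sample_id": self.sample_ids, **cols}).to_csv(
            path, sep="\t", index=False)


@dataclass
class MatchResult:
    """case id -> matched control ids, with per-pair PC1-2 distances."""

    assignments: dict
    distances: dict
    unmatchable: list = field(default_factory=list)
    k: int = 5

    @property
    def matched_controls(self) -> list:
        out = []
        for cid in self.assignments:
            out.extend(self.assignments[cid])
        return out

    def to_tsv(self, path: str) -> None:
        rows = [
            {"case_id": cid, "control_id": ctl, "distance": d}
            for cid in self.assignments
            for ctl, d in zip(self.assignments[cid], self.distances[cid])
        ]
        pd.DataFrame(rows, columns=["case_id", "control_id", "distance"]).to_csv(
            path, sep="\t", index=False)


def compute_pcs(geno: GenotypeMatrix, n_components: int = 10) -> PCResult:
    """PCA of the standardized dosage matrix.

    Column j is transformed to (d - 2 p_j) / sqrt(2 p_j (1 - p_j)) with
    p_j the sample ALT frequency; missing entries are mean-imputed (zero
    after centering).  Scores are the projections onto the right singular
    vectors; eigenvalues are the variances explained (non-increasing).
    """
    p = geno.alt_freq()
    poly = (p > 0) & (p < 1) & ~np.isnan(p)
    if poly.sum() < n_components:
        raise ValueError(
            f"only {int(poly.sum())} polymorphic variants for "
            f"{n_components} components")
    d = geno.dosages[:, poly]
    p = p[poly]
    x = (d - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    x = np.nan_to_num(x, nan=0.0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, len(s))
    u, s, vt = u[:, :k], s[:k], vt[:k]
    # deterministic sign: largest-|loading| entry positive per component
    for c in range(k):
        j = np.argmax(np.abs(vt[c]))
        if vt[c, j] < 0:
            vt[c] *= -1.0
            u[:, c] *= -1.0
    scores = u * s
    eig = s**2 / x.shape[1]
    return PCResult(scores, eig, vt.T, geno.samples.copy(), np.flatnonzero(poly))


def match_controls(case_scores: np.ndarray, control_scores: np.ndarray,
                   case_ids, control_ids, k: int = 5) -> MatchResult:
    """Greedy 1:k nearest-neighbour matching in PC1-2 without replacement.

    Each case takes its ``k`` nearest unused controls.  Cases are ordered
    by descending local control density (inverse distance to the k-th
    nearest control), ties by case id.  A case that cannot receive ``k``
    controls is reported unmatchable (it keeps none).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    cs = np.asarray(case_scores, dtype=float)[:, :2]
    xs = np.asarray(control_scores, dtype=float)[:, :2]
    case_ids = list(case_ids)
    control_ids = list(control_ids)
    if len(case_ids) != len(cs) or len(control_ids) != len(xs):
        raise ValueError("id/score length mismatch")
    tree = cKDTree(xs)
    kk = min(k, len(xs))
    d_k, _ = tree.query(cs, k=kk)
    d_k = np.atleast_2d(d_k)[:, -1] if kk > 1 else np.asarray(d_k).ravel()
    order = sorted(range(len(case_ids)),
                   key=lambda i: (d_k[i], str(case_ids[i])))
    used = np.zeros(len(xs), dtype=bool)
    assignments, distances, unmatchable = {}, {}, []
    for i in order:
        picked, pdist = [], []
        query = 2 * k
        while len(picked) < k and query <= 4 * len(xs):
            dd, jj = tree.query(cs[i], k=min(query, len(xs)))
            dd, jj = np.atleast_1d(dd), np.atleast_1d(jj)
            for d_ij, j in zip(dd, jj):
                if not used[j] and j not in picked:
                    picked.append(int(j))
                    pdist.append(float(d_ij))
                    if len(picked) == k:
                        break
            if query >= len(xs):
                break
            query *= 2
        if len(picked) < k:
            unmatchable.append(case_ids[i])
            continue
        used[picked] = True
        assignments[case_ids[i]] = [control_ids[j] for j in picked]
        distances[case_ids[i]] = pdist
    # report in original case order
    assignments = {cid: assignments[cid] for cid in case_ids if cid in assignments}
    distances = {cid: distances[cid] for cid in case_ids if cid in distances}
    return MatchResult(assignments, distances, unmatchable, k)
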