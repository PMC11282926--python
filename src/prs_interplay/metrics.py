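"""Discrimination and reclassification metrics.

* AUC as the Mann-Whitney probability with ties counted 1/2, analytic CI
  by the DeLong placement-variance estimator;
* the closed-form binormal AUC of a standardized score with per-SD odds
  ratio OR: Phi(log(OR)/sqrt(2)) (equal-variance normal model in the
  rare-disease limit);
* pairwise-concordance composition of a dominant binary predictor with a
  continuous score that breaks smoking-concordant ties;
* Nagelkerke pseudo-R^2 (Cox-Snell rescaled), switchable to McFadden;
* the continuous (category-free) net reclassification index with a
  seeded percentile-bootstrap CI.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ROCResult",
    "NRIResult",
    "auc",
    "binormal_auc",
    "compose_concordance",
    "pseudo_r2",
    "continuous_nri",
]

Z95 = 1.959963984540054


@dataclass
class ROCResult:
    auc: float
    ci95: tuple
    n_cases: int
    n_controls: int
    curve: pd.DataFrame  # fpr, tpr

    def to_tsv(self, path: str) -> None:
        self.curve.to_csv(path, sep="\t", index=False)


@dataclass
class NRIResult:
    overall: float
    event: float  # net proportion of cases moving up
    non_event: float  # net proportion of controls moving down
    ci95: tuple
    n_boot: int
    seed: int


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def auc(case_scores, control_scores) -> ROCResult:
    """Mann-Whitney AUC with DeLong variance for the 95% CI."""
    from sklearn.metrics import roc_curve

    cases = np.asarray(case_scores, dtype=float)
    ctrls = np.asarray(control_scores, dtype=float)
    m, n = len(cases), len(ctrls)
    if m == 0 or n == 0:
        raise ValueError("both classes must be non-empty")
    combined = np.concatenate([cases, ctrls])
    r_all = _midranks(combined)
    r_cases = _midranks(cases)
    r_ctrls = _midranks(ctrls)
    a = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    # DeLong placements
    v10 = (r_all[:m] - r_cases) / n  # per-case placement
    v01 = 1.0 - (r_all[m:] - r_ctrls) / m  # per-control placement
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0)
    half = Z95 * np.sqrt(var)
    y = np.concatenate([np.ones(m), np.zeros(n)])
    fpr, tpr, _ = roc_curve(y, combined)
    return ROCResult(float(a), (float(a - half), float(a + half)), m, n,
                     pd.DataFrame({"fpr": fpr, "tpr": tpr}))


def binormal_auc(or_per_sd: float) -> float:
    """AUC implied by a per-SD odds ratio under the equal-variance
    binormal model (case and control scores unit normal, means shifted by
    log OR; rare-disease limit)."""
    if or_per_sd <= 0:
        raise ValueError("odds ratio must be positive")
    return float(stats.norm.cdf(np.log(or_per_sd) / np.sqrt(2.0)))


def compose_concordance(auc_within: float, p_case_pos: float,
                        p_ctrl_pos: float) -> float:
    """AUC of a model where a binary predictor dominates and a continuous
    score (independent of the binary one, AUC ``auc_within`` in each
    stratum) orders pairs concordant on the binary predictor.

    AUC = P(case+, control-) + P(concordant pair) * auc_within.
    """
    for v, name in ((auc_within, "auc_within"), (p_case_pos, "p_case_pos"),
                    (p_ctrl_pos, "p_ctrl_pos")):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1]")
    concordant = p_case_pos * p_ctrl_pos + (1 - p_case_pos) * (1 - p_ctrl_pos)
    return float(p_case_pos * (1 - p_ctrl_pos) + concordant * auc_within)


def pseudo_r2(llf: float, llnull: float, nobs: int,
              method: str = "nagelkerke") -> float:
    """Pseudo-R^2 of a fitted logistic model.

    Nagelkerke (default): Cox-Snell rescaled to a [0, 1] maximum;
    ``method="mcfadden"`` gives 1 - llf/llnull.
    """
    if method == "mcfadden":
        return float(1.0 - llf / llnull)
    if method != "nagelkerke":
        raise ValueError("method must be 'nagelkerke' or 'mcfadden'")
    cox_snell = 1.0 - np.exp(2.0 * (llnull - llf) / nobs)
    max_cs = 1.0 - np.exp(2.0 * llnull / nobs)
    return float(cox_snell / max_cs)


def continuous_nri(p_baseline, p_augmented, outcome, n_boot: int = 1000,
                   seed: int = 0) -> NRIResult:
    """Continuous (category-free) net reclassification index.

    event component = P(up | case) - P(down | case); non-event component
    = P(down | control) - P(up | control); overall is their sum.  Exact
    ties count as neither direction.  The CI is a seeded percentile
    bootstrap over samples.
    """
    p0 = np.asarray(p_baseline, dtype=float)
    p1 = np.asarray(p_augmented, dtype=float)
    y = np.asarray(outcome, dtype=int)
    if not (len(p0) == len(p1) == len(y)):
        raise ValueError("input lengths differ")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")

    def components(idx):
        up = p1[idx] > p0[idx]
        down = p1[idx] < p0[idx]
        cy = y[idx]
        case = cy == 1
        ctrl = cy == 0
        ev = (up[case].mean() - down[case].mean()) if case.any() else 0.0
        ne = (down[ctrl].mean() - up[ctrl].mean()) if ctrl.any() else 0.0
        return float(ev), float(ne)

    all_idx = np.arange(len(y))
    ev, ne = components(all_idx)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, len(y), size=len(y))
        bev, bne = components(idx)
        boots[b] = bev + bne
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return NRIResult(ev + ne, ev, ne, (float(lo), float(hi)), n_boot, seed)
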