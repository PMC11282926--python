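"""Integrated risk model with a statsmodels-style Model/Results interface.

``RiskModel`` assembles a logistic case-control model from a phenotype
table (standardized PRS, smoking, age, sex, BMI, ancestry PCs in any
combination); ``fit()`` returns a ``RiskModelResults`` carrying the
coefficient table with Wald odds ratios, the model AUC with its DeLong
interval, Nagelkerke R^2, and comparison utilities (likelihood-ratio
test and continuous NRI against a nested model).

Example
-------
>>> model = RiskModel.from_dataframe(df, prs="z", covariates=["age", "sex"],
...                                  smoking="smoking")
>>> res = model.fit()
>>> print(res.summary())
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import assoc, metrics

__all__ = ["RiskModel", "RiskModelResults"]


class RiskModel:
    """Logistic case-control risk model specification.

    Samples with missing smoking are excluded whenever smoking is in the
    model; an optional multiplicative PRS-by-smoking term can be added.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, term_names,
                 label: str = "risk model"):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.term_names = list(term_names)
        self.label = label

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outcome: str = "status",
                       prs: str | None = "z", smoking: str | None = None,
                       covariates=(), interaction: bool = False,
                       label: str | None = None) -> "RiskModel":
        cols = []
        names = []
        use = df
        if smoking is not None:
            use = df.dropna(subset=[smoking])
        if prs is not None:
            cols.append(use[prs].to_numpy(float))
            names.append(prs)
        if smoking is not None:
            cols.append(use[smoking].to_numpy(float))
            names.append(smoking)
        if interaction:
            if prs is None or smoking is None:
                raise ValueError("interaction requires both PRS and smoking")
            cols.append(use[prs].to_numpy(float) * use[smoking].to_numpy(float))
            names.append(f"{prs}_x_{smoking}")
        for c in covariates:
            cols.append(use[c].to_numpy(float))
            names.append(c)
        if not cols:
            raise ValueError("empty model specification")
        X = np.column_stack(cols)
        y = use[outcome].to_numpy(float)
        model = cls(y, X, names, label or " + ".join(names))
        model._source_index = use.index.to_numpy()
        return model

    def fit(self) -> "RiskModelResults":
        lf = assoc.fit_logistic(self.y, self.X, names=self.term_names,
                                model_label=self.label)
        roc = metrics.auc(lf.fitted[self.y == 1], lf.fitted[self.y == 0])
        r2 = metrics.pseudo_r2(lf.llf, lf.llnull, lf.nobs)
        return RiskModelResults(self, lf, roc, r2)


@dataclass
class RiskModelResults:
    model: RiskModel
    fit: assoc.LogisticFit
    roc: metrics.ROCResult
    r2: float
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def params(self) -> pd.Series:
        return pd.Series({t.term: t.beta for t in self.fit.terms.values()})

    @property
    def auc(self) -> float:
        return self.roc.auc

    def or_table(self) -> pd.DataFrame:
        rows = self.fit.result_rows()
        return rows[rows.term != "intercept"].reset_index(drop=True)

    def predicted(self) -> np.ndarray:
        return self.fit.fitted

    def compare(self, nested: "RiskModelResults", n_boot: int = 1000,
                seed: int = 0):
        """LRT and continuous NRI of this model against a nested one.

        Both models must have been fitted on the identical samples.
        Returns ``(lrt_stat, df, p, NRIResult)``.
        """
        stat, df, p = assoc.likelihood_ratio_test(nested.fit, self.fit)
        nri = metrics.continuous_nri(nested.predicted(), self.predicted(),
                                     self.model.y, n_boot=n_boot, seed=seed)
        return stat, df, p, nri

    def summary(self) -> str:
        lines = [
            f"Risk model: {self.model.label}",
            f"n = {self.fit.nobs} ({int(self.model.y.sum())} cases)",
            f"log-likelihood = {self.fit.llf:.2f}  "
            f"Nagelkerke R2 = {self.r2:.3f}",
            f"AUC = {self.roc.auc:.3f} "
            f"(95% CI {self.roc.ci95[0]:.3f}-{self.roc.ci95[1]:.3f})",
            "",
            f"{'term':<16}{'beta':>9}{'SE':>8}{'OR':>8}"
            f"{'CI low':>9}{'CI high':>9}{'P':>12}",
        ]
        for t in self.fit.terms.values():
            if t.term == "intercept":
                continue
            lo, hi = t.ci95
            lines.append(
                f"{t.term:<16}{t.beta:>9.3f}{t.se:>8.3f}{t.odds_ratio:>8.2f}"
                f"{lo:>9.2f}{hi:>9.2f}{t.p:>12.3g}")
        return "\n".join(lines)
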