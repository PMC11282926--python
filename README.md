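# prs-interplay

A case-control polygenic-risk-score (PRS) analysis pipeline for binary
disease outcomes with a dominant environmental risk factor — the
motivating setting is lung cancer, where a standardized genome-wide PRS
(per-SD odds ratio ~1.33) coexists with an ever-smoking effect an order
of magnitude larger (OR ~9.7).  The package provides everything needed
to run and stress-test that analysis without any real cohort data:

* a **synthetic cohort generator** (Balding–Nichols population
  structure, HWE genotypes, a logistic disease model
  `logit P(case) = α + β·z + β_s·smoke + γ·z·smoke`, retrospective
  case-control sampling, and injectable QC artifacts with ground truth);
* **genotype QC** with standard array thresholds (variant call rate
  ≥ 0.97, Hardy–Weinberg exact P ≥ 1e-7 in controls, MAF ≥ 1%, sample
  completion ≥ 95%, inbreeding-coefficient outliers beyond 10 SD,
  duplicate/first-degree removal by KING-robust kinship) and the
  post-imputation filter INFO ≥ 0.3, MAF ≥ 0.001, MAF·INFO·n_cases ≥ 10;
* **ancestry matching**: PCA of the standardized dosage matrix and
  greedy 5:1 nearest-neighbour control matching in PC1–PC2;
* **PRS construction**: PGS-Catalog-style scoring files, allele
  harmonization (sign flips, strand complements, palindromic drops, LD
  proxies at r² > 0.5), weighted/unweighted scoring, combined-cohort
  standardization, quintiles and low/intermediate/high (20th/80th
  percentile) genetic-risk groups;
* **association models**: logistic regression with Wald OR/CI (a
  statsmodels-style `RiskModel`/`RiskModelResults` front-end), raw 2×2
  ORs with Woolf intervals, a vectorized covariate-adjusted score-test
  scan with genomic inflation λ, PRS×smoking interaction and likelihood
  ratio tests, stratified/joint odds tables, and the observed→liability
  heritability conversion;
* **metrics**: Mann–Whitney AUC with DeLong CI, the binormal closed form
  `AUC = Φ(ln OR_SD / √2)`, concordance composition for a dominant
  binary predictor, Nagelkerke R², and the continuous net
  reclassification index (NRI) with bootstrap CI.

## Worked example

Simulate the reference study (4002 cases, 20,010 controls, per-SD OR
1.33, smoking OR 9.7, no interaction) and fit the integrated model:

```python
from prs_interplay import RiskModel
from prs_interplay.simulate import SimConfig, simulate_case_control_scores

df = simulate_case_control_scores(SimConfig(n_cases=4002, n_controls=20010, seed=1))
res = RiskModel.from_dataframe(df, prs="z", smoking="smoking",
                               label="PRS + smoking").fit()
print(res.summary())
```

```
Risk model: PRS + smoking
n = 24012 (4002 cases)
log-likelihood = -9594.79  Nagelkerke R2 = 0.163
AUC = 0.721 (95% CI 0.713-0.729)

term                 beta      SE      OR   CI low  CI high           P
z                   0.283   0.018    1.33     1.28     1.38    2.61e-53
smoking             2.322   0.064   10.19     8.98    11.57   8.16e-284
```

The fitted per-SD OR recovers the generating value 1.33 (SE 0.018), the
smoking OR its generating 9.7 within sampling error, and the model AUC
(0.721) sits at the value implied by concordance composition of the two
independent components (0.719).  Comparing against the smoking-only
model:

```python
base = RiskModel.from_dataframe(df, prs=None, smoking="smoking").fit()
stat, d, p, nri = res.compare(base, n_boot=200, seed=1)
```

```
LRT vs smoking-only: stat=240.7 df=1 p=2.7e-54
NRI=0.21 (events 0.100, non-events 0.108)
```

i.e. adding the PRS moves a net 10% of cases up and ~11% of controls
down in predicted risk.

The full pipeline (simulate → QC → PCA → matching → post-imputation
filter → scoring → models → stratified tables → metrics) runs from the
shell and writes a reproducible report bundle:

```bash
prs-interplay run --config demo.yaml --seed 42 --out results/demo
```

with TSV reports for the cohort summary, risk-group counts, model
coefficients, quintile/tail ORs, the PRS×smoking stratified/joint odds
table, and discrimination metrics.  `prs-interplay --help` lists the
stage-level subcommands (`simulate`, `qc`, `match`, `score`, `assoc`,
`evaluate`, `validate`).

## Layout

```
src/prs_interplay/
  simulate.py   cohort generator + ground truth
  qc.py         variant/sample QC, HWE exact test, kinship
  match.py      PCA + greedy 5:1 matching
  prs.py        harmonization, scoring, risk groups
  assoc.py      logistic/2x2 models, scan, liability conversion
  metrics.py    AUC/DeLong, NRI, pseudo-R2, composition
  model.py      RiskModel / RiskModelResults
  pipeline.py   end-to-end orchestration
  cli.py        command-line interface
docs/methods.md  model and design notes
```
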