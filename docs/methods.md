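# Methods

## The analysis this package implements

The pipeline reproduces, on synthetic data, a retrospective case-control
evaluation of a standardized polygenic risk score (PRS) for a disease
with one dominant environmental risk factor.  The estimands are odds
ratios: per SD of the PRS, across PRS quintiles and 20/80-percentile
genetic-risk groups, within smoking strata, and for joint
(smoking × genetic-risk) cells against the never-smoking low-risk
reference; discrimination is summarized by ROC AUC, variance explained
by Nagelkerke R², and incremental value by the likelihood-ratio test and
the continuous net reclassification index.

## Generative model

Genotypes: each variant has an ancestral allele frequency drawn
uniformly from `maf_range`; subpopulation frequencies follow a
Balding–Nichols draw, Beta(p(1−F)/F, (1−p)(1−F)/F), whose variance is
F·p(1−p) for drift parameter F (`divergence`, default 0.01 across two
subpopulations — the minimal structure that makes PC matching
meaningful).  Within a subpopulation genotypes are Hardy–Weinberg draws,
coded as ALT-allele dosages 0/1/2.

The true score is a weighted sum of dosages with standard-normal causal
weights, standardized to mean 0, SD 1 in the source population.  Disease
follows the logistic model

    logit P(case) = logit(baseline_prev) + β·z + ln(OR_smoke)·smoke + γ·z·smoke

with reference values β = ln 1.33, OR_smoke = 9.7, γ = 0 (odds
multiplicativity holds exactly when γ = 0), and baseline prevalence
0.041 at the covariate reference.  Cases and controls are then sampled
to quota from the population (retrospective design: odds ratios, not
hazard ratios, are the estimands, and slope coefficients of a logistic
model are preserved under outcome-dependent sampling).

Two calibration points deserve note:

* **Smoking prevalence.** The population ever-smoking probability
  defaults to 0.653, solved by quadrature so that the control stratum of
  the retrospective sample lands at 58.0% ever-smokers under the
  reference odds ratios (cases then come out near 93%).  Controls are
  depleted of smokers relative to the population because smokers are
  preferentially ascertained as cases.  A further 1.3% of controls have
  smoking set to missing (cases, being a clinical series, are complete).
* **Non-collapsibility.** The per-SD odds ratio β is a conditional
  effect.  Marginalizing a logistic model over a binary factor with OR
  9.7 attenuates the score coefficient substantially (to ~1.26 at these
  settings), even with score ⊥ smoking.  Recovery checks therefore fit
  the generating mean structure (score + smoking); a univariable fit is
  *expected* to read low, and does.

Smoking is independent of the score by default (this makes closed-form
checks exact; a nonzero `gamma_interaction` departs from odds
multiplicativity).  Age, sex and BMI are drawn from case/control
normal/Bernoulli marginals that mimic an older surgical case series
against a younger population cohort; they carry no causal effect on
disease, so only their moments — not their shapes or correlations — are
meaningful.  QC artifacts (duplicates, parent-offspring pairs built by
allele transmission, all-heterozygote variants, sub-0.3 INFO values,
Bernoulli genotype missingness) are injected on request and recorded in
the ground-truth record.

### What the generator does *not* emulate

No linkage disequilibrium beyond optional correlated pairs, no
haplotype phasing, no X chromosome, no genotype-intensity artifacts, no
real imputation (INFO is simply a per-variant number), and covariates
without realistic mutual correlation.  Passing tests therefore certify
the statistical machinery under the stated model, not robustness to the
full messiness of array data.

## Quality control

Variant rules, in fixed precedence (first failure is the cited reason):
call rate < 0.97; Hardy–Weinberg exact P < 1e-7 — computed in controls
only, since true associations distort genotype frequencies in cases;
MAF < 1%; duplicated chrom:pos (first occurrence kept).  The HWE test is
the exact conditional (on allele counts) two-sided test without mid-p,
evaluated by the stable two-directional recurrence from the modal
heterozygote count; it matches a direct log-factorial enumeration to
1e-12 over every configuration with ≤ 200 alleles.

Sample rules, in order: call rate < 0.95; inbreeding coefficient
F = 1 − observed/expected heterozygosity more than 10 SD from the cohort
mean; relatedness; PC outliers (any of the supplied components beyond
`pca_outlier_sd` SD — an internal substitute for an external reference-
panel check, default 6).  Relatedness is flagged on KING-robust kinship
φ = (N_het_both − 2·N_opposite_hom)/(N_het_i + N_het_j) with the
standard first-degree cutoff 0.177 (duplicates ≈ 0.5, parent-offspring
≈ 0.25, unrelated ≈ 0); the raw mean-IBS similarity (2−|d_i−d_j|)/2 is
also provided but its null value depends on the MAF spectrum, which is
why the kinship estimator drives removal.  Kinship needs on the order of
1,000+ variants for the 0.177 cutoff to be reliable (at 300 variants its
null SD is ~0.05 and false positives appear).  From each flagged pair
the member with the higher call rate is kept; ties break by sample id.

Post-imputation filter: INFO < 0.3, MAF < 0.001, or
MAF·INFO·n_cases < 10.

## Matching

PCA standardizes each variant column by (d − 2p)/√(2p(1−p)) with
missing entries mean-imputed, and takes the SVD; component signs are
fixed deterministically (largest-magnitude loading positive).  Matching
uses PC1–PC2 only (ancestry axes), while 10 PCs are available as model
covariates.  Controls are assigned greedily without replacement, k = 5
per case; cases are processed in descending local control density
(inverse distance to the k-th nearest control, ties by id), which
protects cases in sparse regions and makes the output deterministic and
input-order invariant.  Global-optimal (Hungarian) matching is out of
scope; on clustered toy data the greedy result coincides with the
minimum-cost assignment.

## PRS construction

Harmonization aligns scoring-file entries to cohort REF/ALT by
chrom:pos: effect = ALT is used as-is; effect = REF contributes
w·(2−d); entries matching only after strand complement are complemented
first; palindromic (A/T, C/G) entries are dropped outright because
frequency-based orientation is silent when wrong; entries absent from
the cohort may be replaced by the best in-window LD proxy (maximal
squared Pearson dosage correlation, r² > 0.5, ±500 kb — the r²
threshold is the analysis rule, the window a conventional default), with
the effect allele re-oriented by the correlation sign.  Harmonization is
involution-safe and every entry is logged exactly once.  Missing
dosages are imputed as 2 × effect-allele frequency (per-sample
renormalization was the rejected alternative; mean imputation keeps the
score linear in the observed data and is logged).  Multiple published
effect sizes for one locus merge by the median.

Standardization and all percentile groupings use the **combined**
cases+controls distribution — identified as the convention because the
published group totals split the combined cohort exactly 20/60/20
(4803/14406/4803 of 24,012).  Groups are rank-based so the partition is
exact: low = lowest ceil(0.2n), high = highest ceil(0.2n), quintile
boundaries at ceil(k·n/5), tails strictly above the 90th/95th/99th
ranks.

## Association and metrics

Logistic fits are maximum likelihood (statsmodels) with Wald intervals
exp(β ± 1.96·SE); raw 2×2 tables use the cross-product OR with Woolf
variance 1/a+1/b+1/c+1/d; zero cells raise rather than silently apply a
continuity correction.  Complete separation raises an error naming the
term.  Samples with missing smoking are excluded from any model
containing smoking.  α = 0.05 two-sided; genome-wide threshold 5e-8.

The per-variant scan fits the covariate-only null once and computes the
efficient score test per variant (vectorized); a per-variant Wald refit
is available as `method="wald"`.  The mixed-model machinery of the
original association software is deliberately not reproduced: after QC
the synthetic cohorts contain no cryptic relatedness, so a plain
covariate-adjusted logistic test is calibrated (null λ within
[0.95, 1.05] at 10⁴ variants).  λ = median(χ²)/median(χ²₁), the latter
0.45494.

Single-variant effects convert to the per-SD scale by
exp(ln OR · √(2p(1−p))) — the dosage SD under HWE.  Observed-scale
heritability converts to the liability scale by
h²·K²(1−K)²/(P(1−P)·z²) with z the normal density at the (1−K)
quantile (population prevalence K = 0.041, sample prevalence P = 0.167
in the reference analysis).

AUC is the Mann–Whitney probability (ties ½) with the analytic DeLong
variance for its CI — chosen over bootstrap for determinism and speed.
The binormal closed form Φ(ln OR_SD/√2) is the equal-variance,
rare-disease-limit AUC of a standardized score.  The concordance
composition
`AUC = p₁(1−p₀) + [p₁p₀ + (1−p₁)(1−p₀)]·AUC_within`
treats the binary factor as dominating the model score and the PRS as
breaking smoking-concordant ties, assuming independence; it is a
consistency check, not a replication of any fitted model.  Pseudo-R² is
Nagelkerke by default (the convention of the benchmarking literature),
switchable to McFadden.  The continuous NRI is
[P(up|case) − P(down|case)] + [P(down|control) − P(up|control)], ties
counting as neither, with a seeded percentile bootstrap (default 1,000
replicates) for its CI.

## Numerical and design choices

* All randomness flows from a single root seed; fixed seed ⇒
  byte-identical output files.
* Exclusion reasons use fixed rule precedence so QC reports are
  deterministic; QC is idempotent on its own output.
* The joint-risk simulator used for the multiplicativity check cuts a
  standard-normal score at its 20th/80th quantiles and assigns
  main-effect group coefficients (ln 1.46 intermediate, ln 2.20 high)
  plus ln 7.73 for smoking.  Because cell odds ratios of a categorical
  logistic model do not depend on the baseline risk or the smoking
  prevalence, those two free parameters (0.2 and 0.5) are set to balance
  the four cells of the (ever,high) vs (never,low) contrast and thereby
  minimize Monte-Carlo error at fixed n.
* Problem sizes in the test suite (e.g. 10⁴-variant null scans, 1,000
  interaction replicates at 6,000 samples, 50 recovery seeds at
  4,002/20,010, 2×10⁵ individuals for the joint-odds check) are chosen
  so the whole suite runs in minutes on one CPU while keeping
  Monte-Carlo error well inside the asserted tolerances.

## Known limitations

Real-data quantities that depend on genome-scale LD structure (the
reported inflation factor 0.989, liability heritability, genome-wide
scan hits) are not reproducible at desk scale and are covered only by
calibration and recovery properties.  The matcher is greedy, not
globally optimal.  The PC-outlier rule is internal (SD-based), not
referenced to an external panel.  Unweighted scores define the risk
allele by the sign of the supplied weight.  The concordance composition
assumes PRS ⊥ smoking and a dominant binary effect; with a fitted model
whose smoking coefficient were small the composition would overstate
the tie-breaking structure.
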