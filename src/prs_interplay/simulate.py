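"""Synthetic case-control cohort generator.

The generator emulates the statistical structure the downstream analysis
assumes:

* genotypes in Hardy-Weinberg equilibrium within each subpopulation, with
  between-subpopulation allele-frequency spread following a
  Balding-Nichols drift model (subpopulation frequency drawn from a Beta
  distribution around the ancestral frequency with variance
  ``F * p * (1 - p)``);
* a standard-normal true polygenic score built from per-variant causal
  weights;
* a retrospective case-control design: disease is assigned in the
  population from the logistic model

      logit P(case) = alpha + beta_prs * z + log(or_smoking) * smoke
                      + gamma * z * smoke

  and cases/controls are then sampled until the configured quotas are met
  (the estimands are odds ratios, so case enrichment is harmless);
* non-causal age/sex/BMI covariates drawn from case/control marginals
  mimicking a surgical case series versus a younger population cohort;
* optional QC artifacts: genotype missingness, duplicated samples,
  first-degree relatives, variants forced out of Hardy-Weinberg
  equilibrium, and low imputation-INFO variants, all listed in the
  ground-truth record.

Reference effect sizes: per-SD odds ratio 1.33 for the score and odds
ratio 9.7 for ever-smoking.  The default population ever-smoking
probability (0.653) is calibrated by quadrature so that, under the
reference odds ratios and baseline prevalence, retrospective sampling
yields ever-smoking prevalences of about 93% in cases and 58.0% in
controls (controls are depleted of smokers relative to the population
because smokers are preferentially ascertained as cases).

Note on recovery: the per-SD odds ratio is a conditional (smoking-
adjusted) effect.  A univariable fit of case status on the score is
attenuated by non-collapsibility of the logistic model when the omitted
smoking effect is this strong; recovering beta_prs requires fitting the
generating mean structure (score + smoking).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .containers import Cohort, GenotypeMatrix

__all__ = [
    "SimConfig",
    "ArtifactConfig",
    "TruthRecord",
    "simulate_genotypes",
    "assign_phenotypes",
    "inject_artifacts",
    "simulate_cohort",
    "simulate_case_control_scores",
    "simulate_joint_risk_cohort",
    "write_cohort",
]

# re-export: writing lives in io but the simulator owns the round-trip contract
from .io import write_cohort  # noqa: E402  (import placed after docstring intentionally)


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults are the reference conditions of the analysis: a 4002-case /
    20,010-control study with a per-SD score odds ratio of 1.33, an
    ever-smoking odds ratio of 9.7 at 58% population smoking prevalence,
    no score-by-smoking interaction, and a baseline disease probability
    of 4.1% at the covariate reference.
    """

    n_cases: int = 4002
    n_controls: int = 20010
    n_variants: int = 1000
    maf_range: tuple = (0.05, 0.5)
    n_subpops: int = 2
    divergence: float = 0.01
    beta_prs: float = float(np.log(1.33))
    or_smoking: float = 9.7
    gamma_interaction: float = 0.0
    smoking_prev_pop: float = 0.653
    baseline_prev: float = 0.041
    missing_rate: float = 0.0
    seed: int = 0
    # smoking status is recorded as missing for this fraction of controls
    # (cases come from a clinical series with complete smoking history)
    smoking_missing_rate: float = 0.013
    # case / control marginals for the non-causal covariates
    age_case: tuple = (64.7, 8.78)
    age_control: tuple = (54.6, 7.85)
    bmi_case: tuple = (26.7, 5.25)
    bmi_control: tuple = (27.6, 5.90)
    male_frac_case: float = 0.481
    male_frac_control: float = 0.453

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be >= 1")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be >= 1")
        if not (0.0 <= self.divergence < 1.0):
            raise ValueError("divergence must be in [0, 1)")
        for name in ("smoking_prev_pop", "baseline_prev", "missing_rate",
                     "smoking_missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if self.or_smoking <= 0:
            raise ValueError("or_smoking must be positive")


@dataclass
class ArtifactConfig:
    """How many QC artifacts to inject (all recorded in the truth record)."""

    n_duplicates: int = 0
    n_relatives: int = 0
    n_hwe_violations: int = 0
    n_low_info: int = 0


@dataclass
class TruthRecord:
    """Ground truth of a simulated cohort, for recovery tests."""

    ancestral_freq: np.ndarray = None
    subpop_freq: np.ndarray = None  # (n_subpops, n_variants)
    causal_weight: np.ndarray = None
    subpop: np.ndarray = None  # per final sample
    true_score: np.ndarray = None  # standardized, per final sample
    linear_predictor: np.ndarray = None  # liability-scale eta per sample
    config: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        def enc(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            return x

        payload = {k: enc(v) for k, v in asdict(self).items()}
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str) -> "TruthRecord":
        with open(path) as fh:
            payload = json.load(fh)
        tr = cls(**payload)
        for name in ("ancestral_freq", "subpop_freq", "causal_weight",
                     "subpop", "true_score", "linear_predictor"):
            v = getattr(tr, name)
            if v is not None:
                setattr(tr, name, np.asarray(v))
        return tr


def _rng(config_or_seed) -> np.random.Generator:
    if isinstance(config_or_seed, np.random.Generator):
        return config_or_seed
    return np.random.default_rng(config_or_seed)


def _draw_subpop_freqs(p_anc: np.ndarray, n_subpops: int, F: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols draw: Beta(p(1-F)/F, (1-p)(1-F)/F) per subpopulation."""
    if n_subpops == 1 or F == 0.0:
        return np.tile(p_anc, (n_subpops, 1))
    a = p_anc * (1.0 - F) / F
    b = (1.0 - p_anc) * (1.0 - F) / F
    out = rng.beta(a[None, :], b[None, :], size=(n_subpops, len(p_anc)))
    # keep frequencies polymorphic so dosage variance never collapses to 0
    return np.clip(out, 1e-4, 1.0 - 1e-4)


def simulate_genotypes(config: SimConfig, n_samples: int | None = None,
                       rng: np.random.Generator | None = None):
    """Draw HWE genotypes for ``n_samples`` individuals.

    Within each subpopulation every variant is in Hardy-Weinberg
    equilibrium at its drifted frequency; dosages are ALT-allele counts.
    Returns ``(GenotypeMatrix, TruthRecord)`` — the truth record carries
    ancestral and subpopulation frequencies, causal weights, subpopulation
    labels and the standardized true score.
    """
    rng = _rng(config.seed if rng is None else rng)
    if n_samples is None:
        n_samples = config.n_cases + config.n_controls
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    m = config.n_variants
    lo, hi = config.maf_range
    p_anc = rng.uniform(lo, hi, size=m)
    subpop_freq = _draw_subpop_freqs(p_anc, config.n_subpops, config.divergence, rng)
    subpop = rng.integers(0, config.n_subpops, size=n_samples)
    dosages = rng.binomial(2, subpop_freq[subpop, :]).astype(float)

    weights = rng.normal(size=m)
    raw = dosages @ weights
    sd = raw.std()
    if sd == 0:
        sd = 1.0
    z = (raw - raw.mean()) / sd

    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, m + 1) * 1000,
            "id": [f"rs{j + 1}" for j in range(m)],
            "ref": "A",
            "alt": "G",
            "info": 1.0,
        }
    )
    samples = np.asarray([f"S{i + 1:06d}" for i in range(n_samples)], dtype=object)
    geno = GenotypeMatrix(dosages, samples, variants)
    truth = TruthRecord(
        ancestral_freq=p_anc,
        subpop_freq=subpop_freq,
        causal_weight=weights,
        subpop=subpop,
        true_score=z,
        config=asdict(config),
    )
    return geno, truth


def _population_phenotypes(z: np.ndarray, config: SimConfig,
                           rng: np.random.Generator):
    """Smoking, linear predictor and disease status for a population."""
    n = len(z)
    smoke = rng.random(n) < config.smoking_prev_pop
    if config.baseline_prev == 0.0:
        eta = np.full(n, -np.inf)
    else:
        eta = (
            logit(config.baseline_prev)
            + config.beta_prs * z
            + np.log(config.or_smoking) * smoke
            + config.gamma_interaction * z * smoke
        )
    y = rng.random(n) < expit(eta)
    return smoke.astype(int), eta, y.astype(int)


def _covariates(status: np.ndarray, config: SimConfig, rng: np.random.Generator):
    n = len(status)
    is_case = status == 1
    age = np.where(
        is_case,
        rng.normal(*config.age_case, size=n),
        rng.normal(*config.age_control, size=n),
    )
    bmi = np.where(
        is_case,
        rng.normal(*config.bmi_case, size=n),
        rng.normal(*config.bmi_control, size=n),
    )
    male = np.where(
        is_case,
        rng.random(n) < config.male_frac_case,
        rng.random(n) < config.male_frac_control,
    ).astype(int)
    return age, bmi, male


def assign_phenotypes(geno: GenotypeMatrix, config: SimConfig,
                      truth: TruthRecord,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Assign disease, smoking and covariates; sample cases/controls to quota.

    The genotype matrix is treated as the source population: disease is
    drawn from the logistic model on the standardized true score, then
    ``n_cases`` cases and ``n_controls`` controls are sampled without
    replacement.  Raises if the population cannot meet a quota (e.g. a
    baseline prevalence of 0 with ``n_cases > 0``).

    Returns the phenotype table of the selected samples; the matching
    genotype subset is ``geno.subset(sample_idx=pheno.attrs['row_idx'])``.
    """
    rng = _rng(config.seed + 1 if rng is None else rng)
    z = truth.true_score
    if z is None or len(z) != geno.n_samples:
        raise ValueError("truth.true_score must match the genotype matrix")
    smoke, eta, y = _population_phenotypes(z, config, rng)
    case_idx = np.flatnonzero(y == 1)
    ctrl_idx = np.flatnonzero(y == 0)
    if len(case_idx) < config.n_cases:
        raise ValueError(
            f"population of {geno.n_samples} yielded {len(case_idx)} cases; "
            f"cannot meet quota of {config.n_cases}"
        )
    if len(ctrl_idx) < config.n_controls:
        raise ValueError(
            f"population yielded {len(ctrl_idx)} controls; cannot meet quota "
            f"of {config.n_controls}"
        )
    sel = np.concatenate(
        [
            rng.choice(case_idx, size=config.n_cases, replace=False),
            rng.choice(ctrl_idx, size=config.n_controls, replace=False),
        ]
    )
    status = y[sel]
    age, bmi, male = _covariates(status, config, rng)
    smoking = smoke[sel].astype(float)
    if config.smoking_missing_rate > 0:
        miss = (status == 0) & (rng.random(len(sel)) < config.smoking_missing_rate)
        smoking[miss] = np.nan
    pheno = pd.DataFrame(
        {
            "sample_id": geno.samples[sel],
            "status": status,
            "age": np.round(age, 2),
            "sex": male,
            "bmi": np.round(bmi, 2),
            "smoking": smoking,
        }
    )
    pheno.attrs["row_idx"] = sel
    # restrict the truth record to the selected samples
    truth.subpop = truth.subpop[sel]
    truth.true_score = z[sel]
    truth.linear_predictor = eta[sel]
    return pheno


def simulate_cohort(config: SimConfig,
                    artifacts: ArtifactConfig | None = None) -> Cohort:
    """Generate a complete case-control cohort meeting the configured quotas.

    Sizes the source population from a quick Monte-Carlo estimate of the
    disease prevalence, then draws additional batches if a quota is missed.
    Deterministic given ``config.seed``.
    """
    rng = _rng(config.seed)
    if config.baseline_prev == 0.0 and config.n_cases > 0:
        raise ValueError("baseline_prev=0 cannot produce cases")
    # crude prevalence estimate on the score scale only
    z0 = rng.standard_normal(50_000)
    _, _, y0 = _population_phenotypes(z0, config, rng)
    prev = max(float(y0.mean()), 1e-4)
    need = max(config.n_cases / prev, config.n_controls / max(1 - prev, 1e-4))
    n_pool = int(need * 1.25) + 100

    for attempt in range(5):
        geno, truth = simulate_genotypes(config, n_samples=n_pool, rng=rng)
        try:
            pheno = assign_phenotypes(geno, config, truth, rng=rng)
        except ValueError:
            n_pool *= 2
            continue
        sel = pheno.attrs["row_idx"]
        geno = geno.subset(sample_idx=sel)
        # relabel samples so ids stay unique and ordered after subsetting
        pheno = pheno.drop(columns=[]).reset_index(drop=True)
        cohort = Cohort(geno, pheno, truth)
        if artifacts is not None:
            cohort = inject_artifacts(cohort, artifacts, config, rng=rng)
        return cohort
    raise ValueError("failed to meet case/control quotas after 5 batches")


def inject_artifacts(cohort: Cohort, artifacts: ArtifactConfig,
                     config: SimConfig,
                     rng: np.random.Generator | None = None) -> Cohort:
    """Add QC artifacts to a cohort; every injection is listed in the truth.

    * duplicates: exact genotype copies appended with ids ``DUP_*``;
    * relatives: parent-offspring pairs — the child receives one allele
      transmitted from the parent (Bernoulli(d/2)) and one drawn from the
      parent's subpopulation frequency;
    * HWE violations: selected variants forced to all-heterozygote;
    * low INFO: selected variants' INFO set below the 0.3 filter;
    * missingness: Bernoulli(``config.missing_rate``) per genotype.
    """
    rng = _rng(config.seed + 2 if rng is None else rng)
    n = cohort.geno.n_samples
    m = cohort.geno.n_variants
    if artifacts.n_duplicates + artifacts.n_relatives > n:
        raise ValueError("requested artifact count exceeds cohort size")
    if artifacts.n_hwe_violations + artifacts.n_low_info > m:
        raise ValueError("requested variant artifacts exceed variant count")

    dos = cohort.geno.dosages.copy()
    variants = cohort.geno.variants.copy()
    pheno = cohort.pheno.copy()
    truth = cohort.truth
    art: dict = {"duplicates": [], "relatives": [], "hwe_variants": [],
                 "low_info_variants": []}

    new_rows, new_pheno, new_subpop, new_z, new_eta = [], [], [], [], []
    src = rng.choice(n, size=artifacts.n_duplicates + artifacts.n_relatives,
                     replace=False)
    dup_src, rel_src = src[: artifacts.n_duplicates], src[artifacts.n_duplicates:]

    for k, i in enumerate(dup_src):
        sid = f"DUP_{k + 1:04d}"
        new_rows.append(dos[i, :].copy())
        row = pheno.iloc[i].copy()
        row["sample_id"] = sid
        new_pheno.append(row)
        art["duplicates"].append([str(cohort.geno.samples[i]), sid])
        if truth is not None:
            new_subpop.append(truth.subpop[i])
            new_z.append(truth.true_score[i])
            new_eta.append(truth.linear_predictor[i]
                           if truth.linear_predictor is not None else np.nan)

    for k, i in enumerate(rel_src):
        sid = f"REL_{k + 1:04d}"
        parent = dos[i, :]
        sp = truth.subpop[i] if truth is not None else 0
        p = (truth.subpop_freq[sp, :] if truth is not None
             else np.nanmean(dos, axis=0) / 2.0)
        transmitted = rng.random(m) < np.nan_to_num(parent, nan=1.0) / 2.0
        child = transmitted.astype(float) + rng.binomial(1, p)
        child[np.isnan(parent)] = np.nan
        new_rows.append(child)
        row = pheno.iloc[i].copy()
        row["sample_id"] = sid
        new_pheno.append(row)
        art["relatives"].append([str(cohort.geno.samples[i]), sid])
        if truth is not None:
            new_subpop.append(sp)
            new_z.append(truth.true_score[i])
            new_eta.append(np.nan)

    if new_rows:
        dos = np.vstack([dos] + [r[None, :] for r in new_rows])
        pheno = pd.concat([pheno, pd.DataFrame(new_pheno)], ignore_index=True)
        if truth is not None:
            truth.subpop = np.concatenate([truth.subpop, new_subpop])
            truth.true_score = np.concatenate([truth.true_score, new_z])
            if truth.linear_predictor is not None:
                truth.linear_predictor = np.concatenate(
                    [truth.linear_predictor, new_eta])

    vidx = rng.choice(m, size=artifacts.n_hwe_violations + artifacts.n_low_info,
                      replace=False)
    hwe_idx, info_idx = (vidx[: artifacts.n_hwe_violations],
                         vidx[artifacts.n_hwe_violations:])
    for j in hwe_idx:
        dos[:, j] = 1.0  # all-heterozygote: maximal HWE violation
        art["hwe_variants"].append(str(variants.iloc[j]["id"]))
    for j in info_idx:
        variants.iloc[j, variants.columns.get_loc("info")] = float(
            rng.uniform(0.05, 0.29))
        art["low_info_variants"].append(str(variants.iloc[j]["id"]))

    if config.missing_rate > 0:
        mask = rng.random(dos.shape) < config.missing_rate
        dos[mask] = np.nan

    samples = np.asarray(list(pheno["sample_id"]), dtype=object)
    geno = GenotypeMatrix(dos, samples, variants)
    if truth is not None:
        truth.artifacts = art
    return Cohort(geno, pheno, truth)


def simulate_case_control_scores(config: SimConfig,
                                 rng: np.random.Generator | None = None,
                                 batch: int = 200_000,
                                 max_batches: int = 200) -> pd.DataFrame:
    """Genotype-free fast path: case-control sample of (z, smoking, status).

    Draws the standardized true score directly from N(0,1) and applies the
    same retrospective sampling as the full simulator.  Used for effect
    recovery and calibration studies where individual genotypes are not
    needed.
    """
    rng = _rng(config.seed if rng is None else rng)
    if config.baseline_prev == 0.0 and config.n_cases > 0:
        raise ValueError("baseline_prev=0 cannot produce cases")
    cases, ctrls = [], []
    n_case = n_ctrl = 0
    for _ in range(max_batches):
        z = rng.standard_normal(batch)
        smoke, _, y = _population_phenotypes(z, config, rng)
        df = pd.DataFrame({"z": z, "smoking": smoke, "status": y})
        if n_case < config.n_cases:
            cases.append(df[df.status == 1])
            n_case += int(df.status.sum())
        if n_ctrl < config.n_controls:
            ctrls.append(df[df.status == 0])
            n_ctrl += int((1 - df.status).sum())
        if n_case >= config.n_cases and n_ctrl >= config.n_controls:
            break
    else:
        raise ValueError("could not meet quotas; baseline_prev too extreme")
    out = pd.concat(
        [pd.concat(cases).iloc[: config.n_cases],
         pd.concat(ctrls).iloc[: config.n_controls]],
        ignore_index=True,
    )
    return out


def simulate_joint_risk_cohort(n: int,
                               or_smoking_low: float = 7.73,
                               or_high_vs_low: float = 2.20,
                               or_int_vs_low: float = 1.46,
                               p_smoke: float = 0.5,
                               baseline_prev: float = 0.2,
                               seed=0) -> pd.DataFrame:
    """Stratified, genotype-free cohort under a no-interaction odds model.

    A standard-normal score is cut at its 20th/80th percentiles into
    low/intermediate/high genetic-risk groups; smoking is Bernoulli; the
    disease model has main effects only, calibrated so the smoking odds
    ratio within every genetic-risk group is ``or_smoking_low`` and the
    high-vs-low odds ratio within every smoking stratum is
    ``or_high_vs_low``.  Because the model is multiplicative in odds, the
    joint (ever, high) vs (never, low) odds ratio is exactly the product
    of the two marginal odds ratios.

    ``p_smoke`` and ``baseline_prev`` only set cell occupancies and hence
    Monte-Carlo precision; the defaults balance the four cells of the
    joint contrast.
    """
    from scipy.stats import norm

    rng = _rng(seed)
    z = rng.standard_normal(n)
    lo, hi = norm.ppf(0.2), norm.ppf(0.8)
    group = np.where(z < lo, 0, np.where(z >= hi, 2, 1))
    smoke = (rng.random(n) < p_smoke).astype(int)
    beta_g = np.array([0.0, np.log(or_int_vs_low), np.log(or_high_vs_low)])
    eta = logit(baseline_prev) + beta_g[group] + np.log(or_smoking_low) * smoke
    y = (rng.random(n) < expit(eta)).astype(int)
    return pd.DataFrame(
        {
            "risk_group": pd.Categorical.from_codes(
                group, categories=["low", "intermediate", "high"]),
            "smoking": smoke,
            "status": y,
        }
    )
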