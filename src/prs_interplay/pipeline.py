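"""End-to-end pipeline orchestration.

Stage order mirrors the analysis design: simulate (or load) -> variant/
sample QC -> principal components -> case-control matching -> post-
imputation filter -> PRS scoring and grouping -> association models ->
stratified/joint odds tables -> discrimination metrics.  All randomness
flows from one root seed, split per stage; the resolved configuration is
echoed into the output directory so every number in the report bundle is
reproducible by re-running the underlying module operation.
"""
from __future__ import annotations

import dataclasses
import json
import os
import shutil

import numpy as np
import pandas as pd
import yaml

from . import assoc, io, metrics, prs, qc
from .match import compute_pcs, match_controls
from .model import RiskModel
from .simulate import ArtifactConfig, SimConfig, simulate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs"]

_SIM_FIELDS = {f.name for f in dataclasses.fields(SimConfig)}
_ART_FIELDS = {f.name for f in dataclasses.fields(ArtifactConfig)}
_QC_FIELDS = {f.name for f in dataclasses.fields(qc.QCThresholds)}


@dataclasses.dataclass
class PipelineConfig:
    """Pipeline-level configuration; unknown keys are rejected."""

    seed: int = 0
    out_dir: str = "prs_interplay_run"
    simulate: bool = True
    sim: SimConfig = None
    artifacts: ArtifactConfig = None
    thresholds: qc.QCThresholds = None
    vcf: str | None = None
    pheno: str | None = None
    weights: str | None = None  # scoring file; None -> truth-derived weights
    score_mode: str = "weighted"
    match_k: int = 5
    n_pcs: int = 10
    run_scan: bool = False
    n_boot: int = 200

    def __post_init__(self) -> None:
        if self.sim is None:
            self.sim = SimConfig(seed=self.seed)
        if self.artifacts is None:
            self.artifacts = ArtifactConfig()
        if self.thresholds is None:
            self.thresholds = qc.QCThresholds()

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, fields, typ in (("sim", _SIM_FIELDS, SimConfig),
                                 ("artifacts", _ART_FIELDS, ArtifactConfig),
                                 ("thresholds", _QC_FIELDS, qc.QCThresholds)):
            if key in raw and raw[key] is not None:
                bad = set(raw[key]) - fields
                if bad:
                    raise ValueError(f"unknown {key} keys: {sorted(bad)}")
                sub = dict(raw[key])
                if "maf_range" in sub:
                    sub["maf_range"] = tuple(sub["maf_range"])
                raw[key] = typ(**sub)
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, default_flow_style=False)


def validate_inputs(vcf: str | None = None, pheno: str | None = None,
                    weights: str | None = None) -> list:
    """Diagnostics-only check of input files; returns actionable messages."""
    findings = []
    geno = None
    if vcf is not None:
        if not os.path.exists(vcf):
            findings.append(f"VCF not found: {vcf}")
        else:
            try:
                geno = io.read_vcf(vcf)
            except Exception as exc:
                findings.append(f"VCF unreadable ({vcf}): {exc}")
    if pheno is not None:
        if not os.path.exists(pheno):
            findings.append(f"phenotype file not found: {pheno}")
        else:
            try:
                ph = io.read_pheno(pheno)
                if geno is not None:
                    missing = set(ph["sample_id"]) - set(geno.samples)
                    for sid in sorted(missing):
                        findings.append(
                            f"phenotype sample absent from VCF: {sid}")
            except Exception as exc:
                findings.append(f"phenotype file invalid: {exc}")
    if weights is not None:
        if not os.path.exists(weights):
            findings.append(f"scoring file not found: {weights}")
        else:
            try:
                _, entries = io.read_scoring_file(weights)
                for i, row in entries.iterrows():
                    al = str(row["effect_allele"]) + str(row["other_allele"])
                    if any(b not in "ACGT" for b in al.upper()):
                        findings.append(
                            f"scoring file row {i}: non-ACGT allele "
                            f"{row['effect_allele']}/{row['other_allele']}")
            except Exception as exc:
                findings.append(f"scoring file invalid: {exc}")
    return findings


def _truth_weight_set(cohort, top: int = 50) -> prs.WeightSet:
    """Scoring file from the simulation's own causal weights (synthetic
    stand-in for an external PRS: the top-|weight| causal variants)."""
    truth = cohort.truth
    w = np.asarray(truth.causal_weight)
    order = np.argsort(-np.abs(w))[:top]
    v = cohort.geno.variants.iloc[order]
    entries = pd.DataFrame({
        "rsID": v["id"].to_numpy(),
        "chr": v["chrom"].to_numpy(),
        "pos": v["pos"].to_numpy(),
        "effect_allele": v["alt"].to_numpy(),
        "other_allele": v["ref"].to_numpy(),
        "effect_weight": w[order],
    })
    return prs.WeightSet("truth_top", entries, "weighted")


def _table1(pheno: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for status, name in ((1, "cases"), (0, "controls")):
        g = pheno[pheno.status == status]
        rows.append({
            "group": name, "n": len(g),
            "male_pct": 100.0 * (g.sex == 1).mean(),
            "age_mean": g.age.mean(), "age_sd": g.age.std(),
            "bmi_mean": g.bmi.mean(), "bmi_sd": g.bmi.std(),
            "smoking_ever_pct": 100.0 * (g.smoking == 1).mean(),
            "smoking_missing_pct": 100.0 * g.smoking.isna().mean(),
        })
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the pipeline end to end; returns {name: path} of the report bundle.

    Any stage failure aborts with the stage name in the exception and
    removes partial outputs.
    """
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    paths = {}
    log_lines = []

    def log(msg):
        log_lines.append(msg)

    stage = "setup"
    try:
        import prs_interplay

        log(f"prs-interplay {prs_interplay.__version__}  seed={config.seed}")
        config.to_yaml(os.path.join(out, "config_resolved.yaml"))
        paths["config"] = os.path.join(out, "config_resolved.yaml")

        stage = "simulate" if config.simulate else "load"
        if config.simulate:
            cohort = simulate_cohort(config.sim, config.artifacts)
            io.write_cohort(cohort, out)
            paths["vcf"] = os.path.join(out, "cohort.vcf")
            paths["pheno"] = os.path.join(out, "phenotypes.tsv")
        else:
            if config.vcf is None or not os.path.exists(config.vcf or ""):
                raise FileNotFoundError(f"input VCF missing: {config.vcf}")
            geno = io.read_vcf(config.vcf)
            pheno = io.read_pheno(config.pheno)
            from .containers import Cohort

            cohort = Cohort(geno, pheno)
        log(f"cohort: {cohort.n_cases} cases / {cohort.n_controls} controls, "
            f"{cohort.geno.n_variants} variants")

        stage = "variant_qc"
        controls_mask = (cohort.pheno.status == 0).to_numpy()
        vrep = qc.variant_qc(cohort.geno, config.thresholds, controls_mask)
        vrep.to_tsv(os.path.join(out, "variant_qc.tsv"))
        paths["variant_qc"] = os.path.join(out, "variant_qc.tsv")
        keep_v = np.flatnonzero(vrep.kept_mask)
        log(f"variant QC: kept {len(keep_v)}/{cohort.geno.n_variants} "
            f"({dict(vrep.counts())})")
        geno = cohort.geno.subset(variant_idx=keep_v)

        stage = "sample_qc"
        pcs_pre = compute_pcs(geno, min(config.n_pcs, geno.n_variants))
        srep = qc.sample_qc(geno, config.thresholds, pcs_pre.scores[:, :2])
        srep.to_tsv(os.path.join(out, "sample_qc.tsv"))
        paths["sample_qc"] = os.path.join(out, "sample_qc.tsv")
        keep_s = np.flatnonzero(srep.kept_mask)
        log(f"sample QC: kept {len(keep_s)}/{geno.n_samples} "
            f"({dict(srep.counts())})")
        geno = geno.subset(sample_idx=keep_s)
        pheno = cohort.pheno.iloc[keep_s].reset_index(drop=True)

        stage = "pca"
        pcres = compute_pcs(geno, config.n_pcs)
        pcres.to_tsv(os.path.join(out, "pcs.tsv"))
        paths["pcs"] = os.path.join(out, "pcs.tsv")
        for k in range(min(config.n_pcs, pcres.scores.shape[1])):
            pheno[f"pc{k + 1}"] = pcres.scores[:, k]

        stage = "match"
        case_mask = (pheno.status == 1).to_numpy()
        mres = match_controls(pcres.scores[case_mask],
                              pcres.scores[~case_mask],
                              pheno.sample_id[case_mask].tolist(),
                              pheno.sample_id[~case_mask].tolist(),
                              k=config.match_k)
        mres.to_tsv(os.path.join(out, "matches.tsv"))
        paths["matches"] = os.path.join(out, "matches.tsv")
        log(f"matching: {len(mres.assignments)} cases x {config.match_k}, "
            f"{len(mres.unmatchable)} unmatchable")
        keep_ids = set(mres.assignments) | set(mres.matched_controls)
        keep = pheno.sample_id.isin(keep_ids).to_numpy()
        geno = geno.subset(sample_idx=np.flatnonzero(keep))
        pheno = pheno[keep].reset_index(drop=True)

        stage = "post_imputation_filter"
        pirep = qc.post_imputation_filter(geno.variants, int((pheno.status == 1).sum()),
                                          maf=geno.maf())
        keep_v = np.flatnonzero(pirep.kept_mask)
        log(f"post-imputation filter: kept {len(keep_v)}/{geno.n_variants}")
        geno = geno.subset(variant_idx=keep_v)

        stage = "score"
        if config.weights is not None:
            ws = prs.WeightSet.from_file(config.weights, config.score_mode)
        else:
            ws = _truth_weight_set(cohort)
            ws.to_file(os.path.join(out, "weights_truth_top.tsv"))
        hws, hlog = prs.harmonize_weights(ws, geno.variants, reference=geno)
        hlog.table.to_csv(os.path.join(out, "harmonization.tsv"),
                          sep="\t", index=False)
        raw = prs.compute_score(geno, hws)
        sres = prs.standardize_and_group(raw, pheno.status.to_numpy(),
                                        pheno.sample_id)
        sres.to_tsv(os.path.join(out, "scores.tsv"))
        paths["scores"] = os.path.join(out, "scores.tsv")

        stage = "reports"
        df = pheno.copy()
        df["z"] = sres.table["z"].to_numpy()
        df["quintile"] = sres.table["quintile"].to_numpy()
        df["risk_group"] = sres.table["risk_group"].to_numpy()

        _table1(pheno).to_csv(os.path.join(out, "table1_cohort.tsv"),
                              sep="\t", index=False)
        paths["table1"] = os.path.join(out, "table1_cohort.tsv")

        t2 = df.pivot_table(index="status", columns="risk_group",
                            values="sample_id", aggfunc="count",
                            observed=False).fillna(0).astype(int)
        t2.to_csv(os.path.join(out, "table2_risk_groups.tsv"), sep="\t")
        paths["table2"] = os.path.join(out, "table2_risk_groups.tsv")

        stage = "models"
        pc_cols = [c for c in df.columns if c.startswith("pc")][:10]
        fits = {}
        fits["prs_only"] = RiskModel.from_dataframe(
            df, prs="z", label="PRS").fit()
        fits["prs_smoking"] = RiskModel.from_dataframe(
            df, prs="z", smoking="smoking", label="PRS + smoking").fit()
        full_cov = ["age", "sex", "bmi"] + pc_cols
        df_s = df.dropna(subset=["smoking"])
        fits["full_without_prs"] = RiskModel.from_dataframe(
            df_s, prs=None, smoking="smoking", covariates=full_cov,
            label="full w/o PRS").fit()
        fits["full_with_prs"] = RiskModel.from_dataframe(
            df_s, prs="z", smoking="smoking", covariates=full_cov,
            label="full + PRS").fit()
        rows = []
        for name, res in fits.items():
            t = res.or_table()
            t.insert(0, "model_name", name)
            t["r2"] = res.r2
            t["auc"] = res.auc
            rows.append(t)
        pd.concat(rows, ignore_index=True).to_csv(
            os.path.join(out, "table3_models.tsv"), sep="\t", index=False,
            na_rep="NA")
        paths["table3"] = os.path.join(out, "table3_models.tsv")

        stat, dfree, pval, nri = fits["full_with_prs"].compare(
            fits["full_without_prs"], n_boot=config.n_boot, seed=config.seed)
        log(f"LRT full vs full-without-PRS: stat={stat:.2f} df={dfree} "
            f"p={pval:.3g}; NRI={nri.overall:.3f} "
            f"(events {nri.event:.3f}, non-events {nri.non_event:.3f})")

        stage = "quintiles_tails"
        qrows = []

        def try_or(a, b, c, d, label):
            # small-cohort tails can hold an empty cell: flag, never abort
            try:
                qrows.append(assoc.or_2x2(a, b, c, d, label=label).as_row()
                             | {"flag": ""})
            except ValueError:
                qrows.append({"term": "exposure", "beta": np.nan,
                              "se": np.nan, "or": np.nan, "ci_low": np.nan,
                              "ci_high": np.nan, "p": np.nan, "model": label,
                              "stratum": "", "n": a + b + c + d,
                              "flag": "empty_cell"})

        q1 = df[df.quintile == 1]
        for qq in range(2, 6):
            gq = df[df.quintile == qq]
            try_or(int((gq.status == 1).sum()), int((gq.status == 0).sum()),
                   int((q1.status == 1).sum()), int((q1.status == 0).sum()),
                   f"quintile{qq}_vs_1")
        for tail in ("tail90", "tail95", "tail99"):
            t = sres.table[tail].to_numpy()
            try_or(int(((df.status == 1) & t).sum()),
                   int(((df.status == 0) & t).sum()),
                   int(((df.status == 1) & ~t).sum()),
                   int(((df.status == 0) & ~t).sum()),
                   f"{tail}_vs_rest")
        pd.DataFrame(qrows).to_csv(os.path.join(out, "fig3_quintiles_tails.tsv"),
                                   sep="\t", index=False)
        paths["fig3"] = os.path.join(out, "fig3_quintiles_tails.tsv")

        stage = "stratified_joint"
        joint = assoc.stratify_joint(df.risk_group, df.smoking, df.status)
        joint.to_csv(os.path.join(out, "fig4_joint_strata.tsv"), sep="\t",
                     index=False, na_rep="NA")
        paths["fig4"] = os.path.join(out, "fig4_joint_strata.tsv")

        stage = "interaction"
        try:
            it = assoc.interaction_test(df_s.z, df_s.smoking, df_s.status)
            log(f"PRS x smoking interaction: beta={it.beta:.3f} p={it.p:.3f}")
        except (assoc.SeparationError, ValueError) as exc:
            log(f"interaction test unavailable: {exc}")

        stage = "metrics"
        mrows = []
        for name, res in fits.items():
            mrows.append({"model": name, "auc": res.auc,
                          "ci_low": res.roc.ci95[0],
                          "ci_high": res.roc.ci95[1], "r2": res.r2})
        met = pd.DataFrame(mrows)
        met.loc[met.model == "full_with_prs", "nri"] = nri.overall
        met.loc[met.model == "full_with_prs", "nri_ci_low"] = nri.ci95[0]
        met.loc[met.model == "full_with_prs", "nri_ci_high"] = nri.ci95[1]
        met.to_csv(os.path.join(out, "metrics.tsv"), sep="\t", index=False,
                   na_rep="NA")
        paths["metrics"] = os.path.join(out, "metrics.tsv")
        fits["prs_only"].roc.to_tsv(os.path.join(out, "roc_prs.tsv"))

        if config.run_scan:
            stage = "scan"
            covs = df[["age", "sex"] + pc_cols].to_numpy(float)
            scan = assoc.gwas_scan(geno, df.status.to_numpy(float), covs)
            scan.to_tsv(os.path.join(out, "scan.tsv"))
            paths["scan"] = os.path.join(out, "scan.tsv")
            log(f"scan: lambda={scan.lambda_gc:.3f}, "
                f"{len(scan.skipped)} skipped")

        with open(os.path.join(out, "run.log"), "w") as fh:
            fh.write("\n".join(log_lines) + "\n")
        paths["log"] = os.path.join(out, "run.log")
        return paths
    except Exception as exc:
        shutil.rmtree(out, ignore_errors=True)
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
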