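"""Odds models: logistic fits, 2x2 tables, per-SD conversion, scan,
interaction, LRT, stratified/joint tables, liability conversion."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from conftest import make_geno
from prs_interplay.assoc import (SeparationError, fit_logistic, gwas_scan,
                                 interaction_test, liability_h2,
                                 likelihood_ratio_test, or_2x2,
                                 per_allele_to_per_sd, stratify_joint)
from prs_interplay.simulate import (SimConfig, simulate_case_control_scores,
                                    simulate_joint_risk_cohort)


def expand_2x2(a, b, c, d):
    """Individual-level data for a 2x2 table (exposed cases a, exposed
    controls b, unexposed cases c, unexposed controls d)."""
    y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    x = np.r_[np.ones(a + b), np.zeros(c + d)]
    return y, x


class TestFitLogistic:
    @pytest.mark.parametrize("cells", [(12, 7, 5, 21), (30, 40, 25, 9),
                                       (3, 11, 8, 2)])
    def test_two_group_fit_reproduces_cross_product_or(self, cells):
        y, x = expand_2x2(*cells)
        fit = fit_logistic(y, x, names=["exposure"])
        assert fit["exposure"].beta == pytest.approx(
            or_2x2(*cells).beta, abs=1e-8)

    def test_intercept_only_fits_case_fraction(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        fit = fit_logistic(y, np.zeros((100, 0)), names=[])
        assert np.allclose(fit.fitted, 0.3, atol=1e-8)

    def test_null_predictor_ci_coverage(self):
        """Wald CI for an independent predictor covers OR 1 at about the
        nominal 95% rate."""
        rng = np.random.default_rng(10)
        n, covered = 4000, 0
        reps = 200
        for _ in range(reps):
            x = rng.normal(size=n)
            y = (rng.random(n) < 0.3).astype(float)
            t = fit_logistic(y, x, names=["x"])["x"]
            lo, hi = t.ci95
            covered += lo <= 1.0 <= hi
        assert 0.91 <= covered / reps <= 0.985

    def test_separation_error_names_term(self):
        y = np.r_[np.ones(20), np.zeros(20)]
        x = np.r_[np.ones(20), np.zeros(20)]
        with pytest.raises(SeparationError, match="separation|failed"):
            fit_logistic(y, x, names=["sep_term"])

    def test_rank_deficiency_rejected(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=50)
        y = (rng.random(50) < 0.5).astype(float)
        with pytest.raises(ValueError, match="rank"):
            fit_logistic(y, np.column_stack([x, x]), names=["a", "b"])


class TestOr2x2:
    def test_top_vs_bottom_quintile_study_counts(self):
        # cases 1085 high / 564 low; controls 3718 high / 4239 low
        r = or_2x2(1085, 3718, 564, 4239)
        assert round(r.odds_ratio, 2) == 2.19

    def test_symmetric_table_is_one(self):
        assert or_2x2(10, 10, 10, 10).odds_ratio == pytest.approx(1.0)

    def test_woolf_interval_hand_computed(self):
        r = or_2x2(20, 10, 5, 40)
        assert r.odds_ratio == pytest.approx(16.0)
        lo, hi = r.ci95
        assert lo == pytest.approx(4.818009149, rel=1e-8)
        assert hi == pytest.approx(53.13397963, rel=1e-8)

    def test_zero_cell_raises(self):
        with pytest.raises(ValueError, match="continuity"):
            or_2x2(0, 5, 10, 20)


class TestPerSdConversion:
    def test_sentinel_variant_value(self):
        assert round(per_allele_to_per_sd(1.3, 0.379), 2) == 1.20

    def test_null_is_null(self):
        for p in (0.05, 0.379, 0.9):
            assert per_allele_to_per_sd(1.0, p) == pytest.approx(1.0)

    def test_arithmetic_example(self):
        assert per_allele_to_per_sd(2.0, 0.5) == pytest.approx(1.6325, abs=5e-4)

    def test_degenerate_freq_rejected(self):
        with pytest.raises(ValueError):
            per_allele_to_per_sd(1.3, 0.0)


class TestGwasScan:
    def test_null_scan_lambda_near_one(self):
        rng = np.random.default_rng(12)
        n, m = 1500, 2000
        geno = make_geno(rng.binomial(2, rng.uniform(0.1, 0.5, m),
                                      size=(n, m)).astype(float))
        y = (rng.random(n) < 1 / 6).astype(float)
        scan = gwas_scan(geno, y)
        assert 0.9 < scan.lambda_gc < 1.1
        assert np.all(np.diff(scan.qq["expected"].to_numpy()[::-1]) > 0)

    def test_planted_sentinel_effect_detected(self):
        """A per-allele OR 1.28 variant at MAF 0.35 in a 4002/20010
        case-control study reaches genome-wide significance."""
        rng = np.random.default_rng(13)
        n_pop = 150_000
        g = rng.binomial(2, 0.35, size=n_pop).astype(float)
        eta = stats.norm.ppf(0.05) + np.log(1.28) * g  # logit baseline approx
        y = (rng.random(n_pop) < expit(eta)).astype(float)
        case_idx = np.flatnonzero(y == 1)[:4002]
        ctrl_idx = np.flatnonzero(y == 0)[:20010]
        sel = np.r_[case_idx, ctrl_idx]
        null_g = rng.binomial(2, 0.3, size=(len(sel), 3)).astype(float)
        geno = make_geno(np.column_stack([g[sel], null_g]))
        scan = gwas_scan(geno, y[sel])
        assert scan.table.loc[0, "p"] < 5e-8
        assert (scan.table.loc[1:, "p"] > 5e-8).all()

    def test_monomorphic_variant_skipped(self):
        rng = np.random.default_rng(14)
        d = rng.binomial(2, 0.4, size=(200, 2)).astype(float)
        d[:, 1] = 0.0
        geno = make_geno(d)
        y = (rng.random(200) < 0.4).astype(float)
        scan = gwas_scan(geno, y)
        assert scan.skipped == ["v2"]
        assert np.isnan(scan.table.loc[1, "chi2"])

    def test_lambda_invariant_to_variant_order(self):
        rng = np.random.default_rng(15)
        d = rng.binomial(2, 0.3, size=(400, 50)).astype(float)
        y = (rng.random(400) < 0.3).astype(float)
        lam1 = gwas_scan(make_geno(d), y).lambda_gc
        perm = rng.permutation(50)
        lam2 = gwas_scan(make_geno(d[:, perm]), y).lambda_gc
        assert lam1 == pytest.approx(lam2, rel=1e-12)

    def test_wald_method_agrees_with_score_on_strong_signal(self):
        rng = np.random.default_rng(16)
        n = 3000
        g = rng.binomial(2, 0.3, size=(n, 2)).astype(float)
        y = (rng.random(n) < expit(-1 + 0.4 * g[:, 0])).astype(float)
        s1 = gwas_scan(make_geno(g), y, method="score")
        s2 = gwas_scan(make_geno(g), y, method="wald")
        assert np.log10(s1.table.loc[0, "p"]) == pytest.approx(
            np.log10(s2.table.loc[0, "p"]), abs=0.5)


class TestInteraction:
    def test_power_under_true_interaction(self):
        """gamma = ln(1.5) at 24,000 samples: the product-term test
        rejects decisively."""
        cfg = SimConfig(n_cases=4000, n_controls=20000,
                        gamma_interaction=np.log(1.5), seed=17)
        df = simulate_case_control_scores(cfg)
        res = interaction_test(df.z, df.smoking, df.status)
        assert res.p < 1e-3
        assert res.beta > 0

    def test_missing_smoking_excluded(self):
        rng = np.random.default_rng(18)
        n = 2000
        z = rng.normal(size=n)
        smoke = (rng.random(n) < 0.5).astype(float)
        y = (rng.random(n) < expit(-1 + 0.3 * z + smoke)).astype(float)
        smoke_missing = smoke.copy()
        smoke_missing[:50] = np.nan
        res_full = interaction_test(z[50:], smoke[50:], y[50:])
        res_miss = interaction_test(z, smoke_missing, y)
        assert res_miss.beta == pytest.approx(res_full.beta, abs=1e-10)
        assert res_miss.n == n - 50

    def test_self_interaction_rank_deficient(self):
        rng = np.random.default_rng(19)
        x = (rng.random(500) < 0.5).astype(float)
        y = (rng.random(500) < 0.5).astype(float)
        with pytest.raises(ValueError, match="rank"):
            interaction_test(x, x, y)

    def test_constant_smoking_rejected(self):
        rng = np.random.default_rng(20)
        z = rng.normal(size=100)
        y = (rng.random(100) < 0.5).astype(float)
        with pytest.raises(ValueError, match="constant"):
            interaction_test(z, np.ones(100), y)


class TestLikelihoodRatio:
    def test_identical_models(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=300)
        y = (rng.random(300) < 0.4).astype(float)
        fit = fit_logistic(y, x, names=["x"])
        stat, df, p = likelihood_ratio_test(fit, fit)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert df == 0
        assert p == 1.0

    def test_null_statistic_is_chi2_one(self):
        """Adding a pure-noise column gives an LRT statistic distributed
        as chi-square with 1 df (KS check over replicates)."""
        rng = np.random.default_rng(22)
        stats_out = []
        n = 400
        for _ in range(400):
            x = rng.normal(size=n)
            noise = rng.normal(size=n)
            y = (rng.random(n) < expit(0.3 * x)).astype(float)
            f0 = fit_logistic(y, x, names=["x"])
            f1 = fit_logistic(y, np.column_stack([x, noise]),
                              names=["x", "noise"])
            stats_out.append(likelihood_ratio_test(f0, f1)[0])
        ks = stats.kstest(stats_out, stats.chi2(1).cdf)
        assert ks.pvalue > 0.01

    def test_strong_predictor_reported_bounded(self):
        rng = np.random.default_rng(23)
        n = 3000
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(2.0 * x)).astype(float)
        f0 = fit_logistic(y, np.zeros((n, 0)), names=[])
        f1 = fit_logistic(y, x, names=["x"])
        stat, df, p = likelihood_ratio_test(f0, f1)
        assert stat > 100
        assert 0.0 <= p < 1e-20

    def test_different_samples_rejected(self):
        rng = np.random.default_rng(24)
        x = rng.normal(size=200)
        y = (rng.random(200) < 0.5).astype(float)
        f0 = fit_logistic(y[:150], x[:150], names=["x"])
        f1 = fit_logistic(y, x, names=["x"])
        with pytest.raises(ValueError):
            likelihood_ratio_test(f0, f1)


@pytest.fixture(scope="module")
def toy():
    """Hand-built 6-cell cohort (counts chosen non-degenerate)."""
    cells = {
        (0, "low"): (20, 200), (0, "intermediate"): (70, 580),
        (0, "high"): (40, 190),
        (1, "low"): (90, 120), (1, "intermediate"): (380, 370),
        (1, "high"): (260, 130),
    }
    rows = []
    for (sm, rg), (ncase, nctrl) in cells.items():
        rows.append(pd.DataFrame({
            "risk_group": rg, "smoking": sm,
            "status": np.r_[np.ones(ncase), np.zeros(nctrl)]}))
    df = pd.concat(rows, ignore_index=True)
    return cells, stratify_joint(df.risk_group, df.smoking, df.status)


class TestStratifyJoint:
    def test_reference_cell_is_exactly_one(self, toy):
        _, table = toy
        ref = table[(table.model == "joint") & (table.stratum == "never,low")]
        assert ref["or"].iloc[0] == 1.0
        assert ref["flag"].iloc[0] == "reference"

    def test_all_cells_match_cross_product_arithmetic(self, toy):
        cells, table = toy
        a, b = cells[(1, "high")]
        c, d = cells[(0, "low")]
        joint = table[(table.model == "joint") & (table.stratum == "ever,high")]
        assert joint["or"].iloc[0] == pytest.approx((a * d) / (b * c))
        # smoking OR within low genetic risk
        a2, b2 = cells[(1, "low")]
        row = table[(table.model == "ever_vs_never") & (table.stratum == "risk=low")]
        assert row["or"].iloc[0] == pytest.approx((a2 * d) / (b2 * c))

    def test_empty_cell_flagged_not_dropped(self):
        df = pd.DataFrame({
            "risk_group": ["low"] * 10 + ["high"] * 10,
            "smoking": [0] * 10 + [1] * 10,
            "status": [0, 1] * 10,
        })
        table = stratify_joint(df.risk_group, df.smoking, df.status)
        flagged = table[table.flag == "empty_cell"]
        assert len(flagged) > 0

    def test_joint_or_composes_multiplicatively_at_scale(self):
        df = simulate_joint_risk_cohort(150_000, seed=25)
        table = stratify_joint(df.risk_group, df.smoking, df.status)
        joint = table[(table.model == "joint")
                      & (table.stratum == "ever,high")]["or"].iloc[0]
        low_sm = table[(table.model == "ever_vs_never")
                       & (table.stratum == "risk=low")]["or"].iloc[0]
        high_in_sm = table[(table.model == "high_vs_low")
                           & (table.stratum == "smoking=ever")]["or"].iloc[0]
        assert joint == pytest.approx(low_sm * high_in_sm, rel=0.15)


class TestLiabilityConversion:
    def test_zero_maps_to_zero(self):
        assert liability_h2(0.0, 0.041, 0.167) == 0.0

    def test_half_half_multiplier_is_pi_over_two(self):
        assert liability_h2(1.0, 0.5, 0.5) == pytest.approx(np.pi / 2, rel=1e-12)

    def test_study_prevalence_multiplier(self):
        # frozen from the closed-form evaluation at K=0.041, P=0.167
        assert liability_h2(1.0, 0.041, 0.167) == pytest.approx(
            1.4377420411540505, rel=1e-9)

    def test_degenerate_prevalence_rejected(self):
        with pytest.raises(ValueError):
            liability_h2(0.2, 0.0, 0.167)
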