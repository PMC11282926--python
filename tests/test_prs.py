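"""Weight harmonization, proxy lookup, scoring and percentile grouping."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_geno
from prs_interplay.prs import (WeightSet, compute_score, find_proxy,
                               harmonize_weights, merge_multi_reports,
                               standardize_and_group)


def ws_from_rows(rows, mode="weighted"):
    return WeightSet("test", pd.DataFrame(
        rows, columns=["rsID", "chr", "pos", "effect_allele", "other_allele",
                       "effect_weight"]), mode)


@pytest.fixture
def cohort_geno():
    rng = np.random.default_rng(0)
    d = rng.binomial(2, 0.4, size=(50, 4)).astype(float)
    # cohort variants: ref/alt = A/G, C/T, T/C, A/G
    return make_geno(d, pos=[100, 200, 300, 400],
                     ref=["A", "C", "T", "A"], alt=["G", "T", "C", "G"])


class TestHarmonize:
    def test_effect_allele_alt_matched_as_is(self, cohort_geno):
        ws = ws_from_rows([("r1", "1", 100, "G", "A", 0.2)])
        h, log = harmonize_weights(ws, cohort_geno.variants)
        assert log.table.loc[0, "action"] == "matched"
        assert not bool(h.entries.loc[0, "flip"])

    def test_effect_allele_ref_contributes_via_two_minus_d(self, cohort_geno):
        w = 0.5
        ws = ws_from_rows([("r1", "1", 100, "A", "G", w)])
        h, log = harmonize_weights(ws, cohort_geno.variants)
        assert log.table.loc[0, "action"] == "sign-flipped"
        geno = cohort_geno
        geno.dosages[:, 0] = 2.0  # homozygous ALT: flipped dosage 0
        single = geno.subset(variant_idx=[0])
        scores = compute_score(single, WeightSet("t", h.entries, "weighted"))
        np.testing.assert_allclose(scores, 0.0)

    def test_strand_complement_via_hand_table(self, cohort_geno):
        # entry A/G against cohort T/C: complement(A)=T, complement(G)=C
        ws = ws_from_rows([("r3", "1", 300, "A", "G", 0.3)])
        h, log = harmonize_weights(ws, cohort_geno.variants)
        assert log.table.loc[0, "action"] == "strand-complemented"
        # after complementing, effect allele T equals REF -> flipped
        assert bool(h.entries.loc[0, "flip"])

    def test_palindromic_dropped(self, cohort_geno):
        ws = ws_from_rows([("rp", "1", 100, "A", "T", 0.1)])
        h, log = harmonize_weights(ws, cohort_geno.variants)
        assert len(h.entries) == 0
        assert log.table.loc[0, "action"] == "dropped"
        assert log.table.loc[0, "detail"] == "palindromic"

    def test_unmatched_dropped_without_reference(self, cohort_geno):
        ws = ws_from_rows([("rx", "2", 9999, "G", "A", 0.1)])
        h, log = harmonize_weights(ws, cohort_geno.variants)
        assert log.table.loc[0, "action"] == "dropped"
        assert log.table.loc[0, "detail"] == "unmatched"

    def test_involution(self, cohort_geno):
        ws = ws_from_rows([
            ("r1", "1", 100, "G", "A", 0.2),
            ("r2", "1", 200, "C", "T", -0.4),
            ("r3", "1", 300, "A", "G", 0.3),
        ])
        h1, _ = harmonize_weights(ws, cohort_geno.variants)
        h2, _ = harmonize_weights(h1, cohort_geno.variants)
        pd.testing.assert_frame_equal(h1.entries, h2.entries)

    def test_every_entry_logged_once(self, cohort_geno):
        ws = ws_from_rows([
            ("r1", "1", 100, "G", "A", 0.2),
            ("rp", "1", 200, "G", "C", 0.1),  # palindromic C/G
            ("rx", "9", 1, "G", "A", 0.1),
        ])
        _, log = harmonize_weights(ws, cohort_geno.variants)
        assert sorted(log.table["rsID"]) == ["r1", "rp", "rx"]

    def test_malformed_alleles_rejected(self, cohort_geno):
        ws = ws_from_rows([("r1", "1", 100, "G", "N", 0.2)])
        with pytest.raises(ValueError):
            harmonize_weights(ws, cohort_geno.variants)

    def test_allele_flip_leaves_z_invariant(self, cohort_geno):
        """Swapping effect/other alleles and negating every weight leaves
        the standardized score unchanged."""
        ws = ws_from_rows([("r1", "1", 100, "G", "A", 0.2),
                           ("r2", "1", 200, "T", "C", -0.4)])
        flipped = ws_from_rows([("r1", "1", 100, "A", "G", -0.2),
                                ("r2", "1", 200, "C", "T", 0.4)])
        status = np.zeros(cohort_geno.n_samples, dtype=int)
        zs = []
        for w in (ws, flipped):
            h, _ = harmonize_weights(w, cohort_geno.variants)
            raw = compute_score(cohort_geno, h)
            zs.append(standardize_and_group(raw, status).table["z"].to_numpy())
        np.testing.assert_allclose(zs[0], zs[1], atol=1e-10)


class TestFindProxy:
    def test_duplicate_variant_chosen_with_r2_one(self):
        rng = np.random.default_rng(1)
        d = rng.binomial(2, 0.4, size=(100, 2)).astype(float)
        d[:, 1] = d[:, 0]
        geno = make_geno(d, pos=[100, 150])
        target = {"rsID": "t", "chr": "1", "pos": 100}
        v, r2, sign = find_proxy(target, geno)
        assert v["pos"] == 150
        assert r2 == pytest.approx(1.0)
        assert sign == 1.0

    def test_independent_variants_no_proxy(self):
        rng = np.random.default_rng(2)
        d = rng.binomial(2, 0.4, size=(400, 2)).astype(float)
        geno = make_geno(d, pos=[100, 150])
        assert find_proxy({"rsID": "t", "chr": "1", "pos": 100}, geno) is None

    def test_correlated_block_r2_matches_direct_computation(self):
        """Haplotype-copy construction with rho=0.8 -> dosage r^2 near
        0.64; the returned r^2 equals the direct correlation computation."""
        rng = np.random.default_rng(3)
        n, p, rho = 2000, 0.4, 0.8
        h1 = rng.random((n, 2)) < p
        h2 = rng.random((n, 2)) < p
        keep = rng.random((n, 2)) < rho
        g1 = np.where(keep[:, 0], h1[:, 0], rng.random(n) < p) + np.where(
            keep[:, 1], h2[:, 0], rng.random(n) < p)
        d = np.column_stack([h1.sum(1) + 0.0, g1]).astype(float)
        d[:, 0] = h1[:, 0] + h2[:, 0]
        geno = make_geno(d, pos=[100, 150])
        out = find_proxy({"rsID": "t", "chr": "1", "pos": 100}, geno)
        assert out is not None
        _, r2, _ = out
        direct = np.corrcoef(d[:, 0], d[:, 1])[0, 1] ** 2
        assert r2 == pytest.approx(direct, rel=1e-12)
        assert r2 == pytest.approx(rho**2, abs=0.08)

    def test_absent_target_rejected(self):
        geno = make_geno(np.zeros((5, 1)) + 1.0, pos=[100])
        with pytest.raises(ValueError):
            find_proxy({"rsID": "t", "chr": "1", "pos": 999}, geno)


class TestMergeAndScore:
    def test_median_merging_conventions(self):
        assert merge_multi_reports([1.28, 1.30, 1.35]) == pytest.approx(1.30)
        assert merge_multi_reports([1.2, 1.4]) == pytest.approx(1.3)
        assert merge_multi_reports([1.28]) == pytest.approx(1.28)
        with pytest.raises(ValueError):
            merge_multi_reports([])

    def test_weighted_score_arithmetic(self):
        d = np.array([[2.0, 1.0]])
        geno = make_geno(d, pos=[100, 200])
        ws = ws_from_rows([("v1", "1", 100, "G", "A", np.log(1.3)),
                           ("v2", "1", 200, "G", "A", np.log(1.2))])
        h, _ = harmonize_weights(ws, geno.variants)
        # 2 ln(1.3) + 1 ln(1.2) = 0.707051
        assert compute_score(geno, h)[0] == pytest.approx(0.707051, abs=1e-6)

    def test_unweighted_sums_risk_alleles(self):
        d = np.array([[2.0, 1.0, 0.0]])
        geno = make_geno(d, pos=[100, 200, 300])
        ws = ws_from_rows([("v1", "1", 100, "G", "A", 0.2),
                           ("v2", "1", 200, "G", "A", 0.1),
                           ("v3", "1", 300, "G", "A", 0.3)], mode="unweighted")
        h, _ = harmonize_weights(ws, geno.variants)
        assert compute_score(geno, h)[0] == pytest.approx(3.0)

    def test_missing_dosage_imputed_with_2p(self):
        # effect-allele frequency 2/(2*4) = 0.25 over the observed calls
        # -> imputed dosage 0.5
        d = np.array([[np.nan], [1.0], [1.0], [0.0], [0.0]])
        geno = make_geno(d, pos=[100])
        w = 0.8
        ws = ws_from_rows([("v1", "1", 100, "G", "A", w)])
        h, _ = harmonize_weights(ws, geno.variants)
        scores = compute_score(geno, h)
        assert scores[0] == pytest.approx(w * 0.5)

    def test_no_overlap_rejected(self, cohort_geno):
        ws = ws_from_rows([("rx", "9", 1, "G", "A", 0.1)])
        h, _ = harmonize_weights(ws, cohort_geno.variants)
        with pytest.raises(ValueError):
            compute_score(cohort_geno, h)


class TestStandardizeAndGroup:
    def test_three_point_z(self):
        res = standardize_and_group([1.0, 2.0, 3.0], [0, 0, 1])
        np.testing.assert_allclose(res.table["z"], [-1.0, 0.0, 1.0])

    def test_study_scale_partition(self):
        rng = np.random.default_rng(6)
        n = 24012
        res = standardize_and_group(rng.normal(size=n),
                                    rng.integers(0, 2, size=n))
        counts = res.table["risk_group"].value_counts()
        assert counts["low"] == 4803
        assert counts["intermediate"] == 14406
        assert counts["high"] == 4803

    def test_null_score_quintile_case_fractions(self):
        rng = np.random.default_rng(7)
        n = 10000
        status = (rng.random(n) < 0.2).astype(int)
        res = standardize_and_group(rng.normal(size=n), status)
        frac = res.table.groupby("quintile")["status"].mean()
        assert np.all(np.abs(frac - 0.2) < 0.04)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(min_value=10, max_value=3000),
           st.integers(min_value=0, max_value=2**31 - 1))
    def test_partition_property(self, n, seed):
        """Quintiles partition any cohort with sizes within 1 of each
        other; risk groups partition it exactly into ceil(.2n)/rest."""
        rng = np.random.default_rng(seed)
        res = standardize_and_group(rng.normal(size=n), np.zeros(n, dtype=int))
        t = res.table
        sizes = t["quintile"].value_counts()
        assert sizes.sum() == n
        assert sizes.max() - sizes.min() <= 1
        n_low = int(np.ceil(0.2 * n))
        counts = t["risk_group"].value_counts()
        assert counts["low"] == n_low
        assert counts["high"] == n_low
        assert counts["intermediate"] == n - 2 * n_low

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            standardize_and_group([1.0, 1.0, 1.0], [0, 1, 0])
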