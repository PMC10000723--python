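"""Agreement statistics against hand computations and library oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import spinefs as sf
from spinefs.agreement_stats import (aggregate_kappa_pairs, cohens_kappa,
                                     grading_accuracy, kappa_from_table,
                                     mcnemar_test, summarize_study,
                                     wilcoxon_exact, wilcoxon_signed_rank)

# Per-pathology kappa pairs (two-sequence reading, synthetic-protocol
# reading) reported by the clinical reader study this layer models.
STUDY_KAPPA_PAIRS = {
    "bone_marrow_abnormality": (0.73, 0.74),
    "spondylodiscitis_expansion": (0.35, 0.43),
    "modic_type1": (0.39, 0.68),
    "vertebral_fracture": (0.77, 0.77),
    "cord_lesion": (0.47, 0.52),
    "paravertebral_abnormality": (0.67, 0.73),
}


class TestCohensKappa:
    def test_perfect_agreement_is_one(self):
        g = [0, 1, 2, 0, 1, 2]
        assert cohens_kappa(g, g).kappa == pytest.approx(1.0)

    def test_hand_computed_two_by_two(self):
        # p_o = 3/4; marginals give p_e = 0.5; kappa = 0.25/0.5 = 0.5
        res = cohens_kappa([0, 0, 1, 1], [0, 1, 1, 1])
        assert res.kappa == pytest.approx(0.5)

    def test_independent_gradings_near_zero(self):
        rng = np.random.default_rng(0)
        g1 = rng.integers(0, 3, 10_000)
        g2 = rng.integers(0, 3, 10_000)
        res = cohens_kappa(g1, g2)
        assert res.ci_low < 0 < res.ci_high
        assert abs(res.kappa) < 0.05

    def test_identical_constant_raters_undefined(self):
        res = cohens_kappa([1, 1, 1, 1], [1, 1, 1, 1])
        assert res.undefined

    def test_matches_sklearn_point_estimate(self):
        from sklearn.metrics import cohen_kappa_score
        rng = np.random.default_rng(3)
        for _ in range(20):
            g1 = rng.integers(0, 4, 50)
            g2 = np.where(rng.random(50) < 0.6, g1, rng.integers(0, 4, 50))
            assert cohens_kappa(g1, g2).kappa == pytest.approx(
                cohen_kappa_score(g1, g2), abs=1e-12)

    def test_matches_statsmodels_variance(self):
        from statsmodels.stats.inter_rater import cohens_kappa as sm_kappa
        rng = np.random.default_rng(4)
        for _ in range(10):
            table = rng.integers(0, 20, (3, 3)).astype(float)
            table += np.diag(rng.integers(5, 15, 3))   # some agreement
            res = kappa_from_table(table)
            ref = sm_kappa(table, return_results=True)
            assert res.kappa == pytest.approx(float(ref.kappa), abs=1e-10)
            assert res.se == pytest.approx(float(np.sqrt(ref.var_kappa)),
                                           rel=1e-6)

    def test_brute_force_all_small_tables(self):
        """kappa from the contingency table equals the chance-corrected
        agreement computed directly from enumerated grade sequences, for
        every 3-category table with n <= 6."""
        checked = 0
        for n in range(2, 7):
            for cells in itertools.product(range(n + 1), repeat=9):
                if sum(cells) != n:
                    continue
                table = np.array(cells, dtype=float).reshape(3, 3)
                g1, g2 = [], []
                for i in range(3):
                    for j in range(3):
                        g1 += [i] * int(table[i, j])
                        g2 += [j] * int(table[i, j])
                po = np.mean(np.array(g1) == np.array(g2))
                row = table.sum(1) / n
                col = table.sum(0) / n
                pe = float(row @ col)
                res = kappa_from_table(table)
                if pe >= 1 - 1e-12:
                    assert res.undefined
                else:
                    assert res.kappa == pytest.approx((po - pe) / (1 - pe),
                                                      abs=1e-12)
                checked += 1
        assert checked > 1000

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_relabeling_invariance_and_upper_bound(self, seed):
        rng = np.random.default_rng(seed)
        g1 = rng.integers(0, 3, 30)
        g2 = rng.integers(0, 3, 30)
        res = cohens_kappa(g1, g2)
        if res.undefined:
            return
        relabel = {0: 7, 1: 3, 2: 5}
        res2 = cohens_kappa([relabel[v] for v in g1], [relabel[v] for v in g2])
        assert res.kappa == pytest.approx(res2.kappa, abs=1e-12)
        assert res.kappa <= 1.0 + 1e-12
        assert res.ci_low <= res.kappa <= res.ci_high


class TestGradingAccuracy:
    def test_exact_and_partial(self):
        assert grading_accuracy([1, 2], [1, 2]) == 1.0
        assert grading_accuracy([0] * 9 + [1], [0] * 10) == pytest.approx(0.9)

    def test_pooling_equals_mean_of_equal_sized_readers(self):
        rng = np.random.default_rng(1)
        g1, g2 = rng.integers(0, 3, 40), rng.integers(0, 3, 40)
        gt = rng.integers(0, 3, 40)
        pooled = grading_accuracy(np.concatenate([g1, g2]),
                                  np.concatenate([gt, gt]))
        assert pooled == pytest.approx(
            (grading_accuracy(g1, gt) + grading_accuracy(g2, gt)) / 2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            grading_accuracy([1, 2], [1, 2, 3])


class TestWilcoxon:
    def test_study_kappa_pairs_reproduce_published_p(self):
        # differences 0.01, 0.08, 0.29, 0.00, 0.05, 0.06: zero discarded,
        # n = 5, W+ = 15, z = 7.5/sqrt(13.75) ~ 2.023 -> p = 0.043
        pairs = [(s, t) for t, s in STUDY_KAPPA_PAIRS.values()]
        res = wilcoxon_signed_rank(pairs)
        assert res.n_nonzero == 5 and res.w_plus == 15.0
        assert res.z == pytest.approx(7.5 / np.sqrt(13.75), rel=1e-12)
        assert round(res.p, 3) == 0.043

    def test_exact_enumeration_oracle_differs_as_documented(self):
        pairs = [(s, t) for t, s in STUDY_KAPPA_PAIRS.values()]
        assert wilcoxon_exact(pairs) == pytest.approx(0.0625)

    def test_all_equal_pairs_flagged(self):
        res = wilcoxon_signed_rank([(1.0, 1.0), (2.0, 2.0)])
        assert res.undefined

    def test_antisymmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=8), rng.normal(size=8)
        r1 = wilcoxon_signed_rank(list(zip(a, b)))
        r2 = wilcoxon_signed_rank(list(zip(b, a)))
        assert r1.z == pytest.approx(-r2.z, rel=1e-12)
        assert r1.p == pytest.approx(r2.p, rel=1e-12)

    def test_matches_scipy_asymptotic(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = rng.normal(size=12)
            b = a + rng.normal(0.3, 1.0, size=12)
            res = wilcoxon_signed_rank(list(zip(a, b)))
            ref = scipy_wilcoxon(a, b, zero_method="wilcox", correction=False,
                                 method="approx")
            assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_asymptotic_agrees_with_exact_decision_usually(self):
        """On random small samples, the asymptotic and exact tests reach the
        same alpha = 0.05 rejection decision in >= 95% of cases."""
        rng = np.random.default_rng(6)
        agree = 0
        trials = 200
        for _ in range(trials):
            n = int(rng.integers(6, 11))
            a = rng.normal(size=n)
            b = a + rng.normal(rng.uniform(-1, 1), 1.0, size=n)
            res = wilcoxon_signed_rank(list(zip(a, b)))
            pe = wilcoxon_exact(list(zip(a, b)))
            agree += (res.p < 0.05) == (pe < 0.05)
        assert agree / trials >= 0.95


class TestMcNemar:
    def test_no_discordance_is_p_one(self):
        res = mcnemar_test([True, False, True], [True, False, True])
        assert res.p == 1.0 and res.degenerate

    def test_two_vs_eight_binomial_enumeration(self):
        # b = 2, c = 8: exact p = 2 P(X <= 2 | n=10) = 112/1024
        a = [True] * 2 + [False] * 8 + [True] * 5
        b = [False] * 2 + [True] * 8 + [True] * 5
        res = mcnemar_test(a, b)
        assert res.b == 2 and res.c == 8
        assert res.p == pytest.approx(112 / 1024, abs=1e-12)

    def test_symmetric_discordance_is_p_one(self):
        a = [True] * 3 + [False] * 3
        b = [False] * 3 + [True] * 3
        assert mcnemar_test(a, b).p == pytest.approx(1.0)

    def test_exact_matches_statsmodels_for_all_small_counts(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar
        for b in range(13):
            for c in range(13 - b):
                if b + c == 0:
                    continue
                corr_a = [True] * b + [False] * c
                corr_b = [False] * b + [True] * c
                res = mcnemar_test(corr_a, corr_b)
                table = [[0, b], [c, 0]]
                ref = sm_mcnemar(table, exact=True)
                assert res.p == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_large_counts_use_corrected_chi_square(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar
        a = [True] * 20 + [False] * 15 + [True] * 30
        b = [False] * 20 + [True] * 15 + [True] * 30
        res = mcnemar_test(a, b)
        assert res.method == "chi2_corrected"
        ref = sm_mcnemar([[0, 20], [15, 0]], exact=False, correction=True)
        assert res.p == pytest.approx(float(ref.pvalue), rel=1e-9)


class TestSummarizeStudy:
    def test_published_pair_aggregation_reproduces_headline_numbers(self):
        agg = aggregate_kappa_pairs(STUDY_KAPPA_PAIRS)
        assert round(agg["mean_kappa"]["synthetic_protocol"], 2) == 0.65
        assert round(agg["mean_kappa"]["two_sequence"], 2) == 0.56
        assert round(agg["wilcoxon"].p, 3) == 0.043

    def _perfect_records(self, n=12):
        gt = sf.sample_ground_truth(0, n)
        rows = []
        for proto in ("two_sequence", "synthetic_protocol"):
            rec = sf.simulate_readers(gt, proto, error_model=0.0, seed=1)
            rows.append(rec)
        return pd.concat(rows, ignore_index=True)

    def test_perfect_agreement_everywhere(self):
        report = summarize_study(self._perfect_records())
        for kind, entry in report.per_pathology.items():
            for proto in ("two_sequence", "synthetic_protocol"):
                assert entry[proto]["accuracy"] == 1.0
                kr = entry[proto]["kappa"]
                assert kr.undefined or kr.kappa == pytest.approx(1.0)
        assert report.wilcoxon.undefined

    def test_simulated_study_reproduces_protocol_ordering(self):
        gt = sf.sample_ground_truth(3, 101)
        frames = [sf.simulate_readers(gt, "two_sequence", seed=10),
                  sf.simulate_readers(gt, "synthetic_protocol", seed=11)]
        report = summarize_study(pd.concat(frames, ignore_index=True))
        assert report.mean_kappa["synthetic_protocol"] > \
            report.mean_kappa["two_sequence"]
        # fluid-sensitive kinds should individually favor the synthetic read
        better = sum(
            entry["synthetic_protocol"]["kappa"].kappa
            > entry["two_sequence"]["kappa"].kappa
            for entry in report.per_pathology.values())
        assert better >= 4

    def test_missing_ground_truth_is_explicit_error(self):
        records = self._perfect_records().drop(columns=["gt_grade"])
        with pytest.raises(ValueError, match="ground truth"):
            summarize_study(records)

    def test_ground_truth_rows_joined_when_column_absent(self):
        records = self._perfect_records()
        gt_rows = records[records.protocol == "two_sequence"].copy()
        gt_rows = gt_rows[gt_rows.reader_id == 1]
        gt_rows["protocol"] = "ground_truth"
        gt_rows["reader_id"] = 0
        stacked = pd.concat([records.drop(columns=["gt_grade"]), gt_rows.drop(
            columns=["gt_grade"])], ignore_index=True)
        report = summarize_study(stacked)
        for entry in report.per_pathology.values():
            assert entry["synthetic_protocol"]["accuracy"] == 1.0

    def test_report_json_and_tables(self, tmp_path):
        report = summarize_study(self._perfect_records())
        out = tmp_path / "report.json"
        sf.agreement_stats.write_report(report, out)
        assert out.exists() and "mean_kappa" in out.read_text()
        assert set(report.kappa_table().pathology) == set(
            report.accuracy_table().pathology)
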