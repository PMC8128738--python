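"""Screening statistics: ICC, ROC/AUC, cutoff selection, 2x2 metrics,
group comparisons, sign test and summaries — each checked against an
independent route (hand formulas, enumeration oracles, pingouin, pROC)."""

import math
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import (
    anova_icc2,
    exhaustive_cutoff,
    pairwise_auc,
    rank_sum_exact_p,
    two_sided_binomial_p,
)
from macscore.agatston import ArteryScore, MacsProfile
from macscore.cohort_stats import (
    CohortRecord,
    apply_cutoff,
    classification_metrics,
    compare_groups,
    contingency_test,
    icc,
    median_iqr,
    roc,
    select_cutoff,
    sign_test,
    summarize_scores,
)


def record(pid, group, ca=0.0, sma=0.0, ima=0.0):
    return CohortRecord(
        patient_id=pid, group=group,
        profile=MacsProfile(ArteryScore("CA", ca), ArteryScore("SMA", sma),
                            ArteryScore("IMA", ima)),
    )


# ---------------------------------------------------------------------------
# ICC

RATINGS_6x2 = np.array([
    [9.0, 2.0],
    [1.0, 10.0],
    [8.0, 4.0],
    [12.0, 13.0],
    [3.0, 1.0],
    [17.0, 16.0],
])


class TestIcc:
    def test_duplicate_raters_give_perfect_agreement(self):
        base = np.array([3.0, 8.0, 1.0, 12.0, 5.0, 9.0])
        result = icc(np.column_stack([base, base]))
        assert result.icc == pytest.approx(1.0)
        assert result.band == "excellent"

    def test_matches_hand_anova_oracle(self):
        result = icc(RATINGS_6x2, model="ICC2")
        assert result.icc == pytest.approx(anova_icc2(RATINGS_6x2.tolist()),
                                           abs=1e-12)

    def test_matches_pingouin_point_estimate_and_ci(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        n, k = RATINGS_6x2.shape
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "rating": RATINGS_6x2.ravel(),
        })
        table = pingouin.intraclass_corr(long, targets="subject",
                                         raters="rater", ratings="rating")
        # the absolute-agreement single-rater row is labelled ICC2 or ICC(A,1)
        sel = table["Type"].astype(str).str.replace(" ", "").isin(["ICC2", "ICC(A,1)"])
        ref = table[sel].iloc[0]
        result = icc(RATINGS_6x2, model="ICC2")
        assert result.icc == pytest.approx(ref["ICC"], abs=1e-10)
        ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
        assert result.ci95 == pytest.approx(tuple(ref[ci_col]), abs=5e-3)

    def test_constant_offset_on_one_rater_decreases_absolute_agreement(self):
        base = icc(RATINGS_6x2, model="ICC2").icc
        shifted = RATINGS_6x2.copy()
        shifted[:, 1] += 5.0
        assert icc(shifted, model="ICC2").icc < base

    def test_monotone_degradation_under_rater_noise(self):
        rng = np.random.default_rng(42)
        truth = rng.uniform(0, 100, size=12)
        unit_noise = rng.normal(0, 1, size=12)
        values = []
        for sd in (0.0, 5.0, 10.0, 20.0, 40.0):
            ratings = np.column_stack([truth, truth + sd * unit_noise])
            values.append(icc(ratings).icc)
        assert values[0] == pytest.approx(1.0)
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_ci_brackets_estimate_and_bands(self):
        result = icc(RATINGS_6x2)
        lo, hi = result.ci95
        assert -1.0 <= lo <= result.icc <= hi <= 1.0
        assert result.band in ("poor", "moderate", "good", "excellent")

    def test_constant_ratings_rejected(self):
        with pytest.raises(ValueError):
            icc(np.full((6, 2), 7.0))

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            icc(RATINGS_6x2[:3])


# ---------------------------------------------------------------------------
# ROC / AUC / cutoff

class TestRoc:
    def test_perfect_separation_gives_auc_one(self):
        scores = [1, 2, 3, 10, 11, 12]
        labels = [False] * 3 + [True] * 3
        assert roc(scores, labels).auc == pytest.approx(1.0)

    def test_label_flip_symmetry(self):
        rng = np.random.default_rng(0)
        scores = np.round(rng.uniform(0, 10, 30), 1)  # rounding makes ties
        labels = rng.random(30) > 0.5
        a = roc(scores, labels).auc
        b = roc(scores, ~labels).auc
        assert a + b == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_auc_equals_pairwise_count_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 8, size=20).astype(float)  # heavy ties
        labels = rng.random(20) > 0.4
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        assert roc(scores, labels).auc == pytest.approx(
            pairwise_auc(scores.tolist(), labels.tolist()), abs=1e-12)

    def test_delong_ci_brackets_auc(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(0, 1, 60) + np.repeat([0.0, 1.0], 30)
        labels = np.repeat([False, True], 30)
        r = roc(scores, labels)
        lo, hi = r.auc_ci95
        assert 0.0 <= lo <= r.auc <= hi <= 1.0
        assert hi - lo < 0.5

    def test_delong_ci_matches_r_proc(self, tmp_path):
        rng = np.random.default_rng(9)
        scores = np.round(rng.normal(0, 1, 40) + np.repeat([0.0, 0.8], 20), 3)
        labels = np.repeat([0, 1], 20)
        r = roc(scores, labels.astype(bool))
        script = tmp_path / "ci.R"
        script.write_text(
            "suppressMessages(library(pROC))\n"
            f"s <- c({','.join(map(str, scores))})\n"
            f"l <- c({','.join(map(str, labels))})\n"
            "r <- roc(l, s, quiet=TRUE, direction='<')\n"
            "ci <- ci.auc(r, method='delong')\n"
            "cat(sprintf('%.10f %.10f %.10f', ci[1], ci[2], ci[3]))\n"
        )
        try:
            out = subprocess.run(["Rscript", str(script)], capture_output=True,
                                 text=True, timeout=120)
        except (FileNotFoundError, subprocess.TimeoutExpired):
            pytest.skip("Rscript unavailable")
        if out.returncode != 0:
            pytest.skip(f"pROC unavailable: {out.stderr[:200]}")
        lo, mid, hi = map(float, out.stdout.split())
        assert r.auc == pytest.approx(mid, abs=1e-9)
        assert r.auc_ci95[0] == pytest.approx(max(lo, 0.0), abs=1e-6)
        assert r.auc_ci95[1] == pytest.approx(min(hi, 1.0), abs=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc([1.0, 2.0], [True, True])


class TestSelectCutoff:
    def test_perfect_separation_returns_gap_midpoint(self):
        scores = [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]
        labels = [False] * 3 + [True] * 3
        assert select_cutoff(roc(scores, labels)) == pytest.approx(6.5)

    def test_six_point_toy_set_matches_exhaustive_search(self):
        scores = [0.0, 5.0, 7.0, 6.0, 20.0, 35.0]
        labels = [False, False, True, False, True, True]
        assert select_cutoff(roc(scores, labels)) == pytest.approx(
            exhaustive_cutoff(scores, labels))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_search_on_random_instances(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(6, 25))
        scores = np.round(rng.uniform(0, 50, n), 1)
        labels = rng.random(n) > 0.5
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        assert select_cutoff(roc(scores, labels)) == pytest.approx(
            exhaustive_cutoff(scores.tolist(), labels.tolist()))

    def test_degenerate_all_equal_scores(self, caplog):
        scores = [5.0] * 8
        labels = [True] * 4 + [False] * 4
        with caplog.at_level("WARNING"):
            cutoff = select_cutoff(roc(scores, labels))
        assert cutoff == 5.0


# ---------------------------------------------------------------------------
# screening metrics

class TestClassificationMetrics:
    def test_derived_confusion_table_reproduces_published_row(self):
        # 49 diseased / 135 disease-free split at the combined-score cutoff
        m = classification_metrics(tp=43, fp=65, tn=70, fn=6)
        assert round(m.sensitivity, 1) == 87.8
        assert round(m.specificity, 1) == 51.9
        assert round(m.ppv, 1) == 39.8
        assert round(m.npv, 1) == 92.1

    def test_perfect_two_patient_table(self):
        m = classification_metrics(1, 0, 1, 0)
        assert m.sensitivity == m.specificity == m.ppv == m.npv == 100.0

    def test_undefined_ppv_is_explicit_null(self):
        m = classification_metrics(tp=0, fp=0, tn=5, fn=5)
        assert m.ppv is None
        assert m.npv == pytest.approx(50.0)

    @settings(derandomize=True, max_examples=100)
    @given(st.tuples(st.integers(1, 200), st.integers(0, 200),
                     st.integers(1, 200), st.integers(0, 200)))
    def test_bayes_identity_on_unrounded_values(self, counts):
        tp, fp, tn, fn = counts
        m = classification_metrics(tp, fp, tn, fn)
        if m.ppv is None:
            return
        prev = (tp + fn) / m.n
        sens = m.sensitivity / 100.0
        spec = m.specificity / 100.0
        expected_ppv = sens * prev / (sens * prev + (1 - spec) * (1 - prev))
        assert m.ppv / 100.0 == pytest.approx(expected_ppv, abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(st.tuples(st.integers(1, 200), st.integers(0, 200),
                     st.integers(1, 200), st.integers(0, 200)))
    def test_formulas_match_direct_recomputation(self, counts):
        tp, fp, tn, fn = counts
        m = classification_metrics(tp, fp, tn, fn)
        assert m.sensitivity == pytest.approx(100 * tp / (tp + fn))
        assert m.specificity == pytest.approx(100 * tn / (tn + fp))
        assert m.negative_fraction_non_cmi == pytest.approx(
            100 * tn / (tp + fp + tn + fn))


from conftest import reconstructed_cohort  # noqa: E402


class TestApplyCutoff:
    def test_reconstructed_cohort_reproduces_negative_fraction(self):
        cohort = reconstructed_cohort()
        m = apply_cutoff(cohort, "ca_sma", 29.7)
        assert (m.tp, m.fp, m.tn, m.fn) == (43, 65, 70, 6)
        assert round(m.negative_fraction_non_cmi) == 38  # 70 of 184

    def test_all_below_cutoff(self):
        cohort = [record("a", "CMI", ca=1.0), record("b", "non-CMI", ca=2.0)]
        m = apply_cutoff(cohort, "ca", 100.0)
        assert m.tp == 0 and m.fp == 0

    def test_minus_infinity_cutoff_is_all_positive(self):
        cohort = [record("a", "CMI", ca=1.0), record("b", "non-CMI", ca=2.0)]
        m = apply_cutoff(cohort, "ca", -math.inf)
        assert m.sensitivity == 100.0 and m.specificity == 0.0

    def test_unknown_score_field_rejected(self):
        cohort = [record("a", "CMI"), record("b", "non-CMI")]
        with pytest.raises(ValueError):
            apply_cutoff(cohort, "aorta", 1.0)


# ---------------------------------------------------------------------------
# group comparisons

class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        res = compare_groups([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.pvalue > 0.9

    def test_small_sample_wilcoxon_matches_permutation_oracle(self):
        a = [1.0, 4.0, 6.0, 9.0]
        b = [2.0, 7.0, 11.0, 13.0]
        res = compare_groups(a, b, kind="continuous")
        assert res.pvalue == pytest.approx(rank_sum_exact_p(a, b), abs=1e-12)

    def test_fisher_exact_matches_hypergeometric_hand_computation(self):
        res = contingency_test(np.array([[10, 0], [0, 10]]))
        assert res.test == "fisher-exact"
        # both extreme tables have probability 1/C(20,10)
        assert res.pvalue == pytest.approx(2.0 / math.comb(20, 10), rel=1e-9)

    def test_categorical_from_labels_uses_chi_square_when_well_filled(self):
        a = ["yes"] * 30 + ["no"] * 20
        b = ["yes"] * 10 + ["no"] * 40
        res = compare_groups(a, b, kind="categorical")
        assert res.test == "chi-square"
        assert res.pvalue < 0.01

    def test_sparse_categorical_switches_to_fisher(self):
        a = ["yes"] * 2 + ["no"] * 8
        b = ["yes"] * 8 + ["no"] * 2
        res = compare_groups(a, b, kind="categorical")
        assert res.test == "fisher-exact"


class TestSignTest:
    def test_all_eight_pairs_increase(self):
        a = list(range(8))
        b = [v + 1.0 for v in a]
        res = sign_test(a, b)
        assert res.pvalue == pytest.approx(2 * 0.5 ** 8)

    def test_equal_pairs_give_p_one(self, caplog):
        with caplog.at_level("WARNING"):
            res = sign_test([1.0, 2.0], [1.0, 2.0])
        assert res.pvalue == 1.0
        assert res.n_zero == 2

    def test_seven_of_ten_matches_binomial_tail_enumeration(self):
        a = [0.0] * 10
        b = [1.0] * 7 + [-1.0] * 3
        res = sign_test(a, b)
        assert res.n_positive == 7 and res.n_negative == 3
        assert res.pvalue == pytest.approx(two_sided_binomial_p(7, 10), rel=1e-12)

    def test_zero_differences_dropped_not_counted(self):
        a = [0.0, 0.0, 0.0, 5.0]
        b = [1.0, 1.0, 1.0, 5.0]
        res = sign_test(a, b)
        assert res.n_zero == 1
        assert res.pvalue == pytest.approx(2 * 0.5 ** 3)


# ---------------------------------------------------------------------------
# summaries

class TestSummaries:
    def test_all_zero_group(self):
        assert str(median_iqr([0.0, 0.0, 0.0])) == "0 (0–0)"

    def test_linear_interpolation_quartiles(self):
        m = median_iqr([1.0, 2.0, 3.0, 4.0, 5.0])
        assert (m.median, m.q1, m.q3) == (3.0, 2.0, 4.0)

    def test_per_group_summary(self):
        cohort = [record(f"c{i}", "CMI", ca=v) for i, v in enumerate([10, 20, 30])]
        cohort += [record(f"n{i}", "non-CMI", ca=0.0) for i in range(3)]
        out = summarize_scores(cohort, "ca")
        assert out["CMI"].median == 20.0
        assert out["non-CMI"].median == 0.0
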