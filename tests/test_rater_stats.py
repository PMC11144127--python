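import numpy as np
import pandas as pd
import pytest

from fluoroperf.data import (
    agreement_counts_from_summary,
    load_lesion_sizes,
    load_survey_summary,
)
from fluoroperf.rater_stats import (
    AgreementCounts,
    DegenerateAgreementError,
    RaterTable,
    build_report,
    fleiss_kappa,
    interpret_kappa,
    likert_summary,
    majority_decision,
    majority_from_counts,
    rater_performance,
    size_error,
    spearman_correlation,
)
from fluoroperf.synthetic_data import RaterModelParams, simulate_rater_table


def random_table(n_raters=8, n_items=10, seed=0):
    params = RaterModelParams(
        n_raters=n_raters, n_items=n_items, difficulty=0.0, skill=0.5,
        truth=list(np.random.default_rng(seed).choice(["benign", "cancer"], n_items)),
        seed=seed,
    )
    return simulate_rater_table(params)


class TestFleissKappa:
    def test_reconstructed_survey_counts(self):
        # 14 items x 32 raters reconstructed from the majority percentages
        res = fleiss_kappa(agreement_counts_from_summary())
        assert round(res.kappa, 3) == 0.261
        assert round(res.ci_low, 3) == 0.237
        assert round(res.ci_high, 3) == 0.285
        assert res.band == "fair"

    def test_hand_worked_example(self):
        # 3 raters, 2 items: P_i = 1/3 each, P_bar = 1/3, P_e = 1/2
        counts = AgreementCounts(np.array([[2, 1], [1, 2]]))
        res = fleiss_kappa(counts)
        assert res.p_observed == pytest.approx(1 / 3)
        assert res.p_expected == pytest.approx(1 / 2)
        assert res.kappa == pytest.approx(-1 / 3)

    def test_unanimous_is_one(self):
        counts = AgreementCounts(np.array([[5, 0], [0, 5], [5, 0]]))
        assert fleiss_kappa(counts).kappa == pytest.approx(1.0)

    def test_single_category_degenerate(self):
        counts = AgreementCounts(np.array([[5, 0], [5, 0]]))
        with pytest.raises(DegenerateAgreementError):
            fleiss_kappa(counts)

    def test_matches_statsmodels(self):
        # dual-route check of the point estimate
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss

        rng = np.random.default_rng(8)
        for _ in range(5):
            votes = rng.integers(0, 7, size=(10, 1))
            counts = np.hstack([votes, 6 - votes]).astype(int)
            ours = fleiss_kappa(AgreementCounts(counts)).kappa
            theirs = sm_fleiss(counts, method="fleiss")
            assert ours == pytest.approx(theirs, abs=1e-12)

    def test_item_order_invariance(self):
        counts = agreement_counts_from_summary()
        perm = np.random.default_rng(1).permutation(counts.n_items)
        permuted = AgreementCounts(counts.counts[perm])
        assert fleiss_kappa(permuted).kappa == pytest.approx(
            fleiss_kappa(counts).kappa, abs=1e-15
        )

    def test_category_swap_invariance(self):
        counts = agreement_counts_from_summary()
        swapped = AgreementCounts(counts.counts[:, ::-1].copy())
        assert fleiss_kappa(swapped).kappa == pytest.approx(
            fleiss_kappa(counts).kappa, abs=1e-15
        )

    def test_ci_brackets_kappa_and_shrinks_with_items(self):
        base = agreement_counts_from_summary()
        widths = []
        for reps in (1, 4, 16):
            counts = AgreementCounts(np.tile(base.counts, (reps, 1)))
            res = fleiss_kappa(counts)
            assert res.ci_low <= res.kappa <= res.ci_high
            widths.append(res.ci_high - res.ci_low)
        assert widths[0] > widths[1] > widths[2]

    def test_unbalanced_rater_counts_rejected(self):
        with pytest.raises(ValueError, match="same number of raters"):
            AgreementCounts(np.array([[3, 1], [2, 1]]))


class TestInterpretKappa:
    @pytest.mark.parametrize(
        "kappa,band",
        [(0.261, "fair"), (0.187, "poor"), (1.0, "very good"),
         (0.5, "moderate"), (0.7, "good"), (-0.4, "poor")],
    )
    def test_bands(self, kappa, band):
        assert interpret_kappa(kappa) == band

    def test_gap_value_warns_and_takes_lower_band(self):
        with pytest.warns(UserWarning, match="gap"):
            assert interpret_kappa(0.205) == "poor"

    def test_above_one_rejected(self):
        with pytest.raises(ValueError):
            interpret_kappa(1.2)


class TestLikert:
    def _table_from_counts(self, counts_row):
        # one item, confidence distributed per counts_row over 32 raters
        conf = np.repeat(np.arange(1, 6), counts_row)
        n = conf.size
        answers = pd.DataFrame({"P1": ["benign"] * n}, index=[f"R{i}" for i in range(n)])
        confidence = pd.DataFrame({"P1": conf}, index=answers.index)
        return RaterTable(answers=answers, confidence=confidence)

    def test_printed_mean_examples(self):
        # frequency rows with published means 3.28 and 3.84
        assert likert_summary(self._table_from_counts([0, 4, 16, 11, 1]))["mean"].iloc[0] == 3.28
        assert likert_summary(self._table_from_counts([0, 1, 9, 16, 6]))["mean"].iloc[0] == 3.84

    def test_all_level_three(self):
        out = likert_summary(self._table_from_counts([0, 0, 32, 0, 0]))
        assert out["mean"].iloc[0] == 3.00
        assert out["pct_3"].iloc[0] == 100.0
        assert out["n_3"].iloc[0] == 32

    def test_all_14_published_means(self):
        summary = load_survey_summary()
        for _, row in summary.iterrows():
            counts = [row[f"n_{lv}"] for lv in range(1, 6)]
            mean = likert_summary(self._table_from_counts(counts))["mean"].iloc[0]
            assert mean == pytest.approx(row["mean_likert"]), row["polyp_id"]


class TestRaterPerformance:
    def _table(self, answer_rows, truth):
        answers = pd.DataFrame(
            answer_rows, index=[f"R{i}" for i in range(len(answer_rows))],
            columns=[f"P{j}" for j in range(len(truth))],
        )
        return RaterTable(
            answers=answers,
            truth=pd.Series(truth, index=answers.columns),
            grades=pd.Series(["consultant"] * len(answer_rows), index=answers.index),
        )

    def test_all_correct_rater(self):
        truth = ["cancer"] * 7 + ["benign"] * 7
        table = self._table([truth], truth)
        row = rater_performance(table)["per_rater"].iloc[0]
        assert (row["accuracy"], row["sensitivity"], row["specificity"]) == (100, 100, 100)

    def test_all_cancer_rater(self):
        truth = ["cancer"] * 7 + ["benign"] * 7
        table = self._table([["cancer"] * 14], truth)
        row = rater_performance(table)["per_rater"].iloc[0]
        assert row["accuracy"] == 50
        assert row["sensitivity"] == 100
        assert row["specificity"] == 0

    def test_group_means_match_brute_force(self):
        table = random_table(n_raters=12, n_items=14, seed=5)
        out = rater_performance(table)
        per_rater = out["per_rater"]
        # naive loop oracle
        for rater in table.answers.index:
            correct = tp = fn = tn = fp = 0
            for item in table.answers.columns:
                ans, tru = table.answers.loc[rater, item], table.truth.loc[item]
                correct += ans == tru
                if tru == "cancer":
                    tp += ans == "cancer"
                    fn += ans == "benign"
                else:
                    tn += ans == "benign"
                    fp += ans == "cancer"
            assert per_rater.loc[rater, "accuracy"] == pytest.approx(100 * correct / 14)
            if tp + fn:
                assert per_rater.loc[rater, "sensitivity"] == pytest.approx(100 * tp / (tp + fn))
        assert out["all"].loc["all", "accuracy_mean"] == pytest.approx(
            per_rater["accuracy"].mean()
        )


class TestMajority:
    def test_survey_reconstruction_6_of_14_one_even(self):
        counts = agreement_counts_from_summary()
        truth = load_survey_summary()["pathology"]
        out = majority_from_counts(counts, truth)
        assert out.attrs["n_majority_correct"] == 6
        assert out.attrs["n_even"] == 1
        assert out.loc["P14", "even_split"]

    def test_even_split_flagged(self):
        answers = pd.DataFrame(
            {"P1": ["benign"] * 16 + ["cancer"] * 16}, index=[f"R{i}" for i in range(32)]
        )
        out = majority_decision(RaterTable(answers=answers))
        assert out.loc["P1", "majority_answer"] == "even"
        assert out.loc["P1", "share_pct"] == 50.0
        assert out.loc["P1", "even_split"]

    def test_unanimous(self):
        answers = pd.DataFrame({"P1": ["cancer"] * 5}, index=[f"R{i}" for i in range(5)])
        out = majority_decision(RaterTable(answers=answers))
        assert out.loc["P1", "share_pct"] == 100.0
        assert not out.loc["P1", "even_split"]

    def test_decision_matches_counts_path(self):
        table = random_table(n_raters=9, n_items=12, seed=2)
        a = majority_decision(table)
        b = majority_from_counts(AgreementCounts.from_table(table), table.truth)
        assert (a["majority_answer"] == b["majority_answer"]).all()
        assert a.attrs["n_majority_correct"] == b.attrs["n_majority_correct"]


class TestSpearman:
    def test_monotone_series(self):
        x = np.arange(10.0)
        rho, _ = spearman_correlation(x, x**3)
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_correlation(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            spearman_correlation([1, 1, 1], [1, 2, 3])

    def test_ties_match_naive_rank_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            x = rng.integers(1, 5, 12).astype(float)
            y = rng.integers(0, 2, 12).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue

            def naive_rank(v):
                order = np.argsort(v, kind="stable")
                ranks = np.empty(len(v))
                i = 0
                sorted_v = v[order]
                while i < len(v):
                    j = i
                    while j < len(v) and sorted_v[j] == sorted_v[i]:
                        j += 1
                    ranks[order[i:j]] = (i + j - 1) / 2 + 1
                    i = j
                return ranks

            rx, ry = naive_rank(x), naive_rank(y)
            oracle = np.corrcoef(rx, ry)[0, 1]
            rho, _ = spearman_correlation(x, y)
            assert rho == pytest.approx(oracle, abs=1e-12)


class TestSizeError:
    def test_underestimated_large_lesion(self):
        est = pd.Series({"S1": 60.0})
        actual = pd.Series({"S1": 120.0})
        out = size_error(est, actual)
        assert out.loc["S1", "signed_pct"] == pytest.approx(-50.0)

    def test_small_error_case(self):
        out = size_error(pd.Series({"S3": 44.0}), pd.Series({"S3": 46.0}))
        assert out.loc["S3", "signed_pct"] == pytest.approx(-4.3, abs=0.05)

    def test_exact_estimate(self):
        out = size_error(pd.Series({"a": 30.0}), pd.Series({"a": 30.0}))
        assert out.loc["a", "signed_pct"] == 0.0

    def test_nonpositive_actual_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            size_error(pd.Series({"a": 10.0}), pd.Series({"a": 0.0}))

    def test_bundled_table_means(self):
        sizes = load_lesion_sizes()
        out = size_error(
            sizes.set_index("polyp_id")["mean_estimate_mm"],
            sizes.set_index("polyp_id")["actual_mm"],
        )
        # recomputation gives 21.4% overall and 15.6% for the five
        # fully-visible lesions (printed figures: 20% and 15%)
        assert out.attrs["mean_abs_pct"] == pytest.approx(21.4, abs=0.05)
        visible = out.drop("S1")
        assert visible["abs_pct"].mean() == pytest.approx(15.6, abs=0.05)


class TestReport:
    def test_build_report_sections(self):
        params = RaterModelParams(
            n_raters=10, n_items=14, difficulty=0.0, skill=1.0,
            truth=["benign", "cancer"] * 7, seed=6,
        )
        table = simulate_rater_table(params)
        report = build_report(table)
        for key in ("kappa", "likert", "performance", "majority", "confidence_vs_correct"):
            assert key in report
        assert report["n_raters"] == 10
        assert "kappa" in report["kappa"] or "error" in report["kappa"]
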