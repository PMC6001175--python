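"""ROC/AUC, split enumeration, CI construction, and the model-group runner."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hbresponse.cohort import concat_cohorts, design_frame
from hbresponse.evaluation import (
    TABLE4_GROUPS,
    auc_mann_whitney,
    confusion_metrics,
    enumerate_splits,
    evaluate_model_over_splits,
    mean_auc_ci,
    roc_curve,
    run_model_groups,
)
from hbresponse.pipeline import study_split_scheme
from hbresponse.simulate import (
    early_cohort_config,
    generate_cohort,
    new_cohort_config,
)


class TestRocCurve:
    def test_perfect_separation_gives_auc_one(self):
        roc = roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert roc.auc == pytest.approx(1.0)

    def test_all_tied_scores_give_half(self):
        roc = roc_curve([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert roc.auc == pytest.approx(0.5)

    def test_three_of_four_pairs_concordant(self):
        # class-1 scores {0.9, 0.4} vs class-0 scores {0.2, 0.8}
        roc = roc_curve([0.9, 0.4, 0.2, 0.8], [1, 1, 0, 0])
        assert roc.auc == pytest.approx(0.75)

    def test_curve_shape_invariants(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        roc = roc_curve(scores, labels)
        assert tuple(roc.points[0]) == (0.0, 0.0)
        assert tuple(roc.points[-1]) == (1.0, 1.0)
        assert np.all(np.diff(roc.points[:, 0]) >= 0)
        assert np.all(np.diff(roc.points[:, 1]) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve([0.1, 0.2], [1, 1])


class TestAucIdentity:
    @given(st.integers(0, 999))
    def test_trapezoid_equals_mann_whitney(self, seed):
        # the identity must hold exactly, including under heavy ties
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 40)
        scores = np.round(rng.normal(size=n), rng.integers(0, 3))
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert roc_curve(scores, labels).auc == pytest.approx(
            auc_mann_whitney(scores, labels), abs=1e-12
        )

    @given(st.integers(0, 200))
    def test_complementation_under_score_negation(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=20)
        labels = rng.integers(0, 2, 20)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert auc_mann_whitney(-scores, labels) == pytest.approx(
            1.0 - auc_mann_whitney(scores, labels)
        )

    def test_exhaustive_pairwise_oracle(self, rng):
        scores = rng.normal(size=16)
        labels = rng.integers(0, 2, 16)
        labels[:2] = [0, 1]
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        conc = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert auc_mann_whitney(scores, labels) == pytest.approx(
            conc / (len(pos) * len(neg))
        )


class TestSplitEnumeration:
    def test_study_configuration_yields_462_splits(self):
        ids = [f"H{i}" for i in range(11)]
        fixed = [f"E{i}" for i in range(32)]
        pool = ids + [f"N{i}" for i in range(11)]
        scheme = enumerate_splits(ids, 6, fixed, pool)
        assert scheme.n_splits == 462
        assert scheme.train_size == 38
        for train, test in scheme.splits:
            assert len(train) == 38 and len(test) == 16
            assert set(train).isdisjoint(test)
            assert set(train) | set(test) == set(fixed) | set(pool)

    def test_two_choose_one(self):
        scheme = enumerate_splits(["a", "b"], 1, ["f"], ["a", "b", "c"])
        assert scheme.n_splits == 2
        assert scheme.splits[0] == (("f", "a"), ("b", "c"))
        assert scheme.splits[1] == (("f", "b"), ("a", "c"))

    def test_five_choose_three_all_distinct(self):
        ids = list("abcde")
        scheme = enumerate_splits(ids, 3, ["f1", "f2"], ids)
        assert scheme.n_splits == 10
        transfers = [tuple(sorted(set(tr) - {"f1", "f2"})) for tr, _ in scheme.splits]
        assert sorted(transfers) == sorted(combinations(ids, 3))

    def test_each_id_transferred_binomially_often(self):
        ids = list("abcdefg")
        scheme = enumerate_splits(ids, 3, [], ids)
        for pid in ids:
            count = sum(pid in train for train, _ in scheme.splits)
            assert count == comb(len(ids) - 1, 2)

    def test_k_larger_than_pool_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            enumerate_splits(["a"], 2, [], ["a"])


class TestMeanAucCi:
    def test_empirical_interval_of_constant_aucs(self):
        lo, hi = mean_auc_ci([0.7] * 20, method="empirical")
        assert (lo, hi) == (0.7, 0.7)

    def test_binomial_interval_at_half(self):
        lo, hi = mean_auc_ci([0.5] * 462, method="binomial")
        half = 1.96 * np.sqrt(0.25 / 462)
        assert lo == pytest.approx(0.5 - half)
        assert hi == pytest.approx(0.5 + half)
        assert hi == pytest.approx(0.5456, abs=5e-4)

    def test_upper_bound_clipped_at_one(self):
        lo, hi = mean_auc_ci([1.0] * 10, method="binomial")
        assert hi == 1.0 and lo <= 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mean_auc_ci([], method="binomial")


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        m = confusion_metrics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert (m.sensitivity, m.specificity, m.ppv, m.npv) == (100, 100, 100, 100)

    def test_hand_computed_table(self):
        # TP=3, FN=1, TN=4, FP=2
        probs = [0.9, 0.8, 0.7, 0.2, 0.1, 0.2, 0.3, 0.4, 0.6, 0.7]
        labels = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        m = confusion_metrics(probs, labels)
        assert m.sensitivity == pytest.approx(75.0)
        assert m.specificity == pytest.approx(100 * 4 / 6)
        assert m.ppv == pytest.approx(60.0)
        assert m.npv == pytest.approx(80.0)

    def test_degenerate_all_positive_predictions(self):
        m = confusion_metrics([0.9, 0.8, 0.7], [1, 1, 0])
        assert m.specificity == 0.0
        assert np.isnan(m.npv)

    def test_boundary_probability_is_negative_prediction(self):
        m = confusion_metrics([0.5, 0.9], [1, 0])
        assert m.sensitivity == 0.0  # prob exactly 0.5 → non-responder


@pytest.fixture(scope="module")
def small_pair():
    """Reduced-scale cohort pair: C(4,2)=6 splits keeps group runs fast."""
    early = generate_cohort(
        early_cohort_config(
            seed=31, n_patients=14,
            subtype_counts={"HER2+": 2, "ER+/HER2-": 8, "TN": 4},
        )
    )
    new = generate_cohort(
        new_cohort_config(
            seed=32, n_patients=12,
            subtype_counts={"HER2+": 4, "ER+/HER2-": 4, "TN": 4},
        )
    )
    scheme = study_split_scheme(new, early, k_transfer=2)
    frame = design_frame(concat_cohorts(early, new))
    return scheme, frame


class TestEvaluateOverSplits:
    def test_outcome_leak_gives_auc_one(self, small_pair):
        scheme, frame = small_pair
        leaky = frame.copy()
        leaky["leak"] = leaky["responder"].astype(float)
        # a leak separates every training fit; the Firth-stabilized fit
        # converges and exposes the leak as a perfect test AUC
        _, test, _ = evaluate_model_over_splits(
            scheme, leaky, ["leak"], penalty="firth"
        )
        assert test.mean_auc == pytest.approx(1.0)

    def test_noise_predictor_near_half(self):
        early = generate_cohort(early_cohort_config(seed=55, n_patients=40,
                                subtype_counts={"HER2+": 8, "ER+/HER2-": 22, "TN": 10}))
        new = generate_cohort(new_cohort_config(seed=56, n_patients=30,
                              subtype_counts={"HER2+": 8, "ER+/HER2-": 14, "TN": 8}))
        scheme = study_split_scheme(new, early, k_transfer=4)
        frame = design_frame(concat_cohorts(early, new))
        rng = np.random.default_rng(99)
        frame["noise"] = rng.normal(size=len(frame))
        _, test, _ = evaluate_model_over_splits(scheme, frame, ["noise"])
        # null Monte-Carlo: a pure-noise predictor has no discrimination
        se = np.std(test.per_split_aucs) / np.sqrt(len(test.per_split_aucs)) + 0.08
        assert abs(test.mean_auc - 0.5) < 3 * se

    def test_missing_predictor_rejected(self, small_pair):
        scheme, frame = small_pair
        with pytest.raises(ValueError, match="not in design"):
            evaluate_model_over_splits(scheme, frame, ["nope"])

    def test_missing_values_rejected(self, small_pair):
        scheme, frame = small_pair
        withnan = frame.copy()
        withnan.loc[withnan.index[0], "tHb"] = np.nan
        with pytest.raises(ValueError, match="missing predictor values"):
            evaluate_model_over_splits(scheme, withnan, ["tHb"])


class TestModelGroupRunner:
    def test_published_table_row_structure(self, small_pair):
        scheme, frame = small_pair
        report = run_model_groups(frame, scheme)
        assert len(report) == sum(len(v) for v in TABLE4_GROUPS.values()) == 40
        assert set(report["group"]) == set(TABLE4_GROUPS)
        # one best row per group that produced any usable AUC
        for g, chunk in report.groupby("group"):
            if chunk["test_auc"].notna().any():
                assert chunk["best"].sum() == 1

    def test_outcome_leaking_row_tops_its_group(self, small_pair):
        scheme, frame = small_pair
        leaky = frame.copy()
        leaky["leak"] = leaky["responder"].astype(float)
        groups = {"g": [("tHb",), ("leak",)]}
        report = run_model_groups(leaky, scheme, groups=groups, penalty="firth")
        best = report[report["best"]].iloc[0]
        assert best["predictors"] == "leak"
        assert best["test_auc"] == pytest.approx(1.0)

    def test_her2_signal_helps_over_thb_alone(self):
        # HER2 status carries real signal (91% vs 17-40% response rates), so
        # adding it to baseline tHb should raise mean testing AUC for most
        # cohort draws
        wins = 0
        for s in range(5):
            early = generate_cohort(early_cohort_config(seed=700 + s))
            new = generate_cohort(new_cohort_config(seed=800 + s))
            scheme = study_split_scheme(new, early)
            frame = design_frame(concat_cohorts(early, new))
            _, thb, _ = evaluate_model_over_splits(scheme, frame, ["tHb"])
            _, both, _ = evaluate_model_over_splits(scheme, frame, ["HER2", "tHb"])
            wins += both.mean_auc > thb.mean_auc
        assert wins >= 4
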