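"""Spearman screening, Welch t-tests, and the dataset-poolability check."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from hbresponse.cohort import design_frame
from hbresponse.screening import (
    correlation_screen,
    poolability_dummy_test,
    spearman,
    spearman_exact,
    welch_t_from_samples,
    welch_t_from_summary,
)
from hbresponse.simulate import GeneratorConfig, generate_cohort


def _brute_spearman_no_ties(x, y):
    # 1 − 6Σd²/(n(n²−1)), valid when no ties are present
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    d2 = np.sum((rx - ry) ** 2)
    n = len(x)
    return 1 - 6 * d2 / (n * (n**2 - 1))


class TestSpearman:
    def test_strictly_monotone_pair_gives_one(self):
        res = spearman([1, 2, 3, 5, 8], [10, 20, 21, 40, 100])
        assert res.rho == pytest.approx(1.0)

    def test_textbook_example(self):
        res = spearman([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.rho == pytest.approx(
            _brute_spearman_no_ties([1, 2, 3, 4], [2, 1, 4, 3])
        )
        assert res.rho == pytest.approx(0.6)

    def test_midrank_tie_handling_matches_oracle(self, rng):
        x = rng.integers(0, 4, 20).astype(float)  # heavy ties
        y = rng.integers(0, 4, 20).astype(float)
        # oracle: Pearson correlation of exhaustively computed midranks
        def midranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2.0
                i = j
            return ranks

        expected = np.corrcoef(midranks(x), midranks(y))[0, 1]
        assert spearman(x, y).rho == pytest.approx(expected, rel=1e-12)

    @given(st.integers(0, 100))
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        base = spearman(x, y).rho
        assert spearman(np.exp(x), y).rho == pytest.approx(base)
        assert spearman(x, y**3).rho == pytest.approx(base)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_exact_permutation_p_close_to_t_approximation(self, rng):
        x = rng.normal(size=7)
        y = 0.8 * x + rng.normal(size=7) * 0.5
        approx = spearman(x, y)
        exact = spearman_exact(x, y)
        assert exact.rho == pytest.approx(approx.rho)
        assert abs(exact.p_value - approx.p_value) < 0.08

    def test_exact_limited_to_small_n(self, rng):
        with pytest.raises(ValueError, match="n <= 10"):
            spearman_exact(rng.normal(size=11), rng.normal(size=11))


class TestWelch:
    def test_baseline_tHb_group_difference(self):
        # responders 84.8 ± 11.3 (n=13) vs non-responders 67.9 ± 16.2 (n=9)
        res = welch_t_from_summary(84.8, 11.3, 13, 67.9, 16.2, 9)
        assert res.mean_diff == pytest.approx(16.9, abs=1e-9)
        assert res.p_value == pytest.approx(0.018, abs=0.002)

    def test_cycle1_pct_tHb_group_difference(self):
        # responders 72 ± 22 vs non-responders 102 ± 12 at the end of cycle 1
        res = welch_t_from_summary(72, 22, 13, 102, 12, 9)
        assert abs(res.mean_diff) == pytest.approx(30.0)
        assert res.p_value == pytest.approx(0.001, abs=5e-4)
        # 95% CI of the absolute difference reproduces 14.6-45.0
        assert -res.ci_high == pytest.approx(14.6, abs=0.7)
        assert -res.ci_low == pytest.approx(45.0, abs=0.7)

    def test_pooled_variant_gives_smaller_p_here(self):
        welch = welch_t_from_summary(84.8, 11.3, 13, 67.9, 16.2, 9)
        pooled = welch_t_from_summary(84.8, 11.3, 13, 67.9, 16.2, 9, pooled=True)
        assert pooled.p_value < welch.p_value
        assert pooled.df == 20

    def test_identical_groups(self):
        res = welch_t_from_summary(50, 5, 10, 50, 5, 10)
        assert res.t_stat == 0 and res.p_value == pytest.approx(1.0)
        assert res.ci_low == pytest.approx(-res.ci_high)

    def test_samples_equal_summary_form(self, rng):
        g1 = rng.normal(70, 15, 13)
        g2 = rng.normal(100, 10, 9)
        s = welch_t_from_samples(g1, g2)
        ref = welch_t_from_summary(
            g1.mean(), g1.std(ddof=1), 13, g2.mean(), g2.std(ddof=1), 9
        )
        assert s == ref

    def test_pure_shift_recovered(self, rng):
        g1 = rng.normal(0, 1, 20)
        res = welch_t_from_samples(g1 + 2.5, g1)
        assert res.mean_diff == pytest.approx(2.5)

    @given(st.integers(0, 50))
    def test_antisymmetric_under_group_swap(self, seed):
        rng = np.random.default_rng(seed)
        g1 = rng.normal(1, 2, 8)
        g2 = rng.normal(0, 1, 12)
        a = welch_t_from_samples(g1, g2)
        b = welch_t_from_samples(g2, g1)
        assert a.mean_diff == pytest.approx(-b.mean_diff)
        assert a.t_stat == pytest.approx(-b.t_stat)
        assert a.p_value == pytest.approx(b.p_value)
        assert a.df == pytest.approx(b.df)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            welch_t_from_samples([1.0], [2.0, 3.0])


class TestPoolability:
    def test_duplicated_dataset_gives_null_indicator(self, rng):
        X = rng.normal(0, 1, (40, 2))
        y = (rng.random(40) < 0.5).astype(int)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        p, fit = poolability_dummy_test(X, y, X.copy(), y.copy())
        assert fit.beta[-1] == pytest.approx(0.0, abs=1e-5)
        assert p == pytest.approx(1.0, abs=1e-3)

    def test_intercept_shift_detected(self, rng):
        n = 400
        X = rng.normal(0, 1, (n, 1))
        p_old = 1 / (1 + np.exp(-(0.0 + X[:, 0])))
        y_old = (rng.random(n) < p_old).astype(int)
        X2 = rng.normal(0, 1, (n, 1))
        p_new = 1 / (1 + np.exp(-(2.0 + X2[:, 0])))
        y_new = (rng.random(n) < p_new).astype(int)
        p, _ = poolability_dummy_test(X, y_old, X2, y_new)
        assert p < 1e-6

    def test_mismatched_columns_rejected(self, rng):
        import pandas as pd

        A = pd.DataFrame({"a": [0.0, 1.0, 2.0, 1.0]})
        B = pd.DataFrame({"b": [0.0, 1.0, 0.5, 2.0]})
        with pytest.raises(ValueError, match="same predictor columns"):
            poolability_dummy_test(A, [0, 1, 0, 1], B, [0, 1, 1, 0])


@pytest.fixture(scope="module")
def big_cohort():
    return generate_cohort(GeneratorConfig(n_patients=2000, seed=77))


class TestCorrelationScreen:

    def test_cycle1_ranks_above_day7(self, big_cohort):
        # day-7 distributions are constructed non-separating; cycle 1 is not
        screen = correlation_screen(big_cohort)
        table = screen.outcome_correlations
        assert abs(table.loc["pct_tHb_cyc1", "rho"]) > abs(
            table.loc["pct_tHb_day7", "rho"]
        )
        assert table.loc["pct_tHb_cyc1", "p_value"] < 1e-6

    def test_perfect_predictor_has_rho_one(self, big_cohort):
        frame = design_frame(big_cohort)
        screen = correlation_screen(big_cohort, predictors=["NS", "tHb"])
        # self-correlation sanity on the outcome column itself
        res = spearman(frame["miller_payne"], frame["miller_payne"])
        assert res.rho == pytest.approx(1.0)
        assert set(screen.outcome_correlations.index) == {"NS", "tHb"}

    def test_collinear_duplicate_dropped(self, big_cohort):
        screen = correlation_screen(big_cohort, predictors=["tHb", "NS", "MC"])
        # MC is generated from NS, so the pair crosses the 0.8 threshold
        if "MC" in screen.dropped:
            assert "NS" in screen.selected
        assert len(screen.selected) < 3 or not screen.dropped

    def test_mitotic_count_falls_to_nottingham(self, big_cohort):
        screen = correlation_screen(big_cohort)
        assert "NS" in screen.selected
        assert "MC" in screen.dropped

    def test_subtype_flags_never_dropped(self, big_cohort):
        screen = correlation_screen(big_cohort)
        for flag in ("HER2", "ER_code", "TN"):
            assert flag in screen.selected

    def test_unknown_predictor_rejected(self, big_cohort):
        with pytest.raises(ValueError, match="unknown predictors"):
            correlation_screen(big_cohort, predictors=["not_a_column"])
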