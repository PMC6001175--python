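"""Predictor screening and group comparisons.

Candidate predictors (subtype codings, Nottingham score, mitotic count,
baseline tHb and %tHb at each cycle) are screened by Spearman rank correlation
against the Miller-Payne grade and against each other; highly collinear pairs
are pruned (the mitotic count falls to the Nottingham score this way).
Responder-group differences are compared with two-sample two-sided Welch
t-tests, available both from raw samples and from printed summary statistics.
A dummy-variable poolability test checks whether two cohorts can be treated
as draws from one population before their data are stacked for training.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable, design_frame
from .model import LogisticFit, fit_logistic, wald_test

__all__ = [
    "CorrelationResult",
    "TTestResult",
    "spearman",
    "spearman_exact",
    "welch_t_from_summary",
    "welch_t_from_samples",
    "poolability_dummy_test",
    "correlation_screen",
    "ScreenResult",
]


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman's rho with its two-sided p-value."""

    rho: float
    p_value: float
    n: int


@dataclass(frozen=True)
class TTestResult:
    """Welch two-sample t-test: difference of means with 95% CI."""

    mean_diff: float
    t_stat: float
    df: float
    p_value: float
    ci_low: float
    ci_high: float


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with midrank ties and t-approximation p.

    rho is the Pearson correlation of midranks; the two-sided p-value uses
    t = rho·√((n−2)/(1−rho²)) on n−2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), p_value=float(p), n=int(x.size))


def spearman_exact(x, y) -> CorrelationResult:
    """Exact permutation p-value for Spearman's rho (n ≤ 10 only).

    Enumerates all n! orderings of y; intended as a small-sample oracle for
    the t-approximation, not for production screening.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n > 10:
        raise ValueError("exact enumeration limited to n <= 10")
    rx = stats.rankdata(x)
    observed = float(np.corrcoef(rx, stats.rankdata(y))[0, 1])
    count = 0
    total = 0
    for perm in permutations(y):
        r = float(np.corrcoef(rx, stats.rankdata(perm))[0, 1])
        if abs(r) >= abs(observed) - 1e-12:
            count += 1
        total += 1
    return CorrelationResult(rho=observed, p_value=count / total, n=n)


def _welch(mean1, sd1, n1, mean2, sd2, n2, pooled: bool) -> TTestResult:
    if min(n1, n2) < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    diff = mean1 - mean2
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    if pooled:
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = float(n1 + n2 - 2)
    else:
        se = np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    half = stats.t.ppf(0.975, df) * se
    return TTestResult(
        mean_diff=float(diff),
        t_stat=float(t),
        df=float(df),
        p_value=float(p),
        ci_low=float(diff - half),
        ci_high=float(diff + half),
    )


def welch_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    pooled: bool = False,
) -> TTestResult:
    """Two-sample two-sided t-test from group summaries (mean, SD, n).

    Unequal-variance (Welch) form with Welch-Satterthwaite degrees of freedom
    by default; ``pooled=True`` gives the equal-variance form.
    """
    return _welch(mean1, sd1, n1, mean2, sd2, n2, pooled)


def welch_t_from_samples(group1, group2, pooled: bool = False) -> TTestResult:
    """Two-sample two-sided t-test from raw samples; equals the summary form
    applied to the groups' computed means/SDs."""
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs n >= 2")
    res = _welch(
        g1.mean(), g1.std(ddof=1), g1.size, g2.mean(), g2.std(ddof=1), g2.size, pooled
    )
    # cross-check t/p against scipy's implementation of the same test
    t_ref, p_ref = stats.ttest_ind(g1, g2, equal_var=pooled)
    assert np.isclose(res.t_stat, t_ref) and np.isclose(res.p_value, p_ref)
    return res


def poolability_dummy_test(
    X_old, y_old, X_new, y_new, **fit_params
) -> tuple[float, LogisticFit]:
    """Test whether two datasets may be pooled, via a dataset indicator.

    Stacks the two datasets, appends a dummy predictor coded 0 for the old
    data and 1 for the new, fits one logistic model, and returns the two-sided
    Wald p-value for the dummy coefficient together with the fit. A large p
    is consistent with both datasets arising from one population.
    """
    X_old = pd.DataFrame(X_old)
    X_new = pd.DataFrame(X_new)
    if list(X_old.columns) != list(X_new.columns):
        raise ValueError("datasets must share the same predictor columns")
    X = pd.concat([X_old, X_new], ignore_index=True)
    X["dataset"] = np.concatenate(
        [np.zeros(len(X_old), dtype=int), np.ones(len(X_new), dtype=int)]
    )
    y = np.concatenate([np.asarray(y_old).ravel(), np.asarray(y_new).ravel()])
    fit = fit_logistic(X, y, **fit_params)
    p = wald_test(fit, X.shape[1])  # last coefficient = dataset indicator
    return p, fit


@dataclass
class ScreenResult:
    """Output of the predictor screen."""

    outcome_correlations: pd.DataFrame  # rho / p / n vs Miller-Payne grade
    pairwise_rho: pd.DataFrame  # predictor × predictor rho matrix
    selected: list[str]
    dropped: dict[str, str]  # predictor -> reason


#: Subtype codings retained regardless of correlation screening (TN is kept
#: because it is used clinically to characterize that patient group).
PROTECTED_PREDICTORS = ("HER2", "ER_code", "TN")

#: Predictors preferred within a collinear pair for clinical interpretability:
#: oncologists grade by the Nottingham score, so its mitotic-count component
#: is the one dropped when the two are collinear.
PREFERRED_PREDICTORS = ("NS",)


def correlation_screen(
    cohort: CohortTable,
    predictors: list[str] | None = None,
    collinearity_threshold: float = 0.8,
) -> ScreenResult:
    """Screen predictors against Miller-Payne grade and prune collinear pairs.

    Every predictor is correlated (Spearman) with the Miller-Payne grade and
    with every other predictor. Of any predictor pair with |rho| above the
    collinearity threshold, the member less correlated with the grade is
    dropped — unless it is a protected subtype flag. Rows with missing values
    for a given pair are dropped pairwise.
    """
    frame = design_frame(cohort)
    if predictors is None:
        predictors = [
            c
            for c in frame.columns
            if c not in ("miller_payne", "responder")
            and frame[c].notna().sum() >= 3
            and frame[c].nunique() > 1
        ]
    unknown = [p for p in predictors if p not in frame.columns]
    if unknown:
        raise ValueError(f"unknown predictors: {unknown}")

    grade = frame["miller_payne"].astype(float)
    rows = []
    for name in predictors:
        mask = frame[name].notna()
        res = spearman(frame.loc[mask, name], grade[mask])
        rows.append({"predictor": name, "rho": res.rho, "p_value": res.p_value, "n": res.n})
    outcome = pd.DataFrame(rows).set_index("predictor")

    pairwise = pd.DataFrame(
        np.eye(len(predictors)), index=predictors, columns=predictors
    )
    for i, a in enumerate(predictors):
        for b in predictors[i + 1 :]:
            mask = frame[a].notna() & frame[b].notna()
            if mask.sum() < 3 or frame.loc[mask, a].nunique() < 2 or frame.loc[mask, b].nunique() < 2:
                rho = np.nan
            else:
                rho = spearman(frame.loc[mask, a], frame.loc[mask, b]).rho
            pairwise.loc[a, b] = pairwise.loc[b, a] = rho

    selected = list(predictors)
    dropped: dict[str, str] = {}
    for i, a in enumerate(predictors):
        for b in predictors[i + 1 :]:
            rho = pairwise.loc[a, b]
            if np.isnan(rho) or abs(rho) < collinearity_threshold:
                continue
            if a not in selected or b not in selected:
                continue
            candidates = [
                c for c in (a, b) if c not in PROTECTED_PREDICTORS
            ]
            if not candidates:
                continue
            non_preferred = [c for c in candidates if c not in PREFERRED_PREDICTORS]
            pool = non_preferred or candidates
            # drop the member least correlated with the response grade
            victim = min(pool, key=lambda c: abs(outcome.loc[c, "rho"]))
            selected.remove(victim)
            keeper = b if victim == a else a
            dropped[victim] = (
                f"|rho|={abs(rho):.2f} with {keeper} exceeds "
                f"threshold {collinearity_threshold}"
            )
    return ScreenResult(
        outcome_correlations=outcome,
        pairwise_rho=pairwise,
        selected=selected,
        dropped=dropped,
    )
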