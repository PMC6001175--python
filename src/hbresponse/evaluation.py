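"""ROC/AUC machinery and the combinatorial train/test evaluation scheme.

Because the historical training cohort lacked patients treated with dual HER2
blockade, six HER2+ patients from the new cohort are moved into training; all
C(11, 6) = 462 such transfers are enumerated, a logistic model is fitted on
each 38-patient training set and scored on the remaining 16-patient test set,
and the mean of the 462 test AUCs (with a 95% CI) summarizes each predictor
group. Confusion metrics (sensitivity, specificity, PPV, NPV) use the 0.5
probability rule — predicted responder iff probability > 0.5 — pooled over
all test predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cohort import CohortTable, design_frame
from .model import LogisticResponseModel

__all__ = [
    "RocCurve",
    "AucSummary",
    "ConfusionMetrics",
    "SplitScheme",
    "roc_curve",
    "auc_mann_whitney",
    "enumerate_splits",
    "evaluate_model_over_splits",
    "mean_auc_ci",
    "confusion_metrics",
    "run_model_groups",
    "TABLE4_GROUPS",
]

logger = logging.getLogger(__name__)


@dataclass
class RocCurve:
    """ROC points from a threshold sweep over all distinct scores."""

    points: np.ndarray  # (m, 2) of (FPR, TPR), from (0,0) to (1,1)
    auc: float


@dataclass
class AucSummary:
    """Per-split AUCs with their mean and 95% CI."""

    mean_auc: float
    ci_low: float
    ci_high: float
    n_splits: int
    per_split_aucs: np.ndarray
    ci_method: str
    n_excluded: int = 0  # non-convergent fits, excluded from the mean


@dataclass
class ConfusionMetrics:
    """Sensitivity / specificity / PPV / NPV in percent (NaN if undefined)."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float


def _check_labels(labels: np.ndarray) -> None:
    if not ((labels == 0) | (labels == 1)).all():
        raise ValueError("labels must be coded 0/1")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")


def roc_curve(scores, labels) -> RocCurve:
    """ROC curve by sweeping thresholds over the distinct scores (descending).

    Tied scores are grouped at a single threshold; the AUC is the trapezoidal
    area of the resulting curve and equals the Mann-Whitney AUC exactly.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_labels(labels)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    distinct = np.where(np.diff(s) != 0)[0]  # last index of each tie group
    idx = np.r_[distinct, s.size - 1]
    tpr = np.r_[0.0, tps[idx] / n1]
    fpr = np.r_[0.0, fps[idx] / n0]
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(points=points, auc=auc)


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the Mann-Whitney probability: P(score₁ > score₀) + ½P(tie).

    Exactly equal to the trapezoidal area of :func:`roc_curve` — the identity
    is enforced as a test property, with this rank-based form as the oracle.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_labels(labels)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    ranks = rankdata(scores)  # midranks
    r1 = ranks[labels == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclass
class SplitScheme:
    """Exhaustive enumeration of test→train transfers.

    Every size-``k_transfer`` subset of ``transferable_ids`` is moved from the
    test pool into training; training is that subset plus ``fixed_train_ids``
    and testing is the remainder of the test pool.
    """

    transferable_ids: tuple[str, ...]
    k_transfer: int
    fixed_train_ids: tuple[str, ...]
    test_pool_ids: tuple[str, ...]
    splits: list[tuple[tuple[str, ...], tuple[str, ...]]] = field(default_factory=list)

    @property
    def n_splits(self) -> int:
        return len(self.splits)

    @property
    def train_size(self) -> int:
        return len(self.fixed_train_ids) + self.k_transfer


def enumerate_splits(
    transferable_ids: Sequence[str],
    k_transfer: int,
    fixed_train_ids: Sequence[str],
    test_pool_ids: Sequence[str],
) -> SplitScheme:
    """Enumerate all C(n, k) transfer subsets in lexicographic order.

    For the study configuration — 11 transferable HER2+ patients, k = 6, a
    32-patient fixed training cohort and a 22-patient test pool — this yields
    462 splits, each with 38 patients in training and 16 in testing.
    """
    transferable = tuple(transferable_ids)
    fixed = tuple(fixed_train_ids)
    pool = tuple(test_pool_ids)
    if k_transfer > len(transferable):
        raise ValueError(
            f"k_transfer={k_transfer} exceeds {len(transferable)} transferable ids"
        )
    missing = set(transferable) - set(pool)
    if missing:
        raise ValueError(f"transferable ids not in test pool: {sorted(missing)}")
    if set(fixed) & set(pool):
        raise ValueError("fixed training ids overlap the test pool")
    splits = []
    for subset in combinations(transferable, k_transfer):
        chosen = set(subset)
        train = fixed + subset
        test = tuple(pid for pid in pool if pid not in chosen)
        splits.append((train, test))
    return SplitScheme(
        transferable_ids=transferable,
        k_transfer=k_transfer,
        fixed_train_ids=fixed,
        test_pool_ids=pool,
        splits=splits,
    )


def mean_auc_ci(per_split_aucs, method: str = "binomial") -> tuple[float, float]:
    """95% CI for the mean AUC over the enumerated splits.

    ``binomial`` (default): normal-approximation binomial interval
    m ± 1.96·√(m(1−m)/N) with N = number of splits, clipped to [0, 1].
    ``empirical``: the 2.5/97.5 percentiles of the per-split AUCs.
    """
    aucs = np.asarray(per_split_aucs, dtype=float)
    if aucs.size == 0:
        raise ValueError("no AUC values")
    m = float(aucs.mean())
    if method == "binomial":
        half = 1.96 * np.sqrt(max(m * (1.0 - m), 0.0) / aucs.size)
        return max(m - half, 0.0), min(m + half, 1.0)
    if method == "empirical":
        lo, hi = np.percentile(aucs, [2.5, 97.5])
        return float(lo), float(hi)
    raise ValueError(f"unknown CI method {method!r}")


def confusion_metrics(probs, labels, threshold: float = 0.5) -> ConfusionMetrics:
    """Confusion metrics of the > threshold classification rule, in percent.

    A metric with a zero denominator (e.g. NPV when nothing is predicted
    negative) is reported as NaN, never as 0.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_labels(labels)
    pred = (probs > threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())

    def pct(num: int, den: int) -> float:
        return 100.0 * num / den if den > 0 else float("nan")

    return ConfusionMetrics(
        sensitivity=pct(tp, tp + fn),
        specificity=pct(tn, tn + fp),
        ppv=pct(tp, tp + fp),
        npv=pct(tn, tn + fn),
    )


def _design_for(cohort_or_frame) -> pd.DataFrame:
    if isinstance(cohort_or_frame, CohortTable):
        return design_frame(cohort_or_frame)
    return cohort_or_frame


def evaluate_model_over_splits(
    scheme: SplitScheme,
    cohort,
    predictor_group: Sequence[str],
    ci_method: str = "binomial",
    threshold: float = 0.5,
    **fit_params,
) -> tuple[AucSummary, AucSummary, ConfusionMetrics]:
    """Fit/score one predictor group over every split of the scheme.

    For each enumerated split a logistic model is fitted on the training
    patients and scored on the test patients. Returns the training-AUC
    summary, the testing-AUC summary, and confusion metrics of the pooled
    test predictions at the probability threshold. Splits whose fit does not
    converge (e.g. separated training data) are excluded from the means and
    counted in ``n_excluded``.
    """
    if scheme.n_splits == 0:
        raise ValueError("empty split scheme")
    frame = _design_for(cohort)
    cols = list(predictor_group)
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise ValueError(f"predictors not in design: {missing}")
    sub = frame[cols + ["responder"]]
    if sub[cols].isna().any().any():
        bad = sub[cols].isna().any(axis=1)
        raise ValueError(
            f"missing predictor values for patients {list(sub.index[bad])}"
        )

    # numpy views with an id → row-position map: the 462-split loop is hot
    pos = {pid: i for i, pid in enumerate(sub.index)}
    Xall = sub[cols].to_numpy(dtype=float)
    yall = sub["responder"].to_numpy(dtype=int)

    train_aucs, test_aucs = [], []
    pooled_probs, pooled_labels = [], []
    n_excluded = 0
    import warnings as _warnings

    for train_ids, test_ids in scheme.splits:
        itr = [pos[p] for p in train_ids]
        ite = [pos[p] for p in test_ids]
        Xtr, ytr = Xall[itr], yall[itr]
        Xte, yte = Xall[ite], yall[ite]
        est = LogisticResponseModel(threshold=threshold, **fit_params)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            est.fit(Xtr, ytr)
        if not est.converged_:
            n_excluded += 1
            continue
        train_aucs.append(auc_mann_whitney(est.predict_proba(Xtr)[:, 1], ytr))
        p_test = est.predict_proba(Xte)[:, 1]
        test_aucs.append(auc_mann_whitney(p_test, yte))
        pooled_probs.append(p_test)
        pooled_labels.append(yte)

    if not test_aucs:
        raise ValueError("no split produced a convergent fit")

    def summarize(aucs: list[float]) -> AucSummary:
        arr = np.asarray(aucs)
        lo, hi = mean_auc_ci(arr, ci_method)
        return AucSummary(
            mean_auc=float(arr.mean()),
            ci_low=lo,
            ci_high=hi,
            n_splits=scheme.n_splits,
            per_split_aucs=arr,
            ci_method=ci_method,
            n_excluded=n_excluded,
        )

    metrics = confusion_metrics(
        np.concatenate(pooled_probs), np.concatenate(pooled_labels), threshold
    )
    return summarize(train_aucs), summarize(test_aucs), metrics


_P1, _P2, _P3 = "pct_tHb_cyc1", "pct_tHb_cyc2", "pct_tHb_cyc3"

#: The four published predictor-group families (subtype + hemoglobin markers).
TABLE4_GROUPS: dict[str, list[tuple[str, ...]]] = {
    "group1_HER2": [
        ("HER2",),
        ("HER2", "tHb"),
        ("HER2", "tHb", "ER_code"),
        ("HER2", "tHb", "NS"),
        ("HER2", "tHb", _P1),
        ("HER2", "tHb", _P2),
        ("HER2", "tHb", _P3),
        ("HER2", "tHb", _P1, _P2),
        ("HER2", "tHb", _P1, _P3),
        ("HER2", "tHb", _P2, _P3),
        ("HER2", "tHb", _P1, _P2, _P3),
    ],
    "group2_ER": [
        ("ER_code",),
        ("ER_code", "tHb"),
        ("ER_code", "tHb", "NS"),
        ("ER_code", "tHb", _P1),
        ("ER_code", "tHb", _P2),
        ("ER_code", "tHb", _P3),
        ("ER_code", "tHb", _P1, _P2),
        ("ER_code", "tHb", _P1, _P3),
        ("ER_code", "tHb", _P2, _P3),
    ],
    "group3_TN": [
        ("TN",),
        ("TN", "tHb"),
        ("TN", "tHb", "NS"),
        ("TN", "tHb", _P1),
        ("TN", "tHb", _P2),
        ("TN", "tHb", _P3),
        ("TN", "tHb", _P1, _P2),
        ("TN", "tHb", _P1, _P3),
        ("TN", "tHb", _P2, _P3),
    ],
    "group4_hemoglobin": [
        ("tHb",),
        ("tHb", _P1),
        ("tHb", _P2),
        ("tHb", _P3),
        ("tHb", _P1, _P2),
        ("tHb", _P1, _P2, _P3),
        (_P1,),
        (_P2,),
        (_P3,),
        (_P1, _P2),
        (_P1, _P2, _P3),
    ],
}


def run_model_groups(
    cohort,
    scheme: SplitScheme,
    groups: dict[str, list[tuple[str, ...]]] | None = None,
    ci_method: str = "binomial",
    **fit_params,
) -> pd.DataFrame:
    """Evaluate every predictor set of every group over the split scheme.

    Returns one row per model with training/testing mean AUC and CI, pooled
    confusion metrics, and a ``best`` flag marking the highest testing AUC
    within each group. Rows whose predictors are unavailable in the cohort
    are skipped with a logged reason.
    """
    groups = TABLE4_GROUPS if groups is None else groups
    frame = _design_for(cohort)
    rows = []
    for group_name, model_list in groups.items():
        for predictors in model_list:
            label = ", ".join(predictors)
            try:
                tr, te, cm = evaluate_model_over_splits(
                    scheme, frame, predictors, ci_method=ci_method, **fit_params
                )
            except ValueError as exc:
                if "convergent" in str(exc):
                    # every split separated: keep the row, report no AUC
                    logger.warning("%s [%s]: %s", label, group_name, exc)
                    nan = float("nan")
                    rows.append(
                        {
                            "group": group_name,
                            "predictors": label,
                            "train_auc": nan,
                            "train_ci_low": nan,
                            "train_ci_high": nan,
                            "test_auc": nan,
                            "test_ci_low": nan,
                            "test_ci_high": nan,
                            "sensitivity": nan,
                            "specificity": nan,
                            "ppv": nan,
                            "npv": nan,
                            "n_splits": scheme.n_splits,
                            "n_excluded": scheme.n_splits,
                        }
                    )
                else:
                    logger.warning("skipping %s [%s]: %s", label, group_name, exc)
                continue
            rows.append(
                {
                    "group": group_name,
                    "predictors": label,
                    "train_auc": tr.mean_auc,
                    "train_ci_low": tr.ci_low,
                    "train_ci_high": tr.ci_high,
                    "test_auc": te.mean_auc,
                    "test_ci_low": te.ci_low,
                    "test_ci_high": te.ci_high,
                    "sensitivity": cm.sensitivity,
                    "specificity": cm.specificity,
                    "ppv": cm.ppv,
                    "npv": cm.npv,
                    "n_splits": te.n_splits,
                    "n_excluded": te.n_excluded,
                }
            )
    report = pd.DataFrame(rows)
    if not report.empty:
        report["best"] = False
        for g, chunk in report.groupby("group"):
            if chunk["test_auc"].notna().any():
                report.loc[chunk["test_auc"].idxmax(), "best"] = True
    return report
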