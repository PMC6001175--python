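"""End-to-end pipeline: simulate → screen → enumerate splits → evaluate.

One root seed drives every stage; given identical configuration the report
files are byte-identical across runs. Outputs are CSV reports (per-model AUC
table, best-model confusion metrics, ROC points of the best models), the
cohort CSVs themselves, and a JSON manifest recording the configuration and
SHA-256 hashes of every file written.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortTable, concat_cohorts, design_frame, write_cohort_csv
from .evaluation import (
    SplitScheme,
    enumerate_splits,
    roc_curve,
    run_model_groups,
)
from .model import LogisticResponseModel
from .screening import correlation_screen
from .simulate import (
    GeneratorConfig,
    early_cohort_config,
    generate_cohort,
    new_cohort_config,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "study_split_scheme"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    output_dir: str = "hbresponse_run"
    generator_early: GeneratorConfig | None = None
    generator_new: GeneratorConfig | None = None
    transfer_subtype: str = "HER2+"
    k_transfer: int = 6
    ci_method: str = "binomial"
    collinearity_threshold: float = 0.8
    log_level: str = "INFO"
    model_groups: dict | None = None  # None = the published four groups

    def __post_init__(self) -> None:
        # derive per-cohort seeds from the root seed when not given explicitly
        if self.generator_early is None:
            self.generator_early = early_cohort_config(seed=(2 * self.seed) % 2**31)
        if self.generator_new is None:
            self.generator_new = new_cohort_config(seed=(2 * self.seed + 1) % 2**31)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("generator_early", "generator_new"):
            if key in raw and raw[key] is not None:
                raw[key] = GeneratorConfig.from_dict(raw[key])
        return cls(**raw)


def study_split_scheme(
    new_cohort: CohortTable,
    early_cohort: CohortTable,
    transfer_subtype: str = "HER2+",
    k_transfer: int = 6,
) -> SplitScheme:
    """The study's combinatorial scheme on a (new, early) cohort pair.

    All patients of the given subtype in the new cohort are eligible to move
    into training; every size-k subset of them is enumerated. The early
    cohort is always in training, the rest of the new cohort always in test.
    """
    transferable = [
        p.patient_id for p in new_cohort.patients if p.subtype == transfer_subtype
    ]
    return enumerate_splits(
        transferable_ids=transferable,
        k_transfer=k_transfer,
        fixed_train_ids=[p.patient_id for p in early_cohort.patients],
        test_pool_ids=[p.patient_id for p in new_cohort.patients],
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _pooled_roc(scheme: SplitScheme, frame: pd.DataFrame, predictors: list[str]):
    """ROC of the pooled test predictions of one model over all splits."""
    import warnings as _warnings

    probs, labels = [], []
    cols = list(predictors)
    for train_ids, test_ids in scheme.splits:
        est = LogisticResponseModel()
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            est.fit(frame.loc[list(train_ids), cols], frame.loc[list(train_ids), "responder"])
        if not est.converged_:
            continue
        probs.append(est.predict_proba(frame.loc[list(test_ids), cols])[:, 1])
        labels.append(frame.loc[list(test_ids), "responder"].to_numpy())
    return roc_curve(np.concatenate(probs), np.concatenate(labels))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    # --- simulate ---------------------------------------------------------
    try:
        early = generate_cohort(config.generator_early)
        new = generate_cohort(config.generator_new)
        if len(early) == 0 or len(new) == 0:
            raise PipelineError("simulate: empty cohort")
    except ValueError as exc:
        raise PipelineError(f"simulate: {exc}") from exc
    for name, cohort in (("early", early), ("new", new)):
        pp, mp = out / f"{name}_patients.csv", out / f"{name}_measurements.csv"
        write_cohort_csv(cohort, pp, mp)
        written += [pp, mp]
    combined = concat_cohorts(early, new, provenance="synthetic")

    # --- screen -----------------------------------------------------------
    try:
        screen = correlation_screen(
            combined, collinearity_threshold=config.collinearity_threshold
        )
    except ValueError as exc:
        raise PipelineError(f"screen: {exc}") from exc
    path = out / "screen_outcome_correlations.csv"
    screen.outcome_correlations.to_csv(path)
    written.append(path)
    path = out / "screen_pairwise_rho.csv"
    screen.pairwise_rho.to_csv(path)
    written.append(path)

    # --- enumerate splits -------------------------------------------------
    try:
        scheme = study_split_scheme(
            new, early, config.transfer_subtype, config.k_transfer
        )
    except ValueError as exc:
        raise PipelineError(f"splits: {exc}") from exc
    logger.info(
        "enumerated %d splits (train %d / test %d)",
        scheme.n_splits,
        scheme.train_size,
        len(scheme.test_pool_ids) - scheme.k_transfer,
    )

    # --- evaluate ---------------------------------------------------------
    frame = design_frame(combined)
    try:
        report = run_model_groups(
            frame, scheme, groups=config.model_groups, ci_method=config.ci_method
        )
        if report.empty:
            raise PipelineError("evaluate: no model could be evaluated")
    except ValueError as exc:
        raise PipelineError(f"evaluate: {exc}") from exc
    path = out / "model_report.csv"
    report.to_csv(path, index=False)
    written.append(path)

    best = report[report["best"]].copy()
    path = out / "best_models.csv"
    best[
        ["group", "predictors", "sensitivity", "specificity", "ppv", "npv", "test_auc"]
    ].to_csv(path, index=False)
    written.append(path)

    for _, row in best.iterrows():
        predictors = [p.strip() for p in row["predictors"].split(",")]
        roc = _pooled_roc(scheme, frame, predictors)
        path = out / f"roc_{row['group']}.csv"
        pd.DataFrame(roc.points, columns=["fpr", "tpr"]).to_csv(path, index=False)
        written.append(path)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "n_splits": scheme.n_splits,
        "train_size": scheme.train_size,
        "selected_predictors": screen.selected,
        "dropped_predictors": screen.dropped,
        "config": {
            "seed": config.seed,
            "k_transfer": config.k_transfer,
            "transfer_subtype": config.transfer_subtype,
            "ci_method": config.ci_method,
            "collinearity_threshold": config.collinearity_threshold,
            "generator_early": config.generator_early.to_dict(),
            "generator_new": config.generator_new.to_dict(),
        },
        "files": {p.name: _sha256(p) for p in written},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
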