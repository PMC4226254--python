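"""Train/test phase orchestration.

Ties the stages into the end-to-end workflow: extract (optional) ->
preprocess -> two-stage fit -> evaluate, with every artifact written
to disk (model and standardization tables as JSON, cohorts and
predictions as CSV) so a run is reproducible from its config and
inputs alone.  The standardization tables carry a hash of the
training cohort they came from, so the test phase can verify it never
feeds test data into training statistics.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import model as m
from . import preprocessing as pp
from .audio import FEATURE_NAMES

log = logging.getLogger("scvoice")


class WorkflowError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Everything a training or test run needs, serializable to JSON."""

    cohort_csv: str
    out_dir: str
    sex: str = "male"
    seed: int = 0
    halfwidth: float = 5.0
    folds: int = 10
    n_directions: int | None = None
    thresholds: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "cohort_csv": self.cohort_csv,
            "out_dir": self.out_dir,
            "sex": self.sex,
            "seed": self.seed,
            "halfwidth": self.halfwidth,
            "folds": self.folds,
            "n_directions": self.n_directions,
            "thresholds": self.thresholds,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)


def _file_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _read_cohort(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise WorkflowError(f"input cohort not found: {path}")
    return pp.validate_cohort(pd.read_csv(path))


def run_train_phase(config: RunConfig) -> dict:
    """Preprocess, fit both stages, evaluate on the training rows.

    Writes ``model.json``, ``norm.json``, ``exclusions.json``,
    ``train_clean.csv``, ``train_predictions.csv`` and
    ``train_metrics.json`` under ``config.out_dir`` and returns the
    metrics dict.
    """
    df = _read_cohort(config.cohort_csv)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    thresholds = pp.InfluenceThresholds(**config.thresholds)
    log.info("train phase [%s]: %d rows in", config.sex, len(df))
    clean, norm, report = pp.preprocess_cohort(
        df,
        sex=config.sex,
        halfwidth=config.halfwidth,
        seed=config.seed,
        thresholds=thresholds,
        n_directions=config.n_directions,
    )
    log.info(
        "preprocessing: %d rows kept, exclusions %s", len(clean), report.counts
    )
    if clean.empty:
        raise WorkflowError("preprocessing left no training rows")

    score_model, mlr_model, lam = m.train_full(
        clean, sex=config.sex, seed=config.seed, folds=config.folds
    )
    log.info("selected lambda (one-SE rule): %.6g", lam)

    preds = m.predict_cohort(score_model, mlr_model, clean)
    cm = m.evaluate(preds["sc_label"], preds["predicted"])
    metrics = {
        "phase": "train",
        "sex": config.sex,
        "n": len(clean),
        "lambda": lam,
        **cm.to_dict(),
    }
    log.info("training accuracy %.1f%%", cm.accuracy)

    clean.to_csv(out / "train_clean.csv", index=False)
    preds.to_csv(out / "train_predictions.csv", index=False)
    m.save_model(out / "model.json", score_model, mlr_model)
    norm_doc = norm.to_dict()
    norm_doc["train_cohort_sha256"] = _file_hash(config.cohort_csv)
    (out / "norm.json").write_text(json.dumps(norm_doc, indent=2))
    (out / "exclusions.json").write_text(json.dumps(report.to_dict(), indent=2))
    (out / "train_metrics.json").write_text(json.dumps(metrics, indent=2))
    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=2))
    return metrics


def run_test_phase(
    config: RunConfig, model_path, norm_path, test_csv=None
) -> dict:
    """Apply a trained model to a held-out cohort.

    Eligibility filtering and the training-derived standardization are
    applied to the test rows (training statistics only; the stored
    cohort hash documents their provenance), then the two-stage model
    scores and classifies each subject.  Writes
    ``test_predictions.csv`` and ``test_metrics.json``.
    """
    test_csv = test_csv if test_csv is not None else config.cohort_csv
    df = _read_cohort(test_csv)
    df = df[df["sex"] == config.sex].reset_index(drop=True)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    score_model, mlr_model = m.load_model(model_path)
    norm_doc = json.loads(Path(norm_path).read_text())
    train_hash = norm_doc.pop("train_cohort_sha256", None)
    norm = pp.AgeNorm.from_dict(norm_doc)
    if train_hash is not None and _file_hash(test_csv) == train_hash:
        log.warning("test cohort is byte-identical to the training cohort")

    kept, report = pp.filter_eligibility(df)
    if kept.empty:
        raise WorkflowError("no eligible test rows")
    std = pp.apply_age_standardize(kept, norm)
    preds = m.predict_cohort(score_model, mlr_model, std)
    cm = m.evaluate(preds["sc_label"], preds["predicted"])
    metrics = {
        "phase": "test",
        "sex": config.sex,
        "n": len(std),
        "excluded": report.counts,
        **cm.to_dict(),
    }
    log.info("test accuracy %.1f%% on %d rows", cm.accuracy, len(std))
    preds.to_csv(out / "test_predictions.csv", index=False)
    (out / "test_metrics.json").write_text(json.dumps(metrics, indent=2))
    return metrics
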