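"""Imbalance-aware evaluation, stability runs and sensitivity sweeps.

Evaluation regimes matter here: on a curated test split (~20-25%
positive) all four metrics are informative, but at production prevalence
(~0.09% unstable) accuracy is dominated by the majority class and
precision collapses even for a good classifier — a degenerate all-negative
predictor scores >99% accuracy with zero recall. Reports therefore carry
their regime name and flag degenerate (no-positive-prediction) behaviour
explicitly instead of raising on undefined ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "RunSummary",
    "confusion_from_predictions",
    "report_from_confusion",
    "evaluate",
    "stability_runs",
    "sensitivity_sweep",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def validate(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be nonnegative")


@dataclass(frozen=True)
class EvalReport:
    """Confusion counts and the four headline metrics for one regime.

    Undefined ratios (no predicted or no true positives) are reported as
    0.0 with ``degenerate=True`` so a collapsed classifier is visible
    rather than an exception.
    """

    confusion: ConfusionMatrix
    accuracy: float
    precision: float
    recall: float
    f1: float
    regime: str
    degenerate: bool = False

    def to_dict(self) -> dict:
        c = self.confusion
        return {
            "regime": self.regime,
            "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn,
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1,
            "degenerate": self.degenerate,
        }


def confusion_from_predictions(y_true, y_pred) -> ConfusionMatrix:
    y_true = np.asarray(y_true).ravel().astype(np.int64)
    y_pred = np.asarray(y_pred).ravel().astype(np.int64)
    if y_true.size == 0:
        raise ValidationError("cannot evaluate an empty table")
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred must have equal length")
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def report_from_confusion(c: ConfusionMatrix, regime: str) -> EvalReport:
    c.validate()
    total = c.total
    accuracy = (c.tp + c.tn) / total
    pred_pos = c.tp + c.fp
    true_pos = c.tp + c.fn
    precision = c.tp / pred_pos if pred_pos else 0.0
    recall = c.tp / true_pos if true_pos else 0.0
    f1 = (2 * precision * recall / (precision + recall)) if (precision + recall) else 0.0
    return EvalReport(
        confusion=c, accuracy=accuracy, precision=precision, recall=recall,
        f1=f1, regime=regime, degenerate=(pred_pos == 0),
    )


def evaluate(model, X, y, regime: str = "curated_test") -> EvalReport:
    """Score a fitted classifier on a labelled table under a named regime."""
    X = np.asarray(X, dtype=np.float64)
    if len(X) == 0:
        raise ValidationError("cannot evaluate an empty table")
    y_pred = model.predict(X)
    return report_from_confusion(confusion_from_predictions(y, y_pred), regime)


@dataclass
class RunSummary:
    """Per-seed reports plus min/max metric ranges across seeds."""

    reports: dict                 # seed -> EvalReport
    failures: dict                # seed -> error message
    ranges: pd.DataFrame          # index metric, columns min/max

    @staticmethod
    def from_reports(reports: dict, failures: dict | None = None) -> "RunSummary":
        metrics = ["accuracy", "precision", "recall", "f1"]
        frame = pd.DataFrame(
            {s: [getattr(r, m) for m in metrics] for s, r in reports.items()},
            index=metrics,
        )
        ranges = pd.DataFrame({"min": frame.min(axis=1), "max": frame.max(axis=1)})
        return RunSummary(reports=reports, failures=failures or {}, ranges=ranges)


def stability_runs(pipeline_config, seeds) -> RunSummary:
    """Repeat the full train+evaluate pipeline once per seed.

    Each run uses an identical configuration apart from the seed; failed
    runs are recorded and the others proceed. Requires >= 2 seeds.
    """
    from .pipeline import run_pipeline

    seeds = list(seeds)
    if len(seeds) < 2:
        raise ValidationError("stability_runs requires at least 2 seeds")
    reports, failures = {}, {}
    for seed in seeds:
        try:
            result = run_pipeline(replace(pipeline_config, seed=int(seed)))
            reports[int(seed)] = result.eval_test
        except Exception as exc:
            failures[int(seed)] = str(exc)
    if not reports:
        raise ValidationError("every stability run failed")
    return RunSummary.from_reports(reports, failures)


_SWEEP_BOUNDS = {
    "learning_rate": (1e-6, 1.0),
    "n_steps": (1, 10),
    "gamma": (1e-4, 10.0),
    "reg_coef": (0.0, 1.0),
    "lambda_sparse": (0.0, 1.0),
    "batch_size": (1, 4096),
    "n_d": (1, 512),
    "n_a": (1, 512),
}


def sensitivity_sweep(base_config, param: str, values) -> pd.DataFrame:
    """Re-run the pipeline varying one classifier hyperparameter.

    All values are validated against the parameter's legal range before
    any training starts. Returns one row per value with the test metrics
    and their deltas against the base configuration's run.
    """
    from .pipeline import run_pipeline

    if param not in _SWEEP_BOUNDS:
        raise ValidationError(f"unknown sweep parameter '{param}'")
    lo, hi = _SWEEP_BOUNDS[param]
    values = list(values)
    for v in values:
        if not lo <= v <= hi:
            raise ValidationError(f"{param}={v} outside legal range [{lo}, {hi}]")

    base_result = run_pipeline(base_config)
    base = base_result.eval_test
    rows = []
    for v in values:
        tabnet_cfg = replace(base_config.tabnet, **{param: v})
        result = run_pipeline(replace(base_config, tabnet=tabnet_cfg))
        r = result.eval_test
        rows.append(
            {
                param: v,
                "accuracy": r.accuracy, "precision": r.precision,
                "recall": r.recall, "f1": r.f1,
                "delta_accuracy": r.accuracy - base.accuracy,
                "delta_recall": r.recall - base.recall,
            }
        )
    return pd.DataFrame(rows)
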