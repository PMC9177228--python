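"""Validation of weight-thresholded feature groups and contribution analysis.

For every threshold w in 0..s (s = maximum feature weight), the feature
group F_w = {features with weight >= w} is evaluated by repeated resampled
train/validation/test evaluations (default 10×10 = 100, each on a fresh
stratified split at 160:20:20 proportions), training one seeded ELM per
evaluation and reporting mean accuracies and the test-accuracy standard
deviation.

The contribution of the weight-w group to a metric is the difference
metric(F_w) − metric(F_{w+1}): adding the weight-w features to the stricter
group changes the metric by exactly that amount (the deltas telescope).
Dividing by the group's size (count(>=w) − count(>=w+1)) gives the
per-feature contribution.  The top weight's row is dropped when its group
alone cannot fit the training data (training accuracy below a floor), since
a difference against an untrainable classifier is meaningless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import FeatureDataset, scale_ratios, stratified_split
from .elm_core import accuracy, predict_scores, train_elm

__all__ = [
    "GroupRow",
    "FeatureGroupReport",
    "ContributionRow",
    "ContributionReport",
    "CvConfig",
    "select_feature_group",
    "evaluate_feature_groups",
    "contribution_table",
    "write_group_report",
    "read_group_report",
    "write_contribution_report",
]


def _weights_array(weights) -> np.ndarray:
    return np.asarray(getattr(weights, "weights", weights), dtype=int)


def select_feature_group(weights, threshold: int) -> np.ndarray:
    """0-based indices of features with weight >= threshold (threshold 0
    selects every feature: non-key features carry weight 0)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return np.flatnonzero(_weights_array(weights) >= threshold)


@dataclass(frozen=True)
class GroupRow:
    threshold: int
    feature_count: int
    percent_of_total: float  # 100·count/n, rounded to 2 decimals
    train_accuracy: float  # fractions in [0, 1]; NaN when the group is empty
    val_accuracy: float
    test_accuracy: float
    test_accuracy_std: float


@dataclass
class FeatureGroupReport:
    rows: list[GroupRow]
    n_features_total: int
    # per-threshold array of shape (n_evals, 3): train/val/test accuracies
    per_run: dict[int, np.ndarray] = field(default_factory=dict)

    def row(self, threshold: int) -> GroupRow:
        for r in self.rows:
            if r.threshold == threshold:
                return r
        raise KeyError(f"no report row at threshold {threshold}")

    @property
    def max_threshold(self) -> int:
        return max(r.threshold for r in self.rows)


@dataclass(frozen=True)
class ContributionRow:
    weight: int
    feature_count: int
    val_contribution: float  # percentage points
    val_per_feature: float
    test_contribution: float
    test_per_feature: float


@dataclass
class ContributionReport:
    rows: list[ContributionRow]


@dataclass
class CvConfig:
    """Repeated-resampling evaluation protocol for each feature group."""

    repeats: int = 10
    folds: int = 10
    ratios: tuple[int, int, int] = (160, 20, 20)
    L: int = 1000
    seed: int = 0
    activation: str = "sigmoid"
    mode: str = "resample"  # or "kfold": strict stratified k-fold on test


def _kfold_eval_splits(dataset, config, rng):
    """Strict-k-fold alternative: each fold is a test set once; the rest is
    split into train/validation at the configured proportion."""
    from sklearn.model_selection import StratifiedKFold

    y = np.asarray(dataset.class_labels)
    for _ in range(config.repeats):
        skf = StratifiedKFold(
            n_splits=config.folds, shuffle=True,
            random_state=int(rng.integers(2**31)),
        )
        for rest, test in skf.split(np.zeros(len(y)), y):
            rest_ds = dataset.subset(rest)
            r_train, r_val = config.ratios[0], config.ratios[1]
            tv = scale_ratios((r_train, r_val, 0), rest_ds.n_subjects)
            sub = stratified_split(rest_ds, tv, int(rng.integers(2**31)))
            yield rest[sub.train_idx], rest[sub.val_idx], test


def evaluate_feature_groups(
    dataset: FeatureDataset, weights, config: CvConfig | None = None
) -> FeatureGroupReport:
    """Evaluate every threshold group 0..s with repeats×folds seeded
    evaluations; deterministic for a fixed seed.  Empty groups produce a
    row with NaN accuracies rather than an exception."""
    if config is None:
        config = CvConfig()
    if dataset.n_classes != 2:
        raise ValueError("feature-group validation requires two classes")
    w = _weights_array(weights)
    if w.shape[0] != dataset.n_features:
        raise ValueError("weights length does not match dataset features")
    s = int(w.max()) if w.size else 0
    n_total = dataset.n_features
    ratios = config.ratios
    if sum(ratios) > dataset.n_subjects:
        ratios = scale_ratios(ratios, dataset.n_subjects)

    rows: list[GroupRow] = []
    per_run: dict[int, np.ndarray] = {}
    rng = np.random.default_rng(config.seed)
    for thr in range(0, s + 1):
        group = select_feature_group(w, thr)
        pct = round(100.0 * group.size / n_total, 2)
        if group.size == 0:
            rows.append(
                GroupRow(thr, 0, pct, math.nan, math.nan, math.nan, math.nan)
            )
            continue
        sub = dataset.restrict_features(group)
        accs = []
        if config.mode == "kfold":
            eval_iter = (
                (tr, va, te)
                for tr, va, te in _kfold_eval_splits(sub, config, rng)
            )
        else:
            def resample_iter():
                for _ in range(config.repeats * config.folds):
                    split = stratified_split(sub, ratios, int(rng.integers(2**31)))
                    yield split.train_idx, split.val_idx, split.test_idx
            eval_iter = resample_iter()
        for tr_idx, va_idx, te_idx in eval_iter:
            train = sub.subset(tr_idx)
            val = sub.subset(va_idx)
            test = sub.subset(te_idx)
            model = train_elm(train, config.L, int(rng.integers(2**31)),
                              config.activation)
            accs.append(
                (
                    accuracy(predict_scores(model, train.X), train.T),
                    accuracy(predict_scores(model, val.X), val.T),
                    accuracy(predict_scores(model, test.X), test.T),
                )
            )
        arr = np.asarray(accs, dtype=float)
        per_run[thr] = arr
        rows.append(
            GroupRow(
                thr,
                int(group.size),
                pct,
                float(arr[:, 0].mean()),
                float(arr[:, 1].mean()),
                float(arr[:, 2].mean()),
                float(arr[:, 2].std(ddof=1)),
            )
        )
    return FeatureGroupReport(rows, n_total, per_run)


def contribution_table(
    report: FeatureGroupReport,
    rounded: bool = True,
    exclude_top: bool | None = None,
    train_floor: float = 0.9,
) -> ContributionReport:
    """Per-weight-group contributions from adjacent-threshold differences.

    ``rounded=True`` applies the differences to accuracies expressed as
    percentages rounded to 2 decimals (matching how such tables are
    printed) and rounds per-feature values to 4 decimals; ``rounded=False``
    keeps full precision.  ``exclude_top=None`` drops the highest weight's
    row automatically when the top-threshold group's training accuracy is
    below ``train_floor`` (its classifier cannot even fit the training
    data, so the difference against it is not meaningful).
    """
    thresholds = sorted(r.threshold for r in report.rows)
    if thresholds != list(range(thresholds[0], thresholds[-1] + 1)):
        raise ValueError("report thresholds must be contiguous")
    s = report.max_threshold
    if exclude_top is None:
        top = report.row(s)
        exclude_top = math.isnan(top.train_accuracy) or top.train_accuracy < train_floor
    max_w = s - 2 if exclude_top else s - 1
    if max_w < 0:
        raise ValueError("not enough thresholds for a contribution table")

    def pct(x: float) -> float:
        return round(100.0 * x, 2) if rounded else 100.0 * x

    out: list[ContributionRow] = []
    for wgt in range(max_w, -1, -1):
        lo = report.row(wgt)
        hi = report.row(wgt + 1)
        count = lo.feature_count - hi.feature_count
        if count <= 0:
            out.append(ContributionRow(wgt, count, 0.0, 0.0, 0.0, 0.0))
            continue
        val_c = pct(lo.val_accuracy) - pct(hi.val_accuracy)
        test_c = pct(lo.test_accuracy) - pct(hi.test_accuracy)
        if rounded:
            val_c, test_c = round(val_c, 2), round(test_c, 2)
            per_val = round(val_c / count, 4)
            per_test = round(test_c / count, 4)
        else:
            per_val = val_c / count
            per_test = test_c / count
        out.append(ContributionRow(wgt, count, val_c, per_val, test_c, per_test))
    return ContributionReport(out)


def write_group_report(report: FeatureGroupReport, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "threshold": [r.threshold for r in report.rows],
            "feature_count": [r.feature_count for r in report.rows],
            "percent_of_total": [r.percent_of_total for r in report.rows],
            "train_accuracy": [r.train_accuracy for r in report.rows],
            "val_accuracy": [r.val_accuracy for r in report.rows],
            "test_accuracy": [r.test_accuracy for r in report.rows],
            "test_accuracy_std": [r.test_accuracy_std for r in report.rows],
        }
    )
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_group_report(path: str | Path) -> FeatureGroupReport:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    rows = [
        GroupRow(
            int(r.threshold), int(r.feature_count), float(r.percent_of_total),
            float(r.train_accuracy), float(r.val_accuracy),
            float(r.test_accuracy), float(r.test_accuracy_std),
        )
        for r in df.itertuples()
    ]
    n_total = rows[0].feature_count if rows and rows[0].threshold == 0 else 0
    return FeatureGroupReport(rows, n_total)


def write_contribution_report(report: ContributionReport, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "weight": [r.weight for r in report.rows],
            "feature_count": [r.feature_count for r in report.rows],
            "val_contribution": [r.val_contribution for r in report.rows],
            "val_per_feature": [r.val_per_feature for r in report.rows],
            "test_contribution": [r.test_contribution for r in report.rows],
            "test_per_feature": [r.test_per_feature for r in report.rows],
        }
    )
    df.to_csv(path, sep="\t", index=False)
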