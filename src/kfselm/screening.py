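"""Outer key-feature screening loop and weight accumulation.

Each round: re-split train/validation inside the screening pool (the
frozen test subjects never participate), build an ensemble of ELMs until
the mean validation accuracy converges, select the best classifier, prune
it, and add its surviving input mask into the running integer weight vector
W* (a feature's weight = the number of pruned classifiers that retained
it).  After every round a fresh ELM restricted to the current support of W*
is trained and scored on a validation split; screening stops once that
accuracy has not improved for ``patience`` consecutive rounds.

Different pruned classifiers retain different (possibly disjoint) feature
subsets; the union accumulates a more complete key-feature set than any
single classifier, which is the point of the method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import FeatureDataset, stratified_split
from .elm_core import PruneMasks, accuracy, predict_scores, train_elm
from .ensemble import train_until_converged, select_best
from .pruning import prune_classifier

__all__ = [
    "KeyFeatureWeights",
    "ScreeningConfig",
    "ScreeningRunRecord",
    "accumulate_weights",
    "screen_key_features",
    "aggregate_region_weights",
    "write_run_log",
]


@dataclass
class KeyFeatureWeights:
    """Integer per-feature weights W* accumulated over pruned classifiers,
    with full per-run provenance."""

    weights: np.ndarray
    run_masks: list[np.ndarray] = field(default_factory=list)
    run_metrics: list["ScreeningRunRecord"] = field(default_factory=list)
    test_idx: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=int)

    @property
    def s(self) -> int:
        """Maximum feature weight."""
        return int(self.weights.max()) if self.weights.size else 0

    @property
    def support(self) -> np.ndarray:
        """0-based indices of features with weight >= 1."""
        return np.flatnonzero(self.weights > 0)

    @property
    def n_runs(self) -> int:
        return len(self.run_masks)


@dataclass(frozen=True)
class ScreeningRunRecord:
    iteration: int
    selected_val_accuracy: float
    pruned_input_count: int
    union_size: int
    union_val_accuracy: float


@dataclass
class ScreeningConfig:
    """Knobs of the screening loop.

    L: hidden nodes per ELM (the full-scale study value is 64000; desk
    default 1000).  p: fluctuation tolerance of the ensemble convergence
    rule.  ratios: absolute train/val/test part sizes.  patience: rounds
    without improvement of the union-feature validation accuracy before
    stopping.  union_ensemble: score the union features with a full
    converged ensemble instead of a single seeded ELM.
    """

    L: int = 1000
    p: float = 0.0015
    ratios: tuple[int, int, int] = (90, 90, 20)
    patience: int = 1
    master_seed: int = 0
    max_iterations: int = 100
    max_classifiers: int = 500
    activation: str = "sigmoid"
    union_ensemble: bool = False


def accumulate_weights(
    run_masks: Sequence[np.ndarray], n_features: int | None = None
) -> KeyFeatureWeights:
    """Elementwise integer sum of binary input masks.

    Conservation: sum(weights) equals the sum of mask sizes.
    """
    masks = [np.asarray(m, dtype=int) for m in run_masks]
    if masks:
        n = masks[0].shape[0]
        for m in masks:
            if m.shape[0] != n:
                raise ValueError("run masks have differing lengths")
        weights = np.sum(masks, axis=0)
    else:
        if n_features is None:
            raise ValueError("n_features required for an empty mask sequence")
        n = n_features
        weights = np.zeros(n, dtype=int)
    return KeyFeatureWeights(weights, run_masks=[m.copy() for m in masks])


def _union_accuracy(
    pool: FeatureDataset,
    support: np.ndarray,
    tv_ratios: tuple[int, int, int],
    config: ScreeningConfig,
    seed: int,
) -> float:
    """Validation accuracy of an ELM restricted to the current key features."""
    restricted = pool.restrict_features(support)
    if config.union_ensemble:
        trace, models = train_until_converged(
            restricted, tv_ratios, config.L, config.p, seed=seed,
            max_classifiers=config.max_classifiers,
            activation=config.activation,
        )
        _, best = select_best(trace, models)
        return float(trace.entries[best].val_accuracy)
    split = stratified_split(restricted, tv_ratios, seed)
    train = restricted.subset(split.train_idx)
    val = restricted.subset(split.val_idx)
    model = train_elm(train, config.L, seed, config.activation)
    return accuracy(predict_scores(model, val.X), val.T)


def screen_key_features(
    dataset: FeatureDataset, config: ScreeningConfig | None = None
) -> KeyFeatureWeights:
    """Run the full screening loop; deterministic per ``master_seed``.

    A test split is frozen up front and never touches screening: both the
    ensemble construction and the pruning evaluation see only the pooled
    train+validation subjects.
    """
    if config is None:
        config = ScreeningConfig()
    if dataset.n_classes != 2:
        raise ValueError(
            f"screening requires exactly two classes, got {dataset.label_order}"
        )
    rng = np.random.default_rng(config.master_seed)

    base = stratified_split(dataset, config.ratios, int(rng.integers(2**31)))
    test_idx = base.test_idx
    pool_rows = np.array(
        sorted(set(base.train_idx) | set(base.val_idx)), dtype=int
    )
    pool = dataset.subset(pool_rows)
    tv_ratios = (config.ratios[0], config.ratios[1], 0)

    run_masks: list[np.ndarray] = []
    records: list[ScreeningRunRecord] = []
    best_union = -np.inf
    stall = 0
    weights = np.zeros(dataset.n_features, dtype=int)

    for it in range(1, config.max_iterations + 1):
        ens_seed = int(rng.integers(2**31))
        trace, models = train_until_converged(
            pool, tv_ratios, config.L, config.p, seed=ens_seed,
            max_classifiers=config.max_classifiers,
            activation=config.activation,
        )
        model, best_i = select_best(trace, models)
        sel_val = float(trace.entries[best_i].val_accuracy)

        masks = prune_classifier(model, pool)
        run_masks.append(masks.input_mask.astype(int).copy())
        weights = weights + run_masks[-1]

        support = np.flatnonzero(weights > 0)
        union_seed = int(rng.integers(2**31))
        union_acc = _union_accuracy(pool, support, tv_ratios, config, union_seed)
        records.append(
            ScreeningRunRecord(
                it, sel_val, int(masks.n_active_inputs),
                int(support.size), float(union_acc),
            )
        )
        if union_acc > best_union:
            best_union = union_acc
            stall = 0
        else:
            stall += 1
        if stall >= config.patience:
            break
    else:
        raise RuntimeError(
            f"screening did not stop within {config.max_iterations} iterations"
        )

    return KeyFeatureWeights(
        weights, run_masks=run_masks, run_metrics=records,
        test_idx=np.asarray(test_idx, dtype=int),
    )


def aggregate_region_weights(
    edge_weights: Sequence[tuple[int, int, int]], min_weight: int = 0
) -> dict[int, int]:
    """Per-region weight: the sum of the weights of all qualifying edges
    (weight >= ``min_weight``) incident to that region.

    ``edge_weights`` are (region_i, region_j, weight) triples with 1-based
    region indices; regions are keyed by numeric index.
    """
    out: dict[int, int] = {}
    for i, j, w in edge_weights:
        if w < 0:
            raise ValueError(f"negative edge weight {w} on ({i}, {j})")
        if i < 1 or j < 1:
            raise ValueError(f"region indices must be >= 1, got ({i}, {j})")
        if w >= min_weight:
            out[int(i)] = out.get(int(i), 0) + int(w)
            out[int(j)] = out.get(int(j), 0) + int(w)
    return out


def write_run_log(weights: KeyFeatureWeights, path: str | Path) -> None:
    """One line per screening round: selected-classifier validation
    accuracy, pruned input count, union size, union-ELM accuracy."""
    df = pd.DataFrame(
        {
            "iteration": [r.iteration for r in weights.run_metrics],
            "selected_val_acc": [r.selected_val_accuracy for r in weights.run_metrics],
            "pruned_input_count": [r.pruned_input_count for r in weights.run_metrics],
            "union_size": [r.union_size for r in weights.run_metrics],
            "union_val_acc": [r.union_val_accuracy for r in weights.run_metrics],
        }
    )
    df.to_csv(path, sep="\t", index=False)
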