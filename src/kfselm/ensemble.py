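"""Ensemble construction: train classifiers until the running average
validation accuracy converges, then pick the best one.

Because the hidden layer of each ELM is random, single-classifier accuracy
fluctuates.  Classifiers are therefore trained repeatedly — with the
train/validation subjects re-divided before every training — until, for
some window length Loop, all Loop-long windows of consecutive validation
accuracies among the first 2·Loop recorded have means within a fluctuation
tolerance p of the first window's mean.  Loop is grown incrementally
(2, 3, …) and the smallest satisfying value is returned; the classifier
with the highest validation accuracy among the 2·Loop is the selected one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .data_io import FeatureDataset, stratified_split
from .elm_core import ELMModel, accuracy, predict_scores, train_elm

__all__ = [
    "TraceEntry",
    "EnsembleTrace",
    "ConvergenceError",
    "satisfies_convergence",
    "train_until_converged",
    "select_best",
    "write_trace",
    "read_trace",
]

DEFAULT_P = 0.0015  # fluctuation tolerance on the running mean accuracy


@dataclass(frozen=True)
class TraceEntry:
    index: int
    split_seed: int
    model_seed: int
    train_accuracy: float
    val_accuracy: float


@dataclass
class EnsembleTrace:
    """Audit record of one converged ensemble: 2·loop accuracies."""

    entries: list[TraceEntry]
    loop: int
    p: float
    converged: bool

    @property
    def val_accuracies(self) -> np.ndarray:
        return np.array([e.val_accuracy for e in self.entries])

    @property
    def train_accuracies(self) -> np.ndarray:
        return np.array([e.train_accuracy for e in self.entries])


class ConvergenceError(RuntimeError):
    """Raised when the running mean accuracy fails to stabilize within the
    classifier budget."""


def satisfies_convergence(
    accuracies: Sequence[float], loop: int, p: float
) -> bool:
    """Window-mean stability check over 2·loop recorded accuracies: for every
    offset n in 2..loop+1, |mean(acc[n-1 : n-1+loop]) − mean(acc[:loop])| ≤ p.
    """
    acc = np.asarray(accuracies, dtype=float)
    if loop < 1 or len(acc) < 2 * loop:
        return False
    base = float(np.mean(acc[:loop]))
    for n in range(2, loop + 2):
        window = float(np.mean(acc[n - 1 : n - 1 + loop]))
        if abs(window - base) > p:
            return False
    return True


def train_until_converged(
    dataset: FeatureDataset,
    split_ratios: Sequence[int],
    L: int,
    p: float = DEFAULT_P,
    seed: int = 0,
    max_classifiers: int = 500,
    frozen_test_idx: Sequence[int] | None = None,
    activation: str = "sigmoid",
    trainer: Callable[[int, int], tuple[ELMModel | None, float, float]] | None = None,
    min_loop: int = 2,
) -> tuple[EnsembleTrace, list[ELMModel | None]]:
    """Grow the ensemble until the convergence rule holds; deterministic for
    a fixed master ``seed``.

    ``trainer(split_seed, model_seed) -> (model, train_acc, val_acc)`` may be
    injected (e.g. a scripted stub in tests); by default each call re-splits
    train/validation with a fresh seed and trains one ELM.
    """
    if not (0.0 < p < 1.0):
        raise ValueError(f"fluctuation tolerance p must be in (0, 1), got {p}")
    if min_loop < 1:
        raise ValueError("min_loop must be >= 1")
    rng = np.random.default_rng(seed)

    def default_trainer(
        split_seed: int, model_seed: int
    ) -> tuple[ELMModel, float, float]:
        split = stratified_split(
            dataset, split_ratios, split_seed, frozen_test_idx=frozen_test_idx
        )
        train = dataset.subset(split.train_idx)
        val = dataset.subset(split.val_idx)
        model = train_elm(train, L, model_seed, activation)
        tr = accuracy(predict_scores(model, train.X), train.T)
        va = accuracy(predict_scores(model, val.X), val.T)
        return model, tr, va

    fit_one = trainer if trainer is not None else default_trainer

    entries: list[TraceEntry] = []
    models: list[ELMModel | None] = []
    loop = min_loop
    while True:
        if 2 * loop > max_classifiers:
            raise ConvergenceError(
                f"mean validation accuracy did not stabilize within p={p} "
                f"using {len(entries)} classifiers (cap {max_classifiers})"
            )
        while len(entries) < 2 * loop:
            split_seed = int(rng.integers(2**31))
            model_seed = int(rng.integers(2**31))
            model, tr, va = fit_one(split_seed, model_seed)
            entries.append(
                TraceEntry(len(entries), split_seed, model_seed, tr, va)
            )
            models.append(model)
        if satisfies_convergence([e.val_accuracy for e in entries], loop, p):
            return EnsembleTrace(entries, loop, p, True), models
        loop += 1


def select_best(
    trace: EnsembleTrace, models: Sequence[ELMModel | None]
) -> tuple[ELMModel | None, int]:
    """Classifier with the highest validation accuracy; earliest index on
    ties.  Returns (model, 0-based index)."""
    if not trace.entries:
        raise ValueError("empty ensemble trace")
    vals = trace.val_accuracies
    best = int(np.argmax(vals))  # argmax takes the first maximum
    return models[best], best


def write_trace(trace: EnsembleTrace, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "idx": [e.index for e in trace.entries],
            "split_seed": [e.split_seed for e in trace.entries],
            "model_seed": [e.model_seed for e in trace.entries],
            "train_acc": [e.train_accuracy for e in trace.entries],
            "val_acc": [e.val_accuracy for e in trace.entries],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_trace(path: str | Path, loop: int, p: float) -> EnsembleTrace:
    df = pd.read_csv(path, sep="\t")
    entries = [
        TraceEntry(int(r.idx), int(r.split_seed), int(r.model_seed),
                   float(r.train_acc), float(r.val_acc))
        for r in df.itertuples()
    ]
    conv = satisfies_convergence([e.val_accuracy for e in entries], loop, p)
    return EnsembleTrace(entries, loop, p, conv)
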