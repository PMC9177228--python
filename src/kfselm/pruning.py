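"""Greedy accuracy-preserving pruning of a fitted ELM.

Input nodes (features) and hidden nodes are visited in ascending index
order and tentatively zeroed in the masks; a removal is kept iff the
classifier's accuracy on the pruning-evaluation data (pooled training +
validation subjects) is unchanged or improved, with the incumbent accuracy
updated after every kept removal.  Input pruning is repeated to a fixed
point (the hidden layer is nonlinear in the inputs, so one pass is not
enough); hidden pruning needs a single pass per round because the output is
a linear sum of hidden-node contributions, but any hidden removal re-opens
input pruning.  The fitted β is never re-solved.

Accuracy comparisons use integer correct-counts, never floats: accuracies
are multiples of 1/N, so the kept/reverted decision is exact.  Tentative
evaluations use rank-1 updates of cached pre-activations (input removals)
and scores (hidden removals); these agree with full recomputation to
floating tolerance and caches are rebuilt from scratch at the start of
every pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import FeatureDataset
from .elm_core import ELMModel, PruneMasks, accuracy, correct_count, predict_scores

__all__ = [
    "PruneLogEntry",
    "masked_accuracy",
    "prune_input_pass",
    "prune_input_to_fixed_point",
    "prune_hidden_pass",
    "prune_classifier",
    "write_prune_log",
]


@dataclass(frozen=True)
class PruneLogEntry:
    phase: str  # "input" | "hidden"
    node_index: int
    action: str  # "kept" | "reverted"
    correct_before: int
    correct_after: int


def _check_sizes(model: ELMModel, masks: PruneMasks, data: FeatureDataset) -> None:
    if not model.is_fitted:
        raise ValueError("model has no fitted output weights")
    if masks.input_mask.shape[0] != model.n_features:
        raise ValueError("input mask length does not match model features")
    if masks.hidden_mask.shape[0] != model.n_hidden:
        raise ValueError("hidden mask length does not match model hidden nodes")
    if data.n_features != model.n_features:
        raise ValueError("evaluation data feature count does not match model")


def masked_accuracy(
    model: ELMModel, masks: PruneMasks, eval_data: FeatureDataset
) -> float:
    """Accuracy of the masked classifier on the evaluation subjects; a pure
    function of (model, masks, data)."""
    _check_sizes(model, masks, eval_data)
    return accuracy(predict_scores(model, eval_data.X, masks), eval_data.T)


def prune_input_pass(
    model: ELMModel,
    masks: PruneMasks,
    eval_data: FeatureDataset,
    log: list[PruneLogEntry] | None = None,
    order: Sequence[int] | None = None,
) -> tuple[PruneMasks, int]:
    """One sweep over the active input nodes in ascending order (or a caller
    supplied ``order``); returns (updated masks, number removed)."""
    _check_sizes(model, masks, eval_data)
    X, T = eval_data.X, eval_data.T
    W, b = model.input_weights, model.biases
    beta = model.output_weights
    hm = masks.hidden_mask.astype(float)
    im = masks.input_mask.copy()

    A = (X * im.astype(float)[None, :]) @ W.T + b[None, :]

    def count_of(pre: np.ndarray) -> int:
        H = model.g(pre) * hm[None, :]
        return correct_count(H @ beta, T)

    incumbent = count_of(A)
    removed = 0
    visit = np.flatnonzero(im) if order is None else [k for k in order if im[k]]
    for k in visit:
        A_try = A - np.outer(X[:, k], W[:, k])
        c = count_of(A_try)
        if c >= incumbent:
            im[k] = 0
            A = A_try
            if log is not None:
                log.append(PruneLogEntry("input", int(k), "kept", incumbent, c))
            incumbent = c
            removed += 1
        elif log is not None:
            log.append(PruneLogEntry("input", int(k), "reverted", incumbent, c))
    return PruneMasks(im, masks.hidden_mask.copy()), removed


def prune_input_to_fixed_point(
    model: ELMModel,
    masks: PruneMasks,
    eval_data: FeatureDataset,
    log: list[PruneLogEntry] | None = None,
) -> PruneMasks:
    """Repeat input sweeps until a sweep removes nothing: afterwards no
    single remaining input node can be zeroed without strictly decreasing
    accuracy."""
    current = masks.copy()
    while True:
        current, removed = prune_input_pass(model, current, eval_data, log=log)
        if removed == 0:
            return current


def prune_hidden_pass(
    model: ELMModel,
    masks: PruneMasks,
    eval_data: FeatureDataset,
    log: list[PruneLogEntry] | None = None,
) -> tuple[PruneMasks, int]:
    """One sweep over active hidden nodes: node j's contribution to the
    scores is the rank-1 term H[:, j] ⊗ β[j, :], so removal is a subtraction
    and no refit is needed."""
    _check_sizes(model, masks, eval_data)
    X, T = eval_data.X, eval_data.T
    beta = model.output_weights
    hm = masks.hidden_mask.copy()

    H = model.g(
        (X * masks.input_mask.astype(float)[None, :]) @ model.input_weights.T
        + model.biases[None, :]
    )
    O = (H * hm.astype(float)[None, :]) @ beta
    incumbent = correct_count(O, T)
    removed = 0
    for j in np.flatnonzero(hm):
        O_try = O - np.outer(H[:, j], beta[j, :])
        c = correct_count(O_try, T)
        if c >= incumbent:
            hm[j] = 0
            O = O_try
            if log is not None:
                log.append(PruneLogEntry("hidden", int(j), "kept", incumbent, c))
            incumbent = c
            removed += 1
        elif log is not None:
            log.append(PruneLogEntry("hidden", int(j), "reverted", incumbent, c))
    return PruneMasks(masks.input_mask.copy(), hm), removed


def prune_classifier(
    model: ELMModel,
    eval_data: FeatureDataset,
    masks: PruneMasks | None = None,
    log: list[PruneLogEntry] | None = None,
) -> PruneMasks:
    """Alternate input pruning (to a fixed point) and hidden pruning until
    neither phase removes a node.  Each hidden removal re-opens input
    pruning.  The final evaluation accuracy is >= the initial one by
    construction of the acceptance rule."""
    if masks is None:
        masks = PruneMasks.full(model.n_features, model.n_hidden)
    current = masks.copy()
    while True:
        current = prune_input_to_fixed_point(model, current, eval_data, log=log)
        current, removed_hidden = prune_hidden_pass(model, current, eval_data, log=log)
        if removed_hidden == 0:
            return current


def write_prune_log(entries: Sequence[PruneLogEntry], path: str | Path) -> None:
    """Append-only TSV audit of every kept/reverted removal decision."""
    df = pd.DataFrame(
        {
            "phase": [e.phase for e in entries],
            "node_index": [e.node_index for e in entries],
            "action": [e.action for e in entries],
            "correct_count_before": [e.correct_before for e in entries],
            "correct_count_after": [e.correct_after for e in entries],
        }
    )
    df.to_csv(path, sep="\t", index=False)
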