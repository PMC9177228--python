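"""Extreme learning machine: random hidden layer, least-squares output fit.

The ELM is a single-hidden-layer feedforward network whose input weights W
(L×n) and biases b (L) are drawn once at random and never trained; only the
output weights β (L×m) are fitted, as the minimum-norm least-squares
solution β = H†T of Hβ = T, where H = g(XWᵀ + b) is the hidden-layer output
and T the one-hot targets.  Models are immutable after fitting: pruning
never edits W, b or β but operates through binary masks (an input mask over
features, a hidden mask over hidden nodes), so any mask can be evaluated
against any dataset reproducibly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit

from .data_io import FeatureDataset

__all__ = [
    "ACTIVATIONS",
    "ELMModel",
    "PruneMasks",
    "init_random_elm",
    "hidden_output",
    "fit_output_weights",
    "predict_scores",
    "predict_labels",
    "correct_count",
    "accuracy",
    "train_elm",
    "save_model",
    "load_model",
]

ACTIVATIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "sigmoid": expit,
    "tanh": np.tanh,
    "relu": lambda x: np.maximum(x, 0.0),
}


@dataclass(frozen=True)
class ELMModel:
    """Frozen ELM: random (W, b), fitted β, named activation g."""

    input_weights: np.ndarray  # L×n
    biases: np.ndarray  # L
    output_weights: np.ndarray | None  # L×m once fitted
    activation: str
    seed: int | None = None

    @property
    def n_hidden(self) -> int:
        return self.input_weights.shape[0]

    @property
    def n_features(self) -> int:
        return self.input_weights.shape[1]

    @property
    def is_fitted(self) -> bool:
        return self.output_weights is not None

    @property
    def g(self) -> Callable[[np.ndarray], np.ndarray]:
        return ACTIVATIONS[self.activation]

    def with_output_weights(self, beta: np.ndarray) -> "ELMModel":
        return dataclasses.replace(self, output_weights=np.asarray(beta, float))


@dataclass
class PruneMasks:
    """Binary masks: which features (input nodes) and hidden nodes remain.

    The number of ones in each mask is the rank of the corresponding
    diagonal selection matrix.
    """

    input_mask: np.ndarray
    hidden_mask: np.ndarray

    def __post_init__(self) -> None:
        self.input_mask = np.asarray(self.input_mask, dtype=np.int8)
        self.hidden_mask = np.asarray(self.hidden_mask, dtype=np.int8)

    @classmethod
    def full(cls, n_features: int, n_hidden: int) -> "PruneMasks":
        return cls(np.ones(n_features, np.int8), np.ones(n_hidden, np.int8))

    @property
    def n_active_inputs(self) -> int:
        return int(self.input_mask.sum())

    @property
    def n_active_hidden(self) -> int:
        return int(self.hidden_mask.sum())

    def copy(self) -> "PruneMasks":
        return PruneMasks(self.input_mask.copy(), self.hidden_mask.copy())


def init_random_elm(n: int, L: int, m: int, seed: int) -> ELMModel:
    """Random hidden layer: W ~ U[-1, 1] (L×n), b ~ U[0, 1] (L); β unset."""
    if n < 1 or L < 1 or m < 1:
        raise ValueError("n, L, m must all be >= 1")
    rng = np.random.default_rng(seed)
    W = rng.uniform(-1.0, 1.0, size=(L, n))
    b = rng.uniform(0.0, 1.0, size=L)
    return ELMModel(W, b, None, "sigmoid", int(seed))


def hidden_output(
    model: ELMModel, X: np.ndarray, input_mask: np.ndarray | None = None
) -> np.ndarray:
    """H = g((X·diag(mask))Wᵀ + b); masking a feature zeroes its column."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"X has shape {X.shape}, expected (*, {model.n_features})"
        )
    if input_mask is not None:
        X = X * np.asarray(input_mask, dtype=float)[None, :]
    return model.g(X @ model.input_weights.T + model.biases[None, :])


def fit_output_weights(H: np.ndarray, T: np.ndarray) -> np.ndarray:
    """β = H†T: minimum-Frobenius-norm least-squares solution of Hβ = T,
    via SVD with singular values below max(N, L)·ε·σmax discarded."""
    H = np.asarray(H, dtype=float)
    T = np.asarray(T, dtype=float)
    if H.size == 0:
        raise ValueError("empty hidden-output matrix")
    if H.shape[0] != T.shape[0]:
        raise ValueError("H and T must have the same number of rows")
    beta, *_ = np.linalg.lstsq(H, T, rcond=None)
    return beta


def predict_scores(
    model: ELMModel, X: np.ndarray, masks: PruneMasks | None = None
) -> np.ndarray:
    """O = g(X·diag(input_mask)·Wᵀ + b) · diag(hidden_mask) · β.

    Zeroing hidden_mask[j] removes node j's additive rank-1 contribution
    exactly; all-ones masks reproduce the unmasked prediction.
    """
    if not model.is_fitted:
        raise ValueError("model has no fitted output weights")
    im = masks.input_mask if masks is not None else None
    H = hidden_output(model, X, im)
    if masks is not None:
        H = H * masks.hidden_mask.astype(float)[None, :]
    return H @ model.output_weights


def predict_labels(O: np.ndarray) -> np.ndarray:
    """Per-row argmax class index (0-based); ties go to the lowest index."""
    return np.argmax(np.asarray(O), axis=1)


def correct_count(O: np.ndarray, T: np.ndarray) -> int:
    """Number of rows whose argmax matches the one-hot position in T."""
    O = np.asarray(O)
    T = np.asarray(T)
    if O.shape != T.shape:
        raise ValueError(f"shape mismatch: O {O.shape} vs T {T.shape}")
    return int(np.sum(np.argmax(O, axis=1) == np.argmax(T, axis=1)))


def accuracy(O: np.ndarray, T: np.ndarray) -> float:
    """Fraction of correctly classified rows (argmax decoding)."""
    T = np.asarray(T)
    return correct_count(O, T) / T.shape[0]


def train_elm(
    train: FeatureDataset,
    L: int,
    seed: int,
    activation: str = "sigmoid",
) -> ELMModel:
    """Draw a random hidden layer and fit β on the training set."""
    if train.n_subjects == 0:
        raise ValueError("empty training set")
    model = init_random_elm(train.n_features, L, train.n_classes, seed)
    if activation != model.activation:
        model = dataclasses.replace(model, activation=activation)
    H = hidden_output(model, train.X)
    beta = fit_output_weights(H, train.T)
    return model.with_output_weights(beta)


def save_model(
    model: ELMModel, path: str | Path, masks: PruneMasks | None = None
) -> None:
    """Serialize model (and optional masks) to a single .npz archive."""
    payload: dict[str, np.ndarray] = {
        "input_weights": model.input_weights,
        "biases": model.biases,
        "activation": np.array(model.activation),
        "seed": np.array(-1 if model.seed is None else model.seed),
    }
    if model.output_weights is not None:
        payload["output_weights"] = model.output_weights
    if masks is not None:
        payload["input_mask"] = masks.input_mask
        payload["hidden_mask"] = masks.hidden_mask
    np.savez(path, **payload)


def load_model(path: str | Path) -> tuple[ELMModel, PruneMasks | None]:
    with np.load(path) as z:
        seed = int(z["seed"])
        model = ELMModel(
            z["input_weights"],
            z["biases"],
            z["output_weights"] if "output_weights" in z else None,
            str(z["activation"]),
            None if seed == -1 else seed,
        )
        masks = None
        if "input_mask" in z:
            masks = PruneMasks(z["input_mask"], z["hidden_mask"])
    return model, masks
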