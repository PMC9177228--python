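"""Synthetic connectivity-like two-class data with planted informative edges.

Group differences in functional connectivity are modelled the standard way:
an additive mean shift in Fisher-z space.  Every edge k gets a baseline
mean mu_k (drawn once per dataset), subjects get z-values mu_k + noise, and
the second class is shifted by ``effect_size × noise_sd`` on the informative
edges only.  Values pass through tanh so every entry lies in (-1, 1) like a
correlation, and each subject's row can be folded back into a symmetric
R×R matrix.  No time series are simulated: the generator emulates the
edge-level group structure of a case/control connectome study, not
hemodynamics or the spatial autocorrelation of real connectomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .data_io import (
    FeatureDataset,
    ManifestRecord,
    SubjectManifest,
    edge_feature_names,
    matrix_from_vector,
    n_edge_features,
)

__all__ = [
    "SyntheticSpec",
    "RecoveryMetrics",
    "generate_dataset",
    "subject_matrix",
    "write_simulated_dataset",
    "score_recovery",
]


@dataclass
class SyntheticSpec:
    """Study-design parameters of the generator.

    ``informative_edges`` is either a count (that many edges drawn at
    random from the seed) or an explicit sequence of 0-based feature
    (column) positions.  ``effect_size`` is the standardized between-class
    mean shift on those edges, in units of ``noise_sd`` (the within-class
    standard deviation in Fisher-z space).
    """

    n_regions: int = 45
    n_per_class: int = 60
    informative_edges: int | Sequence[int] = 15
    effect_size: float = 1.5
    noise_sd: float = 0.3
    baseline_mean: float = 0.2
    baseline_sd: float = 0.3
    class_labels: tuple[str, str] = ("case", "control")
    seed: int = 0


@dataclass(frozen=True)
class RecoveryMetrics:
    """How well thresholded screening weights recover the planted edges."""

    precision: float
    recall: float
    informative_mean_weight: float
    noise_mean_weight: float


def _resolve_informative(spec: SyntheticSpec, n: int, rng) -> np.ndarray:
    if isinstance(spec.informative_edges, (int, np.integer)):
        k = int(spec.informative_edges)
        if not 0 <= k <= n:
            raise ValueError(f"informative edge count {k} outside 0..{n}")
        return np.sort(rng.choice(n, size=k, replace=False))
    idx = np.asarray(sorted(set(int(i) for i in spec.informative_edges)))
    if idx.size and (idx.min() < 0 or idx.max() >= n):
        raise ValueError("informative edge positions outside feature range")
    return idx


def generate_dataset(spec: SyntheticSpec) -> tuple[FeatureDataset, dict]:
    """Generate (dataset, ground truth); deterministic per seed.

    Ground truth holds the 0-based informative column positions, the
    applied z-space shift, and the spec itself.
    """
    if spec.n_regions < 2 or spec.n_per_class < 1:
        raise ValueError("need at least 2 regions and 1 subject per class")
    if spec.effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    if spec.noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    rng = np.random.default_rng(spec.seed)
    n = n_edge_features(spec.n_regions)
    informative = _resolve_informative(spec, n, rng)

    mu = rng.normal(spec.baseline_mean, spec.baseline_sd, size=n)
    N = 2 * spec.n_per_class
    Z = mu[None, :] + rng.normal(0.0, spec.noise_sd, size=(N, n))
    shift = spec.effect_size * spec.noise_sd
    # second (lexicographically later may differ; shift is applied to the
    # second listed class) half of the subjects
    Z[spec.n_per_class :, informative] += shift
    X = np.tanh(Z)

    la, lb = spec.class_labels
    labels = [la] * spec.n_per_class + [lb] * spec.n_per_class
    ids = [f"{la}_{i:03d}" for i in range(spec.n_per_class)] + [
        f"{lb}_{i:03d}" for i in range(spec.n_per_class)
    ]
    dataset = FeatureDataset.from_features(
        X, labels, subject_ids=ids,
        feature_names=edge_feature_names(spec.n_regions),
    )
    truth = {
        "informative_edges": informative,
        "shift": shift,
        "shifted_class": lb,
        "spec": spec,
    }
    return dataset, truth


def subject_matrix(dataset: FeatureDataset, row: int, region_count: int) -> np.ndarray:
    """Fold one subject's feature row back into its symmetric R×R matrix
    (unit diagonal, as for a correlation matrix)."""
    return matrix_from_vector(dataset.X[row], region_count, diagonal=1.0)


def write_simulated_dataset(
    dataset: FeatureDataset, region_count: int, out_dir: str | Path
) -> Path:
    """Write per-subject matrix files plus a manifest.csv consumable by the
    connectivity loader; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    for r, (sid, lab) in enumerate(zip(dataset.subject_ids, dataset.class_labels)):
        path = out / f"{sid}.txt"
        np.savetxt(path, subject_matrix(dataset, r, region_count), fmt="%.10f")
        records.append(ManifestRecord(sid, lab, str(path)))
    manifest = SubjectManifest(records)
    manifest_path = out / "manifest.csv"
    manifest.write_csv(manifest_path)
    return manifest_path


def score_recovery(weights, truth: dict, threshold: int = 1) -> RecoveryMetrics:
    """Precision/recall of {features with weight >= threshold} against the
    planted edges, plus mean weight per stratum.  Precision is 0 when
    nothing is selected."""
    w = np.asarray(getattr(weights, "weights", weights))
    informative = np.asarray(truth["informative_edges"], dtype=int)
    selected = np.flatnonzero(w >= threshold)
    inf_set = set(informative.tolist())
    sel_set = set(selected.tolist())
    tp = len(inf_set & sel_set)
    precision = tp / len(sel_set) if sel_set else 0.0
    recall = tp / len(inf_set) if inf_set else 0.0
    noise_mask = np.ones(w.shape[0], dtype=bool)
    noise_mask[informative] = False
    return RecoveryMetrics(
        precision=precision,
        recall=recall,
        informative_mean_weight=float(w[informative].mean()) if informative.size else 0.0,
        noise_mean_weight=float(w[noise_mask].mean()) if noise_mask.any() else 0.0,
    )
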