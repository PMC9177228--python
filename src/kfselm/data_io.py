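"""Dataset handling for connectivity-based two-class classification.

Per-subject functional-connectivity matrices (symmetric R×R correlation
matrices, entries in [-1, 1]) are vectorized into feature rows by taking the
upper triangle in row-major order, so an R-region parcellation yields
R(R-1)/2 edge features.  Feature index ``k`` (1-based) maps bijectively to
the region pair ``(i, j)`` with ``i < j`` via

    k = (i - 1)·R - i(i + 1)/2 + j

Class labels are one-hot encoded with lexicographic column order, and
stratified splits keep the two classes balanced 1:1 within every part
(train, validation, test), with the test part freezable across re-splits.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ManifestRecord",
    "SubjectManifest",
    "FeatureDataset",
    "DataSplit",
    "n_edge_features",
    "region_count_from_features",
    "vectorize_upper_triangle",
    "matrix_from_vector",
    "pair_to_edge_index",
    "edge_index_to_pair",
    "edge_feature_names",
    "one_hot_encode",
    "decode_one_hot",
    "stratified_split",
    "scale_ratios",
    "read_connectivity_matrix",
    "load_connectivity_dataset",
    "load_feature_table",
    "write_feature_weights",
    "read_feature_weights",
    "write_edge_file",
    "write_node_file",
]


# ---------------------------------------------------------------------------
# manifests and datasets


@dataclass(frozen=True)
class ManifestRecord:
    subject_id: str
    class_label: str
    source_path: str = ""


@dataclass
class SubjectManifest:
    """Subject roster: id, class label and (optionally) a path to the
    subject's connectivity matrix on disk."""

    records: list[ManifestRecord]

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({s for s in ids if ids.count(s) > 1})
            raise ValueError(f"duplicate subject ids in manifest: {dupes}")

    @property
    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.records]

    @property
    def class_labels(self) -> list[str]:
        return [r.class_label for r in self.records]

    @classmethod
    def read_csv(cls, path: str | Path) -> "SubjectManifest":
        df = pd.read_csv(path, dtype=str).fillna("")
        required = {"subject_id", "class"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"manifest {path} must have columns subject_id,class[,path]"
            )
        paths = df["path"] if "path" in df.columns else [""] * len(df)
        records = [
            ManifestRecord(str(s), str(c), str(p))
            for s, c, p in zip(df["subject_id"], df["class"], paths)
        ]
        return cls(records)

    def write_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "class": self.class_labels,
                "path": [r.source_path for r in self.records],
            }
        )
        df.to_csv(path, index=False)


@dataclass
class FeatureDataset:
    """Subjects × features matrix with two-class labels and one-hot targets.

    ``X`` is N×n (one row per subject), ``T`` is the N×m one-hot target
    matrix whose column order follows ``label_order`` (lexicographic).
    """

    subject_ids: list[str]
    X: np.ndarray
    class_labels: list[str]
    T: np.ndarray
    feature_names: list[str]
    label_order: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        N = len(self.subject_ids)
        if self.X.shape[0] != N or self.T.shape[0] != N or len(self.class_labels) != N:
            raise ValueError("subject_ids, X rows, class_labels, T rows must agree")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must equal X columns")
        if self.T.shape[1] != len(self.label_order):
            raise ValueError("label_order length must equal T columns")
        rows = self.T.sum(axis=1)
        if not (np.all(rows == 1.0) and np.all((self.T == 0) | (self.T == 1))):
            raise ValueError("each row of T must be one-hot")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return self.T.shape[1]

    @classmethod
    def from_features(
        cls,
        X: np.ndarray,
        class_labels: Sequence[str],
        subject_ids: Sequence[str] | None = None,
        feature_names: Sequence[str] | None = None,
    ) -> "FeatureDataset":
        X = np.asarray(X, dtype=float)
        if subject_ids is None:
            subject_ids = [f"s{i:04d}" for i in range(X.shape[0])]
        if feature_names is None:
            feature_names = [f"f{j + 1}" for j in range(X.shape[1])]
        T, order = one_hot_encode(class_labels)
        return cls(
            list(subject_ids), X, list(class_labels), T,
            list(feature_names), order,
        )

    def subset(self, rows: Sequence[int]) -> "FeatureDataset":
        rows = np.asarray(rows, dtype=int)
        return FeatureDataset(
            [self.subject_ids[i] for i in rows],
            self.X[rows],
            [self.class_labels[i] for i in rows],
            self.T[rows],
            list(self.feature_names),
            list(self.label_order),
        )

    def restrict_features(self, cols: Sequence[int]) -> "FeatureDataset":
        cols = np.asarray(cols, dtype=int)
        return FeatureDataset(
            list(self.subject_ids),
            self.X[:, cols],
            list(self.class_labels),
            self.T.copy(),
            [self.feature_names[j] for j in cols],
            list(self.label_order),
        )


@dataclass(frozen=True)
class DataSplit:
    """Disjoint train/validation/test row indices, each class-balanced 1:1."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    ratios: tuple[int, int, int]
    seed: int


# ---------------------------------------------------------------------------
# edge <-> feature-index bijection


def n_edge_features(region_count: int) -> int:
    """Number of upper-triangle edge features for an R-region parcellation."""
    return region_count * (region_count - 1) // 2


def region_count_from_features(n_features: int) -> int:
    """Invert n = R(R-1)/2; error if n is not a triangular number."""
    R = int(round((1.0 + np.sqrt(1.0 + 8.0 * n_features)) / 2.0))
    if n_edge_features(R) != n_features:
        raise ValueError(f"{n_features} is not R(R-1)/2 for any integer R")
    return R


def vectorize_upper_triangle(matrix: np.ndarray) -> np.ndarray:
    """Row-major upper-triangle (excluding diagonal) of a square symmetric
    matrix, as a vector of length R(R-1)/2."""
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {M.shape}")
    iu = np.triu_indices(M.shape[0], k=1)
    return M[iu].copy()


def matrix_from_vector(
    vec: np.ndarray, region_count: int, diagonal: float = 0.0
) -> np.ndarray:
    """Rebuild the symmetric R×R matrix from its upper-triangle vector."""
    vec = np.asarray(vec, dtype=float)
    R = region_count
    if vec.shape != (n_edge_features(R),):
        raise ValueError("vector length must be R(R-1)/2")
    M = np.full((R, R), diagonal, dtype=float)
    iu = np.triu_indices(R, k=1)
    M[iu] = vec
    M[(iu[1], iu[0])] = vec
    return M


def pair_to_edge_index(i: int, j: int, region_count: int) -> int:
    """1-based feature index of region pair (i, j), i < j, 1-based regions."""
    R = region_count
    if not (1 <= i < j <= R):
        raise ValueError(f"require 1 <= i < j <= {R}, got ({i}, {j})")
    return (i - 1) * R - i * (i + 1) // 2 + j


def edge_index_to_pair(k: int, region_count: int) -> tuple[int, int]:
    """Region pair (i, j) of 1-based feature index k; inverse of
    :func:`pair_to_edge_index`."""
    R = region_count
    n = n_edge_features(R)
    if not (1 <= k <= n):
        raise ValueError(f"feature index {k} outside 1..{n} for R={R}")
    # cumulative pair counts after each row i: sum_{t<=i} (R - t)
    row_counts = np.arange(R - 1, 0, -1)
    cum = np.cumsum(row_counts)
    i = int(np.searchsorted(cum, k, side="left")) + 1
    prev = 0 if i == 1 else int(cum[i - 2])
    j = k - prev + i
    return i, j


def edge_feature_names(region_count: int) -> list[str]:
    """Names "i-j" for all edge features in vectorization order."""
    iu = np.triu_indices(region_count, k=1)
    return [f"{i + 1}-{j + 1}" for i, j in zip(*iu)]


# ---------------------------------------------------------------------------
# labels and splits


def one_hot_encode(class_labels: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """One-hot target matrix with lexicographic label → column order."""
    labels = list(class_labels)
    if not labels:
        raise ValueError("need at least one label")
    order = sorted(set(labels))
    col = {c: k for k, c in enumerate(order)}
    T = np.zeros((len(labels), len(order)), dtype=float)
    for r, lab in enumerate(labels):
        T[r, col[lab]] = 1.0
    return T, order


def decode_one_hot(T: np.ndarray, label_order: Sequence[str]) -> list[str]:
    T = np.asarray(T)
    return [label_order[k] for k in np.argmax(T, axis=1)]


def scale_ratios(
    ratios: Sequence[int], n_subjects: int
) -> tuple[int, int, int]:
    """Scale split ratios proportionally so parts fit ``n_subjects`` with
    every non-empty part of even size (so a 1:1 class balance is exact)."""
    ratios = tuple(int(r) for r in ratios)
    total = sum(ratios)
    if total <= 0:
        raise ValueError("ratios must sum to a positive number")
    sizes = [2 * int(r * n_subjects / total / 2) for r in ratios]
    for k, r in enumerate(ratios):
        if r > 0 and sizes[k] == 0:
            sizes[k] = 2
    if sum(sizes) > n_subjects:
        raise ValueError("cannot fit balanced parts into the subject pool")
    return tuple(sizes)  # type: ignore[return-value]


def _part_class_sizes(size: int, n_classes: int = 2) -> list[int]:
    # even split; when odd, the lexicographically first class takes the extra
    base = size // n_classes
    out = [base] * n_classes
    for k in range(size - base * n_classes):
        out[k] += 1
    return out


def stratified_split(
    dataset: "FeatureDataset",
    ratios: Sequence[int],
    seed: int,
    frozen_test_idx: Sequence[int] | None = None,
) -> DataSplit:
    """Class-balanced train/validation/test split.

    ``ratios`` are absolute part sizes (e.g. 90:90:20 on N=200).  With
    ``frozen_test_idx`` the test part is fixed and only train/validation are
    re-drawn from the remaining subjects — the screening protocol, where the
    held-out test set never changes while train/validation are re-divided
    before each classifier.
    """
    ratios = tuple(int(r) for r in ratios)
    if len(ratios) != 3 or any(r < 0 for r in ratios):
        raise ValueError("ratios must be three non-negative integers")
    labels = dataset.class_labels
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError(f"stratified_split needs exactly two classes, got {classes}")

    frozen = None
    if frozen_test_idx is not None:
        frozen = np.asarray(sorted(frozen_test_idx), dtype=int)

    pools: dict[str, list[int]] = {c: [] for c in classes}
    frozen_set = set(frozen.tolist()) if frozen is not None else set()
    for idx, lab in enumerate(labels):
        if idx not in frozen_set:
            pools[lab].append(idx)

    rng = np.random.default_rng(seed)
    for c in classes:
        pools[c] = list(np.asarray(pools[c])[rng.permutation(len(pools[c]))])

    part_sizes = list(ratios)
    if frozen is not None:
        part_sizes[2] = 0  # test comes from the frozen set

    need = {c: 0 for c in classes}
    takes = []
    for size in part_sizes:
        per = _part_class_sizes(size)
        takes.append(per)
        for c, t in zip(classes, per):
            need[c] += t
    for c in classes:
        if need[c] > len(pools[c]):
            raise ValueError(
                f"infeasible balanced split: class {c!r} has {len(pools[c])} "
                f"subjects available but {need[c]} required"
            )

    parts: list[np.ndarray] = []
    cursor = {c: 0 for c in classes}
    for per in takes:
        chosen: list[int] = []
        for c, t in zip(classes, per):
            chosen.extend(pools[c][cursor[c] : cursor[c] + t])
            cursor[c] += t
        parts.append(np.array(sorted(chosen), dtype=int))
    if frozen is not None:
        parts[2] = frozen
    return DataSplit(parts[0], parts[1], parts[2], ratios, int(seed))


# ---------------------------------------------------------------------------
# file formats


def read_connectivity_matrix(
    path: str | Path,
    region_count: int | None = None,
    symmetry_tol: float = 1e-6,
) -> np.ndarray:
    """Read a dense R×R connectivity matrix (whitespace- or comma-delimited
    text).  Checks squareness, symmetry (within ``symmetry_tol``, then
    symmetrized as (M+Mᵀ)/2) and the correlation range [-1, 1]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"connectivity matrix not found: {path}")
    text = path.read_text()
    delim = "," if "," in text.splitlines()[0] else None
    M = np.loadtxt(path, delimiter=delim, ndmin=2)
    if M.shape[0] != M.shape[1]:
        raise ValueError(f"{path}: matrix is {M.shape}, expected square")
    if region_count is not None and M.shape[0] != region_count:
        raise ValueError(
            f"{path}: matrix is {M.shape[0]}×{M.shape[0]}, "
            f"expected {region_count}×{region_count}"
        )
    if np.max(np.abs(M - M.T)) > symmetry_tol:
        raise ValueError(f"{path}: matrix not symmetric within {symmetry_tol}")
    M = (M + M.T) / 2.0
    if np.max(np.abs(M)) > 1.0 + 1e-9:
        bad = float(M.flat[int(np.argmax(np.abs(M)))])
        raise ValueError(
            f"{path}: entry {bad} outside correlation range [-1, 1]"
        )
    return np.clip(M, -1.0, 1.0)


def load_connectivity_dataset(
    manifest: SubjectManifest, region_count: int
) -> FeatureDataset:
    """Vectorize each subject's R×R matrix into one feature row.

    Errors (missing file, wrong dimension, asymmetry, out-of-range entries)
    name the offending subject.
    """
    rows = []
    for rec in manifest.records:
        try:
            M = read_connectivity_matrix(rec.source_path, region_count)
        except (ValueError, FileNotFoundError, OSError) as exc:
            raise type(exc)(f"subject {rec.subject_id!r}: {exc}") from exc
        rows.append(vectorize_upper_triangle(M))
    X = np.vstack(rows) if rows else np.zeros((0, n_edge_features(region_count)))
    return FeatureDataset.from_features(
        X,
        manifest.class_labels,
        subject_ids=manifest.subject_ids,
        feature_names=edge_feature_names(region_count),
    )


def load_feature_table(path: str | Path) -> FeatureDataset:
    """Alternative input mode: a pre-vectorized one-row-per-subject table
    with header ``subject_id,class,<feature columns...>`` (CSV or TSV)."""
    df = pd.read_csv(path, sep=None, engine="python")
    if "subject_id" not in df.columns or "class" not in df.columns:
        raise ValueError(f"{path}: need subject_id and class columns")
    feat_cols = [c for c in df.columns if c not in ("subject_id", "class")]
    X = df[feat_cols].to_numpy(dtype=float)
    return FeatureDataset.from_features(
        X,
        [str(c) for c in df["class"]],
        subject_ids=[str(s) for s in df["subject_id"]],
        feature_names=[str(c) for c in feat_cols],
    )


def _weights_array(weights) -> np.ndarray:
    w = getattr(weights, "weights", weights)
    return np.asarray(w)


def write_feature_weights(
    weights, region_count: int, path: str | Path
) -> None:
    """Persist accumulated per-edge feature weights as a TSV with columns
    feature_index, region_i, region_j, weight (1-based indices)."""
    w = _weights_array(weights)
    n = n_edge_features(region_count)
    if w.shape != (n,):
        raise ValueError(
            f"weights length {w.shape} does not match R(R-1)/2 = {n}"
        )
    iu = np.triu_indices(region_count, k=1)
    df = pd.DataFrame(
        {
            "feature_index": np.arange(1, n + 1),
            "region_i": iu[0] + 1,
            "region_j": iu[1] + 1,
            "weight": w.astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_feature_weights(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a feature-weight TSV back into (weights vector, region_count)."""
    df = pd.read_csv(path, sep="\t")
    n = len(df)
    R = region_count_from_features(n)
    w = np.zeros(n, dtype=int)
    w[df["feature_index"].to_numpy(dtype=int) - 1] = df["weight"].to_numpy(dtype=int)
    return w, R


def write_edge_file(
    weights, region_count: int, path: str | Path, min_weight: int = 0
) -> None:
    """BrainNet-style .edge export: R×R matrix of selected-edge weights
    (entries below ``min_weight`` zeroed), tab-separated."""
    w = _weights_array(weights).astype(float)
    kept = np.where(w >= min_weight, w, 0.0)
    M = matrix_from_vector(kept, region_count, diagonal=0.0)
    np.savetxt(path, M, delimiter="\t", fmt="%g")


def write_node_file(
    region_weights: dict[int, float],
    region_count: int,
    path: str | Path,
    atlas_csv: str | Path | None = None,
) -> None:
    """BrainNet-style .node export: one row per region, ``x y z color size
    label``.  Coordinates/labels come from an optional atlas metadata CSV
    (columns region_index,x,y,z,label); zeros / "R<i>" otherwise."""
    coords = {r: (0.0, 0.0, 0.0) for r in range(1, region_count + 1)}
    names = {r: f"R{r}" for r in range(1, region_count + 1)}
    if atlas_csv is not None:
        meta = pd.read_csv(atlas_csv)
        for _, row in meta.iterrows():
            r = int(row["region_index"])
            coords[r] = (float(row["x"]), float(row["y"]), float(row["z"]))
            if "label" in meta.columns:
                names[r] = str(row["label"])
    lines = []
    for r in range(1, region_count + 1):
        x, y, z = coords[r]
        size = float(region_weights.get(r, 0.0))
        color = 1.0 if size > 0 else 0.0
        lines.append(f"{x:g}\t{y:g}\t{z:g}\t{color:g}\t{size:g}\t{names[r]}")
    Path(path).write_text("\n".join(lines) + "\n")
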