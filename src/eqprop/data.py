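"""Dataset ingestion, encoding and a synthetic task generator.

All features are rescaled to [0,1] (the clamped inputs feed a hard-sigmoid
network whose states live there), classification labels are one-hot
encoded, and regression targets are min-max scaled to [0,1] so a single
bounded output neuron can represent them.  Rescaling constants always come
from the training split only.

Three sources are supported: CSV files (features + a label column), the
big-endian IDX image/label dialect, and scikit-learn's bundled toy datasets
(diabetes, wine).  :func:`make_synthetic` generates small separable
Gaussian-cluster classification tasks so every experiment runs without any
download.
"""
from __future__ import annotations

import json
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "Dataset",
    "load_csv",
    "from_arrays",
    "read_idx",
    "make_synthetic",
    "load_sklearn_toy",
]


@dataclass
class Dataset:
    """Train/test split of a normalized supervised task.

    Features are (examples x p) in [0,1]; targets are (examples x r) —
    one-hot rows for classification, scalars in [0,1] for regression.
    """

    X_train: np.ndarray
    Y_train: np.ndarray
    X_test: np.ndarray
    Y_test: np.ndarray
    task_kind: str  # "classification" | "regression"
    manifest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.task_kind not in ("classification", "regression"):
            raise ValueError(f"unknown task kind {self.task_kind!r}")
        for name in ("X_train", "Y_train", "X_test", "Y_test"):
            setattr(self, name, np.atleast_2d(np.asarray(getattr(self, name), float)))
        if self.X_train.shape[1] != self.X_test.shape[1]:
            raise ValueError("train/test feature widths differ")

    @property
    def n_features(self) -> int:
        return self.X_train.shape[1]

    @property
    def n_outputs(self) -> int:
        return self.Y_train.shape[1]

    @property
    def n_train(self) -> int:
        return self.X_train.shape[0]

    @property
    def n_test(self) -> int:
        return self.X_test.shape[0]

    def save_manifest(self, path) -> None:
        Path(path).write_text(json.dumps(self.manifest, indent=2, default=float))


def _minmax_scale(
    train: np.ndarray, test: np.ndarray
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Min-max rescale columns to [0,1] using train statistics only.

    Constant columns degenerate (zero range); they map to 0 with a warning.
    """
    lo = train.min(axis=0)
    hi = train.max(axis=0)
    span = hi - lo
    const = span == 0
    if np.any(const):
        warnings.warn(
            f"{int(const.sum())} constant feature(s) mapped to 0", stacklevel=3
        )
        span = np.where(const, 1.0, span)
    scale = lambda a: np.clip(np.where(const, 0.0, (a - lo) / span), 0.0, 1.0)
    stats = {"min": lo.tolist(), "max": hi.tolist()}
    return scale(train), scale(test), stats


def _one_hot(labels: np.ndarray, classes: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(classes, labels)
    if np.any(classes[idx] != labels):
        raise ValueError("label outside the training label set")
    out = np.zeros((len(labels), len(classes)))
    out[np.arange(len(labels)), idx] = 1.0
    return out


def from_arrays(
    features: np.ndarray,
    labels: np.ndarray,
    task_kind: str,
    test_fraction: float = 0.25,
    seed: int = 0,
) -> Dataset:
    """Build a normalized, deterministically split dataset from raw arrays.

    The split is a seeded permutation; the last ``test_fraction`` of it is
    the test set.  Classification labels may be arbitrary sortable values;
    classes are the sorted unique labels of the *whole* array (so a class
    missing from the split cannot silently disappear).
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    labels = np.asarray(labels)
    if features.shape[0] != labels.shape[0]:
        raise ValueError("features and labels disagree on the number of examples")
    if not np.all(np.isfinite(features)):
        raise ValueError("non-numeric or non-finite feature values")
    n = features.shape[0]
    n_test = int(round(n * test_fraction))
    perm = np.random.default_rng(seed).permutation(n)
    train_idx, test_idx = perm[: n - n_test], perm[n - n_test :]

    Xtr, Xte, stats = _minmax_scale(features[train_idx], features[test_idx])
    manifest = {"split_seed": seed, "test_fraction": test_fraction, "features": stats}
    if task_kind == "classification":
        classes = np.unique(labels)
        Ytr = _one_hot(labels[train_idx], classes)
        Yte = _one_hot(labels[test_idx], classes)
        manifest["classes"] = classes.tolist()
    else:
        t = np.asarray(labels, dtype=float)
        lo, hi = t[train_idx].min(), t[train_idx].max()
        span = (hi - lo) or 1.0
        Ytr = np.clip((t[train_idx] - lo) / span, 0, 1)[:, None]
        Yte = np.clip((t[test_idx] - lo) / span, 0, 1)[:, None]
        manifest["target"] = {"min": float(lo), "max": float(hi)}
    return Dataset(Xtr, Ytr, Xte, Yte, task_kind, manifest)


def load_csv(
    path,
    label_column: str,
    task_kind: str,
    test_fraction: float = 0.25,
    seed: int = 0,
) -> Dataset:
    """Load a CSV of numeric features plus one label column."""
    df = pd.read_csv(path)
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found")
    features = df.drop(columns=[label_column])
    try:
        X = features.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric feature values: {exc}") from exc
    labels = df[label_column].to_numpy()
    ds = from_arrays(X, labels, task_kind, test_fraction, seed)
    ds.manifest["source"] = str(path)
    ds.manifest["feature_names"] = list(features.columns)
    return ds


_IDX_DTYPES = {0x08: np.uint8, 0x09: np.int8, 0x0B: ">i2", 0x0C: ">i4",
               0x0D: ">f4", 0x0E: ">f8"}


def read_idx(path) -> np.ndarray:
    """Read a big-endian IDX array (the MNIST file dialect).

    Image arrays (ndim >= 2, unsigned bytes) are returned scaled to [0,1]
    by division by 255; 1-D unsigned-byte vectors are label streams and are
    returned as integers.
    """
    raw = Path(path).read_bytes()
    if len(raw) < 4:
        raise ValueError("truncated IDX header")
    zero1, zero2, dtype_code, ndim = struct.unpack(">BBBB", raw[:4])
    if zero1 != 0 or zero2 != 0 or dtype_code not in _IDX_DTYPES:
        raise ValueError(f"bad IDX magic number {raw[:4]!r}")
    header_end = 4 + 4 * ndim
    if len(raw) < header_end:
        raise ValueError("truncated IDX dimension header")
    shape = struct.unpack(f">{ndim}I", raw[4:header_end])
    data = np.frombuffer(raw, dtype=_IDX_DTYPES[dtype_code], offset=header_end)
    expected = int(np.prod(shape))
    if data.size != expected:
        raise ValueError(
            f"truncated IDX payload: header promises {expected} items, got {data.size}"
        )
    arr = data.reshape(shape)
    if dtype_code == 0x08 and ndim >= 2:
        return arr.astype(float) / 255.0
    if ndim == 1:
        return arr.astype(np.int64)
    return arr.astype(float)


def make_synthetic(
    classes: int,
    dim: int,
    n_per_class: int,
    separation: float = 1.0,
    noise_sd: float = 0.05,
    seed: int = 0,
    test_fraction: float = 0.25,
) -> Dataset:
    """Gaussian class clusters at distinct corners of the unit hypercube.

    Class c's mean sits at ``0.5 + separation * (corner_c - 0.5)`` for a
    distinct binary corner of [0,1]^dim; examples add isotropic Gaussian
    noise with standard deviation ``noise_sd`` and are clipped to [0,1].
    Classes are balanced, generation is a pure function of the arguments,
    and the split is stratified so each class appears in both halves.
    """
    if classes < 2:
        raise ValueError("need at least 2 classes")
    if dim < 1:
        raise ValueError("need at least 1 feature dimension")
    if n_per_class < 1:
        raise ValueError("need at least one example per class")
    if classes > 2**dim:
        raise ValueError(f"cannot place {classes} distinct corners in {dim} dims")
    rng = np.random.default_rng(seed)

    corners: list[tuple] = []
    seen = set()
    while len(corners) < classes:
        c = tuple(rng.integers(0, 2, size=dim).tolist())
        if c not in seen:
            seen.add(c)
            corners.append(c)
    means = 0.5 + separation * (np.array(corners, dtype=float) - 0.5)

    X_parts, y_parts = [], []
    for c in range(classes):
        pts = means[c] + rng.normal(0.0, noise_sd, size=(n_per_class, dim))
        X_parts.append(np.clip(pts, 0.0, 1.0))
        y_parts.append(np.full(n_per_class, c))

    # stratified split: identical per-class proportions in train and test
    n_test_pc = int(round(n_per_class * test_fraction))
    Xtr_l, Ytr_l, Xte_l, Yte_l = [], [], [], []
    for c in range(classes):
        order = rng.permutation(n_per_class)
        Xc = X_parts[c][order]
        Xte_l.append(Xc[:n_test_pc])
        Xtr_l.append(Xc[n_test_pc:])
        Yte_l.append(np.full(n_test_pc, c))
        Ytr_l.append(np.full(n_per_class - n_test_pc, c))
    Xtr = np.concatenate(Xtr_l)
    Xte = np.concatenate(Xte_l)
    ytr = np.concatenate(Ytr_l)
    yte = np.concatenate(Yte_l)
    # interleave classes (c0, c1, ..., c0, c1, ...) so every batch sees a mix
    n_tr_pc = n_per_class - n_test_pc
    tr_order = np.arange(classes * n_tr_pc).reshape(classes, n_tr_pc).T.ravel()
    eye = np.eye(classes)
    ds = Dataset(
        Xtr[tr_order],
        eye[ytr[tr_order].astype(int)],
        Xte,
        eye[yte.astype(int)],
        "classification",
        manifest={
            "generator": "make_synthetic",
            "classes": classes,
            "dim": dim,
            "n_per_class": n_per_class,
            "separation": separation,
            "noise_sd": noise_sd,
            "seed": seed,
            "test_fraction": test_fraction,
        },
    )
    return ds


def load_sklearn_toy(name: str, test_fraction: float = 0.25, seed: int = 0) -> Dataset:
    """The bundled scikit-learn toy tasks: "wine" (3-class classification,
    13 features) or "diabetes" (regression, 10 features, target min-max
    scaled to [0,1])."""
    from sklearn import datasets as skd

    if name == "wine":
        bunch = skd.load_wine()
        return from_arrays(bunch.data, bunch.target, "classification",
                           test_fraction, seed)
    if name == "diabetes":
        bunch = skd.load_diabetes()
        return from_arrays(bunch.data, bunch.target, "regression",
                           test_fraction, seed)
    raise ValueError(f"unknown toy dataset {name!r} (expected 'wine' or 'diabetes')")
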