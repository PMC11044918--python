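"""Tabular containers, feature filtering, scaling, batching and file I/O.

Feature matrices are dense (the target dimensionalities are a few thousand
features at most) and sample alignment between modalities is always by
sample ID, never by row order, because modality-B rows may be missing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrix", "ScalerState", "select_top_variance_features",
    "fit_apply_scaler", "make_batches", "read_feature_matrix",
    "write_feature_matrix", "read_labels", "write_labels",
]


@dataclass
class FeatureMatrix:
    """Samples x features matrix with unique feature names and sample IDs."""

    values: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.feature_names = [str(f) for f in self.feature_names]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        n, d = self.values.shape
        if d != len(self.feature_names):
            raise ValueError("feature name count does not match matrix width")
        if n != len(self.sample_ids):
            raise ValueError("sample ID count does not match matrix height")
        if len(set(self.feature_names)) != d:
            raise ValueError("feature names must be unique")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample IDs must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains NaN or Inf")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, ids: Sequence[str]) -> "FeatureMatrix":
        """Rows for the given IDs, in the given order."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise KeyError(f"sample IDs not present: {missing[:5]}")
        rows = [index[s] for s in ids]
        return FeatureMatrix(self.values[rows], self.feature_names, list(ids))


@dataclass
class ScalerState:
    """Per-feature min/max learned from the training split only.

    Degenerate features (max == min) map to constant 0.
    """

    minimum: np.ndarray
    maximum: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.minimum = np.asarray(self.minimum, dtype=np.float64)
        self.maximum = np.asarray(self.maximum, dtype=np.float64)
        if np.any(self.maximum < self.minimum):
            raise ValueError("max < min in scaler state")

    def transform(self, values: np.ndarray) -> np.ndarray:
        span = self.maximum - self.minimum
        safe = np.where(span > 0, span, 1.0)
        out = (values - self.minimum) / safe
        return np.where(span > 0, out, 0.0)

    def inverse_transform(self, values: np.ndarray) -> np.ndarray:
        span = self.maximum - self.minimum
        return values * span + self.minimum

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "minimum": self.minimum.tolist(),
            "maximum": self.maximum.tolist(),
            "feature_names": self.feature_names,
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScalerState":
        obj = json.loads(Path(path).read_text())
        return cls(np.array(obj["minimum"]), np.array(obj["maximum"]),
                   obj.get("feature_names", []))


def select_top_variance_features(X: FeatureMatrix, k: int) -> FeatureMatrix:
    """Keep the k features with the largest sample variance.

    Original column order is preserved among the survivors; variance ties are
    broken by first occurrence.
    """
    if not 1 <= k <= X.n_features:
        raise ValueError(f"k must be in [1, {X.n_features}], got {k}")
    var = X.values.var(axis=0, ddof=1) if X.n_samples > 1 else np.zeros(X.n_features)
    # stable sort on negated variance keeps first occurrence on ties
    order = np.argsort(-var, kind="stable")[:k]
    keep = np.sort(order)
    return FeatureMatrix(X.values[:, keep],
                         [X.feature_names[i] for i in keep], X.sample_ids)


def fit_apply_scaler(train: FeatureMatrix, *others: FeatureMatrix
                     ) -> tuple[list[FeatureMatrix], ScalerState]:
    """Min-max scale to [0,1] using training statistics only.

    Returns the scaled train matrix followed by the scaled `others` (val /
    test splits, applied unchanged — values outside the training range are
    not clipped), plus the fitted state.
    """
    if train.n_samples == 0:
        raise ValueError("training matrix is empty")
    state = ScalerState(train.values.min(axis=0), train.values.max(axis=0),
                        list(train.feature_names))
    scaled = [FeatureMatrix(state.transform(m.values), m.feature_names, m.sample_ids)
              for m in (train, *others)]
    return scaled, state


def make_batches(n: int, bs: int, shuffle: bool = False,
                 seed: int | None = None) -> Iterator[np.ndarray]:
    """Yield index blocks covering 0..n-1 exactly once; last may be short."""
    if n <= 0:
        raise ValueError("empty dataset")
    if bs < 1:
        raise ValueError("batch size must be >= 1")
    idx = np.arange(n)
    if shuffle:
        idx = np.random.default_rng(seed).permutation(n)
    for start in range(0, n, bs):
        yield idx[start:start + bs]


# ---------------------------------------------------------------------------
# File I/O — TSV with a leading sample-ID column; commas accepted on read.

def write_feature_matrix(X: FeatureMatrix, path: str | Path) -> None:
    df = pd.DataFrame(X.values, index=X.sample_ids, columns=X.feature_names)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.17g")

def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    return FeatureMatrix(df.to_numpy(dtype=np.float64),
                         list(df.columns), [str(i) for i in df.index])


_LABEL_COLS = ["id", "time_years", "event", "stratum", "split"]

def write_labels(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in _LABEL_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"label table missing columns {missing}")
    df[_LABEL_COLS].to_csv(path, sep="\t", index=False, float_format="%.17g")

def read_labels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python",
                     dtype={"id": str, "stratum": str, "split": str})
    missing = [c for c in _LABEL_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"label table missing columns {missing}")
    if (df["time_years"] <= 0).any():
        raise ValueError("survival times must be positive")
    return df
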