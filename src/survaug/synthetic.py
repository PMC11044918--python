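"""Synthetic paired two-modality omics generator with survival outcomes.

The generator emulates the structure of a paired bulk-omics extract: two
tabular modalities (A, e.g. DNA methylation; B, e.g. gene expression) driven
by a small number of shared latent factors, modality-specific Gaussian
noise, right-censored survival times whose hazard depends on the latent
factors, a stratum label standing in for cancer type, and a configurable
fraction of modality-B rows removed from the training and validation splits
only — the test split is always complete.

Mechanics
---------
Latent factors ``z ~ N(0, I)`` (n x k).  Loadings ``W_A`` (k x d_A) and
``W_B`` (k x d_B) are drawn once per seed with standard deviation
``loading_scale``; features are ``X = z W + noise``.  Event times are
exponential with rate ``baseline_hazard * exp(z . hazard_coefs)``,
censoring times exponential with rate ``censor_rate``; the observed time is
the minimum and ``event = 1`` iff the event came first.  Modality-B
missingness is applied completely at random, per stratum with rounding,
within train+val.  Finally every feature is min-max scaled to [0, 1] using
training-split statistics (no clipping of val/test values).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data import (FeatureMatrix, ScalerState, read_feature_matrix,
                   read_labels, write_feature_matrix, write_labels)

__all__ = ["SyntheticConfig", "PairedOmicsDataset", "generate", "split"]


def _default_hazard_coefs(k: int) -> np.ndarray:
    base = np.array([0.8, -0.6, 0.4, -0.2])
    return np.resize(base, k)


@dataclass
class SyntheticConfig:
    n_samples: int
    d_A: int = 200
    d_B: int = 50
    k_latent: int = 4
    loading_scale: float = 1.0
    noise_sd_A: float = 0.1
    noise_sd_B: float = 0.1
    hazard_coefs: np.ndarray | None = None
    baseline_hazard: float = 0.06   # events per year
    censor_rate: float = 0.04       # censorings per year
    n_strata: int = 3
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_samples", "d_A", "d_B", "k_latent", "n_strata"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must be in [0, 1)")
        if self.noise_sd_A < 0 or self.noise_sd_B < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")
        if self.hazard_coefs is None:
            self.hazard_coefs = _default_hazard_coefs(self.k_latent)
        self.hazard_coefs = np.asarray(self.hazard_coefs, dtype=np.float64)
        if self.hazard_coefs.shape != (self.k_latent,):
            raise ValueError("hazard_coefs must have length k_latent")


@dataclass
class PairedOmicsDataset:
    """Matched A/B matrices with survival labels and a B-presence mask.

    ``X_A`` has one row per sample; ``X_B`` holds rows only for samples
    where modality B is present (``b_sample_ids`` gives their IDs, a subset
    of ``sample_ids``).
    """

    sample_ids: list[str]
    X_A: np.ndarray
    feature_names_A: list[str]
    X_B: np.ndarray
    feature_names_B: list[str]
    b_sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    stratum: list[str]
    split: list[str]
    scaler_A: ScalerState | None = None
    scaler_B: ScalerState | None = None

    def __post_init__(self):
        n = len(self.sample_ids)
        if self.X_A.shape[0] != n or len(self.time) != n or len(self.event) != n:
            raise ValueError("per-sample arrays must match sample_ids length")
        if self.X_B.shape[0] != len(self.b_sample_ids):
            raise ValueError("X_B rows must match b_sample_ids")
        unknown = set(self.b_sample_ids) - set(self.sample_ids)
        if unknown:
            raise ValueError(f"B rows without a matching A sample: {sorted(unknown)[:5]}")
        if np.any(np.asarray(self.time) <= 0):
            raise ValueError("survival times must be positive")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def b_present(self) -> np.ndarray:
        present = set(self.b_sample_ids)
        return np.array([s in present for s in self.sample_ids])

    # -- split helpers -----------------------------------------------------
    def _idx(self, which: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.split) if s == which])

    def a_rows(self, which: str) -> tuple[list[str], np.ndarray]:
        idx = self._idx(which)
        return [self.sample_ids[i] for i in idx], self.X_A[idx]

    def b_rows(self, which: str) -> tuple[list[str], np.ndarray]:
        """Present-B rows belonging to the given split."""
        split_of = dict(zip(self.sample_ids, self.split))
        rows = [i for i, s in enumerate(self.b_sample_ids) if split_of[s] == which]
        return [self.b_sample_ids[i] for i in rows], self.X_B[rows]

    def paired_rows(self, which: str) -> tuple[list[str], np.ndarray, np.ndarray]:
        """IDs with both modalities in a split, plus their A and B rows."""
        ids, xb = self.b_rows(which)
        a_index = {s: i for i, s in enumerate(self.sample_ids)}
        xa = self.X_A[[a_index[s] for s in ids]]
        return ids, xa, xb

    def labels_for(self, ids: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in ids]
        return self.time[rows], self.event[rows]

    def labels_df(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": self.sample_ids, "time_years": self.time, "event": self.event,
            "stratum": self.stratum, "split": self.split,
        })

    # -- I/O ---------------------------------------------------------------
    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        write_feature_matrix(FeatureMatrix(self.X_A, self.feature_names_A,
                                           self.sample_ids), path / "modality_A.tsv")
        write_feature_matrix(FeatureMatrix(self.X_B, self.feature_names_B,
                                           self.b_sample_ids), path / "modality_B.tsv")
        write_labels(self.labels_df(), path / "labels.tsv")

    @classmethod
    def from_dir(cls, path: str | Path) -> "PairedOmicsDataset":
        path = Path(path)
        A = read_feature_matrix(path / "modality_A.tsv")
        B = read_feature_matrix(path / "modality_B.tsv")
        lab = read_labels(path / "labels.tsv").set_index("id").loc[A.sample_ids]
        return cls(A.sample_ids, A.values, A.feature_names, B.values,
                   B.feature_names, B.sample_ids,
                   lab["time_years"].to_numpy(float), lab["event"].to_numpy(int),
                   list(lab["stratum"]), list(lab["split"]))


def split(dataset: PairedOmicsDataset, test_frac: float, val_frac: float,
          seed: int = 0) -> PairedOmicsDataset:
    """Assign train/val/test labels by stratified shuffle within stratum.

    ``test_frac`` applies to each stratum; ``val_frac`` applies to the
    non-test remainder (a 0.1/0.1 split of n=1000 leaves ~810 training
    samples).
    """
    if not (0 < test_frac < 1 and 0 < val_frac < 1 and test_frac + val_frac < 1):
        raise ValueError("fractions must lie in (0,1) and sum below 1")
    rng = np.random.default_rng(seed)
    assignment = np.array(["train"] * dataset.n, dtype=object)
    strata = np.asarray(dataset.stratum)
    for s in sorted(set(dataset.stratum)):
        idx = np.where(strata == s)[0]
        if len(idx) < 3:
            raise ValueError(f"stratum {s!r} has fewer than 3 samples")
        idx = rng.permutation(idx)
        n_test = int(round(test_frac * len(idx)))
        n_val = int(round(val_frac * (len(idx) - n_test)))
        assignment[idx[:n_test]] = "test"
        assignment[idx[n_test:n_test + n_val]] = "val"
    return replace(dataset, split=list(assignment))


def generate(config: SyntheticConfig, test_frac: float = 0.1,
             val_frac: float = 0.1) -> PairedOmicsDataset:
    """Draw a complete paired dataset, split it, reduce B, and scale.

    Modality-B rows are removed (completely at random, per stratum with
    rounding) only within train+val; scaling statistics come from the
    training split alone.
    """
    ss = np.random.SeedSequence(config.seed)
    r_load, r_latent, r_noise, r_surv, r_strat, r_split, r_miss = \
        [np.random.default_rng(c) for c in ss.spawn(7)]

    k, n = config.k_latent, config.n_samples
    W_A = r_load.normal(0.0, config.loading_scale, size=(k, config.d_A))
    W_B = r_load.normal(0.0, config.loading_scale, size=(k, config.d_B))
    z = r_latent.standard_normal((n, k))
    X_A = z @ W_A + r_noise.normal(0.0, config.noise_sd_A, size=(n, config.d_A))
    X_B = z @ W_B + r_noise.normal(0.0, config.noise_sd_B, size=(n, config.d_B))

    rate = config.baseline_hazard * np.exp(z @ config.hazard_coefs)
    t_event = r_surv.exponential(1.0 / rate)
    if config.censor_rate > 0:
        t_cens = r_surv.exponential(1.0 / config.censor_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    time = np.maximum(time, 1e-6)  # guard exact zeros from float underflow
    event = (t_event <= t_cens).astype(int)

    stratum = [f"S{r_strat.integers(1, config.n_strata + 1)}" for _ in range(n)]
    ids = [f"sample{i:05d}" for i in range(n)]
    fa = [f"A_f{j}" for j in range(config.d_A)]
    fb = [f"B_f{j}" for j in range(config.d_B)]

    ds = PairedOmicsDataset(ids, X_A, fa, X_B, fb, list(ids), time, event,
                            stratum, ["train"] * n)
    ds = split(ds, test_frac, val_frac, seed=int(r_split.integers(2 ** 31)))

    # remove B rows per stratum within train+val; test stays complete
    keep = np.ones(n, dtype=bool)
    strata_arr = np.asarray(stratum)
    split_arr = np.asarray(ds.split)
    if config.missing_fraction > 0:
        for s in sorted(set(stratum)):
            idx = np.where((strata_arr == s) & (split_arr != "test"))[0]
            n_drop = int(round(config.missing_fraction * len(idx)))
            drop = r_miss.choice(idx, size=n_drop, replace=False)
            keep[drop] = False
        keep[split_arr == "test"] = True
    b_ids = [ids[i] for i in range(n) if keep[i]]
    X_B_kept = X_B[keep]

    # min-max scale from train statistics
    tr_a = split_arr == "train"
    scaler_A = ScalerState(X_A[tr_a].min(axis=0), X_A[tr_a].max(axis=0), fa)
    b_split = np.asarray([dict(zip(ids, ds.split))[s] for s in b_ids])
    tr_b = b_split == "train"
    scaler_B = ScalerState(X_B_kept[tr_b].min(axis=0), X_B_kept[tr_b].max(axis=0), fb)

    return PairedOmicsDataset(
        ids, scaler_A.transform(X_A), fa, scaler_B.transform(X_B_kept), fb,
        b_ids, time, event, stratum, list(ds.split),
        scaler_A=scaler_A, scaler_B=scaler_B)
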