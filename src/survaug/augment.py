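"""Cross-modal imputation, oversampling augmentation, and the discrete-time
survival predictor.

The prediction task estimates a conditional survival probability for each of
J = 30 one-year intervals; the task loss is the discrete-time survival
negative log-likelihood.  Augmentation imputes missing modality-B samples
from their modality-A counterparts (labels carried over verbatim from the A
sample — continuous outcomes are never imputed) and, in the oversampling
variants, draws a fresh batch of A samples with replacement each epoch,
imputes them, keeps only imputations whose current task loss is strictly
below the threshold ``t``, and adds their loss weighted by ``gamma``.

Method variants
---------------
multisurv      no augmentation (reference predictor)
ov             oversample real B rows with replacement (``bs``, ``bsOV``, ``gamma``)
tdimpute       deterministic A->B translator; train on real + imputed union
tdimpute_ov    translator + oversampled, loss-filtered imputation
cmvae_adv      adversarially aligned cross-modal VAE; real + imputed union
cmvae_ov       cross-modal VAE + oversampled, loss-filtered imputation
cmvae_adv_ov   adversarial VAE + oversampling
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from ._autodiff import Tensor, constant, clip as tclip, log as tlog, tmean, tsum
from ._nn import MLP, Adam
from .data import make_batches
from .evaluation import c_td, time_to_interval
from .synthetic import PairedOmicsDataset
from .vae import TrainedVAE, VAESpec, _check_finite, _hidden_widths, recon_loss

__all__ = [
    "AugmentationConfig", "DiscreteSurvivalOutput", "ImputedBatch",
    "SurvivalPredictor", "TrainedTranslator", "METHODS",
    "impute_B_from_A", "survival_nll", "time_to_interval",
    "filter_by_task_loss", "train_predictor", "train_tdimpute",
]

METHODS = ("multisurv", "ov", "tdimpute", "tdimpute_ov",
           "cmvae_adv", "cmvae_ov", "cmvae_adv_ov")
_OVERSAMPLING = {"ov", "tdimpute_ov", "cmvae_ov", "cmvae_adv_ov"}
_THRESHOLDED = {"tdimpute_ov", "cmvae_ov", "cmvae_adv_ov"}
_STATIC_UNION = {"tdimpute", "cmvae_adv"}
_NEEDS_IMPUTER = {"tdimpute", "tdimpute_ov", "cmvae_adv", "cmvae_ov", "cmvae_adv_ov"}


@dataclass
class AugmentationConfig:
    method: str
    bs: int = 32
    bsOV: int = 32
    t: float = np.inf          # strict task-loss threshold; inf keeps all
    gamma: float = 1.0         # weight on the imputed-batch loss
    epochs: int = 400
    learning_rate: float = 1e-5
    n_intervals: int = 30
    predictor_hidden: tuple[int, ...] = (64, 32)
    ov_pool: str = "real"      # "real" or "imputed" pool for method=ov
    seed: int = 0

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; one of {METHODS}")
        if self.bs < 1 or self.bsOV < 1:
            raise ValueError("batch sizes must be >= 1")
        if self.t < 0:
            raise ValueError("loss threshold t must be >= 0")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.ov_pool not in ("real", "imputed"):
            raise ValueError("ov_pool must be 'real' or 'imputed'")


@dataclass
class DiscreteSurvivalOutput:
    """Per-subject conditional survival probabilities for J intervals."""

    cond_surv: np.ndarray  # n x J, values in (0, 1)

    def __post_init__(self):
        self.cond_surv = np.atleast_2d(np.asarray(self.cond_surv, float))
        if np.any(self.cond_surv <= 0) or np.any(self.cond_surv >= 1):
            raise ValueError("conditional survival probabilities must be in (0, 1)")

    def cumulative(self) -> np.ndarray:
        """S(t_j) = prod_{i<=j} cond_surv_i — non-increasing in j."""
        return np.cumprod(self.cond_surv, axis=1)


@dataclass
class ImputedBatch:
    """Imputed B rows with labels carried over from their A sources."""

    X_hat: np.ndarray
    time: np.ndarray
    event: np.ndarray
    source_ids: list[str] = field(default_factory=list)
    task_loss: np.ndarray | None = None
    keep: np.ndarray | None = None

    def kept(self) -> "ImputedBatch":
        if self.keep is None:
            return self
        m = self.keep
        return ImputedBatch(self.X_hat[m], self.time[m], self.event[m],
                            [s for s, k in zip(self.source_ids, m) if k],
                            None if self.task_loss is None else self.task_loss[m],
                            np.ones(int(m.sum()), dtype=bool))


def _require_trained(model, name: str) -> None:
    if getattr(model, "best_epoch", 0) is None:
        raise ValueError(f"{name} has not been trained")


def impute_B_from_A(X_A_rows: np.ndarray, enc_A, dec_B,
                    time: np.ndarray, event: np.ndarray,
                    source_ids: Iterable[str] | None = None) -> ImputedBatch:
    """X_hat_B = Dec_B(Enc_A(X_A)) with deterministic posterior-mean encoding.

    Survival labels are copied verbatim from the source A samples.
    """
    _require_trained(enc_A, "modality A encoder")
    _require_trained(dec_B, "modality B decoder")
    X_A_rows = np.atleast_2d(np.asarray(X_A_rows, float))
    x_hat = dec_B.decode_np(enc_A.encode_mean_np(X_A_rows))
    time = np.asarray(time, float).copy()
    event = np.asarray(event, int).copy()
    if len(time) != len(X_A_rows) or len(event) != len(X_A_rows):
        raise ValueError("labels must align with the imputed rows")
    ids = list(source_ids) if source_ids is not None else [""] * len(time)
    return ImputedBatch(x_hat, time, event, ids)


def survival_nll(output: DiscreteSurvivalOutput, time: np.ndarray,
                 event: np.ndarray, reduce: str = "mean") -> float | np.ndarray:
    """Discrete-time survival negative log-likelihood.

    For a subject with event in interval k: -(sum_{j<k} log s_j + log(1-s_k));
    censored in interval k: -sum_{j<=k} log s_j.  Probabilities are clamped
    to [1e-7, 1-1e-7] before taking logs.
    """
    s = np.clip(output.cond_surv, 1e-7, 1 - 1e-7)
    n, J = s.shape
    k = time_to_interval(time, J)
    event = np.asarray(event, int)
    if len(k) != n or len(event) != n:
        raise ValueError("labels must match the number of subjects")
    j = np.arange(1, J + 1)
    mask_surv = np.where(event[:, None] == 1, j[None, :] < k[:, None],
                         j[None, :] <= k[:, None])
    per_row = -(mask_surv * np.log(s)).sum(axis=1)
    per_row -= event * np.log(1.0 - s[np.arange(n), k - 1])
    if reduce == "mean":
        return float(per_row.mean())
    if reduce == "none":
        return per_row
    raise ValueError("reduce must be 'mean' or 'none'")


def filter_by_task_loss(batch: ImputedBatch, t: float) -> ImputedBatch:
    """Set keep flags where the per-row task loss is strictly below t."""
    if batch.task_loss is None:
        raise ValueError("per-row task losses have not been computed")
    batch.keep = batch.task_loss < t
    return batch


# ---------------------------------------------------------------------------
# Predictor

class SurvivalPredictor:
    """MLP head mapping B features to J per-interval conditional survival
    probabilities (sigmoid outputs)."""

    def __init__(self, d_in: int, hidden: tuple[int, ...] = (64, 32),
                 n_intervals: int = 30, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.n_intervals = n_intervals
        self.net = MLP([d_in, *hidden, n_intervals], rng, final_activation="sigmoid")
        self.best_epoch: int | None = None

    def __call__(self, x: Tensor) -> Tensor:
        return self.net(x)

    def predict(self, X: np.ndarray) -> DiscreteSurvivalOutput:
        s = self.net.forward_np(np.atleast_2d(np.asarray(X, float)))
        return DiscreteSurvivalOutput(np.clip(s, 1e-7, 1 - 1e-7))

    def per_row_loss(self, X: np.ndarray, time, event) -> np.ndarray:
        return survival_nll(self.predict(X), time, event, reduce="none")

    def parameters(self):
        return self.net.parameters()

    def state_dict(self):
        return self.net.state_dict()

    def load_state(self, state):
        self.net.load_state(state)


def _nll_t(s: Tensor, time: np.ndarray, event: np.ndarray) -> Tensor:
    """Tape version of survival_nll (mean reduction) via interval masks."""
    n, J = s.shape
    k = time_to_interval(time, J)
    event = np.asarray(event, int)
    j = np.arange(1, J + 1)
    mask_surv = np.where(event[:, None] == 1, j[None, :] < k[:, None],
                         j[None, :] <= k[:, None]).astype(float)
    mask_ev = np.zeros((n, J))
    mask_ev[np.arange(n), k - 1] = event
    sc = tclip(s, 1e-7, 1 - 1e-7)
    ll = tsum(constant(mask_surv) * tlog(sc), axis=1) \
        + tsum(constant(mask_ev) * tlog(1.0 - sc + 0.0), axis=1)
    return tmean(ll) * -1.0


# ---------------------------------------------------------------------------
# TDImpute-style deterministic translator baseline

class TrainedTranslator:
    """Deterministic A->B autoencoder (no KL, no adversary), RMSE objective.

    Exposes the same encode/decode surface as a trained VAE pair so
    ``impute_B_from_A`` works identically with it.
    """

    def __init__(self, spec: VAESpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        enc_h = _hidden_widths(spec.input_dim, spec.n_layers_enc, spec.latent_dim)
        self.spec = spec
        self.d_out: int | None = None
        self._rng = rng
        self.encoder = MLP([spec.input_dim] + enc_h + [spec.latent_dim], rng,
                           final_activation="linear")
        self.decoder: MLP | None = None
        self.best_epoch: int | None = None
        self.history: pd.DataFrame | None = None

    def _build_decoder(self, d_out: int, n_layers: int) -> None:
        dec_h = _hidden_widths(d_out, n_layers, self.spec.latent_dim)
        self.decoder = MLP([self.spec.latent_dim] + dec_h[::-1] + [d_out],
                           self._rng, final_activation="sigmoid")
        self.d_out = d_out

    def encode_mean_np(self, X: np.ndarray) -> np.ndarray:
        return self.encoder.forward_np(np.asarray(X, float))

    def decode_np(self, Z: np.ndarray) -> np.ndarray:
        return self.decoder.forward_np(np.asarray(Z, float))

    @property
    def latent_dim(self) -> int:
        return self.spec.latent_dim

    def parameters(self):
        return self.encoder.parameters() + self.decoder.parameters()


def train_tdimpute(XA_train: np.ndarray, XB_train: np.ndarray,
                   XA_val: np.ndarray, XB_val: np.ndarray,
                   spec: VAESpec, seed: int = 0) -> TrainedTranslator:
    """Train a single deterministic translator network minimising the RMSE
    between predicted and true paired B rows; checkpoint at min val RMSE."""
    XA_train, XB_train = np.asarray(XA_train, float), np.asarray(XB_train, float)
    if XA_train.shape[0] != XB_train.shape[0] or XA_train.shape[0] == 0:
        raise ValueError("paired, non-empty A/B training rows required")
    ss = np.random.SeedSequence(seed)
    s_init, s_batch = ss.spawn(2)
    model = TrainedTranslator(spec, seed=int(s_init.generate_state(1)[0] % 2 ** 31))
    model._build_decoder(XB_train.shape[1], spec.n_layers_dec)
    opt = Adam(model.parameters(), spec.learning_rate)
    r_batch = np.random.default_rng(s_batch)

    rows, best = [], (np.inf, None, None)
    for epoch in range(spec.epochs):
        for idx in make_batches(len(XA_train), spec.batch_size, shuffle=True,
                                seed=int(r_batch.integers(2 ** 31))):
            xa, xb = constant(XA_train[idx]), constant(XB_train[idx])
            pred = model.decoder(model.encoder(xa))
            d = xb - pred
            loss = tmean(d * d)
            _check_finite(loss, epoch, "translator")
            opt.zero_grad(); loss.backward(); opt.step()
        v_rmse = float(np.sqrt(recon_loss(
            XB_val, model.decode_np(model.encode_mean_np(XA_val)))))
        rows.append({"epoch": epoch, "val_rmse": v_rmse})
        if v_rmse < best[0]:
            best = (v_rmse, epoch,
                    [p.data.copy() for p in model.parameters()])
    for p, s in zip(model.parameters(), best[2], strict=True):
        p.data = s.copy()
    model.best_epoch = best[1]
    model.history = pd.DataFrame(rows)
    return model


# ---------------------------------------------------------------------------
# Predictor training with augmentation variants

def _imputer_from_models(cfg: AugmentationConfig, models: dict | None):
    if cfg.method not in _NEEDS_IMPUTER:
        return None, None
    models = models or {}
    if cfg.method.startswith("tdimpute"):
        tr = models.get("translator")
        if tr is None:
            raise ValueError(f"method {cfg.method!r} requires a trained translator")
        return tr, tr
    enc_A, dec_B = models.get("enc_A"), models.get("dec_B")
    if enc_A is None or dec_B is None:
        raise ValueError(f"method {cfg.method!r} requires trained enc_A and dec_B")
    return enc_A, dec_B


def train_predictor(dataset: PairedOmicsDataset, cfg: AugmentationConfig,
                    models: dict | None = None
                    ) -> tuple[SurvivalPredictor, pd.DataFrame]:
    """Train the discrete-time survival predictor under a method variant.

    Real training rows are the present modality-B rows of the train split.
    Static-union methods add a one-off imputation of every train-split A
    sample without a B row.  Oversampling methods accompany every gradient
    step with a fresh batch of ``bsOV`` A-samples drawn with replacement
    (``bs`` and ``bsOV`` are both per-step batch sizes), imputed, filtered
    by the strict task-loss threshold ``t``, and summed into the step loss
    with weight ``gamma`` — so ``gamma = 0`` reproduces the unaugmented
    trajectory exactly.  The checkpoint maximises the time-dependent
    concordance index on validation.
    """
    enc_A, dec_B = _imputer_from_models(cfg, models)
    ids_tr, XB_tr = dataset.b_rows("train")
    if len(ids_tr) == 0:
        raise ValueError("no modality-B training rows")
    time_tr, event_tr = dataset.labels_for(ids_tr)
    ids_val, XB_val = dataset.b_rows("val")
    time_val, event_val = dataset.labels_for(ids_val)

    # pool of modality-A train rows (OV draws and static-union imputation)
    ids_a_tr, XA_tr = dataset.a_rows("train")
    time_a_tr, event_a_tr = dataset.labels_for(ids_a_tr)

    X_pool, time_pool, event_pool = XB_tr, time_tr, event_tr
    if cfg.method in _STATIC_UNION:
        present = set(dataset.b_sample_ids)
        miss = [i for i, s in enumerate(ids_a_tr) if s not in present]
        if miss:
            imp = impute_B_from_A(XA_tr[miss], enc_A, dec_B,
                                  time_a_tr[miss], event_a_tr[miss],
                                  [ids_a_tr[i] for i in miss])
            X_pool = np.vstack([XB_tr, imp.X_hat])
            time_pool = np.concatenate([time_tr, imp.time])
            event_pool = np.concatenate([event_tr, imp.event])

    ss = np.random.SeedSequence(cfg.seed)
    s_init, s_batch, s_ov = ss.spawn(3)
    predictor = SurvivalPredictor(X_pool.shape[1], cfg.predictor_hidden,
                                  cfg.n_intervals,
                                  seed=int(s_init.generate_state(1)[0] % 2 ** 31))
    opt = Adam(predictor.parameters(), cfg.learning_rate)
    r_batch = np.random.default_rng(s_batch)
    r_ov = np.random.default_rng(s_ov)

    oversampling = cfg.method in _OVERSAMPLING
    thresholded = cfg.method in _THRESHOLDED
    def draw_ov_batch():
        """One fresh oversampled batch, or None if everything was filtered."""
        if cfg.method == "ov" and cfg.ov_pool == "real":
            pick = r_ov.integers(len(X_pool), size=cfg.bsOV)
            return X_pool[pick], time_pool[pick], event_pool[pick]
        pick = r_ov.integers(len(XA_tr), size=cfg.bsOV)
        batch = impute_B_from_A(XA_tr[pick], enc_A, dec_B,
                                time_a_tr[pick], event_a_tr[pick],
                                [ids_a_tr[i] for i in pick])
        if thresholded:
            batch.task_loss = predictor.per_row_loss(
                batch.X_hat, batch.time, batch.event)
            batch = filter_by_task_loss(batch, cfg.t).kept()
        if len(batch.time) == 0:
            return None  # all filtered: this step proceeds with real data only
        return batch.X_hat, batch.time, batch.event

    rows, best = [], (-np.inf, None, None)
    for epoch in range(cfg.epochs):
        n_kept = 0
        epoch_loss = 0.0
        n_batches = 0
        for idx in make_batches(len(X_pool), cfg.bs, shuffle=True,
                                seed=int(r_batch.integers(2 ** 31))):
            s = predictor(constant(X_pool[idx]))
            loss = _nll_t(s, time_pool[idx], event_pool[idx])
            if oversampling:
                ov = draw_ov_batch()
                if ov is not None:
                    ov_x, ov_t, ov_e = ov
                    n_kept += len(ov_t)
                    loss = loss + _nll_t(predictor(constant(ov_x)), ov_t, ov_e) \
                        * cfg.gamma
            _check_finite(loss, epoch, "predictor")
            opt.zero_grad(); loss.backward(); opt.step()
            epoch_loss += loss.item()
            n_batches += 1

        out_val = predictor.predict(XB_val)
        v_ctd = c_td(out_val, time_val, event_val)
        rows.append({"epoch": epoch, "train_loss": epoch_loss / n_batches,
                     "val_ctd": v_ctd, "n_ov_kept": n_kept})
        if v_ctd > best[0]:
            best = (v_ctd, epoch, predictor.state_dict())
    predictor.load_state(best[2])
    predictor.best_epoch = best[1]
    return predictor, pd.DataFrame(rows)
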