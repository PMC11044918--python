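"""Modality VAEs: architecture, losses, cyclic KL annealing, training.

Both modalities use the same fully connected design: encoder hidden widths
halve from the input dimension layer by layer, then map to a Gaussian
posterior (mu, logvar); the decoder mirrors the encoder in reverse and ends
in a sigmoid so reconstructions live on the [0, 1] scale of the min-max
scaled inputs.

The modality A VAE trains on plain reconstruction + annealed KL and is then
frozen.  The modality B VAE additionally carries a cross-modal term: the
squared error between a real B sample and the B decoded from its paired A
sample's (frozen) posterior mean.  Its stopping rule selects the checkpoint
minimising that cross-modal loss on validation.

The KL weight follows a cyclic annealing schedule — the weight ramps from 0
to its plateau over the first part of each cycle and then stays flat —
which counteracts posterior collapse when training small high-dimensional
tabular datasets as VAEs.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._autodiff import Tensor, constant, exp as texp, tmean, tsum
from ._nn import MLP, Linear, Adam
from .data import make_batches

__all__ = [
    "AnnealSpec", "VAESpec", "MLPVAE", "TrainedVAE", "build_mlp_vae",
    "recon_loss", "kl_loss", "anneal_beta", "cross_modal_loss",
    "cross_modal_predict", "reparameterize", "train_vae_A", "train_vae_B",
    "save_vae", "load_vae",
]


@dataclass
class AnnealSpec:
    """Cyclic KL annealing: n_cycles cycles, linear ramp over the first
    ramp_fraction of each cycle, plateau at the configured KL weight."""

    n_cycles: int = 4
    ramp_fraction: float = 0.5

    def __post_init__(self):
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if not 0.0 < self.ramp_fraction <= 1.0:
            raise ValueError("ramp_fraction must be in (0, 1]")


@dataclass
class VAESpec:
    input_dim: int
    n_layers_enc: int = 3
    n_layers_dec: int = 3
    latent_dim: int = 32
    kl_weight: float = 0.001          # modality A default; B uses 0.0001
    cm_weight: float = 0.6            # weight on the cross-modal loss (B only)
    learning_rate: float = 1e-4
    epochs: int = 400
    batch_size: int = 32
    anneal: AnnealSpec = field(default_factory=AnnealSpec)

    def __post_init__(self):
        if self.latent_dim >= self.input_dim:
            raise ValueError("latent_dim must be smaller than input_dim")
        if self.kl_weight < 0 or self.cm_weight < 0:
            raise ValueError("loss weights must be >= 0")
        if self.n_layers_enc < 1 or self.n_layers_dec < 1:
            raise ValueError("need at least one layer")


def _hidden_widths(input_dim: int, n_layers: int, latent_dim: int) -> list[int]:
    widths = [input_dim // 2 ** i for i in range(1, n_layers)]
    bottom = widths[-1] if widths else input_dim
    if bottom <= latent_dim:
        raise ValueError(
            f"halving {input_dim} over {n_layers} layers reaches width {bottom}, "
            f"not above latent_dim={latent_dim}")
    return widths


class MLPVAE:
    """Gaussian-posterior MLP VAE with a sigmoid decoder."""

    def __init__(self, spec: VAESpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        enc_h = _hidden_widths(spec.input_dim, spec.n_layers_enc, spec.latent_dim)
        dec_h = _hidden_widths(spec.input_dim, spec.n_layers_dec, spec.latent_dim)
        self.trunk = MLP([spec.input_dim] + enc_h, rng, final_activation="relu")
        top = enc_h[-1] if enc_h else spec.input_dim
        self.mu_head = Linear(top, spec.latent_dim, rng, gain=1.0)
        self.logvar_head = Linear(top, spec.latent_dim, rng, gain=0.01)
        self.decoder = MLP([spec.latent_dim] + dec_h[::-1] + [spec.input_dim],
                           rng, final_activation="sigmoid")

    # tape-side
    def encode(self, x: Tensor) -> tuple[Tensor, Tensor]:
        h = self.trunk(x)
        return self.mu_head(h), self.logvar_head(h)

    def decode(self, z: Tensor) -> Tensor:
        return self.decoder(z)

    # inference-side (no tape)
    def encode_np(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = self.trunk.forward_np(X)
        return self.mu_head.forward_np(h), self.logvar_head.forward_np(h)

    def encode_mean_np(self, X: np.ndarray) -> np.ndarray:
        return self.encode_np(X)[0]

    def decode_np(self, Z: np.ndarray) -> np.ndarray:
        return self.decoder.forward_np(Z)

    def parameters(self):
        return (self.trunk.parameters() + self.mu_head.parameters()
                + self.logvar_head.parameters() + self.decoder.parameters())

    def encoder_parameters(self):
        return (self.trunk.parameters() + self.mu_head.parameters()
                + self.logvar_head.parameters())

    def state_dict(self):
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state):
        for p, s in zip(self.parameters(), state, strict=True):
            p.data = s.copy()


@dataclass
class TrainedVAE:
    """A (possibly still untrained) VAE plus its training record."""

    model: MLPVAE
    spec: VAESpec
    history: pd.DataFrame | None = None
    best_epoch: int | None = None

    def encode_mean_np(self, X: np.ndarray) -> np.ndarray:
        return self.model.encode_mean_np(X)

    def decode_np(self, Z: np.ndarray) -> np.ndarray:
        return self.model.decode_np(Z)

    @property
    def latent_dim(self) -> int:
        return self.spec.latent_dim

    def parameter_fingerprint(self) -> tuple:
        """Bit-exact summary of all weights, for freezing-contract checks."""
        return tuple(arr.tobytes() for arr in self.model.state_dict())


def build_mlp_vae(spec: VAESpec, seed: int = 0) -> TrainedVAE:
    return TrainedVAE(MLPVAE(spec, seed=seed), spec)


# ---------------------------------------------------------------------------
# Losses.  Each has a tape version (used inside training steps) and a public
# numpy-facing wrapper computing the identical formula.

def _recon_t(x: Tensor, x_hat: Tensor) -> Tensor:
    d = x - x_hat
    return tmean(d * d)


def _kl_t(mu: Tensor, logvar: Tensor) -> Tensor:
    inner = 1.0 + logvar - mu * mu - texp(logvar)
    return tmean(tsum(inner, axis=1)) * (-0.5)


def recon_loss(X: np.ndarray, X_hat: np.ndarray) -> float:
    """Mean squared reconstruction error over samples and features."""
    X, X_hat = np.asarray(X, float), np.asarray(X_hat, float)
    if X.shape != X_hat.shape:
        raise ValueError(f"shape mismatch {X.shape} vs {X_hat.shape}")
    return _recon_t(constant(X), constant(X_hat)).item()


def kl_loss(mu: np.ndarray, logvar: np.ndarray) -> float:
    """Mean over samples of KL(N(mu, e^logvar) || N(0, I)); >= 0."""
    mu, logvar = np.atleast_2d(np.asarray(mu, float)), np.atleast_2d(np.asarray(logvar, float))
    return _kl_t(constant(mu), constant(logvar)).item()


def anneal_beta(epoch: int, total_epochs: int, anneal: AnnealSpec,
                kl_weight: float) -> float:
    """Cyclic KL weight at a given epoch (0-based)."""
    if not 0 <= epoch < total_epochs:
        raise ValueError("epoch out of range")
    cycle = math.ceil(total_epochs / anneal.n_cycles)
    tau = (epoch % cycle) / cycle
    return kl_weight * min(1.0, tau / anneal.ramp_fraction)


def cross_modal_predict(X_A, enc_A, dec_B) -> np.ndarray:
    """Dec_B(Enc_A(X_A)) using the A posterior mean (deterministic)."""
    return dec_B.decode_np(enc_A.encode_mean_np(np.asarray(X_A, float)))


def cross_modal_loss(X_B, X_A, enc_A, dec_B) -> float:
    """Mean squared error between real B rows and their cross-modal
    reconstruction from ID-paired A rows."""
    X_B, X_A = np.asarray(X_B, float), np.asarray(X_A, float)
    if X_B.shape[0] != X_A.shape[0]:
        raise ValueError("X_A and X_B must hold ID-paired rows (equal counts)")
    return recon_loss(X_B, cross_modal_predict(X_A, enc_A, dec_B))


def reparameterize(mu: np.ndarray, logvar: np.ndarray,
                   seed: int | np.random.Generator = 0) -> np.ndarray:
    """z = mu + exp(logvar/2) * eps with eps from a seeded N(0,1) stream."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu, logvar = np.asarray(mu, float), np.asarray(logvar, float)
    return mu + np.exp(0.5 * logvar) * rng.standard_normal(mu.shape)


# ---------------------------------------------------------------------------
# Training loops

def _check_finite(loss: Tensor, epoch: int, what: str) -> None:
    if not np.isfinite(loss.data):
        raise FloatingPointError(f"{what} loss diverged (NaN/Inf) at epoch {epoch}")


def _reparam_t(mu: Tensor, logvar: Tensor, rng: np.random.Generator) -> Tensor:
    eps = constant(rng.standard_normal(mu.shape))
    return mu + texp(logvar * 0.5) * eps


def train_vae_A(X_train: np.ndarray, X_val: np.ndarray, spec: VAESpec,
                seed: int = 0) -> TrainedVAE:
    """Train the modality A VAE on L_recon + beta(epoch) * L_KL.

    Checkpoint rule: the epoch with the best validation reconstruction loss
    among epochs whose validation KL exceeds 1e-6 (reconstruction minimised
    while the KL term has not vanished).  The returned model is meant to be
    frozen for all downstream stages.
    """
    X_train = np.asarray(X_train, float)
    if X_train.shape[0] == 0:
        raise ValueError("empty training set")
    ss = np.random.SeedSequence(seed)
    s_init, s_batch, s_eps = ss.spawn(3)
    model = MLPVAE(spec, seed=int(s_init.generate_state(1)[0] % 2 ** 31))
    opt = Adam(model.parameters(), spec.learning_rate)
    r_batch = np.random.default_rng(s_batch)
    r_eps = np.random.default_rng(s_eps)

    rows, best = [], (np.inf, None, None)  # (val_recon, epoch, state)
    fallback = (np.inf, None, None)
    for epoch in range(spec.epochs):
        beta = anneal_beta(epoch, spec.epochs, spec.anneal, spec.kl_weight)
        for idx in make_batches(len(X_train), spec.batch_size, shuffle=True,
                                seed=int(r_batch.integers(2 ** 31))):
            x = constant(X_train[idx])
            mu, logvar = model.encode(x)
            xhat = model.decode(_reparam_t(mu, logvar, r_eps))
            loss = _recon_t(x, xhat) + _kl_t(mu, logvar) * beta
            _check_finite(loss, epoch, "VAE-A")
            opt.zero_grad(); loss.backward(); opt.step()
        mu_v, logvar_v = model.encode_np(X_val)
        v_recon = recon_loss(X_val, model.decode_np(mu_v))
        v_kl = kl_loss(mu_v, logvar_v)
        rows.append({"epoch": epoch, "beta": beta, "val_recon": v_recon,
                     "val_kl": v_kl})
        if v_recon < fallback[0]:
            fallback = (v_recon, epoch, model.state_dict())
        if v_kl > 1e-6 and v_recon < best[0]:
            best = (v_recon, epoch, model.state_dict())
    chosen = best if best[1] is not None else fallback
    model.load_state(chosen[2])
    return TrainedVAE(model, spec, pd.DataFrame(rows), best_epoch=chosen[1])


def train_vae_B(XB_train: np.ndarray, XB_val: np.ndarray,
                XA_train_paired: np.ndarray, XA_val_paired: np.ndarray,
                enc_A: TrainedVAE, spec: VAESpec, seed: int = 0) -> TrainedVAE:
    """Train the modality B VAE with the cross-modal alignment term.

    Per batch the objective is L_recon + beta * L_KL + cm_weight * L_CM,
    where L_CM compares the batch's B rows with Dec_B applied to the frozen
    A-encoder posterior means of the ID-paired A rows (gradient reaches the
    B decoder only).  The returned checkpoint minimises validation L_CM.
    """
    XB_train = np.asarray(XB_train, float)
    if XB_train.shape[0] == 0:
        raise ValueError("no paired rows to train on")
    if XB_train.shape[0] != np.asarray(XA_train_paired).shape[0]:
        raise ValueError("train rows of A and B must be ID-paired")
    ss = np.random.SeedSequence(seed)
    s_init, s_batch, s_eps = ss.spawn(3)
    model = MLPVAE(spec, seed=int(s_init.generate_state(1)[0] % 2 ** 31))
    opt = Adam(model.parameters(), spec.learning_rate)
    r_batch = np.random.default_rng(s_batch)
    r_eps = np.random.default_rng(s_eps)

    mu_A_train = enc_A.encode_mean_np(np.asarray(XA_train_paired, float))
    mu_A_val = enc_A.encode_mean_np(np.asarray(XA_val_paired, float))

    rows, best = [], (np.inf, None, None)
    for epoch in range(spec.epochs):
        beta = anneal_beta(epoch, spec.epochs, spec.anneal, spec.kl_weight)
        for idx in make_batches(len(XB_train), spec.batch_size, shuffle=True,
                                seed=int(r_batch.integers(2 ** 31))):
            x = constant(XB_train[idx])
            mu, logvar = model.encode(x)
            xhat = model.decode(_reparam_t(mu, logvar, r_eps))
            loss = _recon_t(x, xhat) + _kl_t(mu, logvar) * beta
            if spec.cm_weight > 0:
                x_cm = model.decode(constant(mu_A_train[idx]))
                loss = loss + _recon_t(x, x_cm) * spec.cm_weight
            _check_finite(loss, epoch, "VAE-B")
            opt.zero_grad(); loss.backward(); opt.step()
        mu_v, logvar_v = model.encode_np(XB_val)
        v_recon = recon_loss(XB_val, model.decode_np(mu_v))
        v_kl = kl_loss(mu_v, logvar_v)
        v_cm = recon_loss(XB_val, model.decode_np(mu_A_val))
        rows.append({"epoch": epoch, "beta": beta, "val_recon": v_recon,
                     "val_kl": v_kl, "val_cm": v_cm})
        if v_cm < best[0]:
            best = (v_cm, epoch, model.state_dict())
    model.load_state(best[2])
    return TrainedVAE(model, spec, pd.DataFrame(rows), best_epoch=best[1])


# ---------------------------------------------------------------------------
# Checkpoint I/O

def save_vae(trained: TrainedVAE, path: str | Path) -> None:
    path = Path(path)
    spec = asdict(trained.spec)
    meta = {"spec": spec, "best_epoch": trained.best_epoch}
    arrays = {f"p{i}": a for i, a in enumerate(trained.model.state_dict())}
    np.savez(path.with_suffix(".npz"), meta=json.dumps(meta), **arrays)
    if trained.history is not None:
        trained.history.to_csv(path.with_suffix(".history.tsv"), sep="\t", index=False)


def load_vae(path: str | Path) -> TrainedVAE:
    path = Path(path)
    with np.load(path.with_suffix(".npz"), allow_pickle=False) as f:
        meta = json.loads(str(f["meta"]))
        n = len([k for k in f.files if k.startswith("p")])
        state = [f[f"p{i}"] for i in range(n)]
    spec_d = meta["spec"]
    spec_d["anneal"] = AnnealSpec(**spec_d["anneal"])
    spec = VAESpec(**spec_d)
    trained = build_mlp_vae(spec)
    trained.model.load_state(state)
    trained.best_epoch = meta["best_epoch"]
    hist = path.with_suffix(".history.tsv")
    if hist.exists():
        trained.history = pd.read_csv(hist, sep="\t")
    return trained
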