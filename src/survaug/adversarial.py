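"""Discriminator-based latent alignment with least-squares (LSGAN) losses.

A small fully connected discriminator scores latent vectors; modality-A
latents carry label 1 and modality-B latents label 0.  Training alternates,
after a warm-up phase in which only the modality B VAE learns:

1. a VAE-B step (reconstruction + annealed KL + cross-modal loss),
2. a discriminator step on the LSGAN discriminator loss with the VAE frozen,
3. an encoder-B step on the LSGAN adversarial loss (labels swapped) with
   the discriminator frozen — gradient reaches only the B encoder.

Latents shown to the discriminator are posterior means; sampled latents
would inject extra variance into an already delicate game.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._autodiff import Tensor, constant, exp as texp, tmean
from ._nn import MLP, Adam
from .data import make_batches
from .vae import (MLPVAE, TrainedVAE, VAESpec, _check_finite, _kl_t,
                  _recon_t, _reparam_t, anneal_beta, kl_loss, recon_loss)

__all__ = ["DiscriminatorSpec", "AdvSchedule", "Discriminator",
           "disc_loss", "adv_loss", "train_adversarial"]


@dataclass
class DiscriminatorSpec:
    n_layers: int = 4
    learning_rate: float = 5e-5
    label_A: float = 1.0
    label_B: float = 0.0

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("discriminator needs at least one layer")


@dataclass
class AdvSchedule:
    total_epochs: int = 400
    warmup_epochs: int = 100

    def __post_init__(self):
        if not 0 <= self.warmup_epochs <= self.total_epochs:
            raise ValueError("warmup must not exceed total epochs")


class Discriminator:
    """MLP scoring latent vectors; widths halve from latent_dim, floored at 8."""

    def __init__(self, latent_dim: int, spec: DiscriminatorSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        widths = [latent_dim]
        for _ in range(spec.n_layers - 1):
            widths.append(max(widths[-1] // 2, 8))
        widths.append(1)
        self.spec = spec
        self.net = MLP(widths, rng, final_activation="linear")

    def __call__(self, z: Tensor) -> Tensor:
        return self.net(z)

    def score_np(self, Z: np.ndarray) -> np.ndarray:
        return self.net.forward_np(np.asarray(Z, float)).ravel()

    def parameters(self):
        return self.net.parameters()

    def state_dict(self):
        return self.net.state_dict()


def _lsgan_t(scores: Tensor, target: float) -> Tensor:
    d = scores - target
    return tmean(d * d)


def disc_loss(scores_A, scores_B) -> float:
    """LSGAN discriminator loss: A latents toward 1, B latents toward 0."""
    scores_A, scores_B = np.asarray(scores_A, float), np.asarray(scores_B, float)
    if scores_A.size == 0 or scores_B.size == 0:
        raise ValueError("empty score arrays")
    return (_lsgan_t(constant(scores_A), 1.0).item()
            + _lsgan_t(constant(scores_B), 0.0).item())


def adv_loss(scores_B) -> float:
    """LSGAN generator-side loss: B latents pushed toward label 1."""
    return _lsgan_t(constant(np.asarray(scores_B, float)), 1.0).item()


def train_adversarial(XA_train: np.ndarray, XB_train: np.ndarray,
                      XB_val: np.ndarray, XA_train_paired: np.ndarray,
                      XA_val_paired: np.ndarray, enc_A: TrainedVAE,
                      vae_spec: VAESpec, disc_spec: DiscriminatorSpec,
                      sched: AdvSchedule, seed: int = 0
                      ) -> tuple[TrainedVAE, Discriminator]:
    """Adversarially align the modality B latent space to the frozen A space.

    ``XA_train`` is the full modality-A training matrix (the discriminator
    sees all A latents); ``XA_train_paired`` / ``XA_val_paired`` are the
    rows ID-paired with ``XB_train`` / ``XB_val`` for the cross-modal term.
    Returns the B VAE at the epoch minimising validation L_CM, plus the
    discriminator.  History records the mean discriminator score gap
    |E[D(z_A)] - E[D(z_B)]| per epoch.
    """
    XA_train = np.asarray(XA_train, float)
    XB_train = np.asarray(XB_train, float)
    if XB_train.shape[0] == 0:
        raise ValueError("no B rows to train on")
    ss = np.random.SeedSequence(seed)
    # first three children mirror train_vae_B so warmup == total reproduces it
    s_init, s_batch, s_eps, s_dinit = ss.spawn(4)
    model = MLPVAE(vae_spec, seed=int(s_init.generate_state(1)[0] % 2 ** 31))
    disc = Discriminator(vae_spec.latent_dim, disc_spec,
                         seed=int(s_dinit.generate_state(1)[0] % 2 ** 31))
    opt_vae = Adam(model.parameters(), vae_spec.learning_rate)
    opt_disc = Adam(disc.parameters(), disc_spec.learning_rate)
    opt_enc = Adam(model.encoder_parameters(), vae_spec.learning_rate)
    r_batch = np.random.default_rng(s_batch)
    r_eps = np.random.default_rng(s_eps)

    mu_A_train = enc_A.encode_mean_np(np.asarray(XA_train_paired, float))
    mu_A_val = enc_A.encode_mean_np(np.asarray(XA_val_paired, float))
    z_A_all = enc_A.encode_mean_np(XA_train)  # frozen: compute once

    nB = len(XB_train)
    rows, best = [], (np.inf, None, None)
    for epoch in range(sched.total_epochs):
        beta = anneal_beta(epoch, sched.total_epochs, vae_spec.anneal,
                           vae_spec.kl_weight)
        # (1) VAE-B step over all batches
        for idx in make_batches(nB, vae_spec.batch_size, shuffle=True,
                                seed=int(r_batch.integers(2 ** 31))):
            x = constant(XB_train[idx])
            mu, logvar = model.encode(x)
            xhat = model.decode(_reparam_t(mu, logvar, r_eps))
            loss = _recon_t(x, xhat) + _kl_t(mu, logvar) * beta
            if vae_spec.cm_weight > 0:
                loss = loss + _recon_t(x, model.decode(constant(mu_A_train[idx]))) \
                    * vae_spec.cm_weight
            _check_finite(loss, epoch, "adversarial VAE-B step")
            opt_vae.zero_grad(); loss.backward(); opt_vae.step()

        if epoch >= sched.warmup_epochs:
            # (2) discriminator step — VAE frozen (latents precomputed)
            z_B = model.encode_mean_np(XB_train)
            idx_a = r_batch.choice(len(z_A_all), size=min(len(z_A_all), nB),
                                   replace=False)
            sA = disc(constant(z_A_all[idx_a]))
            sB = disc(constant(z_B))
            d_loss = _lsgan_t(sA, disc_spec.label_A) + _lsgan_t(sB, disc_spec.label_B)
            _check_finite(d_loss, epoch, "discriminator step")
            opt_disc.zero_grad(); d_loss.backward(); opt_disc.step()

            # (3) encoder-B step — discriminator frozen, labels swapped
            x = constant(XB_train)
            mu, _ = model.encode(x)
            a_loss = _lsgan_t(disc(mu), disc_spec.label_A)
            _check_finite(a_loss, epoch, "encoder adversarial step")
            opt_enc.zero_grad(); a_loss.backward()
            for p in disc.parameters():   # gradient reached them; never applied
                p.grad = None
            opt_enc.step()

        mu_v, logvar_v = model.encode_np(XB_val)
        v_cm = recon_loss(XB_val, model.decode_np(mu_A_val))
        gap = abs(float(np.mean(disc.score_np(z_A_all)))
                  - float(np.mean(disc.score_np(model.encode_mean_np(XB_train)))))
        rows.append({"epoch": epoch, "beta": beta,
                     "val_recon": recon_loss(XB_val, model.decode_np(mu_v)),
                     "val_kl": kl_loss(mu_v, logvar_v), "val_cm": v_cm,
                     "score_gap": gap})
        if v_cm < best[0]:
            best = (v_cm, epoch, model.state_dict())
    model.load_state(best[2])
    trained = TrainedVAE(model, vae_spec, pd.DataFrame(rows), best_epoch=best[1])
    return trained, disc
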