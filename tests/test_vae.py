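"""VAE architecture rules, closed-form losses, annealing, and training
contracts."""

import math

import numpy as np
import pytest

from survaug.vae import (AnnealSpec, MLPVAE, VAESpec, anneal_beta,
                         build_mlp_vae, cross_modal_loss, kl_loss, recon_loss,
                         reparameterize, train_vae_A, train_vae_B,
                         load_vae, save_vae)


def spec(input_dim, n_layers=3, latent=32, **kw):
    return VAESpec(input_dim=input_dim, n_layers_enc=n_layers,
                   n_layers_dec=n_layers, latent_dim=latent, **kw)


class TestArchitecture:
    def test_hidden_widths_halve_to_latent(self):
        model = MLPVAE(spec(1000, 3, 32))
        assert model.trunk.widths == [1000, 500, 250]
        assert model.mu_head.W.data.shape == (250, 32)
        assert model.logvar_head.W.data.shape == (250, 32)
        assert model.decoder.widths == [32, 250, 500, 1000]

    def test_two_layer_example(self):
        model = MLPVAE(spec(64, 2, 8))
        assert model.trunk.widths == [64, 32]

    def test_halving_below_latent_raises(self):
        with pytest.raises(ValueError):
            MLPVAE(spec(64, 4, 8))  # 64 -> 32 -> 16 -> 8 not above latent 8

    def test_decoder_outputs_unit_interval(self, rng):
        model = MLPVAE(spec(20, 2, 4), seed=0)
        out = model.decode_np(rng.standard_normal((6, 4)) * 5)
        assert np.all((out > 0) & (out < 1))


class TestClosedFormLosses:
    def test_recon_zero_and_single_cell(self):
        X = np.zeros((1, 1))
        assert recon_loss(X, X) == 0.0
        assert recon_loss(X, X + 0.5) == pytest.approx(0.25, abs=1e-12)

    def test_recon_quadratic_homogeneity(self, rng):
        X = rng.normal(size=(5, 4))
        Y = rng.normal(size=(5, 4))
        r1 = recon_loss(X, Y)
        r2 = recon_loss(2 * X, 2 * Y)
        assert r2 == pytest.approx(4 * r1, rel=1e-12)

    def test_recon_shape_mismatch(self):
        with pytest.raises(ValueError):
            recon_loss(np.zeros((2, 2)), np.zeros((2, 3)))

    def test_kl_closed_form_values(self):
        assert kl_loss(np.zeros((1, 1)), np.zeros((1, 1))) == pytest.approx(0.0)
        assert kl_loss(np.array([[1.0]]), np.array([[0.0]])) == pytest.approx(0.5)
        assert kl_loss(np.array([[0.0]]), np.array([[math.log(4)]])) == \
            pytest.approx(0.5 * (3 - math.log(4)), abs=1e-9)

    def test_kl_matches_quadrature_oracle(self, rng):
        """Analytic Gaussian KL vs numerical integration of the integrand."""
        grid = np.linspace(-40, 40, 200001)
        for _ in range(50):
            mu = rng.normal() * 2
            logvar = rng.normal()
            sd = math.exp(0.5 * logvar)
            p = np.exp(-0.5 * ((grid - mu) / sd) ** 2) / (sd * math.sqrt(2 * math.pi))
            logp = -0.5 * ((grid - mu) / sd) ** 2 - math.log(sd) \
                - 0.5 * math.log(2 * math.pi)
            logq = -0.5 * grid ** 2 - 0.5 * math.log(2 * math.pi)
            oracle = np.trapezoid(p * (logp - logq), grid)
            assert kl_loss(np.array([[mu]]), np.array([[logvar]])) == \
                pytest.approx(oracle, abs=1e-6)

    def test_kl_nonnegative(self, rng):
        mu = rng.normal(size=(100, 5))
        logvar = rng.normal(size=(100, 5))
        assert kl_loss(mu, logvar) >= 0.0


class TestAnnealing:
    def test_formula_examples(self):
        a = AnnealSpec(n_cycles=4, ramp_fraction=0.5)
        assert anneal_beta(0, 400, a, 1e-4) == 0.0
        assert anneal_beta(25, 400, a, 1e-4) == pytest.approx(5e-5)
        assert anneal_beta(60, 400, a, 1e-4) == pytest.approx(1e-4)

    def test_periodicity_and_ramp_monotone(self):
        a = AnnealSpec(n_cycles=5, ramp_fraction=0.4)
        total = 200
        cycle = math.ceil(total / a.n_cycles)
        betas = [anneal_beta(e, total, a, 1.0) for e in range(total)]
        for e in range(total - cycle):
            assert betas[e] == pytest.approx(betas[e + cycle])
        ramp = betas[:int(cycle * a.ramp_fraction)]
        assert all(b2 >= b1 for b1, b2 in zip(ramp, ramp[1:]))

    def test_epoch_out_of_range(self):
        with pytest.raises(ValueError):
            anneal_beta(400, 400, AnnealSpec(), 1.0)


class _IdentityCoder:
    """Toy encoder/decoder pair: latent = input, decode = identity."""

    latent_dim = 3
    best_epoch = 0

    def encode_mean_np(self, X):
        return np.asarray(X, float)

    def decode_np(self, Z):
        return np.asarray(Z, float)


class TestCrossModalLoss:
    def test_perfect_translator_gives_zero(self, rng):
        X = rng.uniform(size=(4, 3))
        assert cross_modal_loss(X, X, _IdentityCoder(), _IdentityCoder()) == 0.0

    def test_hand_value_single_pair(self):
        xb = np.array([[0.5]])
        xa = np.array([[0.6]])
        coder = _IdentityCoder()
        assert cross_modal_loss(xb, xa, coder, coder) == pytest.approx(0.01)

    def test_joint_permutation_invariance(self, rng):
        XA = rng.uniform(size=(6, 3))
        XB = rng.uniform(size=(6, 3))
        coder = _IdentityCoder()
        perm = rng.permutation(6)
        assert cross_modal_loss(XB, XA, coder, coder) == pytest.approx(
            cross_modal_loss(XB[perm], XA[perm], coder, coder), rel=1e-12)

    def test_unpaired_rows_error(self, rng):
        with pytest.raises(ValueError):
            cross_modal_loss(rng.uniform(size=(3, 2)), rng.uniform(size=(4, 2)),
                             _IdentityCoder(), _IdentityCoder())


class TestReparameterize:
    def test_vanishing_variance_returns_mean(self, rng):
        mu = rng.normal(size=(5, 3))
        z = reparameterize(mu, np.full((5, 3), -60.0), seed=0)
        assert np.allclose(z, mu, atol=1e-9)

    def test_seeded_determinism(self, rng):
        mu = rng.normal(size=(4, 2))
        lv = rng.normal(size=(4, 2))
        assert np.array_equal(reparameterize(mu, lv, seed=7),
                              reparameterize(mu, lv, seed=7))

    def test_sample_variance_matches_logvar(self):
        z = reparameterize(np.zeros((10000, 1)), np.full((10000, 1), math.log(4)),
                           seed=3)
        assert z.var() == pytest.approx(4.0, rel=0.1)


@pytest.fixture(scope="module")
def noiseless_training_data():
    rng = np.random.default_rng(42)
    z = rng.standard_normal((260, 2))
    W = rng.normal(size=(2, 16))
    X = z @ W
    X = (X - X.min(axis=0)) / (X.max(axis=0) - X.min(axis=0))
    return X[:200], X[200:]


@pytest.fixture(scope="module")
def trained_vae_A(noiseless_training_data):
    X_tr, X_val = noiseless_training_data
    s = spec(16, 2, 2, kl_weight=1e-4, learning_rate=2e-3, epochs=200)
    return train_vae_A(X_tr, X_val, s, seed=0)


class TestTrainVaeA:
    def test_reconstructs_noiseless_factor_data(self, trained_vae_A,
                                                noiseless_training_data):
        _, X_val = noiseless_training_data
        hist = trained_vae_A.history
        best = trained_vae_A.best_epoch
        assert hist["val_recon"].iloc[best] < 0.01
        assert hist["val_kl"].iloc[best] > 1e-6

    def test_checkpoint_respects_kl_floor(self, trained_vae_A):
        hist = trained_vae_A.history
        eligible = hist[hist["val_kl"] > 1e-6]
        assert trained_vae_A.best_epoch == int(
            eligible.loc[eligible["val_recon"].idxmin(), "epoch"])

    def test_training_is_deterministic(self, noiseless_training_data):
        X_tr, X_val = noiseless_training_data
        s = spec(16, 2, 2, kl_weight=1e-4, learning_rate=1e-3, epochs=15)
        a = train_vae_A(X_tr, X_val, s, seed=5)
        b = train_vae_A(X_tr, X_val, s, seed=5)
        assert a.history.equals(b.history)
        for pa, pb in zip(a.model.state_dict(), b.model.state_dict()):
            assert np.array_equal(pa, pb)


class TestTrainVaeB:
    def test_cm_checkpoint_is_argmin_of_history(self, noiseless_training_data,
                                                trained_vae_A):
        X_tr, X_val = noiseless_training_data
        s = spec(16, 2, 2, kl_weight=1e-5, cm_weight=0.6,
                 learning_rate=1e-3, epochs=30)
        vb = train_vae_B(X_tr, X_val, X_tr, X_val, trained_vae_A, s, seed=1)
        assert vb.best_epoch == int(vb.history["val_cm"].idxmin())
        # alignment sanity: selected checkpoint beats an untrained model
        untrained = build_mlp_vae(s, seed=99)
        assert vb.history["val_cm"].min() < recon_loss(
            X_val, untrained.decode_np(trained_vae_A.encode_mean_np(X_val)))

    def test_cm_weight_zero_ignores_paired_inputs(self, noiseless_training_data,
                                                  trained_vae_A, rng):
        X_tr, X_val = noiseless_training_data
        s = spec(16, 2, 2, cm_weight=0.0, learning_rate=1e-3, epochs=10)
        a = train_vae_B(X_tr, X_val, X_tr, X_val, trained_vae_A, s, seed=2)
        garbage = rng.uniform(size=X_tr.shape)
        b = train_vae_B(X_tr, X_val, garbage, rng.uniform(size=X_val.shape),
                        trained_vae_A, s, seed=2)
        for pa, pb in zip(a.model.state_dict(), b.model.state_dict()):
            assert np.array_equal(pa, pb)

    def test_a_vae_frozen_during_b_training(self, noiseless_training_data,
                                            trained_vae_A):
        X_tr, X_val = noiseless_training_data
        before = trained_vae_A.parameter_fingerprint()
        s = spec(16, 2, 2, learning_rate=1e-3, epochs=8)
        train_vae_B(X_tr, X_val, X_tr, X_val, trained_vae_A, s, seed=3)
        assert trained_vae_A.parameter_fingerprint() == before


class TestCheckpointIO:
    def test_save_load_round_trip(self, tmp_path, trained_vae_A,
                                  noiseless_training_data):
        _, X_val = noiseless_training_data
        save_vae(trained_vae_A, tmp_path / "vae_A")
        back = load_vae(tmp_path / "vae_A")
        assert back.best_epoch == trained_vae_A.best_epoch
        assert np.array_equal(back.encode_mean_np(X_val),
                              trained_vae_A.encode_mean_np(X_val))
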