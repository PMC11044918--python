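"""Discrete-time survival likelihood, imputation contracts, threshold
filtering, and predictor-training method variants."""

import math

import numpy as np
import pytest

from survaug.augment import (AugmentationConfig, DiscreteSurvivalOutput,
                             ImputedBatch, SurvivalPredictor,
                             filter_by_task_loss, impute_B_from_A,
                             survival_nll, train_predictor, train_tdimpute)
from survaug.evaluation import time_to_interval
from survaug.synthetic import SyntheticConfig, generate
from survaug.vae import VAESpec


def out(*rows):
    return DiscreteSurvivalOutput(np.array(rows, float))


def nll_oracle(cond_surv, time, event, n_intervals=30):
    """Brute force: form the discrete likelihood per subject explicitly."""
    s = np.clip(cond_surv, 1e-7, 1 - 1e-7)
    vals = []
    for row, t, e in zip(s, time, event):
        k = min(math.ceil(t), n_intervals)
        if e == 1:
            lik = np.prod(row[:k - 1]) * (1 - row[k - 1])
        else:
            lik = np.prod(row[:k])
        vals.append(-math.log(lik))
    return np.array(vals)


class TestSurvivalNLL:
    def test_event_in_first_interval(self):
        o = out([0.5] + [0.9] * 29)
        assert survival_nll(o, [0.5], [1]) == pytest.approx(math.log(2), abs=1e-9)

    def test_censored_with_certain_survival(self):
        o = out([1 - 1e-7] + [0.5] * 29)
        assert survival_nll(o, [0.5], [0]) == pytest.approx(0.0, abs=1e-6)

    def test_event_in_second_interval(self):
        o = out([0.8, 0.4] + [0.9] * 28)
        expected = -(math.log(0.8) + math.log(0.6))
        assert survival_nll(o, [1.5], [1]) == pytest.approx(expected, abs=1e-9)

    def test_matches_brute_force_likelihood_oracle(self, rng):
        n = 500
        s = rng.uniform(0.05, 0.95, size=(n, 30))
        t = rng.uniform(0.1, 40.0, size=n)
        e = rng.integers(0, 2, size=n)
        mine = survival_nll(DiscreteSurvivalOutput(s), t, e, reduce="none")
        assert np.allclose(mine, nll_oracle(s, t, e), atol=1e-9)

    def test_interval_mapping_and_clamp(self):
        assert time_to_interval(np.array([0.2, 1.0, 29.7, 55.0])).tolist() == \
            [1, 1, 30, 30]
        with pytest.raises(ValueError):
            time_to_interval(np.array([0.0]))

    def test_cumulative_survival_monotone(self, rng):
        pred = SurvivalPredictor(6, hidden=(8,), seed=0)
        S = pred.predict(rng.uniform(size=(40, 6))).cumulative()
        assert np.all(np.diff(S, axis=1) <= 0)


class TestFiltering:
    def test_threshold_is_strict(self):
        batch = ImputedBatch(np.zeros((3, 2)), np.ones(3), np.ones(3, int),
                             task_loss=np.array([0.1, 0.5, 0.9]))
        assert filter_by_task_loss(batch, 0.6).keep.tolist() == [True, True, False]
        assert filter_by_task_loss(batch, np.inf).keep.all()
        assert not filter_by_task_loss(batch, 0.0).keep.any()
        # boundary: a loss exactly at t is dropped
        batch.task_loss = np.array([0.5, 0.5, 0.5])
        assert not filter_by_task_loss(batch, 0.5).keep.any()

    def test_kept_rows_satisfy_invariant(self, rng):
        losses = rng.uniform(size=10)
        batch = ImputedBatch(rng.uniform(size=(10, 2)), np.ones(10),
                             np.ones(10, int), task_loss=losses)
        kept = filter_by_task_loss(batch, 0.5).kept()
        assert np.all(kept.task_loss < 0.5)
        assert kept.X_hat.shape[0] == int((losses < 0.5).sum())


@pytest.fixture(scope="module")
def identity_translator():
    """Translator trained on paired data where B duplicates A."""
    rng = np.random.default_rng(3)
    z = rng.standard_normal((300, 2))
    X = z @ rng.normal(size=(2, 12))
    X = (X - X.min(0)) / (X.max(0) - X.min(0))
    spec = VAESpec(input_dim=12, n_layers_enc=2, n_layers_dec=2, latent_dim=4,
                   learning_rate=2e-3, epochs=150)
    return X, train_tdimpute(X[:240], X[:240], X[240:], X[240:], spec, seed=0)


class TestImputation:
    def test_identity_toy_recovers_inputs(self, identity_translator):
        X, tr = identity_translator
        batch = impute_B_from_A(X[240:], tr, tr, np.ones(60), np.ones(60, int))
        assert np.sqrt(((batch.X_hat - X[240:]) ** 2).mean()) < 0.05

    def test_label_carry_over_is_verbatim(self, identity_translator, rng):
        X, tr = identity_translator
        t = rng.uniform(0.5, 20, size=10)
        e = rng.integers(0, 2, size=10)
        batch = impute_B_from_A(X[:10], tr, tr, t, e, [f"s{i}" for i in range(10)])
        assert np.array_equal(batch.time, t)
        assert np.array_equal(batch.event, e)
        assert batch.source_ids == [f"s{i}" for i in range(10)]

    def test_imputation_deterministic(self, identity_translator):
        X, tr = identity_translator
        a = impute_B_from_A(X[:5], tr, tr, np.ones(5), np.zeros(5, int))
        b = impute_B_from_A(X[:5], tr, tr, np.ones(5), np.zeros(5, int))
        assert np.array_equal(a.X_hat, b.X_hat)

    def test_untrained_models_rejected(self, identity_translator):
        X, tr = identity_translator
        from survaug.vae import build_mlp_vae
        untrained = build_mlp_vae(VAESpec(input_dim=12, n_layers_enc=2,
                                          n_layers_dec=2, latent_dim=4))
        with pytest.raises(ValueError, match="not been trained"):
            impute_B_from_A(X[:2], untrained, tr, np.ones(2), np.ones(2, int))


class TestTDImpute:
    def test_val_rmse_on_noiseless_factor_data(self):
        rng = np.random.default_rng(5)
        z = rng.standard_normal((300, 3))
        XA = z @ rng.normal(size=(3, 16))
        XB = z @ rng.normal(size=(3, 12))
        XA = (XA - XA.min(0)) / (XA.max(0) - XA.min(0))
        XB = (XB - XB.min(0)) / (XB.max(0) - XB.min(0))
        spec = VAESpec(input_dim=16, n_layers_enc=2, n_layers_dec=2,
                       latent_dim=4, learning_rate=2e-3, epochs=200)
        tr = train_tdimpute(XA[:240], XB[:240], XA[240:], XB[240:], spec, seed=0)
        assert tr.history["val_rmse"].iloc[tr.best_epoch] < 0.02

    def test_reproducible_under_fixed_seed(self, identity_translator):
        X, _ = identity_translator
        spec = VAESpec(input_dim=12, n_layers_enc=2, n_layers_dec=2,
                       latent_dim=4, learning_rate=2e-3, epochs=10)
        a = train_tdimpute(X[:100], X[:100], X[100:140], X[100:140], spec, seed=9)
        b = train_tdimpute(X[:100], X[:100], X[100:140], X[100:140], spec, seed=9)
        assert a.history.equals(b.history)


@pytest.fixture(scope="module")
def predictor_dataset():
    return generate(SyntheticConfig(n_samples=400, d_A=16, d_B=10, k_latent=2,
                                    missing_fraction=0.5, seed=17),
                    test_frac=0.15, val_frac=0.3)


def small_cfg(method, **kw):
    base = dict(bs=16, bsOV=16, epochs=40, learning_rate=1e-3, seed=5)
    base.update(kw)
    return AugmentationConfig(method=method, **base)


@pytest.fixture(scope="module")
def small_models(predictor_dataset):
    ds = predictor_dataset
    _, xa_tr, xb_tr = ds.paired_rows("train")
    _, xa_val, xb_val = ds.paired_rows("val")
    spec = VAESpec(input_dim=16, n_layers_enc=2, n_layers_dec=2, latent_dim=3,
                   learning_rate=2e-3, epochs=80)
    tr = train_tdimpute(xa_tr, xb_tr, xa_val, xb_val, spec, seed=2)
    return {"translator": tr, "enc_A": tr, "dec_B": tr}


class TestTrainPredictor:
    def test_method_model_requirements(self, predictor_dataset):
        with pytest.raises(ValueError, match="requires"):
            train_predictor(predictor_dataset, small_cfg("cmvae_ov"), None)
        with pytest.raises(ValueError, match="translator"):
            train_predictor(predictor_dataset, small_cfg("tdimpute"), {})

    def test_gamma_zero_matches_unaugmented_trajectory(self, predictor_dataset,
                                                       small_models):
        ds = predictor_dataset
        p_ms, _ = train_predictor(ds, small_cfg("multisurv"))
        p_ov, _ = train_predictor(ds, small_cfg("cmvae_ov", gamma=0.0),
                                  small_models)
        for a, b in zip(p_ms.state_dict(), p_ov.state_dict()):
            assert np.array_equal(a, b)

    def test_oversampling_leaves_real_rows_untouched(self, predictor_dataset,
                                                     small_models):
        ds = predictor_dataset
        before = ds.X_B.copy()
        train_predictor(ds, small_cfg("cmvae_ov", gamma=0.8, t=5.0), small_models)
        assert np.array_equal(ds.X_B, before)

    def test_checkpoint_is_validation_ctd_argmax(self, predictor_dataset):
        p, hist = train_predictor(predictor_dataset, small_cfg("multisurv"))
        assert p.best_epoch == int(hist["val_ctd"].idxmax())

    def test_zero_threshold_filters_everything(self, predictor_dataset,
                                               small_models, caplog):
        # t=0 with strict inequality keeps nothing: training must still run
        p, hist = train_predictor(predictor_dataset,
                                  small_cfg("cmvae_ov", t=0.0), small_models)
        assert (hist["n_ov_kept"] == 0).all()

    def test_predictive_signal_on_informative_latents(self, predictor_dataset,
                                                      small_models):
        ds = predictor_dataset
        p, hist = train_predictor(ds, small_cfg("cmvae_ov", epochs=80, t=np.inf),
                                  small_models)
        ids_val, _ = ds.b_rows("val")
        t_val, e_val = ds.labels_for(ids_val)
        n_events = int(e_val.sum())
        n_comp = sum((t_val > t_val[i]).sum() for i in range(len(t_val))
                     if e_val[i] == 1)
        se = 0.5 / np.sqrt(n_comp)
        assert hist["val_ctd"].max() > 0.5 + 3 * se

    def test_static_union_uses_imputations(self, predictor_dataset,
                                           small_models):
        # the union method must not fail and must see more rows than real-only
        p, hist = train_predictor(predictor_dataset, small_cfg("tdimpute"),
                                  small_models)
        assert hist["val_ctd"].notna().all()

    def test_ov_method_needs_no_models(self, predictor_dataset):
        p, hist = train_predictor(predictor_dataset,
                                  small_cfg("ov", gamma=0.5))
        assert len(hist) == 40


class TestConfigValidation:
    def test_unknown_method(self):
        with pytest.raises(ValueError):
            AugmentationConfig(method="nope")

    def test_gamma_range(self):
        with pytest.raises(ValueError):
            AugmentationConfig(method="ov", gamma=1.5)

    def test_negative_threshold(self):
        with pytest.raises(ValueError):
            AugmentationConfig(method="cmvae_ov", t=-1.0)
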