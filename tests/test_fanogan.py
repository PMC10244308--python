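"""Anomaly-model training and the local anomaly score L = L_R + k * L_D."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from diffanomaly.fanogan import (AnomalyModel, ConstantScoreModel,
                                 IdentityStubModel, ModelConfig, anomaly_score,
                                 build_networks, load_model, reconstruct,
                                 save_model, train_encoder, train_wgan)
from diffanomaly.preprocess import (compute_difference, compute_norm_stats,
                                    consecutive_negative_pairs,
                                    extract_lesion_patches,
                                    extract_random_patches, normalize_patch)
from diffanomaly.synthetic import generate_subject

from conftest import tiny_config

TINY = ModelConfig(patch_side=8, latent_dim=8, width=64, batch_size=32,
                   gen_steps=150, encoder_steps=300, seed=0)


class _ArithmeticStub:
    """Forces L_R = 1 (y = x + 1) and L_D = 2 (features scaled by sqrt(2))."""

    patch_side = 8
    k = 0.1
    norm_stats = None

    def reconstruct(self, x):
        return np.asarray(x, dtype=np.float64) + 1.0

    def features(self, x_flat):
        return np.sqrt(2.0) * np.asarray(x_flat, dtype=np.float64)


@pytest.fixture(scope="module")
def trained_setup():
    """Tiny model trained on normal patches only, plus held-out score pools."""
    cfg = tiny_config(seed=17, n_negative=6, n_positive=2)
    train = []
    for s in range(5):
        subj = generate_subject(cfg, "negative", s)
        for (i, j) in consecutive_negative_pairs(subj):
            diff = compute_difference(subj.visits[i], subj.visits[j], (i, j))
            train += extract_random_patches(diff, 150, p=8, rng_seed=s).patches
    held_out = generate_subject(cfg, "negative", 77)
    i, j = consecutive_negative_pairs(held_out)[0]
    held_diff = compute_difference(held_out.visits[i], held_out.visits[j])
    normals = extract_random_patches(held_diff, 120, p=8, rng_seed=9).patches
    pos = generate_subject(cfg, "positive", 10_007)
    i, j = consecutive_negative_pairs(pos)[-1]
    pos_diff = compute_difference(pos.visits[i], pos.visits[j])
    lesions = extract_lesion_patches(pos_diff, pos.lesion_mask, p=8,
                                     n_per_lesion=30, rng_seed=4).patches
    stats = compute_norm_stats(train)
    X = np.stack([normalize_patch(p, stats) for p in train])
    G, D, gan_log = train_wgan(X, TINY)
    E, enc_log = train_encoder(X, G, D, TINY)
    model = AnomalyModel(G=G, D=D, E=E, config=TINY, norm_stats=stats)
    return {
        "model": model, "stats": stats, "X": X,
        "normals": np.stack([normalize_patch(p, stats) for p in normals]),
        "lesions": np.stack([normalize_patch(p, stats) for p in lesions]),
        "gan_log": gan_log, "enc_log": enc_log,
    }


class TestScoreFormula:
    def test_weighted_sum_with_default_k(self):
        x = np.zeros((8, 8))
        out = anomaly_score(x, _ArithmeticStub())
        assert out.L_R == pytest.approx(1.0)
        assert out.L_D == pytest.approx(2.0)
        assert out.L == pytest.approx(1.2)

    def test_perfect_reconstruction_scores_zero(self):
        x = np.linspace(-1, 1, 64).reshape(8, 8)
        out = anomaly_score(x, IdentityStubModel(patch_side=8))
        assert out.L_R == 0.0 and out.L_D == 0.0 and out.L == 0.0

    def test_identity_L_equals_components(self, trained_setup):
        out = anomaly_score(trained_setup["normals"], trained_setup["model"])
        np.testing.assert_array_equal(out.L, out.L_R + out.k * out.L_D)
        assert (out.L_R >= 0).all() and (out.L_D >= 0).all()

    def test_monotone_in_k(self):
        x = np.zeros((8, 8))
        scores = []
        for k in (0.0, 0.1, 0.5, 2.0):
            stub = _ArithmeticStub()
            stub.k = k
            scores.append(anomaly_score(x, stub).L)
        assert scores == sorted(scores)
        assert scores[0] < scores[-1]  # strictly increasing since L_D > 0

    def test_batch_order_invariance(self, trained_setup):
        x = trained_setup["normals"][:20]
        model = trained_setup["model"]
        perm = np.random.default_rng(0).permutation(20)
        direct = anomaly_score(x, model).L
        permuted = anomaly_score(x[perm], model).L
        np.testing.assert_array_equal(direct[perm], permuted)

    def test_constant_stub_scores_constant(self):
        model = ConstantScoreModel(patch_side=8, L=2.5)
        out = anomaly_score(np.zeros((5, 8, 8)), model)
        np.testing.assert_allclose(out.L, 2.5)

    def test_wrong_shape_rejected(self, trained_setup):
        with pytest.raises(ValueError, match="patch side"):
            anomaly_score(np.zeros((9, 9)), trained_setup["model"])


class TestReconstruct:
    def test_identity_stub_roundtrip(self):
        x = np.random.default_rng(1).normal(size=(8, 8))
        np.testing.assert_array_equal(reconstruct(x, IdentityStubModel(8)), x)

    def test_batch_order_preserved_no_crosstalk(self, trained_setup):
        x = trained_setup["normals"][:10]
        model = trained_setup["model"]
        y = reconstruct(x, model)
        assert y.shape == x.shape
        perm = np.array([3, 1, 4, 0, 2, 9, 8, 5, 7, 6])
        np.testing.assert_array_equal(reconstruct(x[perm], model), y[perm])


class TestTraining:
    def test_wgan_deterministic_given_seed(self, trained_setup):
        short = ModelConfig(**{**TINY.to_dict(), "gen_steps": 20})
        G1, D1, _ = train_wgan(trained_setup["X"], short)
        G2, D2, _ = train_wgan(trained_setup["X"], short)
        for a, b in zip(G1.params + D1.params, G2.params + D2.params):
            np.testing.assert_array_equal(a, b)

    def test_encoder_deterministic_given_seed(self, trained_setup):
        short = ModelConfig(**{**TINY.to_dict(), "gen_steps": 20,
                               "encoder_steps": 30})
        G, D, _ = train_wgan(trained_setup["X"], short)
        E1, _ = train_encoder(trained_setup["X"], G, D, short)
        E2, _ = train_encoder(trained_setup["X"], G, D, short)
        for a, b in zip(E1.params, E2.params):
            np.testing.assert_array_equal(a, b)

    def test_generator_collapses_to_degenerate_distribution(self):
        """Training on all-zero patches drives G's samples toward zero."""
        X = np.zeros((200, 8, 8))
        cfg = ModelConfig(patch_side=8, latent_dim=8, width=64, batch_size=32,
                          gen_steps=400, seed=1)
        G, _, _ = train_wgan(X, cfg)
        z = np.random.default_rng(2).normal(size=(256, cfg.latent_dim))
        assert np.abs(G(z)).mean() < 0.1

    def test_critic_ranks_real_above_generated(self, trained_setup):
        """The Wasserstein critic separates training data from G's samples."""
        model = trained_setup["model"]
        z = np.random.default_rng(3).normal(size=(200, TINY.latent_dim))
        fake = model.G(z)
        s_real = model.D(trained_setup["X"][:200].reshape(200, -1))
        s_fake = model.D(fake)
        assert s_real.mean() > s_fake.mean() + 0.05

    def test_encoder_inverts_generator_range(self, trained_setup):
        """x = G(z0) reconstructs better than a patch off G's range."""
        model = trained_setup["model"]
        rng = np.random.default_rng(4)
        z0 = rng.normal(size=(64, TINY.latent_dim))
        on_range = model.G(z0).reshape(64, 8, 8)
        off_range = rng.uniform(-1, 1, size=(64, 8, 8))
        err_on = anomaly_score(on_range, model).L_R.mean()
        err_off = anomaly_score(off_range, model).L_R.mean()
        assert err_on < err_off

    def test_untrained_encoder_still_scores(self, trained_setup):
        cfg = ModelConfig(**{**TINY.to_dict(), "encoder_steps": 0})
        E, log = train_encoder(trained_setup["X"], trained_setup["model"].G,
                               trained_setup["model"].D, cfg)
        model = AnomalyModel(G=trained_setup["model"].G,
                             D=trained_setup["model"].D, E=E, config=cfg)
        out = anomaly_score(trained_setup["normals"][:5], model)
        assert np.isfinite(out.L).all()
        assert log["encoder_loss"] == []

    def test_too_few_patches_rejected(self):
        with pytest.raises(ValueError, match="batch_size"):
            train_wgan(np.zeros((8, 8, 8)), TINY)

    def test_loss_log_structure(self, trained_setup):
        log = trained_setup["gan_log"]
        assert len(log["critic_loss"]) == TINY.gen_steps
        assert np.isfinite(log["critic_loss"]).all()
        assert len(trained_setup["enc_log"]["encoder_loss"]) == TINY.encoder_steps


class TestRecovery:
    def test_lesion_patches_dominate_normal_patches(self, trained_setup):
        """Core recovery property: future-lesion patches score higher than
        normal patches after normal-only training (one-sided Mann-Whitney)."""
        Ln = anomaly_score(trained_setup["normals"], trained_setup["model"]).L
        Ll = anomaly_score(trained_setup["lesions"], trained_setup["model"]).L
        assert np.median(Ll) > np.median(Ln)
        p = mannwhitneyu(Ll, Ln, alternative="greater").pvalue
        assert p < 0.01


class TestSerialization:
    def test_save_load_reproduces_scores_exactly(self, trained_setup, tmp_path):
        model = trained_setup["model"]
        path = tmp_path / "model.npz"
        save_model(model, path)
        loaded = load_model(path)
        x = trained_setup["normals"][:16]
        np.testing.assert_array_equal(anomaly_score(x, loaded).L,
                                      anomaly_score(x, model).L)
        assert loaded.k == model.k
        assert loaded.norm_stats.lo == model.norm_stats.lo

    def test_networks_initialise_identically_from_config(self):
        G1, D1, E1 = build_networks(TINY)
        G2, D2, E2 = build_networks(TINY)
        for a, b in zip(G1.params + D1.params + E1.params,
                        G2.params + D2.params + E2.params):
            np.testing.assert_array_equal(a, b)
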