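import numpy as np
import pytest

from lcmil import (
    ConfigError,
    InfeasibleError,
    MILModel,
    TrainConfig,
    attention_pool,
    build_bags,
    focal_gamma,
    focal_loss,
    train,
)
from lcmil.mil import _bag_gradients, _init_params, _sigmoid


class TestBagConstruction:
    def test_pos_neg_split(self, labeled_patches):
        bags = build_bags(labeled_patches, 1000, 10, pos_fraction=0.5, seed=1)
        labels = [b.label for b in bags]
        assert len(bags) == 1000
        assert sum(labels) == 500

    def test_bag_purity(self, labeled_patches):
        """Eq. constraint: positive bags draw only from S_P, negative from S_N."""
        pos = set(labeled_patches.positive_ids.tolist())
        neg = set(labeled_patches.negative_ids.tolist())
        for bag in build_bags(labeled_patches, 50, 7, seed=2):
            pool = pos if bag.label == 1 else neg
            assert set(bag.instance_ids.tolist()) <= pool

    def test_singleton_bag_label_matches_instance(self, labeled_patches):
        for bag in build_bags(labeled_patches, 40, 1, seed=3):
            assert labeled_patches.noisy_labels[bag.instance_ids[0]] == bag.label

    def test_sampling_with_replacement(self, labeled_patches):
        """A tiny pool must repeat instances inside a size-10 bag."""
        import dataclasses

        tiny = dataclasses.replace(labeled_patches)
        labels = np.zeros(len(tiny), dtype=np.int8)
        labels[:2] = 1  # |S_P| = 2
        tiny = tiny.with_labels(labels)
        bags = [b for b in build_bags(tiny, 20, 10, seed=4) if b.label == 1]
        assert any(len(set(b.instance_ids.tolist())) < len(b) for b in bags)

    def test_empty_pool_rejected(self, labeled_patches):
        empty = labeled_patches.with_labels(np.zeros(len(labeled_patches), dtype=np.int8))
        with pytest.raises(InfeasibleError):
            build_bags(empty, 10, 5, pos_fraction=0.5, seed=0)


class TestAttentionPooling:
    def _params(self, d_h=6, d_a=4, seed=0):
        rng = np.random.default_rng(seed)
        return rng.normal(size=(d_a, d_h)), rng.normal(size=(1, d_a))

    def test_single_instance_weight_is_exactly_one(self):
        V, W = self._params()
        h = np.random.default_rng(1).normal(size=(1, 6))
        z, w = attention_pool(h, V, W)
        assert w[0] == 1.0
        np.testing.assert_array_equal(z, h[0])

    def test_identical_embeddings_uniform_weights(self):
        V, W = self._params()
        h = np.tile(np.random.default_rng(2).normal(size=6), (5, 1))
        z, w = attention_pool(h, V, W)
        np.testing.assert_allclose(w, 1 / 5, rtol=1e-9)
        np.testing.assert_allclose(z, h[0], rtol=1e-9)

    def test_matches_direct_formula(self):
        V, W = self._params()
        H = np.random.default_rng(3).normal(size=(3, 6))
        z, w = attention_pool(H, V, W)
        scores = np.array([(W @ np.tanh(V @ h)).item() for h in H])
        expect_w = np.exp(scores - scores.max())
        expect_w /= expect_w.sum()
        np.testing.assert_allclose(w, expect_w, rtol=1e-12)
        np.testing.assert_allclose(z, (expect_w[:, None] * H).sum(axis=0), rtol=1e-12)

    def test_weights_sum_to_one(self, rng):
        V, W = self._params()
        for _ in range(100):
            n = int(rng.integers(1, 51))
            _, w = attention_pool(rng.normal(size=(n, 6)), V, W)
            assert abs(w.sum() - 1.0) < 1e-6
            assert (w >= 0).all()


class TestBagScoring:
    def _model(self, variant, n_features=12, seed=0):
        cfg = TrainConfig(embed_dim=8, attn_dim=5, seed=seed)
        rng = np.random.default_rng(seed)
        return MILModel(variant, _init_params(variant, n_features, cfg, rng))

    def test_zero_classifier_gives_half(self):
        m = self._model("attention")
        m.params["g"][:] = 0.0
        phi = np.random.default_rng(0).normal(size=(4, 12))
        assert m.bag_score(phi) == 0.5

    def test_logistic_is_monotone_in_logit(self):
        """Scaling g along a positive-logit direction drives P monotonically to 1."""
        m = self._model("attention")
        phi = np.random.default_rng(1).normal(size=(3, 12))
        z, _ = attention_pool(m.embed(phi), m.params["V"], m.params["W"])
        direction = z / np.linalg.norm(z)  # <direction, z> > 0
        scores = []
        for scale in (0.1, 1.0, 10.0, 100.0):
            m.params["g"] = scale * direction
            scores.append(m.bag_score(phi))
        assert scores == sorted(scores)
        assert scores[-1] > 0.99

    def test_minet_is_mean_of_instance_scores(self):
        m = self._model("minet")
        phi = np.random.default_rng(2).normal(size=(7, 12))
        expected = np.mean([m.bag_score(phi[i : i + 1]) for i in range(7)])
        assert m.bag_score(phi) == pytest.approx(expected, abs=1e-15)

    def test_minet_mean_example(self):
        """Instance scores (0.2, 0.4, 0.9) average to 0.5."""
        m = self._model("minet", n_features=1)
        # one embedding dim active: score = sigmoid(g1 * tanh(a1*phi))
        m.params["A"][:] = 0.0
        m.params["A"][0, 0] = 1.0
        m.params["b"][:] = 0.0
        m.params["g"][:] = 0.0
        m.params["g"][0] = 1.0
        logits = np.log(np.array([0.2, 0.4, 0.9]) / (1 - np.array([0.2, 0.4, 0.9])))
        m.params["g"][0] = 4.0  # tanh embedding covers logits in (-4, 4)
        phi = np.arctanh(logits / 4.0)[:, None]
        assert m.bag_score(phi) == pytest.approx(0.5, abs=1e-12)

    def test_all_instances_scored_one(self):
        m = self._model("minet")
        m.params["g"][:] = 1e3
        phi = np.abs(np.random.default_rng(3).normal(size=(4, 12)))
        m.params["A"][:] = np.abs(m.params["A"])
        m.params["b"][:] = 1.0
        assert m.bag_score(phi) == pytest.approx(1.0, abs=1e-9)


class TestFocalLoss:
    def test_reference_value(self):
        # Y=1, P=0.5, gamma=3 -> -(0.5)^3 ln(0.5)
        assert focal_loss(1, 0.5, 3) == pytest.approx(0.125 * np.log(2), rel=1e-12)

    def test_gamma_schedule(self):
        assert focal_gamma(0.0) == 5.0
        assert focal_gamma(0.1999) == 5.0
        assert focal_gamma(0.2) == 3.0
        assert focal_gamma(1.0) == 3.0

    def test_gamma_zero_is_cross_entropy(self, rng):
        p = rng.uniform(0.01, 0.99, size=50)
        y = rng.integers(0, 2, size=50)
        bce = -(y * np.log(p) + (1 - y) * np.log(1 - p))
        np.testing.assert_allclose(focal_loss(y, p, 0.0), bce, rtol=1e-12)

    def test_loss_vanishes_for_confident_correct(self):
        assert focal_loss(1, 1 - 1e-9, 3) < 1e-8
        assert focal_loss(0, 1e-9, 3) < 1e-8

    def test_strictly_decreasing_in_p_for_positive(self):
        p = np.linspace(0.01, 0.99, 200)
        losses = focal_loss(1, p, 3.0)
        assert np.all(np.diff(losses) < 0)


class TestGradients:
    @pytest.mark.parametrize("variant", ["attention", "minet"])
    @pytest.mark.parametrize("y", [0, 1])
    def test_analytic_gradients_match_finite_differences(self, variant, y):
        cfg = TrainConfig(embed_dim=5, attn_dim=4)
        rng = np.random.default_rng(17)
        model = MILModel(variant, _init_params(variant, 6, cfg, rng))
        model.params["g"] = rng.normal(0, 0.5, size=5)  # move off near-zero init
        phi = rng.normal(size=(4, 6))

        def loss_at():
            p = model.bag_score(phi)
            return float(focal_loss(y, p, focal_gamma(model.bag_score(phi))))

        _, _, grads = _bag_gradients(model, phi, y)
        eps = 1e-6
        for name, grad in grads.items():
            flat = model.params[name].reshape(-1)
            for idx in range(0, flat.size, max(1, flat.size // 5)):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss_at()
                flat[idx] = orig - eps
                down = loss_at()
                flat[idx] = orig
                fd = (up - down) / (2 * eps)
                assert grad.reshape(-1)[idx] == pytest.approx(fd, rel=1e-4, abs=1e-7)


class TestTraining:
    def test_lr_decay_arithmetic(self):
        cfg = TrainConfig(lr0=5e-5, lr_decay=0.5, lr_decay_every=100)
        assert cfg.lr_at(0) == 5e-5
        assert cfg.lr_at(99) == 5e-5
        assert cfg.lr_at(100) == 2.5e-5
        assert cfg.lr_at(200) == pytest.approx(1.25e-5)

    def test_zero_bags_rejected(self):
        with pytest.raises(ConfigError):
            TrainConfig(n_bags=0)

    def test_training_is_deterministic(self, labeled_patches, patch_features):
        cfg = TrainConfig(n_bags=60, bag_size=5, seed=9)
        probe = patch_features[:3]
        runs = []
        for _ in range(2):
            m = train(labeled_patches, patch_features, cfg, variant="attention")
            runs.append([m.bag_score(probe[i : i + 1]) for i in range(3)])
        assert runs[0] == runs[1]

    def test_history_records_loss_and_lr(self, trained_attention):
        hist = trained_attention.history
        assert len(hist) == trained_attention.config.n_bags
        assert all(np.isfinite(l) for _, l, _ in hist)
        assert hist[0][2] == trained_attention.config.lr0
        assert hist[150][2] == trained_attention.config.lr0 * 0.5

    def test_learnable_at_moderate_noise(self, labeled_patches, patch_features,
                                         trained_attention):
        """Patch scores of the trained model rank lesion above background."""
        from sklearn.metrics import roc_auc_score

        scores = trained_attention.instance_scores(patch_features)
        assert roc_auc_score(labeled_patches.true_labels, scores) > 0.8


def test_sigmoid_is_stable_at_extremes():
    assert _sigmoid(1000.0) == 1.0
    assert _sigmoid(-1000.0) == pytest.approx(0.0, abs=1e-300)
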