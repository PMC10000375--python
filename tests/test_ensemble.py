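"""Architecture fidelity, network gradients, subspace sampling, fusion and
diversity statistics."""

import numpy as np
import pytest

from retinopipe import ensemble as ens
from retinopipe import nn


class TestBuildArchitecture:
    def test_full_scale_layer_table(self):
        arch = ens.build_architecture((224, 224, 3), 3, scale=1.0)
        convs = [l for l in arch.layers if l.kind == "conv"]
        assert [l.filters for l in convs] == (
            [64] * 2 + [128] * 2 + [256] * 4 + [512] * 4 + [512] * 4
        )
        assert all(l.kernel == (3, 3) and l.stride == (1, 1) and l.padding == 1 for l in convs)
        pools = [l for l in arch.layers if l.kind == "maxpool"]
        assert len(pools) == 5
        assert all(l.kernel == (2, 2) and l.stride == (2, 2) for l in pools)
        fcs = [l for l in arch.layers if l.kind == "fc"]
        assert [l.filters for l in fcs] == [4096, 3]

    def test_scaled_architecture_keeps_topology(self):
        arch = ens.build_architecture((64, 64, 5), 3, scale=0.125)
        convs = [l.filters for l in arch.layers if l.kind == "conv"]
        assert convs == [8] * 2 + [16] * 2 + [32] * 4 + [64] * 4 + [64] * 4
        shapes = ens.shape_propagate(arch)
        pool_shapes = [
            s for s, l in zip(shapes, arch.layers) if l.kind == "maxpool"
        ]
        assert [s[:2] for s in pool_shapes] == [
            (32, 32), (16, 16), (8, 8), (4, 4), (2, 2),
        ]

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            ens.build_architecture((100, 100, 3), 3)

    def test_output_width_equals_class_count(self):
        arch = ens.build_architecture((64, 64, 3), 7, scale=0.25)
        assert arch.layers[-1].filters == 7


class TestShapePropagate:
    def test_pooling_stage_shapes_at_full_scale(self):
        arch = ens.build_architecture((224, 224, 3), 3, scale=1.0)
        shapes = ens.shape_propagate(arch)
        pool_shapes = [s for s, l in zip(shapes, arch.layers) if l.kind == "maxpool"]
        assert pool_shapes[0] == (112, 112, 64)
        assert pool_shapes[2] == (28, 28, 256)
        assert pool_shapes[4] == (7, 7, 512)

    def test_conv_preserves_spatial_dims(self):
        arch = ens.build_architecture((224, 224, 3), 3, scale=1.0)
        shapes = ens.shape_propagate(arch)
        assert shapes[0] == (224, 224, 64)  # first conv
        assert shapes[-3] == (4096,)        # fc + relu
        assert shapes[-1] == (3,)

    def test_empty_architecture_returns_nothing(self):
        arch = ens.CNNArchitecture(layers=[], input_shape=(32, 32, 3), n_classes=2)
        assert ens.shape_propagate(arch) == []


class TestNetworkNumerics:
    def test_finite_difference_gradients(self):
        rng = np.random.default_rng(0)
        net = nn.Network([
            nn.Conv3x3(3, 4, rng), nn.ReLU(), nn.MaxPool2x2(),
            nn.Flatten(), nn.Dense(4 * 4 * 4, 3, rng),
        ])
        x = rng.standard_normal((3, 8, 8, 3)).astype(np.float32)
        y = np.array([0, 1, 2])
        logits = net.forward(x, train=True)
        _, grad = nn.cross_entropy_grad(logits, y)
        net.backward(grad)
        params = net.params()
        eps = 1e-3
        for p, g in (params[0], params[-2]):  # conv weight, dense weight
            idx = tuple(0 for _ in p.shape)
            orig = p[idx]
            p[idx] = orig + eps
            l1, _ = nn.cross_entropy_grad(net.forward(x), y)
            p[idx] = orig - eps
            l2, _ = nn.cross_entropy_grad(net.forward(x), y)
            p[idx] = orig
            assert (l1 - l2) / (2 * eps) == pytest.approx(g[idx], abs=2e-3)

    def test_conv_matches_direct_correlation(self):
        from scipy import signal

        rng = np.random.default_rng(1)
        x = rng.standard_normal((2, 8, 8, 3)).astype(np.float32)
        conv = nn.Conv3x3(3, 4, rng)
        out = conv.forward(x)
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        for n in range(2):
            for f in range(4):
                ref = sum(
                    signal.correlate2d(xp[n, :, :, c], conv.w[:, :, c, f], mode="valid")
                    for c in range(3)
                ) + conv.b[f]
                assert np.allclose(out[n, :, :, f], ref, atol=1e-5)

    def test_batchnorm_normalizes_in_training(self):
        rng = np.random.default_rng(2)
        bn = nn.BatchNorm2d(4)
        x = (rng.standard_normal((8, 6, 6, 4)) * 3 + 5).astype(np.float32)
        out = bn.forward(x, train=True)
        assert np.allclose(out.mean(axis=(0, 1, 2)), 0, atol=1e-5)
        assert np.allclose(out.std(axis=(0, 1, 2)), 1, atol=1e-3)


class TestSampleSubspaces:
    def test_full_fraction_selects_everything(self):
        masks = ens.sample_subspaces(5, 1.0, 3, seed=0)
        assert masks.all()

    def test_ceil_of_fraction(self):
        masks = ens.sample_subspaces(6, 0.5, 4, seed=1)
        assert masks.shape == (4, 6)
        assert (masks.sum(axis=1) == 3).all()

    def test_deterministic(self):
        a = ens.sample_subspaces(8, 0.6, 5, seed=7)
        b = ens.sample_subspaces(8, 0.6, 5, seed=7)
        assert np.array_equal(a, b)


class TestAugment:
    def _cfg(self, **kw):
        return ens.EnsembleConfig(**kw)

    def test_zero_ranges_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.random((16, 16, 3)).astype(np.float32)
        out = ens.augment(img, self._cfg(), rng)
        assert np.array_equal(out, img)

    def test_full_rotation_is_near_identity(self):
        rng = np.random.default_rng(1)
        img = np.zeros((17, 17, 1), dtype=np.float32)
        img[5:12, 5:12, 0] = 1.0

        class Deg360Rng:
            def random(self):
                return 0.5

            def uniform(self, lo, hi):
                return hi  # always the top of the range

        out = ens.augment(img, self._cfg(rotation_range=360.0), Deg360Rng())
        assert np.allclose(out, img, atol=1e-3)

    def test_deterministic_given_rng_state(self):
        img = np.random.default_rng(3).random((16, 16, 2)).astype(np.float32)
        cfg = self._cfg(rotation_range=20, width_shift_range=0.1, horizontal_flip=True)
        a = ens.augment(img, cfg, np.random.default_rng(9))
        b = ens.augment(img, cfg, np.random.default_rng(9))
        assert np.array_equal(a, b)


class TestFusion:
    def _model(self, weights, n_scores):
        return ens.EnsembleModel(
            members=[], subspace_masks=np.ones((len(weights), 1), bool),
            weights=np.asarray(weights, float), class_names=["a", "b", "c"],
            architecture=None,
        )

    def test_tie_breaks_to_lowest_class_index(self):
        scores = np.array([[[1.0, 0.0, 0.0]], [[0.0, 1.0, 0.0]]])
        fused = np.einsum("j,jnm->nm", np.array([0.5, 0.5]), scores)
        assert fused[0].tolist() == [0.5, 0.5, 0.0]
        assert int(fused[0].argmax()) == 0

    def test_degenerate_weights_reproduce_single_member(self):
        rng = np.random.default_rng(0)
        scores = rng.dirichlet(np.ones(3), size=(4, 5))  # (members, samples, classes)
        w = np.array([1.0, 0.0, 0.0, 0.0])
        fused = np.einsum("j,jnm->nm", w, scores)
        assert np.allclose(fused, scores[0])

    def test_fused_scores_are_convex_combination(self):
        rng = np.random.default_rng(1)
        scores = rng.dirichlet(np.ones(4), size=(3, 10))
        w = np.array([0.2, 0.5, 0.3])
        fused = np.einsum("j,jnm->nm", w, scores)
        assert np.allclose(fused.sum(axis=1), 1.0)
        assert np.all(fused <= scores.max(axis=0) + 1e-12)
        assert np.all(fused >= scores.min(axis=0) - 1e-12)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError, match="weights"):
            ens.EnsembleConfig(weights=[0.5, 0.6])
        with pytest.raises(ValueError, match="weights"):
            ens.EnsembleConfig(weights=[-0.5, 1.5])


class TestDiversity:
    def test_self_diversity_zero(self):
        p = np.array([0, 1, 2, 0])
        assert ens.classifier_diversity(p, p) == 0.0

    def test_total_disagreement(self):
        assert ens.classifier_diversity([0, 0], [1, 1]) == 1.0

    def test_fractional_disagreement(self):
        a = np.zeros(100, int)
        b = np.zeros(100, int)
        b[:25] = 1
        assert ens.classifier_diversity(a, b) == 0.25

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ens.classifier_diversity(np.empty(0), np.empty(0))

    def test_ensemble_diversity_mean_of_pairs(self):
        # members with pairwise disagreements 0.1, 0.2, 0.3 -> mean 0.2
        n = 10
        a = np.zeros(n, int)
        b = a.copy(); b[:1] = 1            # CD(a,b) = 0.1
        c = a.copy(); c[1:4] = 1           # CD(a,c) = 0.3, CD(b,c) = 0.4... construct directly
        preds = np.stack([a, b, c])
        expected = np.mean([
            ens.classifier_diversity(x, y)
            for i, x in enumerate(preds) for j, y in enumerate(preds) if i != j
        ])
        assert ens.ensemble_diversity(preds) == pytest.approx(expected)

    def test_two_member_ensemble_equals_pair_diversity(self):
        a = np.array([0, 1, 1, 2])
        b = np.array([0, 1, 2, 2])
        assert ens.ensemble_diversity(np.stack([a, b])) == pytest.approx(
            ens.classifier_diversity(a, b)
        )

    def test_single_member_rejected(self):
        with pytest.raises(ValueError, match="2 members"):
            ens.ensemble_diversity(np.zeros((1, 5)))


class TestTraining:
    def _toy_data(self, n=12, size=32, planes=2, seed=0):
        rng = np.random.default_rng(seed)
        y = np.arange(n) % 3
        x = rng.random((n, size, size, planes), dtype=np.float32) * 0.1
        for i, label in enumerate(y):
            x[i, :, :, 0] += label * 0.4  # linearly separable brightness cue
        return x, y

    def test_one_epoch_smoke(self):
        x, y = self._toy_data()
        arch = ens.build_architecture((32, 32, 2), 3, scale=0.05)
        cfg = ens.EnsembleConfig(epochs=1, scale=0.05)
        net, losses = ens.train_member(x, y, arch, np.ones(2, bool), cfg, seed=0)
        assert len(losses) == 1 and np.isfinite(losses[0])

    def test_loss_decreases_over_epochs(self):
        x, y = self._toy_data(n=24)
        arch = ens.build_architecture((32, 32, 2), 3, scale=0.05)
        cfg = ens.EnsembleConfig(epochs=8, scale=0.05)
        net, losses = ens.train_member(x, y, arch, np.ones(2, bool), cfg, seed=1)
        assert losses[-1] < losses[0]

    def test_identical_seeds_identical_weights(self):
        x, y = self._toy_data()
        arch = ens.build_architecture((32, 32, 2), 3, scale=0.05)
        cfg = ens.EnsembleConfig(epochs=2, scale=0.05)
        net1, _ = ens.train_member(x, y, arch, np.ones(2, bool), cfg, seed=5)
        net2, _ = ens.train_member(x, y, arch, np.ones(2, bool), cfg, seed=5)
        for (p1, _), (p2, _) in zip(net1.params(), net2.params()):
            assert np.array_equal(p1, p2)

    def test_masked_planes_are_ignored(self):
        x, y = self._toy_data()
        arch = ens.build_architecture((32, 32, 2), 3, scale=0.05)
        cfg = ens.EnsembleConfig(epochs=1, scale=0.05)
        mask = np.array([True, False])
        x2 = x.copy()
        x2[..., 1] = 999.0  # garbage in the masked plane must not matter
        net1, l1 = ens.train_member(x, y, arch, mask, cfg, seed=2)
        net2, l2 = ens.train_member(x2, y, arch, mask, cfg, seed=2)
        assert l1 == l2

    def test_save_load_roundtrip(self, tmp_path):
        x, y = self._toy_data()
        cfg = ens.EnsembleConfig(n_members=2, epochs=1, scale=0.05)
        model = ens.train_ensemble(x, y, cfg, class_names=["a", "b", "c"])
        scores = ens.predict_ensemble(model, x)
        ens.save_model(model, tmp_path)
        loaded = ens.load_model(tmp_path)
        scores2 = ens.predict_ensemble(loaded, x)
        assert np.allclose(scores.fused, scores2.fused)
        assert np.array_equal(scores.predicted, scores2.predicted)


class TestValidationWeighting:
    def test_weights_proportional_to_member_accuracy(self):
        rng = np.random.default_rng(4)
        n = 18
        y = np.arange(n) % 3
        x = rng.random((n, 32, 32, 2), dtype=np.float32) * 0.1
        for i, label in enumerate(y):
            x[i, :, :, 0] += label * 0.4
        cfg = ens.EnsembleConfig(n_members=3, epochs=3, scale=0.05, seed=0)
        model = ens.train_ensemble(x, y, cfg, class_names=["a", "b", "c"])
        weights = ens.fit_validation_weights(model, x, y)
        assert weights.shape == (3,)
        assert np.all(weights >= 0) and weights.sum() == pytest.approx(1.0)
        scores = ens.predict_ensemble(model, x)
        accs = np.array([float(np.mean(s.argmax(1) == y)) for s in scores.member_scores])
        if accs.sum() > 0:
            assert np.allclose(weights, accs / accs.sum())
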