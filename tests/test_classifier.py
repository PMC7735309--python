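"""Patch extraction, balanced set assembly, CNN training and prediction."""

import dataclasses

import numpy as np
import pytest

from shearwf.classifier import (
    ClassifierEnsemble,
    ClassifierSpec,
    PatchSet,
    TrainConfig,
    build_training_set,
    extract_patch,
    normalize_image,
    predict_wavefront_set,
    train_classifier,
)
from shearwf.errors import InvalidConfigError, TrainingError
from shearwf.shearlets import CoefficientVolume
from shearwf.wavefront import DigitalWavefrontSet
from shearwf._nn import PatchCNN


def make_volume(L=3, M=64, fill=None, rng=None):
    if fill is not None:
        data = np.full((L, M, M), fill, dtype=float)
    else:
        data = rng.standard_normal((L, M, M))
    return CoefficientVolume(data=data, system_id="test")


class TestExtractPatch:
    def test_corner_center_takes_first_window(self, rng):
        vol = make_volume(rng=rng)
        patch = extract_patch(vol, (10, 10))
        assert np.array_equal(patch, vol.data[:, 0:21, 0:21])

    def test_all_ones_volume_gives_all_ones_patch(self):
        patch = extract_patch(make_volume(fill=1.0), (30, 30))
        assert patch.shape == (3, 21, 21) and np.all(patch == 1.0)

    def test_matches_independent_slicing_oracle(self, rng):
        vol = make_volume(L=4, rng=rng)
        for _ in range(20):
            r, c = rng.integers(10, 54, size=2)
            expected = np.array([vol.data[l][r - 10 : r + 11, c - 10 : c + 11]
                                 for l in range(4)])
            assert np.array_equal(extract_patch(vol, (int(r), int(c))), expected)

    @pytest.mark.parametrize("center", [(9, 30), (30, 9), (54, 30), (30, 54)])
    def test_border_centers_rejected(self, center, rng):
        with pytest.raises(ValueError):
            extract_patch(make_volume(rng=rng), center)


def _toy_truths(n_images, M=64, n_orientations=8, seed=0):
    """Truths with a vertical edge (bin 0) at a per-image column."""
    rng = np.random.default_rng(seed)
    truths = []
    for _ in range(n_images):
        wf = DigitalWavefrontSet((M, M), n_orientations=n_orientations)
        col = int(rng.integers(15, M - 15))
        for r in range(12, M - 12):
            wf.add(r, col, 0)
        truths.append(wf)
    return truths


class TestBuildTrainingSet:
    def test_ten_patches_per_image(self, rng):
        truths = _toy_truths(10)
        vols = [make_volume(rng=rng) for _ in range(10)]
        cfg = TrainConfig(patches_per_image=10, epochs=1, n_train=10, n_val=2, n_test=2)
        ps = build_training_set(vols, truths, "edge", cfg, rng)
        assert len(ps.X) == 100
        for i in range(10):
            centers = ps.centers[ps.source_ids == i]
            assert len(np.unique(centers, axis=0)) == len(centers) == 10

    def test_classes_balanced(self, rng):
        truths = _toy_truths(20)
        vols = [make_volume(rng=rng) for _ in range(20)]
        cfg = TrainConfig(patches_per_image=10, epochs=1, n_train=20, n_val=2, n_test=2)
        for task in ["edge", "orientation:0"]:
            ps = build_training_set(vols, truths, task, cfg, rng)
            ratio = ps.y.sum() / (len(ps.y) - ps.y.sum())
            assert 0.9 <= ratio <= 1.1

    def test_labels_agree_with_truth_lookup(self, rng):
        truths = _toy_truths(10)
        vols = [make_volume(rng=rng) for _ in range(10)]
        cfg = TrainConfig(patches_per_image=10, epochs=1, n_train=10, n_val=2, n_test=2)
        ps = build_training_set(vols, truths, "orientation:0", cfg, rng)
        for x, y, (r, c), src in zip(ps.X, ps.y, ps.centers, ps.source_ids):
            bins = truths[src].elements.get((int(r), int(c)), set())
            assert y == (1.0 if 0 in bins else 0.0)
            assert np.array_equal(x, extract_patch(vols[src], (r, c)))

    def test_task_without_positives_errors(self, rng):
        truths = _toy_truths(5)
        vols = [make_volume(rng=rng) for _ in range(5)]
        cfg = TrainConfig(patches_per_image=10, epochs=1, n_train=5, n_val=1, n_test=1)
        with pytest.raises(TrainingError):
            build_training_set(vols, truths, "orientation:4", cfg, rng)


class TestSpecValidation:
    def test_topology_is_fixed(self):
        with pytest.raises(InvalidConfigError):
            ClassifierSpec(conv_channels=(8, 16, 32))
        with pytest.raises(InvalidConfigError):
            ClassifierSpec(pool=3)

    def test_threshold_range(self):
        model = PatchCNN((3, 21, 21), (4, 4, 4, 4), 16, seed=0)
        with pytest.raises(InvalidConfigError):
            ClassifierEnsemble(orientation_models=[model] * 8, edge_model=model,
                               n_orientations=8, threshold=1.5)


class TestTraining:
    @staticmethod
    def _separable_patchset(n=200, seed=0):
        """Two constant patch patterns: trivially separable."""
        rng = np.random.default_rng(seed)
        y = (np.arange(n) % 2).astype(float)
        X = np.empty((n, 3, 21, 21), dtype=np.float32)
        for i in range(n):
            base = 1.0 if y[i] else -1.0
            X[i] = base + 0.05 * rng.standard_normal((3, 21, 21))
        return PatchSet(X=X, y=y, centers=np.zeros((n, 2), int),
                        source_ids=np.zeros(n, int), task="edge")

    def test_separable_patterns_reach_high_accuracy(self):
        ps = self._separable_patchset()
        spec = ClassifierSpec(conv_channels=(4, 4, 8, 8), dense_units=32)
        cfg = TrainConfig(epochs=5, batch_size=32, n_train=10, n_val=2, n_test=2, seed=0)
        model, history = train_classifier(ps, spec, cfg)
        assert history[-1]["val_f"] >= 0.99

    def test_zero_epochs_returns_initialized_model(self):
        ps = self._separable_patchset(50)
        spec = ClassifierSpec(conv_channels=(4, 4, 8, 8), dense_units=32)
        cfg = TrainConfig(epochs=1, n_train=10, n_val=2, n_test=2, seed=3)
        fresh = PatchCNN((3, 21, 21), spec.conv_channels, spec.dense_units, seed=3)
        model, history = train_classifier(
            ps, spec, dataclasses.replace(cfg, epochs=1), val_fraction=0.2
        )
        assert model.weights_hash() != fresh.weights_hash()

    def test_fixed_seed_reproduces_weights_hash(self):
        ps = self._separable_patchset(100)
        spec = ClassifierSpec(conv_channels=(4, 4, 8, 8), dense_units=32)
        cfg = TrainConfig(epochs=2, n_train=10, n_val=2, n_test=2, seed=11)
        m1, _ = train_classifier(ps, spec, cfg)
        m2, _ = train_classifier(ps, spec, cfg)
        assert m1.weights_hash() == m2.weights_hash()


class _ConstantModel:
    """Stub classifier with a fixed output probability."""

    input_shape = None

    def __init__(self, p, input_shape):
        self.p = p
        self.input_shape = input_shape

    def predict_proba(self, x, batch_size=512):
        return np.full(len(x), self.p)


class TestPrediction:
    def _ensemble(self, p_edge, p_orient, system):
        shape = (system.n_slices, 21, 21)
        return ClassifierEnsemble(
            orientation_models=[_ConstantModel(p_orient, shape) for _ in range(8)],
            edge_model=_ConstantModel(p_edge, shape),
            n_orientations=8,
        )

    def test_constant_zero_models_give_empty_set(self, system64):
        ens = self._ensemble(0.0, 0.0, system64)
        wf = predict_wavefront_set(np.random.default_rng(0).random((64, 64)), system64, ens)
        assert wf.is_empty()

    def test_constant_one_models_fill_interior_with_all_bins(self, system64):
        ens = self._ensemble(1.0, 1.0, system64)
        wf = predict_wavefront_set(np.random.default_rng(0).random((64, 64)), system64, ens)
        assert len(wf.elements) == 44 * 44
        assert all(bins == set(range(8)) for bins in wf.elements.values())

    def test_normalization_is_minmax(self):
        img = np.array([[2.0, 4.0], [6.0, 10.0]])
        assert np.allclose(normalize_image(img), (img - 2) / 8)
        assert np.all(normalize_image(np.full((4, 4), 3.0)) == 0)


class TestEnsembleSerialization:
    def test_save_load_round_trip(self, tmp_path):
        models = [PatchCNN((3, 21, 21), (4, 4, 8, 8), 16, seed=i) for i in range(4)]
        ens = ClassifierEnsemble(orientation_models=models[:3], edge_model=models[3],
                                 n_orientations=3, threshold=0.4,
                                 metadata={"seed": 0})
        ens.save(tmp_path / "bundle")
        loaded = ClassifierEnsemble.load(tmp_path / "bundle")
        assert loaded.threshold == 0.4
        assert loaded.n_orientations == 3
        x = np.random.default_rng(0).standard_normal((5, 3, 21, 21)).astype(np.float32)
        for a, b in zip(models, loaded.orientation_models + [loaded.edge_model]):
            assert np.allclose(a.predict_proba(x), b.predict_proba(x))


class TestBackpropagation:
    def test_numeric_gradient_check(self):
        """Analytic gradients agree with central finite differences."""
        rng = np.random.default_rng(0)
        model = PatchCNN((2, 9, 9), (3, 3, 4, 4), 8, seed=1, pool_layers=(1, 3))
        X = rng.standard_normal((4, 2, 9, 9)).astype(np.float32)
        y = np.array([0.0, 1.0, 1.0, 0.0])

        def loss_at():
            z = model.forward_logits(X, train=True)
            return float(np.mean(np.logaddexp(0.0, z) - y * z))

        # train-mode forward throughout: the batch-norm backward formula
        # differentiates through the batch statistics
        z = model.forward_logits(X, train=True)
        dz = (1.0 / (1.0 + np.exp(-z)) - y) / len(y)
        model._backward(dz.astype(np.float32))
        layers = list(model._layers())
        checked = 0
        for layer in layers:
            p, g = layer.params[0], layer.grads[0]
            flat, gflat = p.ravel(), np.asarray(g).ravel()
            # probe the largest-gradient entries (zeros are uninformative)
            for idx in np.argsort(-np.abs(gflat))[:3]:
                eps = 1e-3
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss_at()
                flat[idx] = orig - eps
                down = loss_at()
                flat[idx] = orig
                numeric = (up - down) / (2 * eps)
                # float32 forward noise limits the achievable agreement
                assert numeric == pytest.approx(gflat[idx], rel=0.15, abs=3e-3)
                checked += 1
        assert checked == len(layers) * 3
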