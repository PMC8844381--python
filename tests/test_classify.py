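import numpy as np
import pytest

from polarcall.classify import (
    EnsembleConfig,
    compute_cam,
    ensemble_predict,
    load_models,
    save_models,
    split_cohort,
    train_member,
)
from polarcall.nn import Adam, SGD, SmallConvNet, standardize


def _toy_dataset(rng, n_per_class=16, size=32):
    """Separable textures: smooth blobs vs high-frequency stripes."""
    from scipy.ndimage import gaussian_filter

    smooth = np.stack(
        [gaussian_filter(rng.normal(size=(size, size)), 3.0) for _ in range(n_per_class)]
    )
    stripes = np.stack(
        [
            rng.normal(0, 0.2, (size, size))
            + np.sin(np.arange(size) * 2.0)[None, :] * rng.uniform(0.5, 1.0)
            for _ in range(n_per_class)
        ]
    )
    images = np.concatenate([smooth, stripes])
    labels = np.array([0] * n_per_class + [1] * n_per_class)
    return images, labels


class TestSplitCohort:
    def test_study_scale_counts(self):
        ids = [f"e{i:03d}" for i in range(89)]
        train, test = split_cohort(ids, counts=(70, 19), seed=0)
        assert len(train) == 70 and len(test) == 19
        assert not set(train) & set(test)

    def test_fraction_split(self):
        train, test = split_cohort([f"e{i}" for i in range(10)], test_fraction=0.2)
        assert len(train) == 8 and len(test) == 2
        assert not set(train) & set(test)

    def test_deterministic(self):
        ids = [f"e{i}" for i in range(30)]
        assert split_cohort(ids, 0.3, seed=5) == split_cohort(ids, 0.3, seed=5)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            split_cohort(["a"], 0.5)
        with pytest.raises(ValueError):
            split_cohort(["a", "b", "c"], counts=(1, 1))


class TestTrainMember:
    def test_separable_toy_reaches_full_train_accuracy(self, rng):
        images, labels = _toy_dataset(rng)
        cfg = EnsembleConfig(
            n_members=1, epochs=5, input_size=32, backbone=(4, 8), seed=3
        )
        net = train_member(images, labels, 0, cfg)
        assert net.train_accuracy == 1.0

    def test_optimizer_assignment(self):
        cfg = EnsembleConfig(n_members=6)
        kinds = [type(cfg.optimizer_for(k)) for k in range(6)]
        assert kinds == [SGD, SGD, SGD, Adam, Adam, Adam]

    def test_seeded_reproducibility(self, rng):
        images, labels = _toy_dataset(rng, n_per_class=8)
        cfg = EnsembleConfig(
            n_members=1, epochs=2, input_size=32, backbone=(4,), seed=7
        )
        a = train_member(images, labels, 0, cfg)
        b = train_member(images, labels, 0, cfg)
        for (_, oa, attr, _), (_, ob, _, _) in zip(a.parameters(), b.parameters()):
            assert np.array_equal(getattr(oa, attr), getattr(ob, attr))

    def test_single_class_rejected(self, rng):
        images = rng.random((8, 32, 32))
        with pytest.raises(ValueError, match="both classes"):
            train_member(images, np.zeros(8, int), 0, EnsembleConfig(input_size=32))


class TestEnsemblePredict:
    class _Fixed:
        def __init__(self, probs):
            self._p = np.asarray(probs, float)

        def predict_proba(self, frames):
            return np.tile(self._p, (len(frames), 1))

    def test_probability_average(self):
        models = [self._Fixed([0.9, 0.1]), self._Fixed([0.5, 0.5])]
        probs, labels = ensemble_predict(models, np.zeros((1, 8, 8)))
        assert probs[0].tolist() == pytest.approx([0.7, 0.3])
        assert labels[0] == 0

    def test_unanimous_after(self):
        models = [self._Fixed([0.2, 0.8])] * 3
        probs, labels = ensemble_predict(models, np.zeros((1, 8, 8)))
        assert probs[0].tolist() == pytest.approx([0.2, 0.8])
        assert labels[0] == 1

    def test_exact_tie_goes_before(self):
        models = [self._Fixed([0.4, 0.6]), self._Fixed([0.6, 0.4])]
        _, labels = ensemble_predict(models, np.zeros((1, 8, 8)))
        assert labels[0] == 0

    def test_simplex_preserved(self, rng):
        models = [self._Fixed(p / p.sum()) for p in rng.random((5, 2)) + 0.01]
        probs, _ = ensemble_predict(models, np.zeros((3, 8, 8)))
        assert probs.sum(axis=1) == pytest.approx([1.0] * 3)
        assert (probs >= 0).all()

    def test_majority_mode_ties_before(self):
        cfg = EnsembleConfig(n_members=2, ensemble_mode="label_majority")
        models = [self._Fixed([0.1, 0.9]), self._Fixed([0.9, 0.1])]
        _, labels = ensemble_predict(models, np.zeros((1, 8, 8)), cfg)
        assert labels[0] == 0

    def test_identical_members_match_single(self, rng):
        net = SmallConvNet(16, (4,), seed=0)
        frames = rng.random((4, 16, 16))
        single = net.predict_proba(frames)
        for mode in ("probability_average", "label_majority"):
            cfg = EnsembleConfig(n_members=3, ensemble_mode=mode, input_size=16)
            probs, labels = ensemble_predict([net] * 3, frames, cfg)
            assert probs == pytest.approx(single)
            assert np.array_equal(labels, (single[:, 1] > 0.5).astype(int))

    def test_empty_model_list(self):
        with pytest.raises(ValueError):
            ensemble_predict([], np.zeros((1, 8, 8)))


class TestCam:
    def test_zero_weights_zero_map(self, rng):
        net = SmallConvNet(16, (4,), seed=0)
        net.w[:] = 0.0
        cam = compute_cam(net, rng.random((16, 16)), 1, upsample=False)
        assert not cam.any()

    def test_single_feature_identity(self, rng):
        net = SmallConvNet(16, (4,), seed=0)
        frame = rng.random((16, 16))
        net.w[:] = 0.0
        net.w[1, 2] = 1.0
        cam = compute_cam(net, frame, 1, upsample=False)
        net.forward(standardize(frame[None]), keep_features=True)
        assert cam == pytest.approx(net.features[0, 2])

    def test_logit_identity_random_inputs(self, rng):
        """Spatial mean of the raw map equals logit - bias: GAP and the
        weighted feature sum commute."""
        net = SmallConvNet(32, (4, 8), seed=1)
        for _ in range(5):
            frame = rng.random((32, 32))
            logits = net.forward(standardize(frame[None]))[0]
            for cls in (0, 1):
                raw = compute_cam(net, frame, cls, upsample=False)
                assert abs(raw.mean() - (logits[cls] - net.b[cls])) <= 1e-4

    def test_upsampled_to_input_size(self, rng):
        net = SmallConvNet(32, (4, 8), seed=0)
        cam = compute_cam(net, rng.random((32, 32)), 0)
        assert cam.shape == (32, 32)

    def test_bad_class_rejected(self, rng):
        net = SmallConvNet(16, (4,), seed=0)
        with pytest.raises(ValueError):
            compute_cam(net, rng.random((16, 16)), 2)


class TestCamOverlay:
    def test_png_written(self, rng, tmp_path):
        from polarcall.classify import save_cam_overlay

        net = SmallConvNet(32, (4, 8), seed=0)
        frame = rng.random((32, 32))
        cam = compute_cam(net, frame, 1)
        out = tmp_path / "cam.png"
        save_cam_overlay(frame, cam, out)
        assert out.stat().st_size > 0


class TestModelSerialization:
    def test_round_trip_preserves_predictions(self, rng, tmp_path):
        nets = [SmallConvNet(16, (4, 8), seed=s) for s in range(2)]
        frames = rng.random((3, 16, 16))
        save_models(nets, tmp_path)
        loaded = load_models(tmp_path)
        for a, b in zip(nets, loaded):
            assert a.predict_proba(frames) == pytest.approx(b.predict_proba(frames))
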