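"""Architecture arithmetic, model construction, training contracts, SVM."""
import numpy as np
import pytest

from semgrec.features import FeatureMatrix, featurize, normalize
from semgrec.models import (CNNSpec, ConvBlockSpec, FusionSpec,
                            MovementClassifier, TrainConfig,
                            TransformerSpec, build_model, conv_output_length,
                            conv_stack_trace, forward_shape_trace, train,
                            train_svm)
from semgrec.segmentation import Window, WindowDataset, split_dataset


class TestConvArithmetic:
    def test_single_block_closed_form(self):
        assert conv_output_length(1024, 3, 2) == 511

    def test_boundary(self):
        assert conv_output_length(3, 3, 1) == 1
        with pytest.raises(ValueError, match="shorter"):
            conv_output_length(2, 3, 2)

    def test_published_stack_trace(self):
        trace = conv_stack_trace(CNNSpec())
        assert trace == {"input": 1024, "conv1": 1022, "pool1": 511,
                         "conv2": 509, "pool2": 254, "conv3": 252,
                         "pool3": 126, "flatten": 1260}

    def test_forward_trace_agrees_with_closed_form(self):
        assert forward_shape_trace(CNNSpec()) == conv_stack_trace(CNNSpec())


class TestBuild:
    def test_cnn_probability_output(self):
        model = build_model("cnn", seed=0)
        p = model.predict_proba(np.zeros((1, 7, 1024)))
        assert p.shape == (1, 4)
        assert abs(p.sum() - 1) < 1e-6

    def test_fusion_reshape_invariant(self):
        FusionSpec(seq_len=10)  # 10 x 10 = 100: fine
        with pytest.raises(ValueError, match="must equal"):
            FusionSpec(seq_len=7, transformer=TransformerSpec(d_model=15, n_heads=3))

    def test_inconsistent_fc_size_rejected(self):
        bad = CNNSpec(fc_sizes=(1000, 600, 100))
        with pytest.raises(ValueError, match="does not match"):
            build_model("cnn", bad)

    def test_parameter_count_matches_hand_computation(self):
        model = build_model("cnn", seed=0)
        conv = (64 * 7 * 3 + 64) + (32 * 64 * 3 + 32) + (10 * 32 * 3 + 10)
        bn = 2 * 64 + 2 * 32 + 2 * 10
        fc = (600 * 1260 + 600) + (100 * 600 + 100) + (4 * 100 + 4)
        assert model.n_params() == conv + bn + fc

    def test_build_is_seed_deterministic(self):
        a = build_model("cnn_tl", seed=5)
        b = build_model("cnn_tl", seed=5)
        for pa, pb in zip(a.net.params(), b.net.params()):
            assert np.array_equal(pa.value, pb.value)

    def test_unknown_variant(self):
        with pytest.raises(ValueError, match="unknown variant"):
            build_model("mlp")


def _toy_dataset(per_class=20, length=256, channels=2, noise=0.05, seed=0,
                 separable=True):
    """Four classes distinguished by per-channel amplitude of modulated noise."""
    rng = np.random.default_rng(seed)
    amps = {0: (1.0, 0.1), 1: (0.1, 1.0), 2: (1.0, 1.0), 3: (0.15, 0.15)}
    classes = ("walk", "ascend", "descend", "squat")
    wins = []
    for code, label in enumerate(classes):
        for _ in range(per_class):
            a = amps[code] if separable else (0.5, 0.5)
            x = np.stack([a[c] * rng.standard_normal(length) for c in range(channels)])
            wins.append(Window(samples=x + noise * rng.standard_normal((channels, length)),
                               label=label))
    ds = WindowDataset(windows=wins)
    return split_dataset(ds, 0.25, seed=seed)


def _toy_cnn_spec(length=256, channels=2):
    blocks = (ConvBlockSpec(8), ConvBlockSpec(8), ConvBlockSpec(4))
    spec = CNNSpec(blocks=blocks, fc_sizes=(1, 16, 8), n_classes=4,
                   input_channels=channels, input_length=length)
    flat = conv_stack_trace(CNNSpec(blocks=blocks, fc_sizes=(1, 1, 1),
                                    input_channels=channels,
                                    input_length=length))["flatten"]
    return CNNSpec(blocks=blocks, fc_sizes=(flat, 16, 8), dropout_rate=0.2,
                   n_classes=4, input_channels=channels, input_length=length)


class TestTraining:
    def test_single_epoch_contract(self):
        ds = _toy_dataset(per_class=10)
        model = build_model("cnn", _toy_cnn_spec(), seed=0)
        model, hist = train(model, ds, TrainConfig(epochs=1, batch_size=10, seed=0))
        assert len(hist.train_loss) == 1
        assert len(hist.test_acc) == 1
        assert all(l >= 0 for l in hist.train_loss)

    def test_separable_toy_reaches_high_accuracy(self):
        ds = _toy_dataset(per_class=30)
        model = build_model("cnn", _toy_cnn_spec(), seed=0)
        model, hist = train(model, ds, TrainConfig(epochs=30, batch_size=20, seed=0))
        X, y = ds.stacked()
        tr = ds.subset_indices("train")
        te = ds.subset_indices("test")
        # evaluation-mode accuracies (history's train accuracy carries dropout)
        assert (model.predict(X[tr]) == y[tr]).mean() >= 0.99
        assert (model.predict(X[te]) == y[te]).mean() >= 0.95

    def test_seeded_training_is_reproducible(self):
        ds = _toy_dataset(per_class=10)
        outs = []
        for _ in range(2):
            model = build_model("cnn", _toy_cnn_spec(), seed=1)
            model, hist = train(model, ds, TrainConfig(epochs=3, batch_size=10, seed=1))
            outs.append(hist.train_loss[-1])
        assert abs(outs[0] - outs[1]) < 1e-6

    def test_batch_size_guard(self):
        ds = _toy_dataset(per_class=3)
        model = build_model("cnn", _toy_cnn_spec(), seed=0)
        with pytest.raises(ValueError, match="batch size"):
            train(model, ds, TrainConfig(epochs=1, batch_size=400, seed=0))

    def test_predict_proba_rows_normalized_and_deterministic(self):
        model = build_model("cnn_transformer", seed=0)
        # default fusion spec expects 7 x 1024 windows; random ones suffice
        X = np.random.default_rng(0).normal(size=(3, 7, 1024))
        p = model.predict_proba(np.concatenate([X, X[:1]]))
        assert np.allclose(p.sum(axis=1), 1, atol=1e-6)
        assert np.allclose(p[0], p[3])


class TestSVM:
    def _blob_features(self, per_class=50, seed=0):
        rng = np.random.default_rng(seed)
        centers = rng.normal(scale=5, size=(4, 28))
        vals = np.concatenate([centers[c] + rng.normal(size=(per_class, 28))
                               for c in range(4)])
        labels = np.repeat(np.arange(4), per_class)
        fm = FeatureMatrix(values=vals, labels=labels,
                           columns=[f"f{i}" for i in range(28)])
        return normalize(fm)

    def test_separated_blobs_high_accuracy(self):
        fm = self._blob_features()
        svm = train_svm(fm)
        acc = (svm.predict(fm.values) == fm.labels).mean()
        assert acc >= 0.95

    def test_one_vs_all_cardinality_and_determinism(self):
        fm = self._blob_features()
        a = train_svm(fm)
        b = train_svm(fm)
        assert len(a.models) == 4
        assert [m.support_.size for m in a.models] == [m.support_.size for m in b.models]

    def test_proba_rows_sum_to_one(self):
        fm = self._blob_features()
        p = train_svm(fm).predict_proba(fm.values[:10])
        assert np.allclose(p.sum(axis=1), 1, atol=1e-9)

    def test_unnormalized_rejected(self):
        fm = FeatureMatrix(values=np.zeros((10, 28)), labels=np.zeros(10, dtype=int))
        with pytest.raises(ValueError, match="normalized"):
            train_svm(fm)


class TestCheckpoints:
    def test_roundtrip_reproduces_predictions(self, tmp_path):
        from semgrec.models import load_checkpoint, save_checkpoint
        ds = _toy_dataset(per_class=10)
        model = build_model("cnn", _toy_cnn_spec(), seed=0)
        model, _ = train(model, ds, TrainConfig(epochs=2, batch_size=10, seed=0))
        X, _ = ds.stacked()
        before = model.predict_proba(X[:8])
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path)
        restored = load_checkpoint(path)
        assert restored.variant == "cnn"
        assert restored.trained
        assert np.array_equal(restored.predict_proba(X[:8]), before)

    def test_fusion_spec_embedded(self, tmp_path):
        from semgrec.models import load_checkpoint, save_checkpoint
        model = build_model("cnn_tl", seed=3)
        path = tmp_path / "tl.npz"
        save_checkpoint(model, path)
        restored = load_checkpoint(path)
        assert isinstance(restored.spec, FusionSpec)
        x = np.random.default_rng(0).normal(size=(2, 7, 1024))
        assert np.array_equal(restored.predict_proba(x), model.predict_proba(x))


def test_movement_classifier_summary_smoke():
    ds = _toy_dataset(per_class=10)
    fm = normalize(featurize(ds, fs=1000.0), fit_on=ds.subset_indices("train"))
    res = MovementClassifier(ds, "svm", features=fm).fit()
    text = res.summary()
    assert "svm" in text and "accuracy" in text
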