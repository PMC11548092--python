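"""Movement classifiers: the 1-D CNN, LSTM, Transformer hybrids, and the
one-vs-all RBF-SVM baseline, with Adadelta / cross-entropy training.

The CNN backbone (three conv blocks, kernel 3, stride 1, no padding, each
followed by batch norm, ReLU and max-pool 2) maps a 7 x 1024 window through
per-channel lengths 1022 -> 511 -> 509 -> 254 -> 252 -> 126 with channel
widths 64/32/10, flattening to 1260 features; three fully connected layers
(1260 -> 600 -> 100 -> 4) with two dropout layers finish the plain CNN. The
hybrids reshape the 100-dim representation into a 10-step sequence of 10-dim
vectors and pass it through a Transformer encoder and/or LSTM before the
4-class head. The pure LSTM reads the window as a 1024-step sequence of 7-dim
muscle vectors.

The user-facing surface is statsmodels-like: build a
:class:`MovementClassifier` from a window dataset, call ``fit`` and get a
:class:`ClassifierResults` carrying the trained network, per-epoch history,
held-out metrics and a ``summary()`` table.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from . import nn
from .evaluation import MetricReport, confusion, metrics
from .features import FeatureMatrix
from .nn import positional_encoding, scaled_attention  # re-exported building blocks
from .segmentation import WindowDataset

__all__ = [
    "VARIANTS", "ConvBlockSpec", "CNNSpec", "LSTMSpec", "TransformerSpec",
    "FusionSpec", "SVMSpec", "TrainConfig", "TrainHistory",
    "conv_output_length", "conv_stack_trace", "forward_shape_trace",
    "build_model", "train",
    "predict_proba", "train_svm", "positional_encoding", "scaled_attention",
    "save_checkpoint", "load_checkpoint",
    "NeuralClassifier", "SVMEnsemble", "MovementClassifier", "ClassifierResults",
]

log = logging.getLogger(__name__)

VARIANTS = ("svm", "cnn", "lstm", "cnn_lstm", "cnn_transformer", "cnn_tl")


# ---------------------------------------------------------------------------
# Declarative specs


@dataclass(frozen=True)
class ConvBlockSpec:
    out_channels: int
    kernel_size: int = 3
    pool_size: int = 2

    def __post_init__(self) -> None:
        if self.out_channels <= 0 or self.kernel_size <= 0 or self.pool_size <= 0:
            raise ValueError("conv block sizes must be positive")


@dataclass(frozen=True)
class CNNSpec:
    blocks: tuple[ConvBlockSpec, ...] = (
        ConvBlockSpec(64), ConvBlockSpec(32), ConvBlockSpec(10))
    fc_sizes: tuple[int, int, int] = (1260, 600, 100)
    dropout_rate: float = 0.5
    n_classes: int = 4
    input_channels: int = 7
    input_length: int = 1024


@dataclass(frozen=True)
class LSTMSpec:
    layers: int = 3
    hidden_units: int = 100
    batch_size: int = 40
    learning_rate: float = 1.0     # Adadelta step scale; see docs/methods.md
    frame_len: int = 16            # pure-LSTM input framing; 1 = one step per sample


@dataclass(frozen=True)
class TransformerSpec:
    d_model: int = 10
    n_heads: int = 2
    n_layers: int = 2
    ff_dim: int = 64
    layernorm_eps: float = 1e-5

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")


@dataclass(frozen=True)
class FusionSpec:
    """CNN conv stack -> FC(1260->600) -> FC(600->100) -> reshape to
    (seq_len, d_model) -> Transformer and/or LSTM -> FC head."""

    cnn: CNNSpec = CNNSpec()
    transformer: TransformerSpec = TransformerSpec()
    lstm: LSTMSpec = LSTMSpec()
    seq_len: int = 10

    def __post_init__(self) -> None:
        if self.seq_len * self.transformer.d_model != self.cnn.fc_sizes[2]:
            raise ValueError(
                f"seq_len x d_model = {self.seq_len} x {self.transformer.d_model} "
                f"must equal the {self.cnn.fc_sizes[2]}-dim FC output"
            )


@dataclass(frozen=True)
class SVMSpec:
    C: float = 1.0
    gamma: float = 0.1
    kernel: str = "rbf"

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 300
    batch_size: int = 40
    learning_rate: float = 1.0     # Adadelta step scale
    rho: float = 0.9
    eps: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    test_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    test_acc: list[float] = field(default_factory=list)

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({
            "epoch": np.arange(1, len(self.train_loss) + 1),
            "train_loss": self.train_loss, "test_loss": self.test_loss,
            "train_acc": self.train_acc, "test_acc": self.test_acc,
        })


# ---------------------------------------------------------------------------
# Architecture arithmetic


def conv_output_length(n: int, k: int, pool: int, stride: int = 1) -> int:
    """Length after one conv (stride 1, no padding) + max-pool block:
    floor((n - k + 1) / pool)."""
    if n < k:
        raise ValueError(f"input length {n} shorter than kernel {k}")
    if stride != 1:
        raise ValueError("only stride 1 is used")
    return (n - k + 1) // pool


def forward_shape_trace(spec: CNNSpec | None = None, seed: int = 0) -> dict[str, int]:
    """Run one zero-valued window through the conv/pool stack and record the
    observed per-channel lengths and the flattened size.

    Unlike :func:`conv_stack_trace` this measures actual forward-pass shapes,
    layer by layer, rather than evaluating the closed form.
    """
    spec = spec or CNNSpec()
    rng = np.random.default_rng(seed)
    layers, _ = _conv_backbone(spec, rng)
    x = np.zeros((1, spec.input_channels, spec.input_length))
    trace: dict[str, int] = {"input": x.shape[2]}
    conv_i = pool_i = 0
    for layer in layers:
        x = layer.forward(x, training=False)
        if isinstance(layer, nn.Conv1d):
            conv_i += 1
            trace[f"conv{conv_i}"] = x.shape[2]
        elif isinstance(layer, nn.MaxPool1d):
            pool_i += 1
            trace[f"pool{pool_i}"] = x.shape[2]
        elif isinstance(layer, nn.Flatten):
            trace["flatten"] = x.shape[1]
    return trace


def conv_stack_trace(spec: CNNSpec) -> dict[str, int]:
    """Per-channel lengths through the conv/pool stack and the flattened size."""
    trace: dict[str, int] = {"input": spec.input_length}
    n = spec.input_length
    for i, blk in enumerate(spec.blocks, start=1):
        n_conv = n - blk.kernel_size + 1
        if n_conv < 1:
            raise ValueError(f"block {i} kernel exceeds input length")
        trace[f"conv{i}"] = n_conv
        n = n_conv // blk.pool_size
        trace[f"pool{i}"] = n
    trace["flatten"] = spec.blocks[-1].out_channels * n
    return trace


# ---------------------------------------------------------------------------
# Network assembly


class NeuralClassifier:
    """A variant architecture plus its training loop and probability output."""

    def __init__(self, variant: str, net: nn.Sequential, input_mode: str,
                 spec=None, build_seed: int = 0):
        self.variant = variant
        self.net = net
        self.input_mode = input_mode      # "cwt" = (B, C, L); "seq" = (B, L, C)
        self.spec = spec
        self.build_seed = build_seed
        self.trained = False

    def _prep(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("expected a batch of (channels, length) windows")
        return X.transpose(0, 2, 1) if self.input_mode == "seq" else X

    def logits(self, X: np.ndarray, training: bool = False,
               rng: np.random.Generator | None = None) -> np.ndarray:
        return self.net.forward(self._prep(X), training=training, rng=rng)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if not self.trained:
            log.warning("predict_proba on an untrained %s model", self.variant)
        return nn.softmax(self.logits(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def n_params(self) -> int:
        return sum(p.size for p in self.net.params())


def _conv_backbone(spec: CNNSpec, rng: np.random.Generator) -> tuple[list[nn.Layer], int]:
    layers: list[nn.Layer] = []
    in_ch = spec.input_channels
    for blk in spec.blocks:
        layers += [nn.Conv1d(in_ch, blk.out_channels, blk.kernel_size, rng),
                   nn.BatchNorm1d(blk.out_channels), nn.ReLU(),
                   nn.MaxPool1d(blk.pool_size)]
        in_ch = blk.out_channels
    flat = conv_stack_trace(spec)["flatten"]
    if flat != spec.fc_sizes[0]:
        raise ValueError(
            f"fc_sizes[0] = {spec.fc_sizes[0]} does not match the flattened "
            f"conv output {flat} for a {spec.input_channels} x "
            f"{spec.input_length} input"
        )
    layers.append(nn.Flatten())
    return layers, flat


def _fc_trunk(spec: CNNSpec, rng: np.random.Generator) -> list[nn.Layer]:
    """The first two fully connected layers (1260 -> 600 -> 100), each with
    ReLU and dropout — shared by the plain CNN and all hybrids."""
    f0, f1, f2 = spec.fc_sizes
    return [nn.Linear(f0, f1, rng), nn.ReLU(), nn.Dropout(spec.dropout_rate),
            nn.Linear(f1, f2, rng), nn.ReLU(), nn.Dropout(spec.dropout_rate)]


def build_model(variant: str,
                spec: CNNSpec | LSTMSpec | FusionSpec | None = None,
                seed: int = 0) -> NeuralClassifier:
    """Assemble an untrained classifier for one of the deep variants.

    ``variant`` is one of cnn, lstm, cnn_lstm, cnn_transformer, cnn_tl; a
    matching spec may be passed (defaults reproduce the published
    configuration). Construction is deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    if variant == "cnn":
        spec = spec or CNNSpec()
        layers, _ = _conv_backbone(spec, rng)
        layers += _fc_trunk(spec, rng)
        layers.append(nn.Linear(spec.fc_sizes[2], spec.n_classes, rng))
        return NeuralClassifier(variant, nn.Sequential(layers), "cwt",
                                spec=spec, build_seed=seed)
    if variant == "lstm":
        spec = spec or LSTMSpec()
        if spec.frame_len == 1:
            layers: list[nn.Layer] = [nn.Transpose()]      # (B, 1024, 7)
            in_dim = 7
        else:
            # raw samples grouped into short frames: (B, 1024/frame, 7*frame).
            # One step per raw sample leaves the envelope invisible to the
            # gates (zero-mean inputs) and trains orders of magnitude slower.
            layers = [nn.Frame(spec.frame_len)]
            in_dim = 7 * spec.frame_len
        layers += [nn.LSTM(in_dim, spec.hidden_units, spec.layers, rng),
                   nn.Linear(spec.hidden_units, 4, rng)]
        return NeuralClassifier(variant, nn.Sequential(layers), "cwt",
                                spec=spec, build_seed=seed)
    if variant in ("cnn_lstm", "cnn_transformer", "cnn_tl"):
        spec = spec or FusionSpec()
        if not isinstance(spec, FusionSpec):
            raise ValueError(f"variant {variant!r} needs a FusionSpec")
        cnn, tf, ls = spec.cnn, spec.transformer, spec.lstm
        layers, _ = _conv_backbone(cnn, rng)
        layers += _fc_trunk(cnn, rng)
        layers.append(nn.Reshape((spec.seq_len, tf.d_model)))
        if variant in ("cnn_transformer", "cnn_tl"):
            layers.append(nn.TransformerEncoder(tf.d_model, tf.n_heads, tf.n_layers,
                                                tf.ff_dim, rng, tf.layernorm_eps))
        if variant in ("cnn_lstm", "cnn_tl"):
            layers.append(nn.LSTM(tf.d_model, ls.hidden_units, ls.layers, rng))
            layers.append(nn.Linear(ls.hidden_units, cnn.n_classes, rng))
        else:  # cnn_transformer: flatten the encoded sequence into the head
            layers.append(nn.Flatten())
            layers.append(nn.Linear(spec.seq_len * tf.d_model, cnn.n_classes, rng))
        return NeuralClassifier(variant, nn.Sequential(layers), "cwt",
                                spec=spec, build_seed=seed)
    raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS[1:]}")


# ---------------------------------------------------------------------------
# Training


def _epoch_eval(model: NeuralClassifier, X: np.ndarray, y: np.ndarray,
                batch: int = 200) -> tuple[float, float]:
    losses, hits, n = 0.0, 0, len(y)
    for s in range(0, n, batch):
        xb, yb = X[s:s + batch], y[s:s + batch]
        logits = model.logits(xb, training=False)
        loss, _ = nn.softmax_cross_entropy(logits, yb)
        losses += loss * len(yb)
        hits += int((logits.argmax(axis=1) == yb).sum())
    return losses / n, hits / n


def train(model: NeuralClassifier, ds: WindowDataset, cfg: TrainConfig,
          verbose: bool = False) -> tuple[NeuralClassifier, TrainHistory]:
    """Adadelta minimisation of the cross-entropy over the train split.

    The dataset must carry a train/test split; per-epoch train and test loss
    and accuracy are recorded. Fixed ``cfg.seed`` fixes the batch order and
    dropout masks (initial weights are fixed by the build seed).
    """
    X, y = ds.stacked()
    tr = ds.subset_indices("train")
    te = ds.subset_indices("test")
    if tr.size == 0 or te.size == 0:
        raise ValueError("empty train or test split")
    if cfg.batch_size > tr.size:
        raise ValueError("batch size exceeds the training-set size")
    Xtr, ytr, Xte, yte = X[tr], y[tr], X[te], y[te]
    opt = nn.Adadelta(model.net.params(), lr=cfg.learning_rate, rho=cfg.rho, eps=cfg.eps)
    rng = np.random.default_rng(cfg.seed)
    hist = TrainHistory()
    for epoch in range(cfg.epochs):
        order = rng.permutation(tr.size)
        run_loss, run_hits = 0.0, 0
        for s in range(0, tr.size, cfg.batch_size):
            idx = order[s:s + cfg.batch_size]
            xb, yb = Xtr[idx], ytr[idx]
            logits = model.logits(xb, training=True, rng=rng)
            loss, dlogits = nn.softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch + 1}")
            opt.zero_grad()
            model.net.backward(dlogits)
            opt.step()
            run_loss += loss * len(yb)
            run_hits += int((logits.argmax(axis=1) == yb).sum())
        te_loss, te_acc = _epoch_eval(model, Xte, yte)
        hist.train_loss.append(run_loss / tr.size)
        hist.train_acc.append(run_hits / tr.size)
        hist.test_loss.append(te_loss)
        hist.test_acc.append(te_acc)
        if verbose:
            log.info("epoch %d/%d train loss %.4f acc %.3f | test loss %.4f acc %.3f",
                     epoch + 1, cfg.epochs, hist.train_loss[-1], hist.train_acc[-1],
                     te_loss, te_acc)
    model.trained = True
    return model, hist


def predict_proba(model, X: np.ndarray) -> np.ndarray:
    """Class-probability rows for a batch of windows (deep models) or feature
    rows (SVM ensemble); rows are nonnegative and sum to 1."""
    return model.predict_proba(X)


# ---------------------------------------------------------------------------
# SVM baseline


class SVMEnsemble:
    """Four one-vs-all binary RBF-SVMs combined by maximal decision value.

    Probability-like scores (needed only for ROC curves) are the softmax of
    the four decision values; hard labels use the raw argmax.
    """

    def __init__(self, spec: SVMSpec):
        self.spec = spec
        self.models: list[SVC] = []
        self.trained = False

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SVMEnsemble":
        self.classes_ = np.arange(4)
        self.models = []
        for c in self.classes_:
            m = SVC(kernel=self.spec.kernel, C=self.spec.C, gamma=self.spec.gamma)
            m.fit(X, (y == c).astype(int))
            self.models.append(m)
        self.trained = True
        return self

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return np.column_stack([m.decision_function(X) for m in self.models])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.decision_values(X).argmax(axis=1)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return nn.softmax(self.decision_values(X))


def train_svm(fm: FeatureMatrix, spec: SVMSpec | None = None,
              train_idx: np.ndarray | None = None) -> SVMEnsemble:
    """Fit the one-vs-all SVM baseline on normalized feature rows."""
    if fm.norm_params is None:
        raise ValueError("features must be normalized before SVM training "
                         "(call features.normalize)")
    spec = spec or SVMSpec()
    idx = np.arange(len(fm.labels)) if train_idx is None else np.asarray(train_idx)
    return SVMEnsemble(spec).fit(fm.values[idx], fm.labels[idx])


# ---------------------------------------------------------------------------
# Checkpoints


def _spec_to_dict(spec) -> dict:
    import dataclasses
    return dataclasses.asdict(spec) if spec is not None else {}


def _spec_from_dict(variant: str, d: dict):
    if not d:
        return None
    if variant == "cnn":
        blocks = tuple(ConvBlockSpec(**b) for b in d["blocks"])
        return CNNSpec(**{**d, "blocks": blocks,
                          "fc_sizes": tuple(d["fc_sizes"])})
    if variant == "lstm":
        return LSTMSpec(**d)
    cnn = _spec_from_dict("cnn", d["cnn"])
    return FusionSpec(cnn=cnn, transformer=TransformerSpec(**d["transformer"]),
                      lstm=LSTMSpec(**d["lstm"]), seq_len=d["seq_len"])


def save_checkpoint(model: NeuralClassifier, path) -> None:
    """Persist a trained deep model: parameters, batch-norm running statistics
    and the embedded architecture spec (as JSON), in one .npz archive."""
    import json
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.net.params())}
    for i, layer in enumerate(model.net.layers):
        if isinstance(layer, nn.BatchNorm1d):
            arrays[f"bn_{i}_mean"] = layer.running_mean
            arrays[f"bn_{i}_var"] = layer.running_var
    meta = json.dumps({"variant": model.variant, "build_seed": model.build_seed,
                       "trained": model.trained,
                       "spec": _spec_to_dict(model.spec)})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> NeuralClassifier:
    """Rebuild the architecture from the embedded spec and restore weights."""
    import json
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        model = build_model(meta["variant"],
                            _spec_from_dict(meta["variant"], meta["spec"]),
                            seed=meta["build_seed"])
        for i, p in enumerate(model.net.params()):
            p.value[...] = data[f"param_{i}"]
        for i, layer in enumerate(model.net.layers):
            if isinstance(layer, nn.BatchNorm1d):
                layer.running_mean = data[f"bn_{i}_mean"]
                layer.running_var = data[f"bn_{i}_var"]
    model.trained = meta["trained"]
    return model


# ---------------------------------------------------------------------------
# statsmodels-style surface


class MovementClassifier:
    """Model object binding one architecture variant to a window dataset.

    Parameters
    ----------
    ds : WindowDataset
        Windowed dataset with a train/test split assignment.
    variant : str
        One of svm, cnn, lstm, cnn_lstm, cnn_transformer, cnn_tl.
    spec : optional
        Architecture spec; defaults reproduce the published configuration.
    features : FeatureMatrix, optional
        Normalized features, required for (and only for) the svm variant.
    """

    def __init__(self, ds: WindowDataset, variant: str, spec=None,
                 features: FeatureMatrix | None = None, build_seed: int = 0):
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}")
        if variant == "svm" and features is None:
            raise ValueError("the svm variant needs a FeatureMatrix")
        self.ds = ds
        self.variant = variant
        self.spec = spec
        self.features = features
        self.build_seed = build_seed

    def fit(self, cfg: TrainConfig | None = None, verbose: bool = False
            ) -> "ClassifierResults":
        cfg = cfg or TrainConfig()
        te = self.ds.subset_indices("test")
        if self.variant == "svm":
            tr = self.ds.subset_indices("train")
            model = train_svm(self.features, self.spec, train_idx=tr)
            proba = model.predict_proba(self.features.values[te])
            y_true = self.features.labels[te]
            history = None
        else:
            model = build_model(self.variant, self.spec, seed=self.build_seed)
            model, history = train(model, self.ds, cfg, verbose=verbose)
            X, y = self.ds.stacked()
            proba = model.predict_proba(X[te])
            y_true = y[te]
        y_pred = proba.argmax(axis=1)
        report = metrics(confusion(y_true, y_pred))
        return ClassifierResults(self, model, history, report, proba, y_true)


@dataclass
class ClassifierResults:
    """Trained model plus held-out evaluation; see ``summary()``."""

    model_spec: MovementClassifier
    model: NeuralClassifier | SVMEnsemble
    history: TrainHistory | None
    report: MetricReport
    test_proba: np.ndarray
    test_labels: np.ndarray

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(X)

    def roc(self):
        from .evaluation import roc
        return roc(self.test_proba, self.test_labels)

    def summary(self) -> str:
        r = self.report
        lines = [
            f"Movement classifier: {self.model_spec.variant}",
            "=" * 44,
            f"test windows:      {len(self.test_labels)}",
            f"accuracy:          {100 * r.accuracy:6.2f} %",
            f"precision (macro): {100 * r.precision:6.2f} %",
            f"recall (macro):    {100 * r.recall:6.2f} %",
            f"F1 (macro):        {100 * r.f1:6.2f} %",
        ]
        if self.history is not None:
            lines.append(f"final train loss:  {self.history.train_loss[-1]:.4f}")
            lines.append(f"epochs:            {len(self.history.train_loss)}")
        if isinstance(self.model, NeuralClassifier):
            lines.append(f"parameters:        {self.model.n_params()}")
        return "\n".join(lines)
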