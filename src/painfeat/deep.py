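"""Feature-learning architectures and their truncation to extractors.

Four networks are built, trained and then cut back to a fixed-length feature
map for the shared random-forest classifier:

* **MLP** — Flatten, Dropout 0.1, Dense 250, Dropout 0.1, Dense 100,
  Dense 2 softmax; features come from the penultimate Dense 100 layer.
* **CNN** — two blocks of (Conv 16 kernels, size 7, stride 2, ReLU →
  MaxPool 4 → Dropout 0.1), then Flatten, Dense 100, Dense 2 softmax.
* **ConvLSTM** — the input window is split into 4 equal time segments
  processed recurrently; three blocks of (ConvLSTM → Dropout → BatchNorm →
  MaxPool 4) with 32/16/8 kernels of sizes 11/7/3 and strides 8/8/2, then
  Flatten, Dropout, Dense 100 ReLU, Dense 2 softmax.  Pooling acts on the
  within-segment time axis with ceil semantics (see docs/methods.md).
* **CAE** — convolutional autoencoder: encoder Conv 64/32/16 (kernels
  7/11/11, ReLU) each followed by MaxPool 4; decoder mirrors with
  UpSampling 4 and a final 1-kernel reconstruction convolution.  The
  flattened encoder bottleneck is the feature vector.

Classifier nets train with Adam (lr 1e-4) and categorical cross-entropy;
the CAE trains unsupervised with mean squared error.  Defaults are 50
epochs, batch size 8.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import nn

ARCH_NAMES = ("mlp", "cnn", "convlstm", "cae")
CONVLSTM_SEGMENTS = 4


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    epochs: int = 50
    batch_size: int = 8
    rng_seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.epochs < 0:
            raise ValueError("invalid training configuration")


@dataclass
class ArchitectureSpec:
    name: str
    input_shape: tuple
    layers: list            # list of (kind, params) for auditing
    feature_layer: int      # index whose (flattened) output is exported


def _audit_row(layer) -> tuple:
    if isinstance(layer, nn.Flatten):
        return ("Flatten", {})
    if isinstance(layer, nn.Dropout):
        return ("Dropout", {"rate": layer.rate})
    if isinstance(layer, nn.Dense):
        return ("Dense", {"units": layer.units, "activation": layer.activation})
    if isinstance(layer, nn.Conv1D):
        return ("Conv", {"filters": layer.filters, "kernel": layer.kernel_size,
                         "stride": layer.stride, "activation": layer.activation})
    if isinstance(layer, (nn.MaxPool1D, nn.TemporalMaxPool)):
        return ("MaxPool", {"size": layer.pool_size})
    if isinstance(layer, nn.UpSampling1D):
        return ("UpSampling", {"size": layer.size})
    if isinstance(layer, nn.BatchNorm):
        return ("BatchNorm", {})
    if isinstance(layer, nn.ConvLSTM1D):
        return ("ConvLSTM", {"filters": layer.filters, "kernel": layer.kernel_size,
                             "stride": layer.stride,
                             "activation": layer.activation,
                             "recurrent_activation": layer.recurrent_activation})
    raise TypeError(f"unknown layer {layer!r}")


def build_architecture(name: str, input_shape, rng_seed: int = 0,
                       dtype=None):
    """Construct one of the four architectures.

    ``input_shape`` is (T, S) for mlp/cnn/cae and (N, T/N, S) for convlstm.
    Returns ``(spec, model)`` where the spec carries the layer audit and the
    index of the feature layer.
    """
    name = name.lower()
    if name == "mlp":
        layers = [nn.Flatten(), nn.Dropout(0.1), nn.Dense(250), nn.Dropout(0.1),
                  nn.Dense(100), nn.Dense(2, activation="softmax")]
        feature_layer = 4
        shape = tuple(input_shape)
    elif name == "cnn":
        layers = [nn.Conv1D(16, 7, 2, activation="relu"), nn.MaxPool1D(4),
                  nn.Dropout(0.1),
                  nn.Conv1D(16, 7, 2, activation="relu"), nn.MaxPool1D(4),
                  nn.Dropout(0.1),
                  nn.Flatten(), nn.Dense(100), nn.Dense(2, activation="softmax")]
        feature_layer = 7
        shape = tuple(input_shape)
    elif name == "convlstm":
        shape = tuple(input_shape)
        if len(shape) != 3:
            raise ValueError("convlstm expects an (N, T/N, S) input shape")
        layers = [
            nn.ConvLSTM1D(32, 11, 8), nn.Dropout(0.1), nn.BatchNorm(),
            nn.TemporalMaxPool(4),
            nn.ConvLSTM1D(16, 7, 8), nn.Dropout(0.1), nn.BatchNorm(),
            nn.TemporalMaxPool(4),
            nn.ConvLSTM1D(8, 3, 2), nn.Dropout(0.1), nn.BatchNorm(),
            nn.TemporalMaxPool(4),
            nn.Flatten(), nn.Dropout(0.1),
            nn.Dense(100, activation="relu"), nn.Dense(2, activation="softmax")]
        feature_layer = 14
    elif name == "cae":
        layers = [nn.Conv1D(64, 7, activation="relu"), nn.MaxPool1D(4),
                  nn.Conv1D(32, 11, activation="relu"), nn.MaxPool1D(4),
                  nn.Conv1D(16, 11, activation="relu"), nn.MaxPool1D(4),
                  nn.UpSampling1D(4), nn.Conv1D(16, 11, activation="relu"),
                  nn.UpSampling1D(4), nn.Conv1D(32, 11, activation="relu"),
                  nn.UpSampling1D(4), nn.Conv1D(64, 7, activation="relu"),
                  nn.Conv1D(1, 1)]
        feature_layer = 5
        shape = tuple(input_shape)
    else:
        raise ValueError(f"unknown architecture {name!r}")
    model = nn.Sequential(layers, shape, rng_seed=rng_seed, dtype=dtype)
    spec = ArchitectureSpec(name=name, input_shape=shape,
                            layers=[_audit_row(l) for l in layers],
                            feature_layer=feature_layer)
    return spec, model


def reshape_for_convlstm(segment, n_segments: int = CONVLSTM_SEGMENTS):
    """(T, S) -> (N, T/N, S, 1) time-ordered equal split."""
    x = np.asarray(segment)
    t, s = x.shape
    if t % n_segments:
        raise ValueError(f"T={t} not divisible by {n_segments}")
    return x.reshape(n_segments, t // n_segments, s, 1)


def unsplit_convlstm(tensor):
    """Inverse of :func:`reshape_for_convlstm`."""
    n, length, s, _ = tensor.shape
    return tensor.reshape(n * length, s)


def _batches(n, batch_size, rng):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start: start + batch_size]


def train_supervised(model, x, y, cfg: TrainConfig):
    """Train a classifier net with Adam + categorical cross-entropy.

    ``y`` holds exactly two classes coded 0/1.  Returns the per-epoch mean
    training loss.  All randomness (shuffling, dropout) comes from
    ``cfg.rng_seed``.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"expected 2 classes, got {classes.size}")
    onehot = np.eye(2, dtype=model.dtype)[y.astype(int)]
    rng = np.random.default_rng(cfg.rng_seed)
    opt = nn.Adam(model.params_and_grads(), learning_rate=cfg.learning_rate)
    history = []
    for _ in range(cfg.epochs):
        losses = []
        for idx in _batches(x.shape[0], cfg.batch_size, rng):
            probs = model.forward(x[idx], training=True, rng=rng)
            loss, dpre = nn.softmax_cross_entropy(probs, onehot[idx])
            model.backward(dpre, skip_last_activation=True)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return model, history


def train_cae(model, x, cfg: TrainConfig):
    """Unsupervised reconstruction training with mean squared error."""
    x = np.asarray(x)
    rng = np.random.default_rng(cfg.rng_seed)
    opt = nn.Adam(model.params_and_grads(), learning_rate=cfg.learning_rate)
    history = []
    for _ in range(cfg.epochs):
        losses = []
        for idx in _batches(x.shape[0], cfg.batch_size, rng):
            target = np.asarray(x[idx], dtype=model.dtype)
            out = model.forward(target, training=True, rng=rng)
            loss, dout = nn.mse_loss(out, target)
            model.backward(dout)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return model, history


def truncate_to_extractor(model, spec: ArchitectureSpec):
    """Pure feature function: batch of inputs -> (n, d) matrix from the
    spec's feature layer (flattened), run in inference mode."""
    def extract(batch):
        out = model.forward(np.asarray(batch), training=False,
                            upto=spec.feature_layer)
        return np.asarray(out.reshape(out.shape[0], -1), dtype=float)
    return extract


def deep_extractor_factory(name: str, epochs: int = 50, batch_size: int = 8,
                           learning_rate: float = 1e-4):
    """Build a per-fold extractor trainer for LOSO evaluation.

    The returned factory signature is ``factory(x_train, y_train, seed) ->
    feature_fn`` where ``x_train`` is (n, T, S).  Supervised nets train on
    the fold's binary labels; the CAE trains unsupervised on the same rows.
    """
    name = name.lower()

    def factory(x_train, y_train, seed):
        x_train = np.asarray(x_train)
        cfg = TrainConfig(learning_rate=learning_rate, epochs=epochs,
                          batch_size=batch_size, rng_seed=seed)
        if name == "convlstm":
            n, t, s = x_train.shape
            shape = (CONVLSTM_SEGMENTS, t // CONVLSTM_SEGMENTS, s)
            xt = x_train.reshape((n,) + shape)
            spec, model = build_architecture(name, shape, rng_seed=seed)
            train_supervised(model, xt, y_train, cfg)
            fe = truncate_to_extractor(model, spec)
            return lambda xb: fe(np.asarray(xb).reshape((-1,) + shape))
        shape = x_train.shape[1:]
        spec, model = build_architecture(name, shape, rng_seed=seed)
        if name == "cae":
            train_cae(model, x_train, cfg)
        else:
            train_supervised(model, x_train, y_train, cfg)
        return truncate_to_extractor(model, spec)

    return factory
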