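"""Shallow 4-convolutional-layer CNN (4L-CNN) for benign/malignant slices.

A small, fully deterministic NumPy implementation: four valid (no padding,
stride 1) convolution blocks, each followed by ReLU and 2x2 max-pooling
(stride 2, no padding), then fully connected layers 256-ReLU -> 512-ReLU ->
512 with 50% dropout -> 2-way softmax.  Training uses RMSprop (running
mean of squared gradients) with categorical cross-entropy, batch size 10
and learning rate 1e-5 by default.  Convolutions are evaluated as im2col
matrix products; all randomness (init, shuffling, dropout) flows from a
single seed, so identical runs produce identical weights.

The reference input is 224x224x3; grayscale phantoms are replicated to
three channels and any other size is resized on the way in.  Smaller input
shapes are configurable and shrink the network proportionally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CNNConfig:
    """Architecture and training hyperparameters of the 4L-CNN."""

    input_shape: tuple[int, int, int] = (224, 224, 3)
    conv_filters: tuple[int, int, int, int] = (32, 32, 64, 64)
    kernel_size: int = 3
    pool_size: int = 2
    dense_units: tuple[int, int, int] = (256, 512, 512)
    dropout: float = 0.5
    n_classes: int = 2
    learning_rate: float = 1e-5
    batch_size: int = 10
    epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conv_filters) != 4:
            raise ValueError("the 4L-CNN has exactly four convolution blocks")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise ValueError("learning_rate must be > 0 and batch_size >= 1")


class ConfigError(ValueError):
    """The layer plan is infeasible for the input shape."""


def shape_trace(cfg: CNNConfig) -> list[tuple[str, tuple[int, ...]]]:
    """Closed-form per-layer output shapes (H, W, C) for the config.

    Valid convolution: ``out = (in - k) // 1 + 1``; pooling:
    ``out = (in - pool) // pool + 1``.  Raises :class:`ConfigError` if any
    spatial dimension would fall below 1.
    """
    H, W, C = cfg.input_shape
    k, p = cfg.kernel_size, cfg.pool_size
    trace: list[tuple[str, tuple[int, ...]]] = [("input", (H, W, C))]
    for i, f in enumerate(cfg.conv_filters, start=1):
        H, W = H - k + 1, W - k + 1
        if H < 1 or W < 1:
            raise ConfigError(f"conv{i} output would be {H}x{W}")
        trace.append((f"conv{i}", (H, W, f)))
        H, W = (H - p) // p + 1, (W - p) // p + 1
        if H < 1 or W < 1:
            raise ConfigError(f"pool{i} output would be {H}x{W}")
        trace.append((f"pool{i}", (H, W, f)))
        C = f
    flat = H * W * C
    trace.append(("flatten", (flat,)))
    for i, u in enumerate(cfg.dense_units, start=1):
        trace.append((f"dense{i}", (u,)))
    trace.append(("softmax", (cfg.n_classes,)))
    return trace


def parameter_count(cfg: CNNConfig) -> int:
    """Total trainable parameters, by the layer-wise closed form."""
    k = cfg.kernel_size
    total = 0
    c_in = cfg.input_shape[2]
    for f in cfg.conv_filters:
        total += f * c_in * k * k + f
        c_in = f
    flat = next(s[0] for name, s in shape_trace(cfg) if name == "flatten")
    widths = (flat, *cfg.dense_units, cfg.n_classes)
    for a, b in zip(widths[:-1], widths[1:]):
        total += a * b + b
    return total


# ---------------------------------------------------------------------------
# layers (NCHW tensors)

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H, W) -> (B, Ho*Wo, C*k*k) patch matrix (valid windows)."""
    v = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    B, C, Ho, Wo = v.shape[:4]
    return v.transpose(0, 2, 3, 1, 4, 5).reshape(B, Ho * Wo, C * k * k), Ho, Wo


class _Conv:
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k))
        self.b = np.zeros(c_out)
        self.k = k

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        cols, Ho, Wo = _im2col(x, self.k)
        self._cols, self._x_shape = cols, x.shape
        out = cols @ self.W.reshape(self.W.shape[0], -1).T + self.b
        return out.transpose(0, 2, 1).reshape(x.shape[0], -1, Ho, Wo)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, F, Ho, Wo = dout.shape
        dflat = dout.reshape(B, F, Ho * Wo).transpose(0, 2, 1)  # (B, L, F)
        Wmat = self.W.reshape(F, -1)
        self.dW = np.einsum("blf,blp->fp", dflat, self._cols).reshape(self.W.shape)
        self.db = dout.sum(axis=(0, 2, 3))
        dcols = dflat @ Wmat  # (B, L, C*k*k)
        Bx, C, H, Wd = self._x_shape
        dx = np.zeros(self._x_shape)
        dcols = dcols.reshape(B, Ho, Wo, C, self.k, self.k)
        for ki in range(self.k):
            for kj in range(self.k):
                dx[:, :, ki:ki + Ho, kj:kj + Wo] += dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        return dx

    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


class _ReLU:
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask

    def params(self):
        return []


class _MaxPool:
    def __init__(self, p: int):
        self.p = p

    def forward(self, x, train):
        p = self.p
        B, C, H, W = x.shape
        Ho, Wo = (H - p) // p + 1, (W - p) // p + 1
        xc = x[:, :, :Ho * p, :Wo * p]
        win = xc.reshape(B, C, Ho, p, Wo, p).transpose(0, 1, 2, 4, 3, 5)
        win = win.reshape(B, C, Ho, Wo, p * p)
        self._arg = np.argmax(win, axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(win, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        p = self.p
        B, C, Ho, Wo = dout.shape
        dwin = np.zeros((B, C, Ho, Wo, p * p))
        np.put_along_axis(dwin, self._arg[..., None], dout[..., None], axis=-1)
        dwin = dwin.reshape(B, C, Ho, Wo, p, p).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros(self._in_shape)
        dx[:, :, :Ho * p, :Wo * p] = dwin.reshape(B, C, Ho * p, Wo * p)
        return dx

    def params(self):
        return []


class _Flatten:
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)

    def params(self):
        return []


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


class _Dropout:
    """Inverted dropout: active only in training, identity at inference."""

    def __init__(self, p: float):
        self.p = p
        self.rng = np.random.default_rng(0)

    def forward(self, x, train):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask

    def params(self):
        return []


class Model4LCNN:
    """The layer graph plus forward/backward plumbing."""

    def __init__(self, cfg: CNNConfig):
        self.cfg = cfg
        self.trace = shape_trace(cfg)  # validates feasibility
        rng = np.random.default_rng(cfg.seed)
        k, p = cfg.kernel_size, cfg.pool_size
        layers: list = []
        c_in = cfg.input_shape[2]
        for f in cfg.conv_filters:
            layers += [_Conv(c_in, f, k, rng), _ReLU(), _MaxPool(p)]
            c_in = f
        layers.append(_Flatten())
        flat = next(s[0] for name, s in self.trace if name == "flatten")
        widths = (flat, *cfg.dense_units)
        for a, b in zip(widths[:-1], widths[1:]):
            layers += [_Dense(a, b, rng), _ReLU()]
        layers.pop()  # last dense block: dropout replaces the ReLU
        self.dropout_layer = _Dropout(cfg.dropout)
        layers.append(self.dropout_layer)
        layers.append(_Dense(widths[-1], cfg.n_classes, rng))
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a (B, C, H, W) batch."""
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def parameters(self):
        for li, layer in enumerate(self.layers):
            for name, arr, gname in layer.params():
                yield f"layer{li}.{name}", layer, name, gname

    def n_parameters(self) -> int:
        return sum(getattr(layer, name).size
                   for _, layer, name, _ in self.parameters())

    def get_weights(self) -> dict[str, np.ndarray]:
        return {key: getattr(layer, name).copy()
                for key, layer, name, _ in self.parameters()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for key, layer, name, _ in self.parameters():
            setattr(layer, name, weights[key].copy())


def build_4lcnn(cfg: CNNConfig = CNNConfig()) -> Model4LCNN:
    """Instantiate the 4L-CNN; raises :class:`ConfigError` if infeasible."""
    return Model4LCNN(cfg)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def prepare_input(img: np.ndarray, input_shape: tuple[int, int, int]) -> np.ndarray:
    """Gray/RGB [0,1] image -> (C, H, W) tensor matching the config."""
    from lpbrain.preprocess import resize

    img = np.asarray(img, dtype=np.float64)
    H, W, C = input_shape
    if img.ndim == 2:
        img = np.repeat(img[:, :, None], C, axis=2)
    if img.shape[:2] != (H, W):
        img = resize(img, H, W)
    return img.transpose(2, 0, 1)


@dataclass
class TrainedCNN:
    """Frozen weights + config + per-epoch training history."""

    weights: dict[str, np.ndarray]
    config: CNNConfig
    history: pd.DataFrame
    classes: tuple[str, ...]
    seed: int

    def _model(self) -> Model4LCNN:
        m = build_4lcnn(self.config)
        m.set_weights(self.weights)
        return m

    def save(self, path) -> None:
        import json
        from dataclasses import asdict
        from pathlib import Path

        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.weights)
        meta = {"config": asdict(self.config), "classes": list(self.classes),
                "seed": self.seed}
        path.with_suffix(".json").write_text(json.dumps(meta))
        self.history.to_csv(path.with_suffix(".history.csv"), index=False)

    @classmethod
    def load(cls, path) -> "TrainedCNN":
        import json
        from pathlib import Path

        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        ccfg = meta["config"]
        for key in ("input_shape", "conv_filters", "dense_units"):
            ccfg[key] = tuple(ccfg[key])
        cfg = CNNConfig(**ccfg)
        with np.load(path.with_suffix(".npz")) as z:
            weights = {k: z[k] for k in z.files}
        history = pd.read_csv(path.with_suffix(".history.csv"))
        return cls(weights, cfg, history, tuple(meta["classes"]), meta["seed"])


def train_cnn(
    model: Model4LCNN,
    images,
    labels,
    epochs: int | None = None,
    seed: int = 0,
    stop_at_accuracy: float | None = None,
) -> TrainedCNN:
    """Train with RMSprop + categorical cross-entropy; fully seeded.

    History records (epoch, loss, accuracy) per epoch, where ``loss`` is
    the mean mini-batch cross-entropy seen during the epoch and
    ``accuracy`` is the end-of-epoch training accuracy evaluated in
    inference mode (dropout off) — the with-dropout running accuracy is a
    noisy underestimate.  ``stop_at_accuracy`` (e.g. 100.0) ends training
    early once that accuracy reaches the threshold.
    """
    cfg = model.cfg
    epochs = cfg.epochs if epochs is None else int(epochs)
    classes = tuple(sorted(set(labels)))
    if len(classes) < 2:
        raise ValueError(f"need >= 2 classes, got {classes}")
    counts = {c: sum(1 for l in labels if l == c) for c in classes}
    if min(counts.values()) == 0:
        raise ValueError(f"empty class in training labels: {counts}")

    X = np.stack([prepare_input(im, cfg.input_shape) for im in images])
    y = np.array([classes.index(l) for l in labels])
    n = X.shape[0]

    rng = np.random.default_rng(seed)
    model.dropout_layer.rng = np.random.default_rng(rng.integers(2 ** 31))

    # RMSprop state: running mean of squared gradients per parameter
    state = {key: np.zeros_like(getattr(layer, name))
             for key, layer, name, _ in model.parameters()}
    decay, eps, lr = 0.9, 1e-8, cfg.learning_rate

    records = []
    for epoch in range(1, epochs + 1):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = X[idx], y[idx]
            logits = model.forward(xb, train=True)
            probs = _softmax(logits)
            losses.append(float(-np.mean(
                np.log(probs[np.arange(len(idx)), yb] + 1e-12))) * len(idx))
            dlogits = probs.copy()
            dlogits[np.arange(len(idx)), yb] -= 1.0
            dlogits /= len(idx)
            model.backward(dlogits)
            for key, layer, name, gname in model.parameters():
                g = getattr(layer, gname)
                state[key] = decay * state[key] + (1 - decay) * g * g
                getattr(layer, name)[...] -= lr * g / (np.sqrt(state[key]) + eps)
        loss = sum(losses) / n
        eval_logits = model.forward(X, train=False)
        acc = 100.0 * float(np.mean(np.argmax(eval_logits, axis=1) == y))
        records.append({"epoch": epoch, "loss": loss, "accuracy": acc})
        if stop_at_accuracy is not None and acc >= stop_at_accuracy:
            break

    return TrainedCNN(model.get_weights(), cfg, pd.DataFrame(records),
                      classes, seed)


def predict_cnn(model: TrainedCNN, img: np.ndarray) -> tuple[str, np.ndarray]:
    """Classify one image: returns ``(label, class probabilities)``.

    Inference runs with dropout disabled, so repeated calls are identical.
    """
    net = model._model()
    x = prepare_input(img, model.config.input_shape)[None]
    probs = _softmax(net.forward(x, train=False))[0]
    return model.classes[int(np.argmax(probs))], probs


def predict_cnn_batch(model: TrainedCNN, images) -> list[str]:
    net = model._model()
    X = np.stack([prepare_input(im, model.config.input_shape) for im in images])
    probs = _softmax(net.forward(X, train=False))
    return [model.classes[i] for i in np.argmax(probs, axis=1)]
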