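"""VGG-style convolutional feature extractor with a NumPy training backend.

The full architecture is the 19-weight-layer network: five convolution
groups of 2-2-4-4-4 conv+ReLU layers (64/128/256/512/512 filters, all
3x3, stride 1, pad 1), each followed by 2x2 stride-2 max pooling, then
three fully-connected layers of 4096/4096/2 units with ReLU and dropout
0.5 on the first two and softmax on the last.  From a 224x224x3 input
the conv stack ends at 7x7x512 = 25,088 activations; the second
fully-connected layer's 4096 post-ReLU activations are the deep feature
vector, and the 2-unit softmax head doubles as a direct classifier.

Training uses stochastic gradient descent with momentum 0.9, mini-batch
32, initial learning rate 0.001 dropped by a factor of 0.1 every 3
epochs, for 9 epochs, with He-style seeded initialization (an optional
hook accepts externally supplied initial weights).  The full network is
constructed and shape-verified; a structurally identical *reduced* spec
(two conv groups of 8/16 filters, 512-wide fully-connected layers,
small square input) is the configuration actually trained in tests.

Everything here is plain NumPy: convolution is evaluated as nine shifted
matrix products (one per 3x3 tap), which keeps forward and backward
passes exact and dependency-free.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from irispad.errors import TrainingError, ValidationError
from irispad.mlbp import FeatureVector


@dataclass(frozen=True)
class LayerSpec:
    kind: str  # conv | relu | maxpool | fc | dropout | softmax
    n: int = 0  # filters (conv) or units (fc)
    size: int = 0  # filter/pool side
    stride: int = 1
    pad: int = 0
    rate: float = 0.0  # dropout rate

    def __post_init__(self) -> None:
        if self.kind not in ("conv", "relu", "maxpool", "fc", "dropout", "softmax"):
            raise ValidationError(f"unknown layer kind {self.kind!r}")


@dataclass(frozen=True)
class NetworkSpec:
    """Named groups of layers plus the input geometry."""

    groups: tuple[tuple[str, tuple[LayerSpec, ...]], ...]
    input_shape: tuple[int, int, int] = (224, 224, 3)
    n_classes: int = 2

    @property
    def layers(self) -> list[LayerSpec]:
        return [l for _, ls in self.groups for l in ls]

    @property
    def n_conv_layers(self) -> int:
        return sum(1 for l in self.layers if l.kind == "conv")

    @property
    def n_fc_layers(self) -> int:
        return sum(1 for l in self.layers if l.kind == "fc")

    @property
    def n_weight_layers(self) -> int:
        return self.n_conv_layers + self.n_fc_layers


def _conv_group(name: str, filters: int, repeat: int) -> tuple[str, tuple[LayerSpec, ...]]:
    layers: list[LayerSpec] = []
    for _ in range(repeat):
        layers.append(LayerSpec("conv", n=filters, size=3, stride=1, pad=1))
        layers.append(LayerSpec("relu"))
    layers.append(LayerSpec("maxpool", size=2, stride=2))
    return name, tuple(layers)


def _fc_group(name: str, units: int, dropout: float) -> tuple[str, tuple[LayerSpec, ...]]:
    layers = [LayerSpec("fc", n=units), LayerSpec("relu")]
    if dropout > 0:
        layers.append(LayerSpec("dropout", rate=dropout))
    return name, tuple(layers)


def build_vgg19_spec() -> NetworkSpec:
    """The full 19-weight-layer network (16 conv + 3 fc)."""
    groups = (
        _conv_group("G_1", 64, 2),
        _conv_group("G_2", 128, 2),
        _conv_group("G_3", 256, 4),
        _conv_group("G_4", 512, 4),
        _conv_group("G_5", 512, 4),
        _fc_group("G_6", 4096, 0.5),
        _fc_group("G_7", 4096, 0.5),
        ("G_8", (LayerSpec("fc", n=2), LayerSpec("softmax"))),
    )
    return NetworkSpec(groups=groups, input_shape=(224, 224, 3), n_classes=2)


def build_reduced_spec(
    input_size: int = 64,
    conv_filters: tuple[int, ...] = (8, 16),
    fc_width: int = 512,
    dropout: float = 0.0,
) -> NetworkSpec:
    """Desk-scale network with the same structural grammar as the full one.

    Dropout is off by default: it regularizes the full network's
    4096-wide layers against overfitting a 50k-image training set, but at
    desk scale (a few hundred images, a handful of SGD steps) it only
    injects gradient noise the short schedule cannot average out.
    """
    groups = [
        _conv_group(f"G_{i + 1}", f, 1) for i, f in enumerate(conv_filters)
    ]
    n = len(conv_filters)
    groups.append(_fc_group(f"G_{n + 1}", fc_width, dropout))
    groups.append(_fc_group(f"G_{n + 2}", fc_width, dropout))
    groups.append((f"G_{n + 3}", (LayerSpec("fc", n=2), LayerSpec("softmax"))))
    return NetworkSpec(
        groups=tuple(groups), input_shape=(input_size, input_size, 3), n_classes=2
    )


def output_shapes(spec: NetworkSpec) -> list[tuple[str, tuple[int, ...]]]:
    """Per-group output shape, by standard conv/pool arithmetic.

    out = floor((in + 2*pad - filter)/stride) + 1 for conv and pool.
    """
    shape: tuple[int, ...] = spec.input_shape
    out: list[tuple[str, tuple[int, ...]]] = []
    for name, layers in spec.groups:
        for l in layers:
            if l.kind == "conv":
                h, w, _ = shape
                oh = (h + 2 * l.pad - l.size) // l.stride + 1
                ow = (w + 2 * l.pad - l.size) // l.stride + 1
                if oh <= 0 or ow <= 0:
                    raise ValidationError(f"non-positive conv output in {name}")
                shape = (oh, ow, l.n)
            elif l.kind == "maxpool":
                h, w, c = shape
                oh = (h + 2 * l.pad - l.size) // l.stride + 1
                ow = (w + 2 * l.pad - l.size) // l.stride + 1
                if oh <= 0 or ow <= 0:
                    raise ValidationError(f"non-positive pool output in {name}")
                shape = (oh, ow, c)
            elif l.kind == "fc":
                shape = (l.n,)
        out.append((name, shape))
    return out


@dataclass(frozen=True)
class TrainConfig:
    """SGD-with-momentum schedule (defaults are the study settings)."""

    momentum: float = 0.9
    batch_size: int = 32
    initial_lr: float = 0.001
    lr_drop_factor: float = 0.1
    lr_drop_period: int = 3
    n_epochs: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.batch_size, self.initial_lr, self.lr_drop_period, self.n_epochs) <= 0:
            raise ValidationError("training parameters must be positive")
        if self.lr_drop_period > self.n_epochs:
            raise ValidationError("lr_drop_period must not exceed n_epochs")


def lr_schedule(config: TrainConfig) -> list[float]:
    """Learning rate for epochs 1..n: a step drop every drop period."""
    return [
        config.initial_lr * config.lr_drop_factor ** ((e - 1) // config.lr_drop_period)
        for e in range(1, config.n_epochs + 1)
    ]


def preprocess_input(images: np.ndarray) -> np.ndarray:
    """Map 8-bit intensities to the network's input range.

    Intensities are scaled to [0, 1] and centered at the mid-gray 0.5
    with a gain of 4, giving inputs roughly zero-mean with unit-order
    variance.  Centering matters here: with the short step-decayed SGD
    schedule an uncentered input leaves the first-layer gradients
    dominated by the DC component and the loss barely moves.
    """
    return (np.asarray(images, dtype=np.float64) / 255.0 - 0.5) * 4.0


# ---------------------------------------------------------------------------
# NumPy forward/backward primitives (NHWC layout)

def _conv3_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    # x: (N,H,W,C), w: (3,3,C,F), stride 1 pad 1
    n, h, wd, c = x.shape
    f = w.shape[-1]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    out = np.empty((n, h, wd, f))
    out[:] = b
    flat = out.reshape(-1, f)
    for u in range(3):
        for v in range(3):
            flat += xp[:, u : u + h, v : v + wd, :].reshape(-1, c) @ w[u, v]
    return out


def _conv3_backward(
    x: np.ndarray, w: np.ndarray, dout: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n, h, wd, c = x.shape
    f = w.shape[-1]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    dxp = np.zeros_like(xp)
    dw = np.zeros_like(w)
    dflat = dout.reshape(-1, f)
    for u in range(3):
        for v in range(3):
            patch = xp[:, u : u + h, v : v + wd, :].reshape(-1, c)
            dw[u, v] = patch.T @ dflat
            dxp[:, u : u + h, v : v + wd, :] += (dflat @ w[u, v].T).reshape(n, h, wd, c)
    db = dflat.sum(axis=0)
    return dxp[:, 1:-1, 1:-1, :], dw, db


def _pool2_forward(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n, h, w, c = x.shape
    xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
    xr = xr.reshape(n, h // 2, w // 2, c, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _pool2_backward(dout: np.ndarray, idx: np.ndarray, in_shape) -> np.ndarray:
    n, h, w, c = in_shape
    dxr = np.zeros((n, h // 2, w // 2, c, 4))
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
    dxr = dxr.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
    return dxr.reshape(n, h, w, c)


class CnnModel:
    """A trained (or freshly initialized) network instance.

    Weights follow the spec's layer order; dropout is active only during
    training steps, so inference — feature extraction and classification
    — is deterministic.
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        self.trained = False
        rng = np.random.default_rng(seed)
        self.params: list[dict[str, np.ndarray]] = []
        shape: tuple[int, ...] = spec.input_shape
        for l in spec.layers:
            if l.kind == "conv":
                h, w, c = shape
                fan_in = l.size * l.size * c
                wts = rng.normal(0.0, np.sqrt(2.0 / fan_in), (l.size, l.size, c, l.n))
                self.params.append({"w": wts, "b": np.zeros(l.n)})
                shape = (h, w, l.n)
            elif l.kind == "maxpool":
                h, w, c = shape
                shape = (h // 2, w // 2, c)
            elif l.kind == "fc":
                fan_in = int(np.prod(shape))
                wts = rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, l.n))
                self.params.append({"w": wts, "b": np.zeros(l.n)})
                shape = (l.n,)

    # -- structural helpers -------------------------------------------------

    def _fc_group_indices(self) -> list[int]:
        """Indices (into spec.layers) of the fc layers, in order."""
        return [i for i, l in enumerate(self.spec.layers) if l.kind == "fc"]

    @property
    def feature_dim(self) -> int:
        return self.spec.layers[self._fc_group_indices()[1]].n

    def load_weights(self, source) -> None:
        """Optional hook: install externally supplied initial weights.

        ``source`` is a sequence of ``{"w": array, "b": array}`` dicts in
        layer order; shapes must match the spec.
        """
        if len(source) != len(self.params):
            raise ValidationError("weight count mismatch")
        for mine, theirs in zip(self.params, source):
            if mine["w"].shape != theirs["w"].shape:
                raise ValidationError("weight shape mismatch")
            mine["w"] = np.array(theirs["w"], dtype=np.float64)
            mine["b"] = np.array(theirs["b"], dtype=np.float64)

    # -- forward / backward -------------------------------------------------

    def _forward(
        self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None
    ) -> tuple[np.ndarray, list]:
        """Returns logits and a cache of per-layer records for backward."""
        cache: list = []
        p = 0
        h = x
        for l in self.spec.layers:
            if l.kind == "conv":
                wts = self.params[p]
                out = _conv3_forward(h, wts["w"], wts["b"])
                cache.append(("conv", p, h))
                h = out
                p += 1
            elif l.kind == "relu":
                h = np.maximum(h, 0.0)
                cache.append(("relu", None, h))
            elif l.kind == "maxpool":
                out, idx = _pool2_forward(h)
                cache.append(("maxpool", idx, h.shape))
                h = out
            elif l.kind == "fc":
                wts = self.params[p]
                flat = h.reshape(h.shape[0], -1)
                cache.append(("fc", p, (flat, h.shape)))
                h = flat @ wts["w"] + wts["b"]
                p += 1
            elif l.kind == "dropout":
                if train:
                    assert rng is not None
                    mask = (rng.random(h.shape) >= l.rate) / (1.0 - l.rate)
                    h = h * mask
                    cache.append(("dropout", mask, None))
                else:
                    cache.append(("dropout", None, None))
            elif l.kind == "softmax":
                cache.append(("softmax", None, None))
        return h, cache

    def _backward(self, dlogits: np.ndarray, cache: list) -> list[dict[str, np.ndarray]]:
        grads: list[dict[str, np.ndarray] | None] = [None] * len(self.params)
        d = dlogits
        for kind, aux, stored in reversed(cache):
            if kind == "softmax":
                continue
            if kind == "dropout":
                if aux is not None:
                    d = d * aux
            elif kind == "fc":
                p = aux
                flat, in_shape = stored
                grads[p] = {"w": flat.T @ d, "b": d.sum(axis=0)}
                d = (d @ self.params[p]["w"].T).reshape(in_shape)
            elif kind == "maxpool":
                d = _pool2_backward(d, aux, stored)
            elif kind == "relu":
                d = d * (stored > 0)
            elif kind == "conv":
                p = aux
                d, dw, db = _conv3_backward(stored, self.params[p]["w"], d)
                grads[p] = {"w": dw, "b": db}
        return grads  # type: ignore[return-value]

    # -- inference ----------------------------------------------------------

    def _prep(self, rois: np.ndarray) -> np.ndarray:
        x = np.asarray(rois, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1:] != self.spec.input_shape:
            raise ValidationError(
                f"input shape {x.shape[1:]} does not match spec {self.spec.input_shape}"
            )
        return preprocess_input(x)

    def extract_features(self, roi: np.ndarray) -> FeatureVector:
        """Post-ReLU activations of the second fully-connected layer."""
        feats = self.extract_features_batch(np.asarray(roi, dtype=np.float64)[None])
        return FeatureVector(values=feats[0], kind="cnn")

    def extract_features_batch(self, rois: np.ndarray) -> np.ndarray:
        x = self._prep(rois)
        fc_layers = self._fc_group_indices()
        target = fc_layers[1]
        h = x
        p = 0
        after_target = False
        for i, l in enumerate(self.spec.layers):
            if l.kind == "conv":
                h = _conv3_forward(h, self.params[p]["w"], self.params[p]["b"])
                p += 1
            elif l.kind == "relu":
                h = np.maximum(h, 0.0)
                if after_target:
                    return h.copy()
            elif l.kind == "maxpool":
                h, _ = _pool2_forward(h)
            elif l.kind == "fc":
                h = h.reshape(h.shape[0], -1) @ self.params[p]["w"] + self.params[p]["b"]
                p += 1
            after_target = l.kind == "fc" and i == target
        raise ValidationError("spec has no second fully-connected layer")

    def classify(self, roi: np.ndarray) -> np.ndarray:
        """Softmax class probabilities [p(bona fide), p(attack)]."""
        if not self.trained:
            raise TrainingError("model has not been trained")
        x = self._prep(roi)
        logits, _ = self._forward(x, train=False)
        probs = _softmax(logits)
        return probs[0] if np.asarray(roi).ndim == 3 else probs

    def classify_batch(self, rois: np.ndarray) -> np.ndarray:
        if not self.trained:
            raise TrainingError("model has not been trained")
        logits, _ = self._forward(self._prep(rois), train=False)
        return _softmax(logits)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def train(
    spec: NetworkSpec,
    images: np.ndarray,
    labels: np.ndarray,
    config: TrainConfig | None = None,
    initial_weights=None,
    verbose: bool = False,
) -> CnnModel:
    """Train by SGD with momentum on 2-class cross-entropy.

    ``images``: (N, H, W, 3) in [0, 255]; ``labels``: 0 = bona fide,
    1 = attack.  Deterministic for a fixed config seed.
    """
    if config is None:
        config = TrainConfig()
    images = np.asarray(images, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if images.ndim != 4 or images.shape[1:] != spec.input_shape:
        raise ValidationError(
            f"images shape {images.shape[1:]} does not match spec {spec.input_shape}"
        )
    if len(np.unique(labels)) < 2:
        raise TrainingError("training requires examples of both classes")

    model = CnnModel(spec, seed=config.seed)
    if initial_weights is not None:
        model.load_weights(initial_weights)
    rng = np.random.default_rng(config.seed + 1)
    velocity = [
        {"w": np.zeros_like(p["w"]), "b": np.zeros_like(p["b"])}
        for p in model.params
    ]
    x_all = preprocess_input(images)
    n = len(x_all)
    onehot = np.eye(2)[labels]

    for epoch, lr in enumerate(lr_schedule(config), start=1):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            sel = order[start : start + config.batch_size]
            xb, yb = x_all[sel], onehot[sel]
            logits, cache = model._forward(xb, train=True, rng=rng)
            probs = _softmax(logits)
            loss = -np.mean(np.sum(yb * np.log(probs + 1e-12), axis=1))
            losses.append(loss)
            dlogits = (probs - yb) / len(sel)
            grads = model._backward(dlogits, cache)
            for p, v, g in zip(model.params, velocity, grads):
                for key in ("w", "b"):
                    v[key] = config.momentum * v[key] - lr * g[key]
                    p[key] += v[key]
        if verbose:
            print(f"epoch {epoch}: lr={lr:g} loss={np.mean(losses):.4f}")
    model.trained = True
    model.final_loss = float(np.mean(losses))
    return model


def save_model(model: CnnModel, path) -> None:
    """Single-file archive: JSON spec + weight arrays."""
    spec_json = json.dumps(
        {
            "groups": [
                [name, [asdict(l) for l in layers]]
                for name, layers in model.spec.groups
            ],
            "input_shape": model.spec.input_shape,
            "n_classes": model.spec.n_classes,
            "trained": model.trained,
        }
    )
    arrays = {}
    for i, p in enumerate(model.params):
        arrays[f"w{i}"] = p["w"]
        arrays[f"b{i}"] = p["b"]
    np.savez(path, spec=np.frombuffer(spec_json.encode(), dtype=np.uint8), **arrays)


def load_model(path) -> CnnModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["spec"]).decode())
        spec = NetworkSpec(
            groups=tuple(
                (name, tuple(LayerSpec(**l) for l in layers))
                for name, layers in meta["groups"]
            ),
            input_shape=tuple(meta["input_shape"]),
            n_classes=meta["n_classes"],
        )
        model = CnnModel(spec, seed=0)
        model.load_weights(
            [{"w": data[f"w{i}"], "b": data[f"b{i}"]} for i in range(len(model.params))]
        )
        model.trained = bool(meta["trained"])
    return model
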