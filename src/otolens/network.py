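"""A small, fully introspectable feed-forward convolutional classifier.

Five layer kinds are supported — ``conv``, ``relu``, ``maxpool``,
``flatten``, ``dense`` — which is exactly the vocabulary the relevance
engine understands.  Every forward pass returns an :class:`ActivationTrace`
holding the input and output of every layer, so relevance propagation can
reuse the true activations of the pass it explains.

The network is deliberately tiny (a miniature VGG: conv/relu/maxpool
blocks followed by dense layers) and runs on plain numpy.  Convolutions
use an im2col formulation; training uses minibatch Adam on the softmax
cross-entropy loss with the on-the-fly augmentation scheme of the study
recipe (random 0-360 degree rotation, random horizontal/vertical flips,
random vertical shift of up to 10 pixels).  Everything is seeded through
``numpy.random.Generator``; repeated runs with the same seed produce
bit-identical weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.transform import rotate as _sk_rotate


# ---------------------------------------------------------------------------
# layer specifications


@dataclass(frozen=True)
class LayerSpec:
    """One layer of the network.

    kind-specific fields:
      conv:    in_channels, out_channels, kernel, stride, padding
      maxpool: pool (window and stride)
      dense:   in_units, out_units
      relu / flatten: no parameters
    """

    kind: str
    in_channels: int = 0
    out_channels: int = 0
    kernel: int = 3
    stride: int = 1
    padding: int = 1
    pool: int = 2
    in_units: int = 0
    out_units: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("conv", "relu", "maxpool", "flatten", "dense"):
            raise ValueError(f"unknown layer kind {self.kind!r}")


def conv(in_channels: int, out_channels: int, kernel: int = 3,
         stride: int = 1, padding: int = 1) -> LayerSpec:
    return LayerSpec("conv", in_channels=in_channels, out_channels=out_channels,
                     kernel=kernel, stride=stride, padding=padding)


def relu() -> LayerSpec:
    return LayerSpec("relu")


def maxpool(pool: int = 2) -> LayerSpec:
    return LayerSpec("maxpool", pool=pool)


def flatten() -> LayerSpec:
    return LayerSpec("flatten")


def dense(in_units: int, out_units: int) -> LayerSpec:
    return LayerSpec("dense", in_units=in_units, out_units=out_units)


@dataclass
class NetworkModel:
    """Ordered layers plus their weights and class labels.

    ``params[i]`` is a dict with keys ``"W"`` and ``"b"`` for parametric
    layers (conv weights are stored ``(out_c, in_c, k, k)``; dense weights
    ``(in_units, out_units)``) and an empty dict otherwise.
    ``normalization_stats`` is ``(mean, sd)`` computed from training
    images only and applied identically at train and test time.
    """

    layers: list[LayerSpec]
    params: list[dict]
    class_labels: list[int]
    normalization_stats: tuple[float, float] | None = None

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)


@dataclass
class ActivationTrace:
    """Inputs and outputs of every layer for one forward pass."""

    inputs: list[np.ndarray]
    outputs: list[np.ndarray]

    @property
    def logits(self) -> np.ndarray:
        return self.outputs[-1]


# ---------------------------------------------------------------------------
# model construction


def build_model(
    input_size: int,
    class_labels: list[int],
    conv_channels: tuple[int, ...] = (8, 16),
    dense_units: int = 64,
    kernel: int = 3,
    seed: int = 0,
) -> NetworkModel:
    """Miniature VGG: (conv-relu-maxpool) blocks, then dense-relu-dense."""
    rng = np.random.default_rng(seed)
    layers: list[LayerSpec] = []
    c_in, size = 1, input_size
    for c_out in conv_channels:
        layers += [conv(c_in, c_out, kernel=kernel, padding=kernel // 2),
                   relu(), maxpool(2)]
        c_in = c_out
        size //= 2
    layers.append(flatten())
    flat = c_in * size * size
    if dense_units > 0:
        layers += [dense(flat, dense_units), relu(),
                   dense(dense_units, len(class_labels))]
    else:
        layers.append(dense(flat, len(class_labels)))
    params = init_params(layers, rng)
    return NetworkModel(layers=layers, params=params,
                        class_labels=list(class_labels))


def init_params(layers: list[LayerSpec], rng: np.random.Generator) -> list[dict]:
    """He-style seeded initialization; biases start at zero."""
    params: list[dict] = []
    for spec in layers:
        if spec.kind == "conv":
            fan_in = spec.in_channels * spec.kernel * spec.kernel
            W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                           (spec.out_channels, spec.in_channels,
                            spec.kernel, spec.kernel))
            params.append({"W": W, "b": np.zeros(spec.out_channels)})
        elif spec.kind == "dense":
            W = rng.normal(0.0, np.sqrt(2.0 / spec.in_units),
                           (spec.in_units, spec.out_units))
            params.append({"W": W, "b": np.zeros(spec.out_units)})
        else:
            params.append({})
    return params


# ---------------------------------------------------------------------------
# im2col helpers (shared with the relevance engine)


def im2col(x: np.ndarray, kernel: int, stride: int, padding: int) -> np.ndarray:
    """(B, C, H, W) -> (B, out_h*out_w, C*kernel*kernel) patch matrix."""
    b, c, h, w = x.shape
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    out_h = (h + 2 * padding - kernel) // stride + 1
    out_w = (w + 2 * padding - kernel) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, (kernel, kernel),
                                                       axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]  # (B, C, out_h, out_w, k, k)
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(
        b, out_h * out_w, c * kernel * kernel)
    return np.ascontiguousarray(cols)


def col2im(cols: np.ndarray, x_shape: tuple, kernel: int, stride: int,
           padding: int) -> np.ndarray:
    """Scatter-add the patch matrix back onto the input grid (adjoint of
    :func:`im2col`)."""
    b, c, h, w = x_shape
    out_h = (h + 2 * padding - kernel) // stride + 1
    out_w = (w + 2 * padding - kernel) // stride + 1
    cols = cols.reshape(b, out_h, out_w, c, kernel, kernel)
    xp = np.zeros((b, c, h + 2 * padding, w + 2 * padding))
    for ki in range(kernel):
        for kj in range(kernel):
            xp[:, :, ki:ki + stride * out_h:stride,
               kj:kj + stride * out_w:stride] += cols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
    if padding:
        return xp[:, :, padding:-padding, padding:-padding]
    return xp


def conv_out_shape(spec: LayerSpec, x_shape: tuple) -> tuple:
    b, c, h, w = x_shape
    out_h = (h + 2 * spec.padding - spec.kernel) // spec.stride + 1
    out_w = (w + 2 * spec.padding - spec.kernel) // spec.stride + 1
    return (b, spec.out_channels, out_h, out_w)


def conv_weight_matrix(W: np.ndarray) -> np.ndarray:
    """(out_c, in_c, k, k) -> (in_c*k*k, out_c) matrix matching im2col order."""
    out_c = W.shape[0]
    return W.reshape(out_c, -1).T


# ---------------------------------------------------------------------------
# forward / backward


def _layer_forward(spec: LayerSpec, p: dict, x: np.ndarray) -> np.ndarray:
    if spec.kind == "conv":
        cols = im2col(x, spec.kernel, spec.stride, spec.padding)
        out = cols @ conv_weight_matrix(p["W"]) + p["b"]
        b_, _, oh, ow = conv_out_shape(spec, x.shape)
        return out.reshape(b_, oh, ow, spec.out_channels).transpose(0, 3, 1, 2)
    if spec.kind == "relu":
        return np.maximum(x, 0.0)
    if spec.kind == "maxpool":
        b, c, h, w = x.shape
        k = spec.pool
        if h % k or w % k:
            raise ValueError("maxpool requires spatial dims divisible by pool")
        return x.reshape(b, c, h // k, k, w // k, k).max(axis=(3, 5))
    if spec.kind == "flatten":
        return x.reshape(x.shape[0], -1)
    if spec.kind == "dense":
        if x.shape[1] != spec.in_units:
            raise ValueError(
                f"dense layer expected {spec.in_units} inputs, got {x.shape[1]}")
        return x @ p["W"] + p["b"]
    raise ValueError(spec.kind)


def forward(model: NetworkModel, x: np.ndarray) -> ActivationTrace:
    """Run the network on a batch ``(B, 1, H, W)`` (or ``(H, W)`` for a
    single image) and record every layer's input and output."""
    x = np.asarray(x, dtype=float)
    if model.layers[0].kind == "dense":
        if x.ndim == 1:
            x = x[None, :]
    elif x.ndim == 2:
        x = x[None, None]
    elif x.ndim == 3:
        x = x[:, None]
    inputs, outputs = [], []
    for spec, p in zip(model.layers, model.params):
        inputs.append(x)
        x = _layer_forward(spec, p, x)
        outputs.append(x)
    return ActivationTrace(inputs=inputs, outputs=outputs)


def _layer_backward(spec: LayerSpec, p: dict, x: np.ndarray, out: np.ndarray,
                    dout: np.ndarray) -> tuple[np.ndarray, dict]:
    if spec.kind == "conv":
        b_, oc, oh, ow = dout.shape
        dflat = dout.transpose(0, 2, 3, 1).reshape(b_, oh * ow, oc)
        cols = im2col(x, spec.kernel, spec.stride, spec.padding)
        Wm = conv_weight_matrix(p["W"])
        dW = np.einsum("bli,blo->io", cols, dflat)
        grads = {"W": dW.T.reshape(p["W"].shape), "b": dflat.sum(axis=(0, 1))}
        dcols = dflat @ Wm.T
        dx = col2im(dcols, x.shape, spec.kernel, spec.stride, spec.padding)
        return dx, grads
    if spec.kind == "relu":
        return dout * (x > 0), {}
    if spec.kind == "maxpool":
        b, c, h, w = x.shape
        k = spec.pool
        xr = x.reshape(b, c, h // k, k, w // k, k)
        mx = out[:, :, :, None, :, None]
        # subgradient choice: divide among ties (ties are rare in practice)
        m = (xr == mx)
        m = m / np.maximum(m.sum(axis=(3, 5), keepdims=True), 1)
        dx = m * dout[:, :, :, None, :, None]
        return dx.reshape(b, c, h, w), {}
    if spec.kind == "flatten":
        return dout.reshape(x.shape), {}
    if spec.kind == "dense":
        grads = {"W": x.T @ dout, "b": dout.sum(axis=0)}
        return dout @ p["W"].T, grads
    raise ValueError(spec.kind)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, y_idx: np.ndarray) -> float:
    p = softmax(logits)
    return float(-np.mean(np.log(p[np.arange(len(y_idx)), y_idx] + 1e-12)))


# ---------------------------------------------------------------------------
# augmentation / normalization


def augment(image: np.ndarray, rng: np.random.Generator,
            max_shift: int = 10, angle: float | None = None,
            flip_h: bool | None = None, flip_v: bool | None = None,
            shift: int | None = None, order: int = 1) -> np.ndarray:
    """Random rotation in [0, 360), independent horizontal/vertical flips
    (p = 0.5 each) and a vertical shift uniform in [-10, +10] px.

    Each component can be forced to a fixed value (``angle``, ``flip_h``,
    ``flip_v``, ``shift``) for deterministic use.
    """
    out = np.asarray(image, dtype=float)
    if angle is None:
        angle = rng.uniform(0.0, 360.0)
    if angle % 360.0 != 0.0:
        out = _sk_rotate(out, angle, order=order, preserve_range=True)
    if flip_h if flip_h is not None else rng.random() < 0.5:
        out = out[:, ::-1]
    if flip_v if flip_v is not None else rng.random() < 0.5:
        out = out[::-1, :]
    if shift is None:
        shift = int(rng.integers(-max_shift, max_shift + 1))
    if shift:
        out = ndimage.shift(out, (shift, 0), order=0, cval=0.0)
    return np.clip(out, 0.0, 1.0)


def compute_normalization(images: np.ndarray) -> tuple[float, float]:
    """Channel mean and sd over a stack of training images."""
    mean = float(np.mean(images))
    sd = float(np.std(images))
    if sd == 0.0:
        raise ValueError("degenerate channel: zero standard deviation")
    return mean, sd


def normalize(images: np.ndarray, stats: tuple[float, float]) -> np.ndarray:
    mean, sd = stats
    if sd == 0.0:
        raise ValueError("degenerate channel: zero standard deviation")
    return (np.asarray(images, dtype=float) - mean) / sd


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainConfig:
    """Adam on softmax cross-entropy; batch 8 and lr 4e-4 follow the
    study recipe, the epoch count is problem-size dependent."""

    batch_size: int = 8
    learning_rate: float = 4e-4
    epochs: int = 10
    seed: int = 0
    augment: bool = True
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")


def train(
    model: NetworkModel,
    images: np.ndarray,
    ages: np.ndarray,
    config: TrainConfig,
) -> tuple[NetworkModel, list[dict]]:
    """Train in place on raw (unnormalized) images in [0, 1].

    Normalization statistics are computed here from the training images
    and stored on the model; augmentation (if enabled) is applied to the
    raw images each epoch before normalization.  Returns the model and a
    per-epoch history ``[{"epoch", "loss", "accuracy"}, ...]``.
    """
    images = np.asarray(images, dtype=float)
    ages = np.asarray(ages)
    if len(images) == 0:
        raise ValueError("empty training set")
    label_to_idx = {a: i for i, a in enumerate(model.class_labels)}
    try:
        y_idx = np.array([label_to_idx[int(a)] for a in ages])
    except KeyError as e:  # pragma: no cover - config error
        raise ValueError(f"age {e} not among model class labels") from e

    if model.normalization_stats is None:
        model.normalization_stats = compute_normalization(images)

    rng = np.random.default_rng(config.seed)
    m_state = [{k: np.zeros_like(v) for k, v in p.items()} for p in model.params]
    v_state = [{k: np.zeros_like(v) for k, v in p.items()} for p in model.params]
    t = 0
    history: list[dict] = []

    for epoch in range(config.epochs):
        order = rng.permutation(len(images))
        epoch_loss, correct = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            if config.augment:
                batch = np.stack([augment(images[i], rng) for i in idx])
            else:
                batch = images[idx]
            xb = normalize(batch, model.normalization_stats)[:, None]
            yb = y_idx[idx]

            trace = forward(model, xb)
            logits = trace.logits
            epoch_loss += cross_entropy(logits, yb) * len(idx)
            correct += int(np.sum(np.argmax(logits, axis=1) == yb))

            p_soft = softmax(logits)
            dout = p_soft.copy()
            dout[np.arange(len(yb)), yb] -= 1.0
            dout /= len(yb)

            t += 1
            for li in range(len(model.layers) - 1, -1, -1):
                dout, grads = _layer_backward(
                    model.layers[li], model.params[li],
                    trace.inputs[li], trace.outputs[li], dout)
                for k, g in grads.items():
                    m_state[li][k] = (config.beta1 * m_state[li][k]
                                      + (1 - config.beta1) * g)
                    v_state[li][k] = (config.beta2 * v_state[li][k]
                                      + (1 - config.beta2) * g * g)
                    mhat = m_state[li][k] / (1 - config.beta1 ** t)
                    vhat = v_state[li][k] / (1 - config.beta2 ** t)
                    model.params[li][k] = model.params[li][k] - (
                        config.learning_rate * mhat / (np.sqrt(vhat) + config.eps))
        history.append({
            "epoch": epoch,
            "loss": epoch_loss / len(images),
            "accuracy": correct / len(images),
        })
    return model, history


def predict_age(model: NetworkModel, image: np.ndarray) -> tuple[int, np.ndarray]:
    """Predicted age (argmax logit, ties broken toward the lowest class)
    and the logit vector for one normalized image."""
    trace = forward(model, image)
    logits = trace.logits[0]
    return int(model.class_labels[int(np.argmax(logits))]), logits


def predict_batch(model: NetworkModel, images: np.ndarray) -> np.ndarray:
    """Predicted ages for a batch of normalized images ``(B, H, W)``."""
    trace = forward(model, images)
    idx = np.argmax(trace.logits, axis=1)
    return np.array([model.class_labels[i] for i in idx])


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: NetworkModel, path: str | Path) -> None:
    """Single-archive checkpoint: layer specs and class labels in a JSON
    header, weight arrays alongside."""
    header = {
        "layers": [vars(s) for s in model.layers],
        "class_labels": model.class_labels,
        "normalization_stats": model.normalization_stats,
    }
    arrays = {}
    for i, p in enumerate(model.params):
        for k, v in p.items():
            arrays[f"layer{i}_{k}"] = v
    np.savez(path, __header__=np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> NetworkModel:
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        layers = [LayerSpec(**d) for d in header["layers"]]
        params: list[dict] = []
        for i in range(len(layers)):
            p = {}
            for k in ("W", "b"):
                key = f"layer{i}_{k}"
                if key in data:
                    p[k] = data[key]
            params.append(p)
    stats = header["normalization_stats"]
    return NetworkModel(
        layers=layers, params=params,
        class_labels=[int(a) for a in header["class_labels"]],
        normalization_stats=tuple(stats) if stats is not None else None,
    )
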