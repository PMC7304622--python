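"""Shared fixtures and independent brute-force oracles.

The LRP oracle here is deliberately naive: convolutions are expanded to
explicit dense matrices with Python loops, the forward pass is a
per-neuron loop, and relevance propagation evaluates every message
R_{i<-j} individually from the alpha-beta rule.  It shares no code path
with the vectorized engine it checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from otolens import network
from otolens.network import LayerSpec, NetworkModel


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


# ---------------------------------------------------------------------------
# tiny random networks


def make_tiny_model(rng, input_size=6, conv_channels=2, dense_units=5,
                    n_classes=3, nonneg=False, zero_bias=False):
    """conv-relu-maxpool-flatten-dense-relu-dense on a small input."""
    layers = [
        network.conv(1, conv_channels, kernel=3, padding=1),
        network.relu(),
        network.maxpool(2),
        network.flatten(),
        network.dense(conv_channels * (input_size // 2) ** 2, dense_units),
        network.relu(),
        network.dense(dense_units, n_classes),
    ]
    params = network.init_params(layers, rng)
    for p in params:
        if not p:
            continue
        if nonneg:
            p["W"] = np.abs(p["W"])
        if zero_bias:
            p["b"] = np.zeros_like(p["b"])
        else:
            p["b"] = rng.normal(0, 0.1, p["b"].shape)
    return NetworkModel(layers=layers, params=params,
                        class_labels=list(range(1, n_classes + 1)))


# ---------------------------------------------------------------------------
# naive forward (per-neuron loops)


def conv_as_matrix(spec: LayerSpec, W: np.ndarray, in_shape):
    """Explicit dense matrix of a convolution, built index by index."""
    c, h, w = in_shape
    oh = (h + 2 * spec.padding - spec.kernel) // spec.stride + 1
    ow = (w + 2 * spec.padding - spec.kernel) // spec.stride + 1
    M = np.zeros((c * h * w, spec.out_channels * oh * ow))
    for oc in range(spec.out_channels):
        for oy in range(oh):
            for ox in range(ow):
                out_idx = oc * oh * ow + oy * ow + ox
                for ci in range(c):
                    for ky in range(spec.kernel):
                        for kx in range(spec.kernel):
                            iy = oy * spec.stride - spec.padding + ky
                            ix = ox * spec.stride - spec.padding + kx
                            if 0 <= iy < h and 0 <= ix < w:
                                in_idx = ci * h * w + iy * w + ix
                                M[in_idx, out_idx] = W[oc, ci, ky, kx]
    return M, (spec.out_channels, oh, ow)


def naive_forward(model: NetworkModel, image: np.ndarray):
    """Per-neuron forward pass; returns the flat activation entering each
    layer, the flat activation leaving it, and shape bookkeeping."""
    shape = (1, image.shape[0], image.shape[1])
    a = np.asarray(image, dtype=float).ravel().copy()
    records = []
    for spec, p in zip(model.layers, model.params):
        a_in, shape_in = a.copy(), shape
        if spec.kind == "conv":
            M, shape = conv_as_matrix(spec, p["W"], shape)
            out = np.zeros(M.shape[1])
            for j in range(M.shape[1]):
                s = 0.0
                for i in range(M.shape[0]):
                    s += a[i] * M[i, j]
                out[j] = s + p["b"][j // (shape[1] * shape[2])]
            a = out
        elif spec.kind == "dense":
            M = p["W"]
            out = np.zeros(M.shape[1])
            for j in range(M.shape[1]):
                s = 0.0
                for i in range(M.shape[0]):
                    s += a[i] * M[i, j]
                out[j] = s + p["b"][j]
            a = out
            shape = (M.shape[1],)
        elif spec.kind == "relu":
            a = np.array([max(v, 0.0) for v in a])
        elif spec.kind == "maxpool":
            c, h, w = shape
            k = spec.pool
            grid = a.reshape(c, h, w)
            out = np.zeros((c, h // k, w // k))
            for ci in range(c):
                for oy in range(h // k):
                    for ox in range(w // k):
                        out[ci, oy, ox] = grid[ci, oy * k:(oy + 1) * k,
                                               ox * k:(ox + 1) * k].max()
            a = out.ravel()
            shape = (c, h // k, w // k)
        elif spec.kind == "flatten":
            shape = (int(np.prod(shape)),)
        records.append({"spec": spec, "p": p, "a_in": a_in,
                        "shape_in": shape_in, "a_out": a.copy(),
                        "shape_out": shape})
    return records


def naive_ab_backward(a, M, r_upper, alpha, beta, eps):
    """Every message of the alpha-beta rule, evaluated individually."""
    n_in, n_out = M.shape
    r = np.zeros(n_in)
    for j in range(n_out):
        z = [a[i] * M[i, j] for i in range(n_in)]
        sp = sum(max(v, 0.0) for v in z)
        sn = sum(min(v, 0.0) for v in z)
        for i in range(n_in):
            msg = alpha * max(z[i], 0.0) / (sp + eps)
            if beta != 0.0:
                msg -= beta * min(z[i], 0.0) / (sn - eps)
            r[i] += msg * r_upper[j]
    return r


def naive_relevance(model: NetworkModel, image: np.ndarray, target_class,
                    alpha=1.0, beta=0.0, eps=1e-9):
    """Brute-force LRP map (and per-layer sums) for one image."""
    records = naive_forward(model, image)
    logits = records[-1]["a_out"]
    idx = model.class_labels.index(target_class)
    r = np.zeros_like(logits)
    r[idx] = logits[idx]
    sums = [float(r.sum())]
    for rec in reversed(records):
        spec, p = rec["spec"], rec["p"]
        if spec.kind == "conv":
            M, _ = conv_as_matrix(spec, p["W"], rec["shape_in"])
            r = naive_ab_backward(rec["a_in"], M, r, alpha, beta, eps)
        elif spec.kind == "dense":
            r = naive_ab_backward(rec["a_in"], p["W"], r, alpha, beta, eps)
        elif spec.kind == "maxpool":
            c, h, w = rec["shape_in"]
            k = spec.pool
            grid = rec["a_in"].reshape(c, h, w)
            upper = r.reshape(c, h // k, w // k)
            lower = np.zeros((c, h, w))
            for ci in range(c):
                for oy in range(h // k):
                    for ox in range(w // k):
                        win = grid[ci, oy * k:(oy + 1) * k,
                                   ox * k:(ox + 1) * k]
                        m = win == win.max()
                        lower[ci, oy * k:(oy + 1) * k,
                              ox * k:(ox + 1) * k] += (
                            m / m.sum() * upper[ci, oy, ox])
            r = lower.ravel()
        # relu and flatten pass relevance through unchanged
        sums.append(float(r.sum()))
    h, w = image.shape
    return r.reshape(h, w), sums
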