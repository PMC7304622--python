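"""Layer-wise relevance propagation (LRP) with the alpha-beta rule.

LRP explains a single network output by redistributing the output
neuron's pre-softmax score ``R_f = x_f`` backwards through the layers
down to the input pixels.  Between two consecutive layers the message a
lower neuron *i* receives from an upper neuron *j* is its share of the
upper neuron's relevance, proportional to its contribution
``q_ij`` to that neuron's activation:

    R_{i<-j} = q_ij / sum_i q_ij * R_j,        R_i = sum_j R_{i<-j}.

With the alpha-beta rule the positive and negative parts of the
pre-activation products ``a_i * w_ij`` are normalized separately,

    R_i = sum_j ( alpha * (a_i w_ij)+ / sum_i (a_i w_ij)+
                 - beta * (a_i w_ij)- / sum_i (a_i w_ij)- ) * R_j,

with ``alpha - beta = 1`` and ``beta >= 0``.  Setting ``beta = 0``
(the alpha1-beta0 rule used throughout this package by default) keeps
only the activating contributions; with ReLU activations, non-negative
inputs and a non-negative starting relevance, every propagated score
stays non-negative.

Implementation notes (conventions this engine commits to):

* biases are excluded from numerator and denominators; a stabilizer
  (default 1e-9) guards empty denominators, so conservation is exact
  only for bias-free layers and leakage elsewhere is reported, not
  hidden (:func:`audit_conservation`);
* convolutions reuse the im2col patch formulation of the forward pass,
  so the positive part of the product matrix is computed as
  ``cols+ @ W+ + cols- @ W-`` without materializing per-message arrays;
* max-pooling redistributes relevance winner-take-all to the argmax of
  each window, splitting equally on ties; flatten is an index-wise
  pass-through; ReLU passes relevance through unchanged;
* the rule is applied unchanged at the first (input) layer as well —
  no dedicated input-domain rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from .network import (ActivationTrace, LayerSpec, NetworkModel, col2im,
                      conv_out_shape, conv_weight_matrix, forward, im2col)


@dataclass(frozen=True)
class RuleParams:
    """alpha-beta rule parameters; alpha - beta = 1 and beta >= 0."""

    alpha: float = 1.0
    beta: float = 0.0
    stabilizer: float = 1e-9

    def __post_init__(self) -> None:
        if abs(self.alpha - self.beta - 1.0) > 1e-12:
            raise ValueError("alpha - beta must equal 1")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.stabilizer <= 0:
            raise ValueError("stabilizer must be positive")


ALPHA1BETA0 = RuleParams(alpha=1.0, beta=0.0)


@dataclass
class RelevanceMap:
    """Per-pixel relevance for one image and one target class."""

    scores: np.ndarray  # same (H, W) shape as the input image
    target_class: int
    rule: RuleParams
    per_layer_sums: list[float]  # output-to-input order, R_f first
    r_f: float  # initial relevance (target logit)


def init_relevance(trace: ActivationTrace, target_class: int,
                   class_labels: list[int]) -> np.ndarray:
    """Output-layer relevance: the target class's logit at its own slot,
    zero elsewhere (R_f = x_f)."""
    if target_class not in class_labels:
        raise ValueError(f"target class {target_class} not among model classes")
    logits = np.asarray(trace.logits)
    if logits.ndim == 2:
        logits = logits[0]
    r = np.zeros_like(logits)
    idx = class_labels.index(target_class)
    r[idx] = logits[idx]
    return r


def _alphabeta_matrix(xp, xn, Wp, Wn, upper, params):
    """Shared alpha-beta backward step in patch-matrix form.

    ``xp``/``xn`` are the positive/negative parts of the lower
    activations arranged as (..., n_in); ``Wp``/``Wn`` those of the
    weight matrix (n_in, n_out); ``upper`` is (..., n_out) relevance.
    """
    eps = params.stabilizer
    sp = xp @ Wp + xn @ Wn  # sum of positive products, >= 0
    tp = params.alpha * upper / (sp + eps)
    lower = (tp @ Wp.T) * xp + (tp @ Wn.T) * xn
    if params.beta != 0.0:
        sn = xp @ Wn + xn @ Wp  # sum of negative products, <= 0
        tn = -params.beta * upper / (sn - eps)
        lower = lower + (tn @ Wn.T) * xp + (tn @ Wp.T) * xn
    return lower


def propagate_alphabeta(spec: LayerSpec, p: dict, x: np.ndarray,
                        upper: np.ndarray, params: RuleParams) -> np.ndarray:
    """alpha-beta propagation through one dense or conv layer.

    ``x`` is the layer's input activation from the same forward pass,
    ``upper`` the relevance arriving at the layer's output.  Biases do
    not take part.
    """
    if spec.kind == "dense":
        xp = np.maximum(x, 0.0)
        xn = np.minimum(x, 0.0)
        W = p["W"]
        return _alphabeta_matrix(xp, xn, np.maximum(W, 0.0),
                                 np.minimum(W, 0.0), upper, params)
    if spec.kind == "conv":
        cols = im2col(x, spec.kernel, spec.stride, spec.padding)
        Wm = conv_weight_matrix(p["W"])
        b_, oc, oh, ow = conv_out_shape(spec, x.shape)
        upper_flat = upper.transpose(0, 2, 3, 1).reshape(b_, oh * ow, oc)
        lower_cols = _alphabeta_matrix(
            np.maximum(cols, 0.0), np.minimum(cols, 0.0),
            np.maximum(Wm, 0.0), np.minimum(Wm, 0.0), upper_flat, params)
        return col2im(lower_cols, x.shape, spec.kernel, spec.stride,
                      spec.padding)
    raise ValueError(f"alpha-beta rule applies to dense/conv, not {spec.kind}")


def propagate_pool(spec: LayerSpec, x: np.ndarray, out: np.ndarray,
                   upper: np.ndarray) -> np.ndarray:
    """Winner-take-all relevance redistribution through max-pooling;
    window ties split equally.  Conserves the total exactly."""
    b, c, h, w = x.shape
    k = spec.pool
    xr = x.reshape(b, c, h // k, k, w // k, k)
    m = (xr == out[:, :, :, None, :, None]).astype(float)
    m /= m.sum(axis=(3, 5), keepdims=True)
    lower = m * upper[:, :, :, None, :, None]
    return lower.reshape(b, c, h, w)


def propagate_layer(spec: LayerSpec, p: dict, x: np.ndarray, out: np.ndarray,
                    upper: np.ndarray, params: RuleParams) -> np.ndarray:
    if spec.kind in ("dense", "conv"):
        return propagate_alphabeta(spec, p, x, upper, params)
    if spec.kind == "maxpool":
        return propagate_pool(spec, x, out, upper)
    if spec.kind == "relu":
        return upper
    if spec.kind == "flatten":
        return upper.reshape(x.shape)
    raise ValueError(f"unsupported layer kind for relevance propagation: "
                     f"{spec.kind!r}")


def compute_relevance_map(
    model: NetworkModel,
    image: np.ndarray,
    target_class: int | None = None,
    params: RuleParams = ALPHA1BETA0,
    trace: ActivationTrace | None = None,
) -> RelevanceMap:
    """Full LRP pass for one image.

    ``target_class`` defaults to the model's predicted class (lowest
    class on logit ties).  The per-layer relevance totals are recorded
    from the output boundary down to the pixels.
    """
    if trace is None:
        trace = forward(model, image)
    logits = trace.logits[0]
    if target_class is None:
        target_class = int(model.class_labels[int(np.argmax(logits))])
    r = init_relevance(trace, target_class, model.class_labels)[None, :]
    r_f = float(r.sum())
    sums = [r_f]
    for li in range(len(model.layers) - 1, -1, -1):
        r = propagate_layer(model.layers[li], model.params[li],
                            trace.inputs[li], trace.outputs[li], r, params)
        sums.append(float(r.sum()))
    scores = r[0, 0] if r.ndim == 4 else r[0]
    return RelevanceMap(scores=scores, target_class=target_class,
                        rule=params, per_layer_sums=sums, r_f=r_f)


@dataclass
class ConservationReport:
    """Per-layer relevance totals and their deviation from R_f.

    Leakage is expected (and only reported, never raised) when layers
    carry biases or when negative contributions are dropped by the
    alpha1-beta0 rule.
    """

    r_f: float
    per_layer_sums: list[float]
    max_relative_deviation: float
    negative_output: bool


def audit_conservation(rmap: RelevanceMap) -> ConservationReport:
    sums = np.asarray(rmap.per_layer_sums)
    if rmap.r_f == 0.0:
        dev = float(np.max(np.abs(sums))) if sums.size else 0.0
    else:
        dev = float(np.max(np.abs(sums - rmap.r_f)) / abs(rmap.r_f))
    return ConservationReport(
        r_f=rmap.r_f,
        per_layer_sums=list(rmap.per_layer_sums),
        max_relative_deviation=dev,
        negative_output=rmap.r_f < 0.0,
    )


def save_heatmap_png(scores: np.ndarray, path) -> None:
    """Render a relevance map as a white-to-red PNG (deeper red = more
    positive contribution); negative scores render in blue."""
    s = np.asarray(scores, dtype=float)
    peak = np.max(np.abs(s)) or 1.0
    v = s / peak
    pos = np.clip(v, 0.0, 1.0)
    neg = np.clip(-v, 0.0, 1.0)
    rgb = np.stack([1.0 - neg, 1.0 - pos - neg, 1.0 - pos], axis=-1)
    arr = np.round(np.clip(rgb, 0, 1) * 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path)
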