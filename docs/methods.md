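# Methods

This note documents the models and procedures implemented in
`otolens`, their assumptions, the defaults and why they were chosen,
and what the synthetic setting can and cannot show about real otolith
data.

## Synthetic otolith generator

The generator emulates the documented qualitative morphology of
Greenland halibut otoliths across ages 1–26:

* juveniles (1–4): smooth, nearly circular outline, no fingers, and a
  nucleus that is large relative to the whole otolith;
* adolescents (5–9): distinct but short anterior fingers, growth
  biased to the anterior (upward) direction;
* young adults (10–13): longer fingers;
* adults (14–26): many long fingers and strongly asymmetric outlines.

Each otolith is a star-convex region defined by a polar radius profile
r(θ) around a centre, θ measured from the anterior (up) axis:
a base circle, a smooth anterior lobe scaled by an elongation factor,
Gaussian finger bumps spread over the anterior arc, and low-order
Fourier contour noise. The interior holds a brighter nucleus disk
(radius = `nucleus_relative_radius · base_radius`), `ring_count = age`
concentric low-contrast sinusoidal rings blurred by a 1 px Gaussian
(mimicking the loss of annual-zone detail that downsampling real
images causes), and pixel noise. All otoliths are rendered
anterior-up, so no registration is needed downstream.

Age-conditional parameter distributions (canvas 112, scaled linearly
for other canvases):

| parameter | mean | sd | rationale |
|---|---|---|---|
| base_radius (px) | 11 + 0.75·age | 2.2 | size grows with age; the sd spans ~3 years of growth so neighbouring young ages overlap in size |
| nucleus_relative_radius | 0.72·exp(−0.13·(age−1)) | 0.02 | steep, clean decline over the youngest ages; nearly flat for adults |
| anterior_elongation | 0.05·max(age−3, 0), cap 0.6 | 0.04 | anterior growth from adolescence onward; cap keeps age 26 on the canvas |
| n_fingers | 2 + (age−5)//3 (+0/1), 0 below age 5 | — | juveniles have none; old adults have many |
| finger_length | base_radius·min(0.06+0.02·(age−4), 0.35) | 15% | fingers lengthen with age |

This makes the **nucleus the discriminative feature for young ages**
and shape/size the discriminative features for older ages — the
mechanism the binary/standardized variant comparison is designed to
probe. Removing inner structure (binary variant) should therefore
degrade juvenile precision most, which is exactly what the end-to-end
checks assert.

A `separability` knob divides all within-age parameter noise; values
above 1 create an "easy" regime with near-deterministic per-age
shapes, used by tests that need a learnable signal in few epochs. The
default (1.0) is the study condition.

What the generator does **not** model: photographic background
texture and illumination (background is faint dark noise — there is no
published description to validate against), daily increments,
left/right otolith differences, reader disagreement (the read age is
the generating age), and colour. Consequently, passing tests show the
*pipeline mechanics* are correct and that the qualitative
variant/age-group effects emerge under a controlled morphology; they
do not certify performance on real images.

## Classifier

A miniature VGG-style stack (default: conv(8)-ReLU-pool,
conv(16)-ReLU-pool, dense(64)-ReLU, dense(n_classes)) in plain numpy,
with im2col convolutions, trained with Adam on the softmax
cross-entropy (batch 8, learning rate 4·10⁻⁴ — the standard recipe for
this task), with on-the-fly augmentation: rotation uniform in
[0°, 360°), independent horizontal/vertical flips (p = 0.5), vertical
shift uniform in ±10 px. Images are normalized by the training-set
channel mean and standard deviation; the same statistics are applied
to the test set (the natural convention when test statistics are
unavailable at deployment). Initialization is seeded He-normal — at
this scale pretrained initialization is neither available nor needed.
Argmax ties resolve to the lowest age for determinism. Epoch counts
are configuration-driven; the desk-scale default is 20.

Everything is seeded through `numpy.random.Generator`; identical
(config, seed) runs produce bit-identical weights, which the
reproducibility checks rely on.

## Relevance propagation

The αβ-rule redistributes the pre-softmax logit of the target class
(default: the predicted class) backwards through the network, with
α−β = 1, β ≥ 0; the default α₁β₀ keeps only activating contributions.
Commitments where the rule leaves room:

* **Biases** are excluded from numerators and denominators. With this
  convention α₁β₀ redistributes each upper neuron's relevance
  exactly, so the conservation audit is interpretable: leakage can
  arise only from upper neurons whose positive-contribution
  denominator is empty (then stabilized to ε = 10⁻⁹ and the relevance
  is dropped).
* **Max-pooling** is winner-take-all, window ties split equally —
  deterministic and exactly conserving. Flatten is an index-wise
  pass-through; ReLU passes relevance through unchanged.
* **Input layer**: the same αβ-rule is applied at the first layer; no
  dedicated input-domain rule is used. This is a known divergence
  point between LRP implementations.
* Negative target logits yield non-positive maps; this is flagged in
  the conservation report rather than hidden.

The vectorized engine is verified against a naive per-message loop
oracle (convolutions expanded to explicit dense matrices) to 10⁻⁹ on
random tiny networks, for both α₁β₀ and general αβ.

## SpRAy

* Descriptors: crop to the mask bounding box (drops background
  relevance), bilinear-resize to a common 112×112 with total-mass
  renormalization (the common intermediate size is a free choice; 2×
  the descriptor size keeps the sum-pooling exact), sum-pool to
  56×56. Total relevance is conserved throughout.
* Affinity: binary Euclidean k-NN graph, k = ⌈ln n⌉ (natural log per
  the standard spectral-clustering heuristic; ceiling guarantees
  k ≥ 1), symmetrized by union.
* Clustering: symmetric normalized Laplacian, eigenvectors of the 2
  smallest eigenvalues, row-normalized, seeded k-means (the
  Ng–Jordan–Weiss construction). If the graph has more components
  than clusters a warning is emitted and clustering proceeds.
* F1: binary F1 under the better of the two cluster-to-group
  matchings, computed against model-predicted age groups by default
  (switchable to read-age groups). Significance is judged against a
  permutation null (group labels shuffled, default 199 permutations).
* t-SNE: 2-D, on shortest-path hop distances over the k-NN graph
  (disconnected pairs capped at twice the largest finite distance),
  perplexity min(30, (n−1)/3), seeded. The distance derivation from
  the affinity graph is a documented substitute — only "distances
  derived from the affinity matrix" is prescribed by the procedure
  this follows.
* Clustering is run per pair of consecutive age groups
  (juvenile+adolescent, adolescent+young-adult, young-adult+adult).
  Binary-variant maps are excluded from clustering: they vary only
  along the otolith contour.

## Agreement statistics

Per otolith, the two independent age estimates (human read age,
network prediction) give CV = 100·sd/mean with the two-reading sample
standard deviation |a−b|/√2 (n−1 denominator — the form used in the
between-reader precision literature; an `ddof=0` switch gives
|a−b|/2). Group CV̄ averages the per-otolith CVs after the 1.5×IQR
rule with linear-interpolation quartiles (the fence values depend on
the quartile convention, so it is fixed and stated). Groups are
assigned from the read age: the grouping is a property of the
specimen, not of the model. RMSE is reported per variant and split.

## Pipeline defaults and problem sizes

The desk-scale default (`ExperimentConfig()`): ages 1–13, 24 otoliths
per age, 56×56 canvas, 80/20 split, three variants, 20 epochs each.
This covers three age groups (so two consecutive-pair clustering
experiments), trains in under a minute per run on one CPU, and is
large enough for the qualitative effects to be stable under the
default seeds. The full 26-class, 112×112 setting remains available
through the config. Stage outputs are deterministic: two runs from
the same config are byte-identical in every CSV and stored array
(PNG rendering is excluded from bit-exactness guarantees).

## Known limitations

* The CNN is far smaller than production architectures; absolute
  accuracy/CV̄ values are not comparable to published full-scale
  results and are not meant to be.
* The synthetic morphology model is qualitative; its parameters were
  fixed from the documented growth description, not fitted to images.
* α₁β₀ relevance is non-negative only when the target logit is
  non-negative; explanations of strongly "rejected" classes are
  reported with a negative-output flag instead.
* Spectral clustering can fragment when the affinity graph has many
  components (small n with tight clusters); the warning is the
  intended signal to enlarge n or k.
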