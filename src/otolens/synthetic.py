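"""Seeded synthetic generator for otolith-like grayscale images.

Greenland halibut otoliths change morphology with age in a way that is
well documented qualitatively: juveniles (ages 1-4) are smooth, nearly
circular and have a large nucleus relative to the whole otolith;
from adolescence onward the otolith grows mostly in the anterior
direction and develops lobed protrusions ("fingers") on the anterior
margin that lengthen and multiply with age, while overall size keeps
increasing.  This module emulates those trends procedurally so that the
explanation pipeline (CNN -> LRP -> SpRAy) can be exercised end to end
without access to a real image collection.

Three data variants are produced, mirroring the standard experimental
contrasts for disentangling size / shape / inner-structure attributes:

* ``baseline``      - the rendered grayscale image (nucleus, annual rings,
                      noise) on a dark noisy background;
* ``binary``        - otolith pixels set to 1, background to 0 (shape and
                      size only);
* ``standardized``  - background zeroed and the otolith rescaled so its
                      vertical extent is fixed (shape and structure,
                      size removed).

Deliberate property of the default parameter distributions: for the
youngest ages the overall radius is noisy enough that neighbouring ages
overlap in size, while the *relative nucleus radius* declines steeply and
cleanly.  The nucleus is therefore the discriminative feature for young
fish, and removing the inner structure (binary variant) should degrade
precision most for juveniles.  All randomness flows through an explicit
``numpy.random.Generator``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.transform import resize

AGE_MIN = 1
AGE_MAX = 26

VARIANTS = ("baseline", "binary", "standardized")

#: canvas the default radius scale is calibrated for; radii scale linearly
#: with canvas_size / REFERENCE_CANVAS.
REFERENCE_CANVAS = 112


def _check_age(age: int) -> int:
    age = int(age)
    if not (AGE_MIN <= age <= AGE_MAX):
        raise ValueError(f"age must be in [{AGE_MIN}, {AGE_MAX}], got {age}")
    return age


@dataclass(frozen=True)
class ShapeParams:
    """Age-conditional morphology parameters for one otolith.

    All lengths are in pixels at the rendering canvas scale.
    """

    base_radius: float
    anterior_elongation: float  # relative anterior lobe growth, >= 0
    n_fingers: int
    finger_length: float
    nucleus_relative_radius: float  # nucleus radius / base_radius, in (0, 1]
    ring_count: int
    noise_amplitude: float  # radial contour noise, relative

    def __post_init__(self) -> None:
        if not np.isfinite(
            [self.base_radius, self.anterior_elongation, self.finger_length,
             self.nucleus_relative_radius, self.noise_amplitude]
        ).all():
            raise ValueError("ShapeParams fields must be finite")
        if self.base_radius <= 0:
            raise ValueError("base_radius must be positive")
        if self.anterior_elongation < 0 or self.finger_length < 0:
            raise ValueError("anterior_elongation and finger_length must be >= 0")
        if not (0 < self.nucleus_relative_radius <= 1):
            raise ValueError("nucleus_relative_radius must be in (0, 1]")
        if self.n_fingers < 0 or self.ring_count < 0:
            raise ValueError("n_fingers and ring_count must be >= 0")


@dataclass
class OtolithSample:
    """One grayscale otolith image with its foreground mask and read age."""

    image: np.ndarray  # (H, W) float in [0, 1]
    mask: np.ndarray  # (H, W) bool, True on otolith pixels
    age: int
    variant: str
    params: ShapeParams
    sample_id: str

    def __post_init__(self) -> None:
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask must have identical shapes")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")


@dataclass
class DatasetSplit:
    train: list[OtolithSample]
    test: list[OtolithSample]
    seed: int

    def __post_init__(self) -> None:
        train_ids = {s.sample_id for s in self.train}
        test_ids = {s.sample_id for s in self.test}
        if train_ids & test_ids:
            raise ValueError("sample_id appears in both train and test")


def sample_shape_params(
    age: int,
    rng: np.random.Generator,
    separability: float = 1.0,
    radius_scale: float = 1.0,
) -> ShapeParams:
    """Draw morphology parameters from age-conditional distributions.

    ``separability`` > 1 shrinks the within-age parameter noise, producing
    an "easy" regime with stronger between-age contrast; 1.0 is the
    default study condition.  ``radius_scale`` rescales all lengths
    (use canvas_size / 112 for smaller canvases).
    """
    age = _check_age(age)
    if separability <= 0:
        raise ValueError("separability must be positive")
    s = float(separability)

    # Size grows with age, but with ~2-3 years' worth of spread so that
    # neighbouring young ages overlap in size.  Calibrated so an age-26
    # otolith (with anterior growth and fingers) still fits a 112 canvas.
    base_radius = rng.normal(11.0 + 0.75 * age, 2.2 / s)
    base_radius = float(np.clip(base_radius, 6.0, 34.0)) * radius_scale

    # Relative nucleus size: steep clean decline over the youngest ages,
    # nearly flat for adults.
    nuc = 0.72 * np.exp(-0.13 * (age - 1)) + rng.normal(0.0, 0.02 / s)
    nucleus_relative_radius = float(np.clip(nuc, 0.10, 0.80))

    # Anterior growth and fingers appear from adolescence onward.
    elong = rng.normal(0.05 * max(age - 3, 0), 0.04 / s)
    anterior_elongation = float(np.clip(elong, 0.0, 0.6))

    if age <= 4:
        n_fingers = 0
        finger_length = 0.0
    else:
        n_fingers = int(min(2 + (age - 5) // 3 + rng.integers(0, 2), 12))
        frac = min(0.06 + 0.02 * (age - 4), 0.35)
        finger_length = float(
            max(base_radius * frac * (1.0 + rng.normal(0.0, 0.15 / s)), 0.5)
        )

    return ShapeParams(
        base_radius=base_radius,
        anterior_elongation=anterior_elongation,
        n_fingers=n_fingers,
        finger_length=finger_length,
        nucleus_relative_radius=nucleus_relative_radius,
        ring_count=age,
        noise_amplitude=0.03,
    )


def _radius_profile(params: ShapeParams, theta: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Polar contour radius r(theta); theta measured from the anterior
    (up) direction, in [-pi, pi]."""
    r = np.full_like(theta, params.base_radius, dtype=float)
    # smooth anterior lobe, maximal at theta = 0, vanishing posteriorly
    lobe = ((1.0 + np.cos(theta)) / 2.0) ** 2
    r *= 1.0 + params.anterior_elongation * lobe
    # fingers: Gaussian bumps spread over the anterior arc
    if params.n_fingers > 0:
        centers = np.linspace(-1.0, 1.0, params.n_fingers)
        if params.n_fingers == 1:
            centers = np.array([0.0])
        width = max(0.9 / params.n_fingers, 0.10)
        for c in centers:
            r += params.finger_length * np.exp(-((theta - c) / width) ** 2)
    # low-order Fourier contour noise
    if params.noise_amplitude > 0:
        for m in range(2, 6):
            amp = rng.normal(0.0, params.noise_amplitude / m)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            r *= 1.0 + amp * np.cos(m * theta + phase)
    return r


def render_baseline(
    params: ShapeParams,
    canvas_size: int = REFERENCE_CANVAS,
    rng: np.random.Generator | None = None,
    age: int | None = None,
    sample_id: str = "sample",
) -> OtolithSample:
    """Render a baseline-variant otolith image from shape parameters.

    The foreground is a closed star-convex region whose polar contour
    carries the anterior lobe, finger bumps and noise; the interior holds
    a brighter nucleus disk and ``ring_count`` concentric low-contrast
    rings (blurred, emulating the loss of annual-zone detail that image
    downsampling causes).  Raises ``ValueError`` if the shape cannot fit
    on the canvas.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    n = int(canvas_size)

    theta_grid = np.linspace(-np.pi, np.pi, 720, endpoint=False)
    # freeze the stochastic contour on a dense theta grid, then interpolate
    r_dense = _radius_profile(params, theta_grid, rng)

    up = float(np.max(r_dense * np.clip(np.cos(theta_grid), 0, None)))
    down = float(np.max(r_dense * np.clip(-np.cos(theta_grid), 0, None)))
    side = float(np.max(r_dense * np.abs(np.sin(theta_grid))))
    if up + down > n - 2 or 2 * side > n - 2:
        raise ValueError("shape parameters imply a foreground exceeding the canvas")

    # centre the bounding box vertically; anterior points upward (row 0 side)
    cy = (n - (up + down)) / 2.0 + up
    cx = n / 2.0

    rows, cols = np.mgrid[0:n, 0:n]
    dx = cols - cx
    dy = cy - rows  # +y is up / anterior
    rho = np.hypot(dx, dy)
    theta = np.arctan2(dx, dy)  # angle from the anterior axis

    r_at = np.interp(theta, theta_grid, r_dense, period=2.0 * np.pi)
    mask = rho <= r_at

    image = np.zeros((n, n), dtype=float)
    # background: faint dark noise (appearance of real backgrounds is
    # unvalidated; see the methods note)
    image += np.abs(rng.normal(0.0, 0.015, size=(n, n)))

    interior = np.zeros((n, n), dtype=float)
    interior[mask] = 0.45

    if params.ring_count > 0:
        u = np.divide(rho, r_at, out=np.zeros_like(rho), where=r_at > 0)
        rings = 0.08 * np.sin(2.0 * np.pi * params.ring_count * u)
        rings = ndimage.gaussian_filter(rings, sigma=1.0)
        interior[mask] += rings[mask]

    if params.noise_amplitude > 0:
        tex = rng.normal(0.0, params.noise_amplitude, size=(n, n))
        interior[mask] += tex[mask]

    # bright nucleus disk centred on the base circle
    nucleus_r = params.nucleus_relative_radius * params.base_radius
    nucleus = rho <= nucleus_r
    interior[nucleus & mask] += 0.35

    image[mask] = interior[mask]
    image = np.clip(image, 0.0, 1.0)

    return OtolithSample(
        image=image,
        mask=mask,
        age=age if age is not None else AGE_MIN,
        variant="baseline",
        params=params,
        sample_id=sample_id,
    )


def make_binary(sample: OtolithSample) -> OtolithSample:
    """Binary variant: otolith pixels 1, background 0 (shape/size only).

    Idempotent: a binary sample passes through unchanged.
    """
    if sample.variant == "binary":
        return replace(sample, image=sample.image.copy(),
                       mask=sample.mask.copy())
    if sample.variant != "baseline":
        raise ValueError("make_binary expects a baseline-variant sample")
    return replace(
        sample,
        image=sample.mask.astype(float),
        mask=sample.mask.copy(),
        variant="binary",
    )


def make_standardized(
    sample: OtolithSample, target_vertical_extent: int | None = None
) -> OtolithSample:
    """Standardized variant: background zeroed, otolith rescaled (aspect
    ratio preserved) so the mask's vertical extent equals
    ``target_vertical_extent`` (default: 70% of the canvas height), and
    recentred on the canvas."""
    if sample.variant != "baseline":
        raise ValueError("make_standardized expects a baseline-variant sample")
    if not sample.mask.any():
        raise ValueError("cannot standardize a sample with an empty mask")
    n = sample.image.shape[0]
    if target_vertical_extent is None:
        target_vertical_extent = int(round(0.7 * n))
    rows = np.flatnonzero(sample.mask.any(axis=1))
    cols = np.flatnonzero(sample.mask.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1

    fg = np.where(sample.mask, sample.image, 0.0)[r0:r1, c0:c1]
    msk = sample.mask[r0:r1, c0:c1]
    h, w = fg.shape
    scale = target_vertical_extent / h
    out_h = int(target_vertical_extent)
    out_w = max(int(round(w * scale)), 1)
    if out_h > sample.image.shape[0] or out_w > sample.image.shape[1]:
        raise ValueError("target vertical extent does not fit on the canvas")

    fg_r = resize(fg, (out_h, out_w), order=1, anti_aliasing=False,
                  preserve_range=True)
    msk_r = resize(msk.astype(float), (out_h, out_w), order=0,
                   anti_aliasing=False, preserve_range=True) > 0.5

    image = np.zeros_like(sample.image)
    mask = np.zeros_like(sample.mask)
    top = (sample.image.shape[0] - out_h) // 2
    left = (sample.image.shape[1] - out_w) // 2
    image[top:top + out_h, left:left + out_w] = np.where(msk_r, fg_r, 0.0)
    mask[top:top + out_h, left:left + out_w] = msk_r
    return replace(
        sample,
        image=np.clip(image, 0.0, 1.0),
        mask=mask,
        variant="standardized",
    )


def apply_variant(sample: OtolithSample, variant: str,
                  target_vertical_extent: int | None = None) -> OtolithSample:
    if variant == "baseline":
        return sample
    if variant == "binary":
        return make_binary(sample)
    if variant == "standardized":
        return make_standardized(sample, target_vertical_extent)
    raise ValueError(f"unknown variant {variant!r}")


def generate_dataset(
    n_per_age: int,
    ages: list[int] | None = None,
    variant: str = "baseline",
    canvas_size: int = REFERENCE_CANVAS,
    split_fraction: float = 0.2,
    seed: int = 0,
    separability: float = 1.0,
) -> DatasetSplit:
    """Generate ``n_per_age`` samples per age, rendered in ``variant``,
    split reproducibly into train/test by ``seed``.

    The baseline geometry is always rendered first; binary and
    standardized samples are derived from it, so a given ``sample_id``
    has the same geometry in every variant.
    """
    if n_per_age < 1:
        raise ValueError("n_per_age must be >= 1")
    if not (0.0 <= split_fraction < 1.0):
        raise ValueError("split_fraction must be in [0, 1)")
    if ages is None:
        ages = list(range(AGE_MIN, AGE_MAX + 1))
    ages = [_check_age(a) for a in ages]

    rng = np.random.default_rng(seed)
    radius_scale = canvas_size / REFERENCE_CANVAS
    samples: list[OtolithSample] = []
    for age in ages:
        for i in range(n_per_age):
            params = sample_shape_params(age, rng, separability=separability,
                                         radius_scale=radius_scale)
            base = render_baseline(
                params, canvas_size=canvas_size, rng=rng, age=age,
                sample_id=f"a{age:02d}_{i:04d}",
            )
            samples.append(apply_variant(base, variant))

    order = rng.permutation(len(samples))
    n_test = int(round(split_fraction * len(samples)))
    test_idx = set(order[:n_test].tolist())
    train = [s for j, s in enumerate(samples) if j not in test_idx]
    test = [s for j, s in enumerate(samples) if j in test_idx]
    return DatasetSplit(train=train, test=test, seed=seed)


# ---------------------------------------------------------------------------
# PNG / manifest I/O


def save_png(sample: OtolithSample, path: str | Path) -> None:
    arr = np.round(np.clip(sample.image, 0, 1) * 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def save_mask_png(sample: OtolithSample, path: str | Path) -> None:
    Image.fromarray(sample.mask.astype(np.uint8) * 255, mode="L").save(path)


def load_png(path: str | Path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"), dtype=float)
    return arr / 255.0


def write_manifest(split: DatasetSplit, path: str | Path) -> None:
    """Dataset manifest CSV: sample_id, age, variant, split, seed."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "age", "variant", "split", "seed"])
        for part, items in (("train", split.train), ("test", split.test)):
            for s in items:
                w.writerow([s.sample_id, s.age, s.variant, part, split.seed])
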