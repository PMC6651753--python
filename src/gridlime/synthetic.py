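"""Synthetic H&E-like patches, annotation masks and mock classifiers.

The generator emulates the visual contrasts that drive explanations of
metastasis detectors on 96×96 lymph-node patches: a pink stained-tissue
background, many small, dark-purple, near-circular nuclei (normal tissue)
and — in positive patches — a cluster of enlarged, irregularly-shaped,
lighter-purple nuclei whose union is the tumor annotation.  Labels follow
the patch convention: class 1 iff at least one annotated pixel falls inside
the central 32×32 window; annotated tissue outside that window does not
affect the label.

No histological realism is claimed; the generator reproduces the
statistical contrasts (size, shape regularity, lightness) that the
explanation pipeline keys on, so every other module is testable without
any dataset download.

The mock classifiers are deterministic, closed-form adapters used as
oracles: a classifier exactly affine in segment visibility (the surrogate
recovers its coefficients to machine precision), a near-linear variant with
a small smooth nonlinearity (for Monte-Carlo stability measurements), and a
smooth "tumor detector" that responds only to visible annotated tissue in
the central window (for localization checks).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .perturbation import ClassifierAdapter
from .segmentation import InvalidParameterError, SegmentMap

# Palette (RGB); verbal convention made concrete.
BACKGROUND_PINK = np.array([230, 180, 200], dtype=float)
NORMAL_PURPLE = np.array([90, 40, 110], dtype=float)    # small round nuclei
TUMOR_PURPLE = np.array([170, 120, 180], dtype=float)   # enlarged blobs

#: Side of the central labelling window.
CENTER_SIDE = 32


@dataclasses.dataclass(frozen=True)
class SynthParams:
    """Patch-generator knobs.  Defaults emulate the canonical 96×96 patch
    geometry; tumor radii are strictly larger than the normal-nucleus
    radius (enlarged nuclei are the class-1 signature)."""

    height: int = 96
    width: int = 96
    n_normal_nuclei: int = 25
    normal_radius: float = 3.0
    tumor_blob_count: int = 5
    tumor_radius_range: tuple[float, float] = (8.0, 14.0)
    noise_scale: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < CENTER_SIDE or self.width < CENTER_SIDE:
            raise InvalidParameterError(
                f"patch must be at least {CENTER_SIDE}×{CENTER_SIDE}"
            )
        lo, hi = self.tumor_radius_range
        if not 0 < lo <= hi:
            raise InvalidParameterError("tumor_radius_range must be 0 < lo <= hi")
        if lo <= self.normal_radius:
            raise InvalidParameterError(
                "tumor radii must be strictly larger than the normal radius"
            )
        if hi >= min(self.height, self.width) / 2:
            raise InvalidParameterError(
                "tumor radius exceeds the image (impossible geometry)"
            )


def _center_window(height: int, width: int) -> tuple[slice, slice]:
    r0 = height // 2 - CENTER_SIDE // 2
    c0 = width // 2 - CENTER_SIDE // 2
    return slice(r0, r0 + CENTER_SIDE), slice(c0, c0 + CENTER_SIDE)


def _irregular_blob(
    yy: np.ndarray,
    xx: np.ndarray,
    cy: float,
    cx: float,
    radius: float,
    rng: np.random.Generator,
    irregularity: float = 0.3,
) -> np.ndarray:
    """Boolean mask of a disc whose boundary radius is perturbed by a
    low-order sinusoid of the polar angle ("less consistently shaped")."""
    dy, dx = yy - cy, xx - cx
    theta = np.arctan2(dy, dx)
    dist = np.hypot(dy, dx)
    boundary = np.ones_like(theta)
    for m in (2, 3, 4):
        amp = rng.uniform(-1.0, 1.0) / m
        phase = rng.uniform(0.0, 2.0 * np.pi)
        boundary += irregularity * amp * np.sin(m * theta + phase)
    return dist <= radius * np.clip(boundary, 0.3, None)


def generate_patch(
    target_class: int, params: SynthParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Generate one patch and its annotation mask.

    Class 0: textured pink background plus small round dark nuclei, empty
    annotation.  Class 1: additionally a cluster of enlarged irregular
    lighter-purple blobs; their union is the annotation, and the first blob
    is centred inside the central window so the label rule is satisfied by
    construction.  Deterministic in ``params.seed``.
    """
    if target_class not in (0, 1):
        raise InvalidParameterError("target_class must be 0 or 1")
    if params is None:
        params = SynthParams()
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width
    yy, xx = np.mgrid[0:h, 0:w].astype(float)

    # stained-tissue background: smoothed Gaussian texture around pink
    noise = rng.normal(0.0, params.noise_scale, size=(h, w, 3))
    noise = gaussian_filter(noise, sigma=(1.5, 1.5, 0))
    image = BACKGROUND_PINK[None, None, :] + noise

    annotation = np.zeros((h, w), dtype=np.uint8)

    if target_class == 1:
        # enlarged irregular lighter-purple blobs clustered near the centre
        rs, cs = _center_window(h, w)
        cy0 = float(rng.integers(rs.start + 4, rs.stop - 4))
        cx0 = float(rng.integers(cs.start + 4, cs.stop - 4))
        for b in range(params.tumor_blob_count):
            if b == 0:
                cy, cx = cy0, cx0
            else:
                cy = float(np.clip(cy0 + rng.normal(0, 14), 0, h - 1))
                cx = float(np.clip(cx0 + rng.normal(0, 14), 0, w - 1))
            radius = rng.uniform(*params.tumor_radius_range)
            blob = _irregular_blob(yy, xx, cy, cx, radius, rng)
            color = TUMOR_PURPLE + rng.normal(0, 8, size=3)
            image[blob] = color[None, :] + rng.normal(0, 4, size=(int(blob.sum()), 3))
            annotation[blob] = 1

    # small, round, dark-purple nuclei scattered everywhere (normal tissue)
    for _ in range(params.n_normal_nuclei):
        cy = rng.uniform(0, h - 1)
        cx = rng.uniform(0, w - 1)
        radius = params.normal_radius * rng.uniform(0.85, 1.15)
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        color = NORMAL_PURPLE + rng.normal(0, 6, size=3)
        image[disc] = color

    # clip to [1, 255]: pure black is reserved for masked-out pixels
    image = np.clip(np.round(image), 1, 255).astype(np.uint8)
    return image, annotation


def label_from_annotation(annotation: np.ndarray) -> int:
    """1 iff any annotated pixel lies in the centred 32×32 window (rows and
    columns [32, 64) for the canonical 96×96 patch); tissue outside the
    window never influences the label."""
    annotation = np.asarray(annotation)
    if annotation.ndim != 2:
        raise InvalidParameterError("annotation must be a 2-D mask")
    h, w = annotation.shape
    if h < CENTER_SIDE or w < CENTER_SIDE:
        raise InvalidParameterError(
            f"mask smaller than the {CENTER_SIDE}×{CENTER_SIDE} labelling window"
        )
    rs, cs = _center_window(h, w)
    return int(bool((annotation[rs, cs] != 0).any()))


# ---------------------------------------------------------------------------
# Mock classifiers (deterministic oracles)

def _segment_presence_fn(reference_image: np.ndarray, segments: SegmentMap):
    """Return a function mapping an image batch to a B×k boolean matrix:
    segment j present iff every one of its pixels matches the reference."""
    ref = np.asarray(reference_image)
    if ref.shape[:2] != segments.shape:
        raise InvalidParameterError("reference image does not match segment map")
    flat_labels = segments.labels.ravel()
    order = np.argsort(flat_labels, kind="stable")
    counts = np.bincount(flat_labels, minlength=segments.k)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])

    def presence(batch: np.ndarray) -> np.ndarray:
        batch = np.asarray(batch)
        eq = (batch == ref[None]).all(axis=-1).reshape(batch.shape[0], -1)
        mismatches = np.add.reduceat(
            (~eq[:, order]).astype(np.int32), starts, axis=1
        )
        return mismatches == 0

    return presence


def _two_class(p1: np.ndarray) -> np.ndarray:
    return np.stack([1.0 - p1, p1], axis=1)


def linear_mock_classifier(
    reference_image: np.ndarray,
    segments: SegmentMap,
    coefficients: np.ndarray,
    intercept: float,
) -> ClassifierAdapter:
    """Classifier exactly affine in segment visibility:
    ``p1 = intercept + Σ_j c_j · [segment j fully matches the reference]``.

    The affine range over the whole {0,1}^k cube must stay inside [0, 1]
    (validated up front), so the surrogate's exact-recovery property holds
    without clipping.
    """
    c = np.asarray(coefficients, dtype=float)
    if c.shape != (segments.k,):
        raise InvalidParameterError(
            f"expected {segments.k} coefficients, got {c.shape}"
        )
    if not np.isfinite(c).all():
        raise InvalidParameterError("coefficients must be finite")
    lo = intercept + c[c < 0].sum()
    hi = intercept + c[c > 0].sum()
    if lo < 0.0 or hi > 1.0:
        raise InvalidParameterError(
            f"affine range [{lo:.4f}, {hi:.4f}] leaves [0, 1]; the mock must "
            "not clip on the mask cube"
        )
    presence = _segment_presence_fn(reference_image, segments)

    def predict(batch: np.ndarray) -> np.ndarray:
        p1 = intercept + presence(batch).astype(float) @ c
        return _two_class(p1)

    return ClassifierAdapter(predict_fn=predict, n_classes=2)


def near_linear_mock_classifier(
    reference_image: np.ndarray,
    segments: SegmentMap,
    coefficients: np.ndarray,
    intercept: float,
    nonlinearity: float = 0.02,
) -> ClassifierAdapter:
    """Affine in segment visibility plus a small smooth nonlinearity:
    ``p1 = intercept + Σ c_j v_j + nonlinearity · sin(2π · mean(v))``.

    The nonlinear term leaves the surrogate a small irreducible residual,
    so repeated explanations carry genuine Monte-Carlo noise — the regime
    in which weight stability across reruns is meaningful to measure.
    """
    c = np.asarray(coefficients, dtype=float)
    if c.shape != (segments.k,):
        raise InvalidParameterError(
            f"expected {segments.k} coefficients, got {c.shape}"
        )
    if nonlinearity < 0:
        raise InvalidParameterError("nonlinearity must be non-negative")
    lo = intercept + c[c < 0].sum() - nonlinearity
    hi = intercept + c[c > 0].sum() + nonlinearity
    if lo < 0.0 or hi > 1.0:
        raise InvalidParameterError(
            f"output range [{lo:.4f}, {hi:.4f}] leaves [0, 1]"
        )
    presence = _segment_presence_fn(reference_image, segments)

    def predict(batch: np.ndarray) -> np.ndarray:
        v = presence(batch).astype(float)
        p1 = intercept + v @ c + nonlinearity * np.sin(2.0 * np.pi * v.mean(axis=1))
        return _two_class(p1)

    return ClassifierAdapter(predict_fn=predict, n_classes=2)


def tumor_detector_classifier(
    reference_annotation: np.ndarray, steepness: float = 4.0
) -> ClassifierAdapter:
    """Smooth detector of visible annotated tissue in the central window:
    ``p1 = logistic(steepness · (visible annotated central pixels / 1024 − ½))``
    where a pixel is visible iff it is not pure black (masked out).
    """
    if steepness <= 0:
        raise InvalidParameterError("steepness must be positive")
    ann = np.asarray(reference_annotation)
    if ann.ndim != 2:
        raise InvalidParameterError("annotation must be a 2-D mask")
    rs, cs = _center_window(*ann.shape)
    central = (ann[rs, cs] != 0)

    def predict(batch: np.ndarray) -> np.ndarray:
        batch = np.asarray(batch)
        visible = (batch[:, rs, cs, :] != 0).any(axis=-1)
        frac = (visible & central[None]).sum(axis=(1, 2)) / float(CENTER_SIDE**2)
        p1 = expit(steepness * (frac - 0.5))
        return _two_class(p1)

    return ClassifierAdapter(predict_fn=predict, n_classes=2)
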