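"""Perturbed-image distributions for local surrogate fitting.

A perturbation is a binary vector over segments: 1 keeps the segment, 0
paints it black.  :func:`sample_masks` draws the distribution (row 0 is
always the unperturbed instance, the rest i.i.d. Bernoulli(0.5) per
segment), :func:`apply_mask` composes one masked image, and
:func:`predict_perturbations` streams the masked images through a
black-box classifier in batches.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np

from .segmentation import InvalidParameterError, SegmentMap

#: Number of perturbed images in the sampling distribution.
DEFAULT_N_SAMPLES: int = 10_000

#: Fill colour for hidden segments (RGB).  Black is the convention; kept as
#: module config for extensions.
MASK_FILL: tuple[int, int, int] = (0, 0, 0)


class AdapterContractError(RuntimeError):
    """A classifier adapter returned malformed probability rows."""


@dataclasses.dataclass(frozen=True)
class MaskMatrix:
    """N×K binary design matrix; one row per perturbation.

    Row 0 is all ones (the unperturbed instance), so the original
    prediction always belongs to the fitting set.
    """

    rows: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows)
        if rows.ndim != 2:
            raise InvalidParameterError("mask matrix must be 2-D")
        if not np.isin(rows, (0, 1)).all():
            raise InvalidParameterError("mask entries must be exactly 0 or 1")
        if not (rows[0] == 1).all():
            raise InvalidParameterError("row 0 must be the all-ones mask")
        object.__setattr__(self, "rows", rows.astype(np.uint8))

    @property
    def n_samples(self) -> int:
        return self.rows.shape[0]

    @property
    def k(self) -> int:
        return self.rows.shape[1]


@dataclasses.dataclass(frozen=True)
class ClassifierAdapter:
    """Uniform contract over black-box classifiers.

    ``predict_fn`` maps a batch of RGB rasters (B×H×W×3, uint8) to B rows of
    class probabilities.  Single-sigmoid models may return one column p; it
    is expanded to ``[1-p, p]``.  Rows are validated: non-negative, summing
    to 1.  The function must be deterministic.
    """

    predict_fn: Callable[[np.ndarray], np.ndarray]
    n_classes: int = 2

    def predict(self, batch: np.ndarray) -> np.ndarray:
        batch = np.asarray(batch)
        if batch.ndim == 3:
            batch = batch[None]
        out = np.asarray(self.predict_fn(batch), dtype=float)
        if out.ndim == 1:
            out = out[:, None]
        if out.shape[0] != batch.shape[0]:
            raise AdapterContractError(
                f"classifier returned {out.shape[0]} rows for a batch of "
                f"{batch.shape[0]} images"
            )
        if out.shape[1] == 1:
            out = np.concatenate([1.0 - out, out], axis=1)
        if (out < -1e-9).any():
            raise AdapterContractError("classifier returned negative probabilities")
        sums = out.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise AdapterContractError(
                "classifier probability rows do not sum to 1 "
                f"(min {sums.min():.6f}, max {sums.max():.6f})"
            )
        if out.shape[1] != self.n_classes:
            raise AdapterContractError(
                f"expected {self.n_classes} classes, got {out.shape[1]}"
            )
        return out


def sample_masks(k: int, n_samples: int, seed: int) -> MaskMatrix:
    """Draw the perturbation design: row 0 all ones, rows 1..N-1 i.i.d.
    Bernoulli(0.5) per entry from a generator seeded with ``seed``."""
    if k < 1 or n_samples < 1:
        raise InvalidParameterError("k and n_samples must be positive")
    rng = np.random.default_rng(seed)
    rows = np.empty((n_samples, k), dtype=np.uint8)
    rows[0] = 1
    if n_samples > 1:
        rows[1:] = rng.integers(0, 2, size=(n_samples - 1, k), dtype=np.uint8)
    return MaskMatrix(rows=rows, seed=seed)


def apply_mask(
    image: np.ndarray, segments: SegmentMap, mask_row: Sequence[int]
) -> np.ndarray:
    """Black out the segments whose mask bit is 0; the input is untouched."""
    image = np.asarray(image)
    mask_row = np.asarray(mask_row)
    if image.shape[:2] != segments.shape:
        raise ValueError(
            f"image {image.shape[:2]} does not match segment map {segments.shape}"
        )
    if mask_row.shape != (segments.k,):
        raise ValueError(
            f"mask row length {mask_row.shape} does not match k={segments.k}"
        )
    keep = mask_row.astype(bool)[segments.labels]
    out = np.where(keep[..., None], image, np.array(MASK_FILL, dtype=image.dtype))
    return out.astype(image.dtype)


def masked_batch(
    image: np.ndarray, segments: SegmentMap, mask_rows: np.ndarray
) -> np.ndarray:
    """Vectorised apply_mask over a batch of mask rows (B×K → B×H×W×3)."""
    keep = mask_rows.astype(bool)[:, segments.labels]
    fill = np.array(MASK_FILL, dtype=image.dtype)
    return np.where(keep[..., None], image[None], fill)


def predict_perturbations(
    image: np.ndarray,
    segments: SegmentMap,
    masks: MaskMatrix,
    classifier: ClassifierAdapter,
    batch_size: int = 256,
) -> np.ndarray:
    """Probability matrix, one row per perturbation: row i is the classifier
    output on ``apply_mask(image, segments, masks.rows[i])``.  Batching is a
    throughput knob only; it never changes the result."""
    if batch_size < 1:
        raise InvalidParameterError("batch_size must be positive")
    image = np.asarray(image)
    if image.shape[:2] != segments.shape:
        raise ValueError("image dimensions do not match the segment map")
    if masks.k != segments.k:
        raise ValueError(f"mask width {masks.k} does not match k={segments.k}")
    chunks = []
    for start in range(0, masks.n_samples, batch_size):
        rows = masks.rows[start : start + batch_size]
        chunks.append(classifier.predict(masked_batch(image, segments, rows)))
    return np.concatenate(chunks, axis=0)


def save_probabilities_csv(probabilities: np.ndarray, path) -> None:
    np.savetxt(path, probabilities, fmt="%.17g", delimiter=",")
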