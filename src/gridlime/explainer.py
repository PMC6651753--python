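"""End-to-end explanation pipelines.

``explain`` runs the four-step local-surrogate procedure for one image and
one segmentation: segment → sample perturbations → query the classifier →
fit the linear surrogate, then broadcasts segment weights to pixels as a
heat map.  ``squaregrid_explain`` repeats it over progressively finer
square grids (9 → 576 squares by default) and sums the per-level heat maps
into a parameter-free multi-scale attribution map.  ``average_heatmaps``
combines maps from different segmenters; ``stability_check`` quantifies the
Monte-Carlo reproducibility of the weights across reruns.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .perturbation import (
    DEFAULT_N_SAMPLES,
    ClassifierAdapter,
    predict_perturbations,
    sample_masks,
)
from .segmentation import (
    InvalidParameterError,
    SegmenterParams,
    SegmentMap,
    default_levels,
    segment_image,
    squaregrid_segments,
)
from .surrogate import Explanation, explanation_for_class


@dataclasses.dataclass(frozen=True)
class HeatMap:
    """Per-pixel real-valued attribution raster.

    For a single segmentation the values are piecewise constant on
    segments (each pixel carries its segment's surrogate weight);
    multi-scale and averaged maps are sums/means of such rasters.
    """

    values: np.ndarray
    provenance: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise InvalidParameterError("heat map values must be a 2-D raster")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


def heatmap_from_weights(
    segments: SegmentMap, weights: np.ndarray, provenance: str
) -> HeatMap:
    """Broadcast one weight per segment onto that segment's pixels."""
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (segments.k,):
        raise InvalidParameterError(
            f"expected {segments.k} weights, got {weights.shape}"
        )
    return HeatMap(values=weights[segments.labels], provenance=provenance)


def resolve_class_index(
    image: np.ndarray, classifier: ClassifierAdapter, class_index: int | None
) -> int:
    """Default class choice: the classifier's argmax on the unperturbed
    image (explanations are generated for the predicted class)."""
    if class_index is not None:
        return class_index
    probs = classifier.predict(np.asarray(image)[None])[0]
    return int(np.argmax(probs))


def explain(
    image: np.ndarray,
    classifier: ClassifierAdapter,
    params: SegmenterParams,
    class_index: int | None = None,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    batch_size: int = 256,
    use_kernel: bool = False,
    kernel_width: float = 0.25,
    segments: SegmentMap | None = None,
) -> tuple[Explanation, HeatMap]:
    """Explain one prediction with one segmentation.

    A precomputed ``segments`` map may be supplied (e.g. from a
    count-matching search) to skip re-segmentation; it must match the image.
    Deterministic: identical inputs and seed give bit-identical output.
    """
    image = np.asarray(image)
    if segments is None:
        segments = segment_image(image, params)
    cls = resolve_class_index(image, classifier, class_index)
    masks = sample_masks(segments.k, n_samples, seed)
    probs = predict_perturbations(image, segments, masks, classifier, batch_size)
    explanation = explanation_for_class(
        masks, probs, cls, use_kernel=use_kernel, kernel_width=kernel_width
    )
    heat = heatmap_from_weights(segments, explanation.weights, params.algorithm)
    return explanation, heat


def squaregrid_explain(
    image: np.ndarray,
    classifier: ClassifierAdapter,
    class_index: int | None = None,
    levels: Sequence[int] | None = None,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    batch_size: int = 256,
) -> tuple[HeatMap, list[tuple[int, Explanation, HeatMap]]]:
    """Multi-scale square-grid explanation.

    One independent surrogate run per grid level (per-level seed =
    ``seed`` + level index, masks resampled fresh at every level); the
    final heat map is the elementwise sum of the per-level maps.  Returns
    ``(final_map, [(level, explanation, level_map), ...])``.
    """
    image = np.asarray(image)
    if levels is None:
        levels = default_levels()
    if not levels:
        raise InvalidParameterError("levels must be non-empty")
    h, w = image.shape[:2]
    cls = resolve_class_index(image, classifier, class_index)
    total = np.zeros((h, w), dtype=float)
    per_level: list[tuple[int, Explanation, HeatMap]] = []
    for i, level in enumerate(levels):
        segments = squaregrid_segments(h, w, level)
        explanation, heat = explain(
            image,
            classifier,
            SegmenterParams(algorithm="squaregrid", n_squares=level),
            class_index=cls,
            n_samples=n_samples,
            seed=seed + i,
            batch_size=batch_size,
            segments=segments,
        )
        total += heat.values
        per_level.append((int(level), explanation, heat))
    final = HeatMap(values=total, provenance="squaregrid-sum")
    return final, per_level


def average_heatmaps(maps: Sequence[HeatMap]) -> HeatMap:
    """Elementwise arithmetic mean of heat maps sharing one geometry."""
    if not maps:
        raise InvalidParameterError("cannot average an empty list of heat maps")
    shape = maps[0].shape
    for m in maps[1:]:
        if m.shape != shape:
            raise InvalidParameterError(
                f"heat map shape {m.shape} does not match {shape}"
            )
    stacked = np.stack([m.values for m in maps])
    return HeatMap(values=stacked.mean(axis=0), provenance="avg")


def stability_check(
    image: np.ndarray,
    classifier: ClassifierAdapter,
    params: SegmenterParams,
    class_index: int | None = None,
    n_samples: int = DEFAULT_N_SAMPLES,
    repeats: int = 3,
    base_seed: int = 0,
    batch_size: int = 256,
) -> float:
    """Mean absolute pairwise weight difference across repeated runs.

    Reruns ``explain`` with seeds ``base_seed .. base_seed+repeats-1`` and
    averages |w_j(run a) − w_j(run b)| over all segments j and unordered
    run pairs (a, b).  Small values mean the Monte-Carlo sample size is
    large enough for reproducible weights.
    """
    if repeats < 2:
        raise InvalidParameterError("stability_check needs at least 2 repeats")
    image = np.asarray(image)
    segments = segment_image(image, params)
    cls = resolve_class_index(image, classifier, class_index)
    runs = []
    for r in range(repeats):
        explanation, _ = explain(
            image,
            classifier,
            params,
            class_index=cls,
            n_samples=n_samples,
            seed=base_seed + r,
            batch_size=batch_size,
            segments=segments,
        )
        runs.append(explanation.weights)
    diffs = [
        np.abs(runs[a] - runs[b]).mean()
        for a in range(repeats)
        for b in range(a + 1, repeats)
    ]
    return float(np.mean(diffs))


def save_heatmap_csv(heat: HeatMap, path) -> None:
    """Full-precision decimal text; reading back reproduces the values
    exactly."""
    np.savetxt(path, heat.values, fmt="%.17g", delimiter=",")


def load_heatmap_csv(path, provenance: str = "file") -> HeatMap:
    values = np.loadtxt(path, delimiter=",", ndmin=2)
    return HeatMap(values=values, provenance=provenance)
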