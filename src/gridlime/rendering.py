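"""Heat-map rendering with a symmetric diverging colour convention.

Weights are drawn on a blue–white–red map with symmetric limits
[−L, +L]: zero is white, positive weights shade towards saturated blue,
negative towards saturated red, intensity proportional to |weight|, values
outside the limits clipped.  Expert annotation masks are overlaid as
transparent green.  ``limit_sweep`` re-renders one map at a series of
colour-scale limits so that small-weight structure can be brought out;
``comparison_panel`` composes the side-by-side strips used to compare
segmenters against the annotation.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from .explainer import HeatMap
from .segmentation import InvalidParameterError

# Colormap anchors: linear interpolation in RGB between these.
WHITE = np.array([255, 255, 255], dtype=float)
BLUE = np.array([0, 0, 255], dtype=float)      # positive weights
RED = np.array([255, 0, 0], dtype=float)       # negative weights
OVERLAY_GREEN = np.array([0, 200, 0], dtype=float)
DEFAULT_OVERLAY_ALPHA = 0.35

#: Default colour-limit sweep, spanning [−0.001, 0.001] to [−0.8, 0.8].
DEFAULT_SWEEP = (0.001, 0.005, 0.01, 0.05, 0.1, 0.2, 0.4, 0.8)


@dataclasses.dataclass(frozen=True)
class RenderSpec:
    """Symmetric colour limits and overlay opacity.

    ``vmin`` must equal ``-vmax`` — the convention keeps white pinned at
    weight zero so blue/red areas are comparable across images.
    """

    vmin: float = -1.0
    vmax: float = 1.0
    overlay_alpha: float = DEFAULT_OVERLAY_ALPHA

    def __post_init__(self) -> None:
        if not (self.vmin < 0 < self.vmax) or self.vmin != -self.vmax:
            raise InvalidParameterError(
                f"colour limits must be symmetric about zero, got "
                f"[{self.vmin}, {self.vmax}]"
            )
        if not 0.0 <= self.overlay_alpha <= 1.0:
            raise InvalidParameterError("overlay_alpha must lie in [0, 1]")


def render_heatmap(heat: HeatMap, spec: RenderSpec | None = None) -> np.ndarray:
    """Map weights to an 8-bit RGB raster.

    ``t = clip(value / vmax, −1, 1)``; pixels interpolate white→blue for
    t > 0 and white→red for t < 0, linearly in RGB.  Pure function: the
    same map and spec always give a bit-identical raster.
    """
    if spec is None:
        spec = RenderSpec()
    t = np.clip(heat.values / spec.vmax, -1.0, 1.0)
    mag = np.abs(t)[..., None]
    pos_color = WHITE + (BLUE - WHITE) * mag
    neg_color = WHITE + (RED - WHITE) * mag
    rgb = np.where(t[..., None] >= 0, pos_color, neg_color)
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)


def overlay_annotation(
    base: np.ndarray, annotation: np.ndarray, alpha: float = DEFAULT_OVERLAY_ALPHA
) -> np.ndarray:
    """Blend annotated pixels towards green with opacity ``alpha``."""
    base = np.asarray(base)
    annotation = np.asarray(annotation)
    if annotation.shape != base.shape[:2]:
        raise ValueError(
            f"annotation {annotation.shape} does not match image {base.shape[:2]}"
        )
    mask = (annotation != 0)[..., None]
    blended = base.astype(float) * (1.0 - alpha) + OVERLAY_GREEN * alpha
    out = np.where(mask, blended, base.astype(float))
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def limit_sweep(
    heat: HeatMap, limits: Sequence[float] = DEFAULT_SWEEP
) -> list[np.ndarray]:
    """Render one map at each colour limit L, i.e. with spec (−L, +L).

    Tight limits saturate small weights; loose limits wash them out —
    sweeping reveals at which scale the relevant structure lives.
    """
    limits = list(limits)
    if any(l <= 0 for l in limits):
        raise InvalidParameterError("all sweep limits must be positive")
    if limits != sorted(limits):
        raise InvalidParameterError("sweep limits must be ascending")
    return [render_heatmap(heat, RenderSpec(vmin=-l, vmax=l)) for l in limits]


def comparison_panel(
    image: np.ndarray,
    heatmaps: Mapping[str, HeatMap],
    annotation: np.ndarray | None = None,
    spec: RenderSpec | None = None,
) -> np.ndarray:
    """Horizontal strip: original | annotation overlay (if given) | one
    rendering per named heat map, in mapping order, all at the same
    (default [−1, 1]) colour scale."""
    image = np.asarray(image)
    if spec is None:
        spec = RenderSpec()
    tiles = [image]
    if annotation is not None:
        tiles.append(overlay_annotation(image, annotation, spec.overlay_alpha))
    for name, heat in heatmaps.items():
        if heat.shape != image.shape[:2]:
            raise ValueError(
                f"heat map {name!r} shape {heat.shape} does not match the image"
            )
        tiles.append(render_heatmap(heat, spec))
    return np.concatenate(tiles, axis=1)
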