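"""Image segmentation backends with a uniform contract.

Four ways of partitioning a patch into the atomic units of an explanation:

* ``squaregrid`` — regular r×r grids of (near-)equal squares, the
  parameter-free decomposition used by the multi-scale explainer;
* ``fha`` (Felzenszwalb), ``slic`` and ``quickshift`` — the three classical
  superpixel algorithms, delegated to scikit-image.

All backends return a :class:`SegmentMap` whose labels are renumbered to a
contiguous ``0..k-1`` range in row-major first-occurrence order, so the
output is deterministic and backend-independent in its labelling.

Because quickshift offers no direct control over its segment count, it
serves as the baseline in three-way comparisons: FHA's ``scale`` and SLIC's
``n_segments`` are tuned (:func:`match_segment_counts`) until the counts
agree.
"""

from __future__ import annotations

import csv
import dataclasses
import math
from typing import Callable

import numpy as np
from skimage import segmentation as _sk_seg

#: Gaussian pre-smoothing width shared by all backends (the library default
#: for Felzenszwalb, adopted uniformly).
DEFAULT_SIGMA: float = 0.8

#: Quickshift defaults; only sigma is canonical, the rest are chosen so that
#: 96×96 patches land in the typical 20–40 superpixel range.
QUICKSHIFT_DEFAULTS = {"kernel_size": 4.0, "max_dist": 6.0, "ratio": 0.5}

#: The seven square-grid sizes of the multi-scale explainer.
SQUAREGRID_LEVELS = (9, 16, 36, 64, 144, 256, 576)

ALGORITHMS = ("fha", "slic", "quickshift", "squaregrid")


class InvalidParameterError(ValueError):
    """A segmentation / explanation parameter is out of its valid domain."""


@dataclasses.dataclass(frozen=True)
class SegmentMap:
    """Integer label per pixel partitioning an image into ``k`` segments.

    Invariants: ``labels`` has shape (height, width); every pixel's label
    lies in ``[0, k)`` and every label in that range occurs at least once.
    """

    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise InvalidParameterError("labels raster must be 2-D")
        present = np.unique(labels)
        if present.size != self.k or present[0] != 0 or present[-1] != self.k - 1:
            raise InvalidParameterError(
                f"labels must cover 0..{self.k - 1} contiguously; found {present.size} "
                f"distinct labels in [{present[0]}, {present[-1]}]"
            )
        object.__setattr__(self, "labels", labels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def segment_sizes(self) -> np.ndarray:
        """Pixel count per segment, indexed by label."""
        return np.bincount(self.labels.ravel(), minlength=self.k)


@dataclasses.dataclass(frozen=True)
class SegmenterParams:
    """Algorithm id plus the parameters that algorithm consults.

    Fields irrelevant to ``algorithm`` are ignored.  ``sigma`` is the width
    of the Gaussian pre-smoothing step common to all backends.
    """

    algorithm: str
    sigma: float = DEFAULT_SIGMA
    scale: float = 100.0            # fha only
    n_segments: int = 30            # slic only
    kernel_size: float = QUICKSHIFT_DEFAULTS["kernel_size"]  # quickshift only
    max_dist: float = QUICKSHIFT_DEFAULTS["max_dist"]        # quickshift only
    ratio: float = QUICKSHIFT_DEFAULTS["ratio"]              # quickshift only
    n_squares: int = 9              # squaregrid only

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise InvalidParameterError(
                f"unknown segmentation algorithm {self.algorithm!r}; "
                f"expected one of {ALGORITHMS}"
            )
        if self.sigma < 0:
            raise InvalidParameterError("sigma must be >= 0")


def _as_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise InvalidParameterError(
            f"expected a height×width×3 RGB raster, got shape {image.shape}"
        )
    return image


def squaregrid_segments(height: int, width: int, n_squares: int) -> SegmentMap:
    """Partition a ``height``×``width`` raster into an r×r grid of squares.

    ``n_squares`` must be a perfect square r². Block edges sit at
    ``round(i * dim / r)``, so when the dimension is divisible by r all
    blocks are identical and otherwise block sides differ by at most one
    pixel. Labels run row-major, 0 at the top-left block.
    """
    if n_squares < 1:
        raise InvalidParameterError("n_squares must be positive")
    r = math.isqrt(n_squares)
    if r * r != n_squares:
        raise InvalidParameterError(
            f"n_squares must be a perfect square, got {n_squares}"
        )
    if r > min(height, width):
        raise InvalidParameterError(
            f"grid side {r} exceeds the smallest image dimension "
            f"{min(height, width)}"
        )
    row_edges = np.array([round(i * height / r) for i in range(r + 1)])
    col_edges = np.array([round(i * width / r) for i in range(r + 1)])
    # searchsorted maps each pixel coordinate to its block index
    row_block = np.searchsorted(row_edges, np.arange(height), side="right") - 1
    col_block = np.searchsorted(col_edges, np.arange(width), side="right") - 1
    labels = row_block[:, None] * r + col_block[None, :]
    return SegmentMap(labels=labels.astype(np.int32), k=n_squares)


def default_levels() -> list[int]:
    """The seven square-grid sizes, coarse to fine: 9 through 576 squares."""
    return list(SQUAREGRID_LEVELS)


def relabel_contiguous(raw: np.ndarray) -> SegmentMap:
    """Renumber arbitrary integer labels to 0..k-1 in row-major
    first-occurrence order, preserving the partition."""
    raw = np.asarray(raw)
    flat = raw.ravel()
    _, first_idx, inverse = np.unique(flat, return_index=True, return_inverse=True)
    # order labels by where each first appears in the row-major scan
    order = np.argsort(first_idx, kind="stable")
    remap = np.empty(order.size, dtype=np.int32)
    remap[order] = np.arange(order.size, dtype=np.int32)
    labels = remap[inverse].reshape(raw.shape)
    return SegmentMap(labels=labels, k=int(order.size))


def segment_image(image: np.ndarray, params: SegmenterParams) -> SegmentMap:
    """Run the backend named by ``params.algorithm`` and normalise labels.

    squaregrid is content-independent and routes to
    :func:`squaregrid_segments`; the other three call scikit-image.
    """
    image = _as_rgb(image)
    h, w = image.shape[:2]
    if params.algorithm == "squaregrid":
        return squaregrid_segments(h, w, params.n_squares)
    if params.algorithm == "fha":
        raw = _sk_seg.felzenszwalb(image, scale=params.scale, sigma=params.sigma)
    elif params.algorithm == "slic":
        raw = _sk_seg.slic(
            image,
            n_segments=params.n_segments,
            sigma=params.sigma,
            start_label=0,
        )
    elif params.algorithm == "quickshift":
        raw = _sk_seg.quickshift(
            image,
            kernel_size=params.kernel_size,
            max_dist=params.max_dist,
            ratio=params.ratio,
            sigma=params.sigma,
            rng=0,  # quickshift seeds its mode seeking; fixed for determinism
        )
    else:  # pragma: no cover - guarded by SegmenterParams
        raise InvalidParameterError(f"unknown algorithm {params.algorithm!r}")
    return relabel_contiguous(raw)


@dataclasses.dataclass(frozen=True)
class MatchResult:
    """One algorithm's best parameters in a count-matching search."""

    params: SegmenterParams
    segments: SegmentMap
    achieved_count: int
    target_count: int
    exact: bool


def _count_for(image: np.ndarray, params: SegmenterParams) -> tuple[int, SegmentMap]:
    seg = segment_image(image, params)
    return seg.k, seg


def _search_monotone(
    image: np.ndarray,
    make_params: Callable[[float], SegmenterParams],
    lo: float,
    hi: float,
    target: int,
    increasing: bool,
    integer: bool,
) -> MatchResult:
    """Bisect a parameter whose segment count is (assumed) monotone.

    ``increasing`` gives the direction of count vs parameter. If the counts
    at the bracket ends contradict monotonicity, or bisection terminates
    without an exact hit, fall back to a coarse scan and return the closest
    count with ``exact`` set accordingly.
    """
    cache: dict[float, tuple[int, SegmentMap]] = {}

    def evaluate(x: float) -> tuple[int, SegmentMap]:
        x = float(round(x)) if integer else float(x)
        if x not in cache:
            cache[x] = _count_for(image, make_params(x))
        return cache[x]

    a, b = float(lo), float(hi)
    monotone = True
    ca, _ = evaluate(a)
    cb, _ = evaluate(b)
    lo_count, hi_count = (ca, cb) if increasing else (cb, ca)
    if lo_count > hi_count:
        monotone = False

    if monotone:
        # bisect until exact hit or the bracket collapses
        while True:
            mid = (a + b) / 2
            if integer:
                mid = round(mid)
            cm, _ = evaluate(mid)
            if cm == target:
                break
            # shrink towards the side that should contain the target
            want_higher = cm < target
            go_up = want_higher == increasing
            if go_up:
                a = mid
            else:
                b = mid
            width = b - a
            if (integer and width <= 1) or (not integer and width <= max(1e-6, 1e-4 * abs(hi))):
                break

    if not monotone or min(cache.items(), key=lambda kv: abs(kv[1][0] - target))[1][0] != target:
        # scan fallback: coarse grid over the range
        n_grid = 24
        if integer:
            grid = np.unique(np.round(np.linspace(lo, hi, min(n_grid, int(hi - lo) + 1))))
        else:
            grid = np.linspace(lo, hi, n_grid)
        for x in grid:
            evaluate(float(x))

    best_x, (best_count, best_seg) = min(
        cache.items(), key=lambda kv: (abs(kv[1][0] - target), kv[0])
    )
    return MatchResult(
        params=make_params(best_x),
        segments=best_seg,
        achieved_count=best_count,
        target_count=target,
        exact=best_count == target,
    )


def match_segment_counts(
    image: np.ndarray,
    baseline: SegmenterParams | None = None,
    fha_scale_range: tuple[float, float] = (200.0, 600.0),
    slic_range: tuple[int, int] = (5, 120),
) -> dict[str, MatchResult]:
    """Tune FHA and SLIC so their segment counts match the quickshift baseline.

    Runs the quickshift ``baseline`` (defaults if None), records its count
    k*, then searches FHA's ``scale`` (count decreasing in scale) and SLIC's
    ``n_segments`` (count increasing) for parameters reproducing k*.
    Bisection is used first; on detected non-monotonicity or a miss, a coarse
    scan picks the closest count, flagged via ``exact``.
    """
    image = _as_rgb(image)
    if baseline is None:
        baseline = SegmenterParams(algorithm="quickshift")
    if baseline.algorithm != "quickshift":
        raise InvalidParameterError("baseline must use the quickshift algorithm")
    for name, (lo, hi) in (("fha", fha_scale_range), ("slic", slic_range)):
        if not lo <= hi:
            raise InvalidParameterError(f"empty search range for {name}: {(lo, hi)}")

    base_seg = segment_image(image, baseline)
    target = base_seg.k
    sigma = baseline.sigma

    results: dict[str, MatchResult] = {
        "quickshift": MatchResult(
            params=baseline,
            segments=base_seg,
            achieved_count=target,
            target_count=target,
            exact=True,
        )
    }
    results["slic"] = _search_monotone(
        image,
        lambda n: SegmenterParams(algorithm="slic", sigma=sigma, n_segments=int(n)),
        slic_range[0],
        slic_range[1],
        target,
        increasing=True,
        integer=True,
    )
    results["fha"] = _search_monotone(
        image,
        lambda s: SegmenterParams(algorithm="fha", sigma=sigma, scale=float(s)),
        fha_scale_range[0],
        fha_scale_range[1],
        target,
        increasing=False,
        integer=False,
    )
    return results


# ---------------------------------------------------------------------------
# SegmentMap file round-tripping

def save_segments_csv(seg: SegmentMap, path) -> None:
    np.savetxt(path, seg.labels, fmt="%d", delimiter=",")

def load_segments_csv(path) -> SegmentMap:
    with open(path, newline="") as fh:
        rows = [[int(v) for v in row] for row in csv.reader(fh) if row]
    return relabel_contiguous(np.array(rows, dtype=np.int32))

def save_segments_png(seg: SegmentMap, path) -> None:
    """Write labels as a single-channel 16-bit PNG (label = pixel value)."""
    import imageio.v3 as iio

    if seg.k > 65536:
        raise InvalidParameterError("more than 65536 segments cannot fit 16-bit PNG")
    iio.imwrite(path, seg.labels.astype(np.uint16))

def load_segments_png(path) -> SegmentMap:
    import imageio.v3 as iio

    return relabel_contiguous(np.asarray(iio.imread(path)).astype(np.int32))
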