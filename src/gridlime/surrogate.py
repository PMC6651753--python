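"""Linear surrogate fitting: from (mask, probability) pairs to per-segment
explanation weights.

The surrogate is ordinary least squares of a class-probability column on
the binary mask bits plus an intercept — each coefficient estimates how
much revealing that segment moves the probability of the explained class.
An optional exponential proximity kernel (weights decaying with cosine
distance from the unperturbed instance) is available for parity with the
reference LIME implementation; plain unweighted regression is the default.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .perturbation import MaskMatrix
from .segmentation import InvalidParameterError


class SingularDesignError(np.linalg.LinAlgError):
    """The [1 | masks] design matrix is rank deficient."""


@dataclasses.dataclass(frozen=True)
class Explanation:
    """Fitted surrogate for one class: per-segment weights w_j, intercept b
    and the coefficient of determination of the fit.

    Positive weights favour the explained class (revealing the segment
    raises its probability); negative weights oppose it.
    """

    class_index: int
    weights: np.ndarray
    intercept: float
    fit_score: float
    n_samples: int
    seed: int

    @property
    def k(self) -> int:
        return self.weights.shape[0]

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "class": self.class_index,
            "intercept": float(self.intercept),
            "weights": [float(w) for w in self.weights],
            "fit_score": float(self.fit_score),
            "seed": self.seed,
            "n_samples": self.n_samples,
        }


def _collinear_columns(design: np.ndarray) -> list[int]:
    """Indices of design columns involved in a rank deficiency (QR with
    column pivoting; the columns pivoted past the numerical rank)."""
    from scipy.linalg import qr

    _, r, piv = qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return sorted(int(c) for c in piv[rank:])


def fit_surrogate(
    masks: MaskMatrix,
    targets: np.ndarray,
    sample_weights: np.ndarray | None = None,
) -> tuple[np.ndarray, float, float]:
    """Least squares of ``targets`` on the mask bits plus an intercept.

    Returns ``(weights, intercept, fit_score)`` where ``fit_score`` is the
    (possibly weighted) coefficient of determination on the fitting set,
    defined as 1 when the residuals are identically zero.

    Raises :class:`SingularDesignError` naming the collinear columns when
    the design is rank deficient (fewer samples than k+1, or duplicated /
    constant mask columns).
    """
    x = masks.rows.astype(float)
    y = np.asarray(targets, dtype=float).ravel()
    n, k = x.shape
    if y.shape[0] != n:
        raise InvalidParameterError(
            f"targets length {y.shape[0]} does not match {n} mask rows"
        )
    if n < k + 1:
        raise SingularDesignError(
            f"need at least k+1={k + 1} samples to fit {k} weights plus an "
            f"intercept; got {n}"
        )
    design = np.concatenate([np.ones((n, 1)), x], axis=1)

    if sample_weights is not None:
        w = np.asarray(sample_weights, dtype=float).ravel()
        if w.shape[0] != n:
            raise InvalidParameterError("sample_weights length mismatch")
        if (w < 0).any():
            raise InvalidParameterError("sample_weights must be non-negative")
        sw = np.sqrt(w)
        design_w = design * sw[:, None]
        y_w = y * sw
    else:
        w = None
        design_w = design
        y_w = y

    coef, _, rank, _ = np.linalg.lstsq(design_w, y_w, rcond=None)
    if rank < k + 1:
        cols = _collinear_columns(design_w)
        names = ["intercept" if c == 0 else f"segment {c - 1}" for c in cols]
        raise SingularDesignError(
            f"rank-deficient design (rank {rank} < {k + 1}); collinear "
            f"columns: {', '.join(names)}"
        )

    intercept, weights = float(coef[0]), coef[1:]
    residuals = y - design @ coef
    if w is None:
        ss_res = float(residuals @ residuals)
        y_bar = float(y.mean())
        ss_tot = float(((y - y_bar) ** 2).sum())
    else:
        ss_res = float(w @ residuals**2)
        y_bar = float(w @ y / w.sum()) if w.sum() > 0 else 0.0
        ss_tot = float(w @ (y - y_bar) ** 2)

    scale = max(ss_tot, float(y @ y), 1.0)
    if ss_res <= 1e-12 * scale:
        score = 1.0
    elif ss_tot <= 0.0:
        score = 0.0
    else:
        score = max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return weights, intercept, score


def proximity_weights(masks: MaskMatrix, kernel_width: float = 0.25) -> np.ndarray:
    """Exponential kernel on cosine distance from the all-ones row:
    ``exp(-d_i^2 / kernel_width^2)``.  The all-zeros row has distance 1 by
    convention (zero norm)."""
    if kernel_width <= 0:
        raise InvalidParameterError("kernel_width must be positive")
    x = masks.rows.astype(float)
    k = masks.k
    norms = np.sqrt((x**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_sim = x.sum(axis=1) / (norms * np.sqrt(k))
    cos_sim = np.where(norms == 0, 0.0, cos_sim)
    d = 1.0 - cos_sim
    return np.exp(-(d**2) / kernel_width**2)


def explanation_for_class(
    masks: MaskMatrix,
    probabilities: np.ndarray,
    class_index: int,
    use_kernel: bool = False,
    kernel_width: float = 0.25,
) -> Explanation:
    """Fit the surrogate on one probability column and package the result."""
    probabilities = np.asarray(probabilities, dtype=float)
    if probabilities.ndim != 2:
        raise InvalidParameterError("probabilities must be an N×C matrix")
    n_classes = probabilities.shape[1]
    if not 0 <= class_index < n_classes:
        raise InvalidParameterError(
            f"class_index {class_index} out of range for {n_classes} classes"
        )
    sw = proximity_weights(masks, kernel_width) if use_kernel else None
    weights, intercept, score = fit_surrogate(
        masks, probabilities[:, class_index], sample_weights=sw
    )
    return Explanation(
        class_index=class_index,
        weights=weights,
        intercept=intercept,
        fit_score=score,
        n_samples=masks.n_samples,
        seed=masks.seed,
    )
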