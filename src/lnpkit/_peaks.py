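"""Sub-bin peak refinement shared by the Raman and SAXS peak pickers."""

from __future__ import annotations

import numpy as np

__all__ = ["parabolic_vertex", "refine_peak"]


def parabolic_vertex(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Vertex of the parabola through three points.

    Parameters
    ----------
    x, y : arrays of length 3 — the maximum bin and its two neighbours,
        in increasing-x order. The grid need not be uniform.

    Returns
    -------
    (x_vertex, y_vertex). If the three points have non-negative curvature
    (no local maximum), the centre point is returned unchanged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != (3,) or y.shape != (3,):
        raise ValueError("parabolic_vertex needs exactly 3 points")
    # exact quadratic through 3 points
    coef = np.polyfit(x - x[1], y, 2)
    a = coef[0]
    if a >= 0:  # flat or concave-up: fall back to the sampled maximum
        return float(x[1]), float(y[1])
    dx = -coef[1] / (2.0 * a)
    yv = np.polyval(coef, dx)
    return float(x[1] + dx), float(yv)


def refine_peak(x: np.ndarray, y: np.ndarray, idx: int) -> tuple[float, float]:
    """Refine the peak at bin ``idx`` with a 3-point parabola.

    Refinement applies only where bin ``idx`` is a genuine local maximum
    (at least as high as both neighbours); on a flank — e.g. a search window
    whose highest bin sits at its edge against a neighbouring band — the
    parabola would extrapolate an unphysical vertex outside the stencil, so
    the bin value is returned unchanged. Array edges likewise.
    """
    if idx <= 0 or idx >= len(x) - 1:
        return float(x[idx]), float(y[idx])
    if y[idx] < y[idx - 1] or y[idx] < y[idx + 1]:
        return float(x[idx]), float(y[idx])
    return parabolic_vertex(x[idx - 1 : idx + 2], y[idx - 1 : idx + 2])
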