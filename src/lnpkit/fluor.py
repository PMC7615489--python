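"""Fluorescence-cascade enzyme-activity analysis.

Phospholipase D activity is read out by a coupled assay: PLD releases
choline from DOPC, choline oxidase converts it to betaine + H2O2, and
horseradish peroxidase uses the H2O2 to turn a profluorophore into the
fluorescent reporter. Modelling the cascade as two sequential first-order
steps (rate-limiting PLD step k_pld, lumped reporter step k_cascade) gives

    F(t) = Fmax * [1 - (k2 e^{-k1 t} - k1 e^{-k2 t}) / (k2 - k1)],

with Fmax proportional to the initial substrate amount. The analysis
extracts the plateau Fmax, the time to half-maximal fluorescence T_1/2 (the
time to convert half the substrate), the local linear rate around the
half-max point, and the plateau-vs-substrate calibration line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats

__all__ = [
    "FluoCurve",
    "FmaxEstimate",
    "FluoResult",
    "cascade_model",
    "estimate_fmax",
    "time_to_half",
    "rate_at_half",
    "FmaxCalibration",
    "CalibrationResults",
    "fmax_calibration",
    "analyze_curve",
]


@dataclass
class FluoCurve:
    """Kinetic plate-reader trace: time (min, strictly increasing) vs F (a.u.)."""

    t: np.ndarray
    F: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.F.shape:
            raise ValueError("t and F must be 1-D arrays of equal length")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")
        if not np.all(np.isfinite(self.F)):
            raise ValueError("F must be finite")

    def __len__(self) -> int:
        return len(self.t)


def cascade_model(t: np.ndarray, fmax: float, k_pld: float, k_cascade: float
                  ) -> np.ndarray:
    """Noiseless two-step first-order cascade fluorescence.

    ``k_pld`` and ``k_cascade`` must be positive and distinct. In the limit
    k_cascade >> k_pld this reduces to Fmax * (1 - exp(-k_pld t)).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    k1, k2 = k_pld, k_cascade
    if k1 <= 0 or k2 <= 0:
        raise ValueError("rates must be positive")
    if k1 == k2:
        raise ValueError("k_cascade must differ from k_pld")
    return fmax * (1.0 - (k2 * np.exp(-k1 * t) - k1 * np.exp(-k2 * t)) / (k2 - k1))


def cascade_rate(t: np.ndarray, fmax: float, k_pld: float, k_cascade: float
                 ) -> np.ndarray:
    """Analytic time derivative of :func:`cascade_model` (a.u. / min)."""
    t = np.asarray(t, dtype=float)
    k1, k2 = k_pld, k_cascade
    return fmax * k1 * k2 * (np.exp(-k1 * t) - np.exp(-k2 * t)) / (k2 - k1)


@dataclass(frozen=True)
class FmaxEstimate:
    value: float
    unsaturated: bool


def estimate_fmax(curve: FluoCurve, tail_frac: float = 0.05,
                  rise_frac: float = 0.10, rise_tol: float = 0.01) -> FmaxEstimate:
    """Plateau fluorescence from the tail of the trace.

    Fmax is the median of the last ``tail_frac`` of time-ordered points
    (at least 3). The estimate is flagged ``unsaturated`` when the last
    ``rise_frac`` of the trace still rises faster than ``rise_tol`` * Fmax
    per minute.
    """
    if len(curve) < 20:
        raise ValueError("need at least 20 points to estimate Fmax")
    n_tail = max(3, int(round(tail_frac * len(curve))))
    fmax = float(np.median(curve.F[-n_tail:]))
    n_rise = max(3, int(round(rise_frac * len(curve))))
    slope = scipy.stats.linregress(curve.t[-n_rise:], curve.F[-n_rise:]).slope
    unsaturated = bool(abs(fmax) > 0 and slope > rise_tol * abs(fmax))
    return FmaxEstimate(value=fmax, unsaturated=unsaturated)


def _baseline(curve: FluoCurve, n_baseline: int = 5) -> float:
    return float(np.median(curve.F[: max(1, min(n_baseline, len(curve)))]))


def _half_crossing_index(curve: FluoCurve, fmax: float,
                         baseline_subtracted: bool = True,
                         n_baseline: int = 5) -> tuple[int, float] | None:
    """Index i of the first upward crossing (between i and i+1) and threshold."""
    f0 = _baseline(curve, n_baseline) if baseline_subtracted else 0.0
    threshold = f0 + (fmax - f0) / 2.0
    above = curve.F >= threshold
    for i in range(len(curve) - 1):
        if not above[i] and above[i + 1]:
            return i, threshold
    if above[0]:
        return 0, threshold  # already above at start
    return None


def time_to_half(curve: FluoCurve, fmax: float | None = None,
                 baseline_subtracted: bool = True,
                 n_baseline: int = 5) -> float:
    """Time of the first upward crossing of half-maximal fluorescence.

    The threshold is F0 + (Fmax - F0)/2 with F0 the median of the first
    ``n_baseline`` points (set ``baseline_subtracted=False`` for a plain
    Fmax/2 criterion). Linear interpolation between the bracketing samples;
    NaN if the curve never crosses.
    """
    if fmax is None:
        fmax = estimate_fmax(curve).value
    hit = _half_crossing_index(curve, fmax, baseline_subtracted, n_baseline)
    if hit is None:
        return float("nan")
    i, threshold = hit
    if curve.F[i] >= threshold:
        return float(curve.t[i])
    f1, f2 = curve.F[i], curve.F[i + 1]
    t1, t2 = curve.t[i], curve.t[i + 1]
    return float(t1 + (threshold - f1) / (f2 - f1) * (t2 - t1))


def rate_at_half(curve: FluoCurve, fmax: float | None = None,
                 n_points: int = 5, baseline_subtracted: bool = True
                 ) -> tuple[float, dict]:
    """OLS slope over ``n_points`` samples centred on the half-max crossing.

    Returns (slope in a.u./min, info dict). At the ends of the trace the
    window is shifted inward and the shift recorded in the info dict; fewer
    than ``n_points`` total samples is an error.
    """
    if len(curve) < n_points:
        raise ValueError(f"need at least {n_points} points")
    if fmax is None:
        fmax = estimate_fmax(curve).value
    hit = _half_crossing_index(curve, fmax, baseline_subtracted)
    if hit is None:
        raise ValueError("curve never crosses half-maximal fluorescence")
    # centre the window on the sample nearest the interpolated crossing,
    # not on the left bracket, so the local fit straddles the 50% point
    t_cross = time_to_half(curve, fmax, baseline_subtracted)
    i = int(np.argmin(np.abs(curve.t - t_cross)))
    start = i - (n_points - 1) // 2
    shifted = 0
    if start < 0:
        shifted = -start
        start = 0
    if start + n_points > len(curve):
        shifted = len(curve) - n_points - start
        start = len(curve) - n_points
    sel = slice(start, start + n_points)
    fit = scipy.stats.linregress(curve.t[sel], curve.F[sel])
    return float(fit.slope), {"window": (start, start + n_points),
                              "shifted_by": shifted,
                              "stderr": float(fit.stderr)}


@dataclass(frozen=True)
class FluoResult:
    """Per-trace readout: plateau, half time, local rate."""

    fmax: float
    unsaturated: bool
    t_half: float  # min; NaN when the curve never crosses
    rate_at_half: float  # a.u. / min


def analyze_curve(curve: FluoCurve, n_points: int = 5,
                  baseline_subtracted: bool = True) -> FluoResult:
    est = estimate_fmax(curve)
    t_half = time_to_half(curve, est.value, baseline_subtracted)
    try:
        rate, _ = rate_at_half(curve, est.value, n_points, baseline_subtracted)
    except ValueError:
        rate = float("nan")
    return FluoResult(fmax=est.value, unsaturated=est.unsaturated,
                      t_half=t_half, rate_at_half=rate)


# ---------------------------------------------------------------------------
# plateau-vs-substrate calibration

@dataclass(frozen=True)
class CalibrationResults:
    slope: float
    intercept: float
    r_squared: float
    slope_stderr: float
    n_levels: int

    def predict(self, substrate: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(substrate, dtype=float)

    def summary(self) -> str:
        return ("Fmax calibration: Fmax = "
                f"{self.intercept:.4g} + {self.slope:.4g} * S0 "
                f"(R^2 = {self.r_squared:.4f}, {self.n_levels} levels)")


class FmaxCalibration:
    """Straight-line model of plateau fluorescence vs substrate amount."""

    def __init__(self, substrate: np.ndarray, fmax: np.ndarray):
        self.substrate = np.asarray(substrate, dtype=float)
        self.fmax = np.asarray(fmax, dtype=float)
        if len(np.unique(self.substrate)) < 3:
            raise ValueError("need at least 3 distinct substrate levels")

    def fit(self) -> CalibrationResults:
        fit = scipy.stats.linregress(self.substrate, self.fmax)
        return CalibrationResults(
            slope=float(fit.slope), intercept=float(fit.intercept),
            r_squared=float(fit.rvalue**2), slope_stderr=float(fit.stderr),
            n_levels=len(np.unique(self.substrate)))


def fmax_calibration(curves: list[FluoCurve],
                     substrate_key: str = "substrate") -> CalibrationResults:
    """Fit the calibration line from curves labelled with substrate amounts."""
    substrate = np.array([c.meta[substrate_key] for c in curves], dtype=float)
    fmax = np.array([estimate_fmax(c).value for c in curves])
    return FmaxCalibration(substrate, fmax).fit()
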