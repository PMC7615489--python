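"""First-order kinetics of enzymatic DOPC -> DOPA conversion.

Per-particle choline:cholesterol band ratios are mapped to substrate
fractions via a two-point calibration built from control formulations with
all-substrate (15:0 mol% PC:PA) and all-product (0:15) compositions, then
the population time-course is fitted with a first-order decay. Because the
enzyme is in excess relative to the substrate, Michaelis-Menten parameters
are not identifiable; the module deliberately offers only the first-order
rate (and its half-time t50 = ln2 / k) and the model-free band-crossing
estimator of the time at which single particles pass 50% conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.optimize

__all__ = [
    "CalibrationCurve",
    "KineticsResults",
    "BandCrossing",
    "ratio_to_fraction",
    "FirstOrderKinetics",
    "fit_first_order",
    "t50_band_crossing",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Two-point ratio calibration from control formulations."""

    ratio_at_full_substrate: float  # median ratio of the 15:0 PC:PA control
    ratio_at_zero_substrate: float  # median ratio of the 0:15 control

    def __post_init__(self) -> None:
        if not self.ratio_at_full_substrate > self.ratio_at_zero_substrate:
            raise ValueError(
                "calibration endpoints degenerate: full-substrate ratio must "
                "exceed zero-substrate ratio")


def ratio_to_fraction(ratio, cal: CalibrationCurve):
    """Substrate fraction remaining, by linear interpolation, clipped to [0, 1]."""
    ratio = np.asarray(ratio, dtype=float)
    frac = (ratio - cal.ratio_at_zero_substrate) / (
        cal.ratio_at_full_substrate - cal.ratio_at_zero_substrate)
    out = np.clip(frac, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class KineticsResults:
    """First-order fit: f(t) = offset + amplitude * exp(-k (t - lag)_+)."""

    k: float  # 1/min
    amplitude: float
    offset: float
    lag: float  # min (0 unless the lag term was enabled)
    residual_rms: float
    n_points: int
    k_stderr: float
    flags: tuple[str, ...] = ()

    @property
    def t50(self) -> float:
        """Half-time ln2 / k; infinite for k = 0 (flagged non-identifiable)."""
        return math.log(2.0) / self.k if self.k > 0 else float("inf")

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.offset + self.amplitude * np.exp(
            -self.k * np.clip(t - self.lag, 0.0, None))

    def summary(self) -> str:
        lines = [
            "First-order conversion kinetics",
            "=" * 34,
            f"{'k (1/min)':<16}{self.k:>12.5g} +/- {self.k_stderr:.3g}",
            f"{'t50 (min)':<16}{self.t50:>12.5g}",
            f"{'amplitude':<16}{self.amplitude:>12.5g}",
            f"{'offset':<16}{self.offset:>12.5g}",
            f"{'residual rms':<16}{self.residual_rms:>12.4g}",
            f"{'n points':<16}{self.n_points:>12d}",
        ]
        if self.flags:
            lines.append("flags: " + ", ".join(self.flags))
        return "\n".join(lines)

    def plot(self, times=None, fractions=None, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if times is not None:
            ax.plot(times, fractions, "o", ms=4, label="particles")
            grid = np.linspace(min(times), max(times), 200)
        else:
            grid = np.linspace(0.0, 3.0 * self.t50 if self.k > 0 else 30.0, 200)
        ax.plot(grid, self.predict(grid), "-", label="first-order fit")
        ax.set_xlabel("time since enzyme addition (min)")
        ax.set_ylabel("substrate fraction remaining")
        ax.legend()
        return ax


class FirstOrderKinetics:
    """First-order decay model of substrate fraction vs time.

    Bounds: k >= 0, offset in [0, 0.5] (conversion is observed to complete,
    so the offset may not absorb the signal), amplitude in [0, 1.2]. The
    offset and an optional dead-time lag are off by default. Fitting is
    bounded least squares with a multi-start over 5 log-spaced rate
    initialisations; the best residual wins.
    """

    def __init__(self, times, fractions, include_offset: bool = False,
                 include_lag: bool = False):
        self.times = np.asarray(times, dtype=float)
        self.fractions = np.asarray(fractions, dtype=float)
        if self.times.shape != self.fractions.shape or self.times.ndim != 1:
            raise ValueError("times and fractions must be 1-D and equal length")
        if len(self.times) < 5:
            raise ValueError("need at least 5 points")
        if np.any(self.times < 0):
            raise ValueError("times must be non-negative")
        self.include_offset = include_offset
        self.include_lag = include_lag

    def fit(self, n_starts: int = 5) -> KineticsResults:
        t, f = self.times, self.fractions
        flags: list[str] = []
        if np.ptp(f) == 0:
            # all-constant fractions: rate not identifiable
            return KineticsResults(
                k=0.0, amplitude=0.0, offset=float(f[0]), lag=0.0,
                residual_rms=0.0, n_points=len(t), k_stderr=float("nan"),
                flags=("non-identifiable",))

        t_span = max(t.max() - t.min(), 1e-9)
        k_starts = np.geomspace(0.1, 50.0, n_starts) / t_span

        # parameter vector: [k, amplitude, (offset), (lag)]
        lo = [0.0, 0.0]
        hi = [np.inf, 1.2]
        if self.include_offset:
            lo.append(0.0)
            hi.append(0.5)
        if self.include_lag:
            lo.append(0.0)
            hi.append(float(t.max()))
        lo, hi = np.array(lo), np.array(hi)

        def unpack(x):
            k, amp = x[0], x[1]
            i = 2
            off = x[i] if self.include_offset else 0.0
            i += self.include_offset
            lag = x[i] if self.include_lag else 0.0
            return k, amp, off, lag

        def resid(x):
            k, amp, off, lag = unpack(x)
            return off + amp * np.exp(-k * np.clip(t - lag, 0.0, None)) - f

        best = None
        for k0 in k_starts:
            x0 = [k0, min(max(f.max(), 0.1), 1.2)]
            if self.include_offset:
                x0.append(min(max(f.min(), 0.0), 0.5))
            if self.include_lag:
                x0.append(0.0)
            sol = scipy.optimize.least_squares(
                resid, np.clip(np.array(x0), lo, hi), bounds=(lo, hi),
                method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
            if best is None or sol.cost < best.cost:
                best = sol

        k, amp, off, lag = unpack(best.x)
        rms = float(np.sqrt(2.0 * best.cost / len(t)))
        dof = max(len(t) - len(best.x), 1)
        try:
            cov = np.linalg.pinv(best.jac.T @ best.jac) * (2.0 * best.cost / dof)
            k_stderr = float(np.sqrt(max(cov[0, 0], 0.0)))
        except Exception:
            k_stderr = float("nan")
        if k == 0:
            flags.append("non-identifiable")
        return KineticsResults(k=float(k), amplitude=float(amp),
                               offset=float(off), lag=float(lag),
                               residual_rms=rms, n_points=len(t),
                               k_stderr=k_stderr, flags=tuple(flags))


def fit_first_order(times, fractions, include_offset: bool = False,
                    include_lag: bool = False, n_starts: int = 5
                    ) -> KineticsResults:
    """Fit f(t) = offset + amplitude * exp(-k t) to a particle time-course."""
    return FirstOrderKinetics(times, fractions, include_offset,
                              include_lag).fit(n_starts)


@dataclass
class BandCrossing:
    """Model-free t50: observation times of particles near 50% conversion."""

    times: np.ndarray
    median: float
    iqr: float
    n: int
    band: tuple[float, float]
    empty: bool = False

    def summary(self) -> str:
        if self.empty:
            return (f"band {self.band}: no particles in band "
                    "(warning: t50 not estimable)")
        return (f"band {self.band}: n = {self.n}, median = "
                f"{self.median:.3g} min, IQR = {self.iqr:.3g} min")


def t50_band_crossing(times, fractions,
                      band: tuple[float, float] = (0.45, 0.55)) -> BandCrossing:
    """Times of particles whose remaining-substrate fraction is in ``band``.

    Mirrors the single-particle estimator of time-to-50%-conversion: every
    trapped particle with a fraction between the band edges contributes its
    observation time; the population median +- IQR summarises. An empty
    selection is a warning (flagged result), not an error.
    """
    lo, hi = band
    if not (0.0 < lo < hi < 1.0):
        raise ValueError("band must satisfy 0 < lower < upper < 1")
    times = np.asarray(times, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    sel = (fractions >= lo) & (fractions <= hi)
    chosen = times[sel]
    if len(chosen) == 0:
        return BandCrossing(times=chosen, median=float("nan"),
                            iqr=float("nan"), n=0, band=band, empty=True)
    q25, q50, q75 = np.percentile(chosen, [25, 50, 75])
    return BandCrossing(times=chosen, median=float(q50),
                        iqr=float(q75 - q25), n=len(chosen), band=band)
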