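"""Broad-peak + Lorentz-peak model for 1D small-angle scattering curves.

The scattered intensity of a lipid nanoparticle with partially ordered
internal structure is described empirically as

    I(q) = A / q^n
         + C / (1 + (|q - q0| * xi)^m)
         + B / (1 + ((q - qB) / hwhm_B)^2)
         + bkg

i.e. a low-q Porod-like power law (prefactor A held at 1), a broad
correlation peak of amplitude C ("Lorentz scale"), correlation length xi and
position q0 that tracks the internal lattice, a narrow Lorentzian Bragg-like
peak near 0.1 A^-1 that flags a coexisting inverted-hexagonal phase, and a
flat incoherent background.

The broad-peak position is converted to a d-spacing (d = 2 pi / q0) and,
treating it as the lowest allowed Im3m reflection, to a bicontinuous-cubic
lattice parameter and water-channel diameter via minimal-surface geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import scipy.ndimage
import scipy.optimize
import scipy.signal

__all__ = [
    "SASCurve",
    "BroadPeakParams",
    "BroadPeakModel",
    "BroadPeakResults",
    "Im3mGeometry",
    "MINIMAL_SURFACE_CONSTANTS",
    "model_intensity",
    "fit_curve",
    "detect_hii_feature",
    "broadpeak_to_im3m_geometry",
    "read_sas_ascii",
    "write_sas_ascii",
]

#: (sigma0, euler_characteristic) of the underlying triply periodic minimal
#: surface, per cubic unit cell: P surface (Im3m), D surface (Pn3m),
#: G surface (Ia3d). sigma0 is the dimensionless surface area a^-2.
MINIMAL_SURFACE_CONSTANTS: dict[str, tuple[float, float]] = {
    "Im3m": (2.3451, -4.0),
    "Pn3m": (1.919, -2.0),
    "Ia3d": (3.091, -8.0),
}


@dataclass
class SASCurve:
    """1D reduced scattering curve: q (A^-1), intensity, optional uncertainty."""

    q: np.ndarray
    I: np.ndarray
    dI: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.I.shape:
            raise ValueError("q and I must be 1-D arrays of equal length")
        if not np.all(self.q > 0):
            raise ValueError("q must be strictly positive")
        if not np.all(np.diff(self.q) > 0):
            raise ValueError("q must be strictly increasing")
        if self.dI is not None:
            self.dI = np.asarray(self.dI, dtype=float)
            if self.dI.shape != self.q.shape:
                raise ValueError("dI must match q in length")
            if not np.all(self.dI > 0):
                raise ValueError("dI must be positive where provided")

    def __len__(self) -> int:
        return len(self.q)


@dataclass(frozen=True)
class BroadPeakParams:
    """Parameter vector of the combined broad-peak + Lorentz-peak model."""

    porod_scale: float = 1.0  # A, held fixed at 1 in fits
    porod_exp: float = 2.0  # n
    lorentz_scale: float = 250.0  # C, broad-peak amplitude
    cor_length: float = 50.0  # xi, A
    peak_pos: float = 0.088  # q0, A^-1
    lorentz_exp: float = 2.0  # m
    peak_scale_B: float = 25.0  # B, narrow Lorentz-peak amplitude
    peak_pos_B: float = 0.10  # A^-1
    peak_hwhm: float = 0.004  # A^-1
    background: float = 1.0

    def __post_init__(self) -> None:
        if self.cor_length <= 0:
            raise ValueError("cor_length must be positive")
        if self.peak_scale_B < 0:
            raise ValueError("peak_scale_B must be non-negative")
        if self.background < 0:
            raise ValueError("background must be non-negative")
        if self.peak_hwhm <= 0:
            raise ValueError("peak_hwhm must be positive")


def model_intensity(q: np.ndarray, params: BroadPeakParams) -> np.ndarray:
    """Evaluate the combined broad-peak + Lorentz-peak model at q (> 0)."""
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q must be positive (Porod term undefined at q <= 0)")
    p = params
    porod = p.porod_scale / q**p.porod_exp
    broad = p.lorentz_scale / (1.0 + (np.abs(q - p.peak_pos) * p.cor_length) ** p.lorentz_exp)
    narrow = p.peak_scale_B / (1.0 + ((q - p.peak_pos_B) / p.peak_hwhm) ** 2)
    return porod + broad + narrow + p.background


def detect_hii_feature(
    curve: SASCurve,
    window: tuple[float, float] = (0.08, 0.12),
    coverage: tuple[float, float] = (0.07, 0.13),
    noise_factor: float = 3.0,
    rel_floor: float = 0.005,
) -> bool:
    """Detect a narrow peak near 0.1 A^-1 signalling an H_II coexistence.

    The curve restricted to ``coverage`` is detrended with a quadratic
    Savitzky-Golay baseline whose ~0.015 A^-1 window follows the smooth
    Porod decay and the wide correlation peak (locally parabolic on that
    scale) but not a narrow Bragg-like peak; a local maximum of the residual
    inside ``window`` exceeding ``noise_factor`` times the local noise (plus
    a small relative floor) counts as a feature.
    """
    if curve.q[0] > coverage[0] or curve.q[-1] < coverage[1]:
        raise ValueError(f"data must cover {coverage} A^-1")
    sel = (curve.q >= coverage[0]) & (curve.q <= coverage[1])
    q = curve.q[sel]
    y = curve.I[sel]
    if len(q) < 9:
        raise ValueError("insufficient q coverage for feature detection")
    dq = np.median(np.diff(q))
    win = max(5, min(int(round(0.015 / dq)) | 1, (len(q) - 1) | 1))
    trend = scipy.signal.savgol_filter(y, win, 2)
    resid = y - trend
    inside = (q >= window[0]) & (q <= window[1])
    noise = 1.4826 * np.median(np.abs(resid[~inside])) if (~inside).any() else 0.0
    local_level = float(np.median(y[inside]))
    threshold = noise_factor * noise + rel_floor * local_level
    r_in = resid[inside]
    if len(r_in) < 3:
        return False
    peaks, _ = scipy.signal.find_peaks(r_in)
    return bool(len(peaks) and r_in[peaks].max() > threshold)


# ---------------------------------------------------------------------------
# fitting

_FREE_ALL = ("porod_exp", "lorentz_scale", "cor_length", "peak_pos",
             "lorentz_exp", "peak_scale_B", "peak_pos_B", "peak_hwhm",
             "background")
_FREE_NO_B = ("porod_exp", "lorentz_scale", "cor_length", "peak_pos",
              "lorentz_exp", "background")


@dataclass
class BroadPeakResults:
    """Fitted broad-peak model: parameters, uncertainties, diagnostics."""

    params: BroadPeakParams
    stderr: dict[str, float]
    redchi: float
    n_points: int
    n_free: int
    include_B_peak: bool

    @property
    def d_spacing(self) -> float:
        """Repeat distance d = 2 pi / q0 of the broad correlation peak, A."""
        return 2.0 * math.pi / self.params.peak_pos

    def geometry(self, monolayer_length: float = 17.0,
                 reflection_factor: float = math.sqrt(2.0)) -> "Im3mGeometry":
        """Im3m lattice parameter and water-channel diameter from q0."""
        return broadpeak_to_im3m_geometry(
            self.params.peak_pos, monolayer_length,
            reflection_factor=reflection_factor)

    def summary(self) -> str:
        lines = ["Broad-peak + Lorentz-peak fit",
                 "=" * 34,
                 f"{'n_points':<16}{self.n_points:>12d}",
                 f"{'n_free':<16}{self.n_free:>12d}",
                 f"{'red. chi-sq':<16}{self.redchi:>12.4g}",
                 f"{'d spacing (A)':<16}{self.d_spacing:>12.4g}",
                 "-" * 34]
        for name in _FREE_ALL:
            val = getattr(self.params, name)
            err = self.stderr.get(name, float("nan"))
            lines.append(f"{name:<16}{val:>12.5g} +/- {err:.3g}")
        return "\n".join(lines)

    def plot(self, curve: SASCurve, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.loglog(curve.q, curve.I, ".", ms=3, label="data")
        ax.loglog(curve.q, model_intensity(curve.q, self.params), "-",
                  label="fit")
        ax.axvline(self.params.peak_pos, ls=":", color="gray")
        ax.set_xlabel(r"q ($\mathrm{\AA}^{-1}$)")
        ax.set_ylabel("I (a.u.)")
        ax.legend()
        return ax


class BroadPeakModel:
    """Weighted least-squares model for a reduced SAS curve.

    Weights are 1/dI^2 when uncertainties are present, unity otherwise. The
    overall multiplier and the Porod prefactor are held at 1; the narrow
    0.1 A^-1 Lorentz peak is included only when requested or when
    :func:`detect_hii_feature` finds evidence for it.
    """

    def __init__(self, curve: SASCurve, include_B_peak: bool | None = None):
        if len(curve) < 30:
            raise ValueError("need at least 30 points to fit")
        self.curve = curve
        if include_B_peak is None:
            try:
                include_B_peak = detect_hii_feature(curve)
            except ValueError:
                include_B_peak = False
        self.include_B_peak = bool(include_B_peak)

    # -- initialisation -----------------------------------------------------
    def _heuristic_init(self, q0: float) -> BroadPeakParams:
        q, y = self.curve.q, self.curve.I
        bkg = max(float(np.min(y)) * 0.5, 1e-12)
        # Porod exponent from the first decade of q
        lo = q <= q[0] * 4
        if lo.sum() >= 3:
            slope = np.polyfit(np.log(q[lo]), np.log(np.clip(y[lo], 1e-300, None)), 1)[0]
            n = float(np.clip(-slope, 0.1, 5.5))
        else:
            n = 2.0
        i0 = float(np.interp(q0, q, y))
        c = max(i0 - 1.0 / q0**n - bkg, 1e-6)
        return BroadPeakParams(
            porod_exp=n, lorentz_scale=c, cor_length=2.0 / q0, peak_pos=q0,
            lorentz_exp=2.0, peak_scale_B=0.0 if not self.include_B_peak else c / 10,
            peak_pos_B=0.1, peak_hwhm=0.005, background=bkg)

    def _q0_from_data(self) -> float | None:
        """Data-driven broad-peak position: maximum of I(q) minus the
        power law anchored on the low-q end, after light smoothing."""
        q, y = self.curve.q, self.curve.I
        lo = q <= q[0] * 4
        if lo.sum() < 3:
            return None
        slope, icpt = np.polyfit(np.log(q[lo]),
                                 np.log(np.clip(y[lo], 1e-300, None)), 1)
        resid = y - np.exp(icpt) * q**slope
        k = max(5, (len(q) // 40) | 1)
        resid = scipy.ndimage.uniform_filter1d(resid, k)
        mid = (q > q[0] * 4) & (q < q[-1] * 0.8)
        if not mid.any():
            return None
        return float(q[mid][np.argmax(resid[mid])])

    def _pack(self, p: BroadPeakParams, names: Sequence[str]) -> np.ndarray:
        return np.array([getattr(p, n) for n in names])

    def _unpack(self, x: np.ndarray, names: Sequence[str],
                base: BroadPeakParams) -> BroadPeakParams:
        return replace(base, **dict(zip(names, x)))

    def _bounds(self, names: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        q = self.curve.q
        # the B peak is by construction a narrow Bragg-like feature around
        # 0.1 A^-1; keeping it narrow and near 0.1 prevents it from trading
        # roles with the broad correlation peak
        lo_hi = {
            "porod_exp": (0.0, 6.0),
            "lorentz_scale": (0.0, np.inf),
            "cor_length": (1e-3, np.inf),
            "peak_pos": (q[0], q[-1]),
            "lorentz_exp": (1.0, 4.0),
            "peak_scale_B": (0.0, np.inf),
            "peak_pos_B": (0.08, 0.12),
            "peak_hwhm": (1e-4, 0.01),
            "background": (0.0, np.inf),
        }
        lo = np.array([lo_hi[n][0] for n in names])
        hi = np.array([lo_hi[n][1] for n in names])
        return lo, hi

    # -- fit ----------------------------------------------------------------
    def fit(self, init: BroadPeakParams | None = None, n_starts: int = 5
            ) -> BroadPeakResults:
        """Fit with multi-start over q0 spread across the data range.

        Raises RuntimeError (carrying the best partial diagnostics) if no
        start converges.
        """
        curve = self.curve
        names = _FREE_ALL if self.include_B_peak else _FREE_NO_B
        weights = 1.0 / curve.dI if curve.dI is not None else np.ones(len(curve))

        q0_starts = list(np.geomspace(curve.q[0] * 2, curve.q[-1] / 2, n_starts))
        q0_data = self._q0_from_data()
        if q0_data is not None:
            q0_starts.insert(0, q0_data)
        inits = [self._heuristic_init(q0) for q0 in q0_starts]
        if init is not None:
            inits.insert(0, init if self.include_B_peak
                         else replace(init, peak_scale_B=0.0))

        lo, hi = self._bounds(names)
        best = None
        failures = []
        for start in inits:
            base = start if self.include_B_peak else replace(start, peak_scale_B=0.0)
            x0 = np.clip(self._pack(base, names), lo, hi)

            def resid(x):
                p = self._unpack(x, names, base)
                return (model_intensity(curve.q, p) - curve.I) * weights

            try:
                sol = scipy.optimize.least_squares(
                    resid, x0, bounds=(lo, hi), method="trf",
                    x_scale="jac", xtol=1e-12, ftol=1e-12, gtol=1e-12,
                    max_nfev=2000)
            except Exception as exc:  # numerical failure on this start
                failures.append(str(exc))
                continue
            if best is None or sol.cost < best.cost:
                best = sol
                best_base = base
        if best is None:
            raise RuntimeError(f"fit failed on all starts: {failures}")

        params = self._unpack(best.x, names, best_base)
        n_free = len(names)
        dof = max(len(curve) - n_free, 1)
        redchi = 2.0 * best.cost / dof
        stderr = self._stderr(best, names, dof)
        return BroadPeakResults(params=params, stderr=stderr, redchi=redchi,
                                n_points=len(curve), n_free=n_free,
                                include_B_peak=self.include_B_peak)

    @staticmethod
    def _stderr(sol, names: Sequence[str], dof: int) -> dict[str, float]:
        try:
            jtj = sol.jac.T @ sol.jac
            cov = np.linalg.pinv(jtj) * (2.0 * sol.cost / dof)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
            return {n: float(s) for n, s in zip(names, se)}
        except Exception:
            return {n: float("nan") for n in names}


def fit_curve(
    curve: SASCurve,
    init: BroadPeakParams | None = None,
    include_B_peak: bool | None = None,
    n_starts: int = 5,
) -> BroadPeakResults:
    """Convenience wrapper: build a :class:`BroadPeakModel` and fit it."""
    return BroadPeakModel(curve, include_B_peak=include_B_peak).fit(
        init=init, n_starts=n_starts)


# ---------------------------------------------------------------------------
# geometry

@dataclass(frozen=True)
class Im3mGeometry:
    """Bicontinuous-cubic geometry derived from a peak position."""

    d: float  # repeat spacing 2 pi / q0, A
    lattice_a: float  # cubic lattice parameter, A
    water_channel_diameter: float  # A
    reflection_factor: float  # a / d factor used (1 or sqrt(2))
    monolayer_length: float  # l, A
    degenerate: bool = False

    @property
    def water_channel_diameter_nm(self) -> float:
        return self.water_channel_diameter / 10.0

    @property
    def lattice_a_nm(self) -> float:
        return self.lattice_a / 10.0


def broadpeak_to_im3m_geometry(
    q0: float,
    monolayer_length: float = 17.0,
    reflection_factor: float = math.sqrt(2.0),
    phase: str = "Im3m",
    lattice_a: float | None = None,
) -> Im3mGeometry:
    """Water-channel diameter of a bicontinuous cubic phase from a peak at q0.

    d = 2 pi / q0; the lattice parameter is ``reflection_factor * d``
    (default sqrt(2), reading the broad peak as the lowest allowed Im3m
    reflection, the (110)); the aqueous-channel radius follows from
    minimal-surface geometry,

        r_w = sqrt(sigma0 / (-2 pi chi)) * a - l,

    with (sigma0, chi) from :data:`MINIMAL_SURFACE_CONSTANTS` and l the lipid
    monolayer length (A). For Im3m the prefactor is ~0.3055. Pass
    ``lattice_a`` to bypass the reflection-factor step (e.g. when a comes
    from Bragg indexing).
    """
    if q0 <= 0:
        raise ValueError("q0 must be positive")
    if monolayer_length <= 0:
        raise ValueError("monolayer length must be positive")
    if phase not in MINIMAL_SURFACE_CONSTANTS:
        raise ValueError(f"no minimal-surface constants for phase {phase!r}")
    sigma0, chi = MINIMAL_SURFACE_CONSTANTS[phase]
    d = 2.0 * math.pi / q0
    a = lattice_a if lattice_a is not None else reflection_factor * d
    prefactor = math.sqrt(sigma0 / (-2.0 * math.pi * chi))
    radius = prefactor * a - monolayer_length
    tol = 1e-9 * a
    if radius < -tol:
        raise ValueError(
            f"channel closed / l inconsistent: {prefactor:.4f}*a = "
            f"{prefactor * a:.2f} A <= l = {monolayer_length} A")
    degenerate = radius < tol
    return Im3mGeometry(
        d=d, lattice_a=a, water_channel_diameter=max(2.0 * radius, 0.0),
        reflection_factor=a / d, monolayer_length=monolayer_length,
        degenerate=degenerate)


# ---------------------------------------------------------------------------
# I/O: common reduced-SANS 3-column ASCII dialect

def read_sas_ascii(path) -> SASCurve:
    """Read a '#'-commented, whitespace-delimited q/I[/dI] ASCII file."""
    data = np.loadtxt(path, comments="#")
    data = np.atleast_2d(data)
    if data.shape[1] < 2:
        raise ValueError("expected at least 2 columns (q, I)")
    dI = data[:, 2] if data.shape[1] >= 3 else None
    return SASCurve(q=data[:, 0], I=data[:, 1], dI=dI)


def write_sas_ascii(curve: SASCurve, path, header: str = "") -> None:
    cols = [curve.q, curve.I] + ([curve.dI] if curve.dI is not None else [])
    names = "q I dI" if curve.dI is not None else "q I"
    head = (header + "\n" if header else "") + names
    np.savetxt(path, np.column_stack(cols), header=head, comments="# ")
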