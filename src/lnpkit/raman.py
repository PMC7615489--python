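"""Single-particle Raman preprocessing and ratiometric composition readout.

Implements the SPARTA-style standard analysis chain for spectra of optically
trapped lipid nanoparticles: truncation to the fingerprint window, instrument
response correction, cosmic-spike removal, Whittaker (asymmetric least
squares) baseline subtraction and Savitzky-Golay smoothing, followed by
parabolic sub-bin peak localisation and band-ratio extraction.

The composition readout is ratiometric: the choline band at 718 cm-1 reports
the DOPC (substrate) content of a particle and is normalised either to the
cholesterol band at 703 cm-1 or to the beta-CH band at 990 cm-1, which makes
the readout invariant to overall particle intensity and laser power.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.ndimage
import scipy.signal
import scipy.sparse
import scipy.sparse.linalg

from ._peaks import refine_peak

__all__ = [
    "RamanSpectrum",
    "PeakFeature",
    "BandRatio",
    "UnusableSpectrumError",
    "TRUNCATION_RANGE",
    "preprocess",
    "whittaker_asls_baseline",
    "locate_peak",
    "band_ratio",
    "population_summary",
    "feature_table",
]

#: fingerprint window retained after truncation, cm-1
TRUNCATION_RANGE = (340.0, 1825.0)

#: standard band-ratio pairs (numerator, denominator), cm-1
CHOLINE_TO_CHOLESTEROL = (718.0, 703.0)
CHOLINE_TO_BETA_CH = (718.0, 990.0)


class UnusableSpectrumError(ValueError):
    """Raised when a spectrum cannot yield a requested band ratio.

    Mirrors the population-level QC step in which spectra without a usable
    denominator band are excluded from further analysis.
    """


@dataclass
class RamanSpectrum:
    """One particle's Raman trace on a strictly increasing shift grid."""

    shift: np.ndarray  # Raman shift, cm-1
    intensity: np.ndarray  # counts (a.u. after preprocessing)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.shift = np.asarray(self.shift, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.shift.ndim != 1 or self.shift.shape != self.intensity.shape:
            raise ValueError("shift and intensity must be 1-D arrays of equal length")
        if not np.all(np.diff(self.shift) > 0):
            raise ValueError("shift grid must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")

    def __len__(self) -> int:
        return len(self.shift)


@dataclass(frozen=True)
class PeakFeature:
    """Sub-bin peak location from local parabolic fitting."""

    center: float  # cm-1
    height: float  # baseline-subtracted counts
    window: tuple[float, float]  # search interval used, cm-1


@dataclass(frozen=True)
class BandRatio:
    numerator_center: float
    denominator_center: float
    value: float


def whittaker_asls_baseline(
    y: np.ndarray, lam: float = 1e5, p: float = 0.001, n_iter: int = 10
) -> np.ndarray:
    """Asymmetric-least-squares baseline via the Whittaker smoother.

    Minimises ``sum(w_i (y_i - z_i)^2) + lam * sum((d2 z)_i^2)`` with the
    asymmetry reweighting ``w_i = p`` where the residual is positive (signal
    above baseline) and ``1 - p`` below, iterated ``n_iter`` times.

    Parameters
    ----------
    lam : second-difference penalty weight (default 100 000).
    p : asymmetry (default 0.001); small p lets the baseline hug the minima.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 points for a baseline")
    d = scipy.sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    penalty = lam * (d.T @ d)
    w = np.ones(n)
    z = y
    for _ in range(n_iter):
        wmat = scipy.sparse.diags(w)
        z = scipy.sparse.linalg.spsolve((wmat + penalty).tocsc(), w * y)
        w = np.where(y > z, p, 1.0 - p)
    return z


def _find_spikes(y: np.ndarray, mad_factor: float = 8.0, med_window: int = 9,
                 max_width: int = 2) -> np.ndarray:
    """Boolean mask of cosmic-spike bins.

    A spike is a run of at most ``max_width`` bins exceeding ``mad_factor``
    robust sigma above a rolling median.
    """
    med = scipy.ndimage.median_filter(y, size=med_window, mode="nearest")
    resid = y - med
    # noise scale from successive differences: the rolling-median residual
    # itself is exactly zero wherever the data are locally monotone (e.g. on
    # a sloped fluorescence baseline), so its MAD underestimates badly
    sigma = 1.4826 * np.median(np.abs(np.diff(y))) / np.sqrt(2.0)
    sigma = max(sigma, 1e-12 * max(1.0, float(np.max(np.abs(y)))))
    hot = resid > mad_factor * sigma
    # a spike's full support is narrow; a sharp Raman band can poke above
    # the 8-sigma level in a 1-2 bin sliver at its very top while remaining
    # above the noise over its whole width, so the width test is applied to
    # the 3-sigma support of the excursion, not the 8-sigma sliver
    support = resid > 3.0 * sigma
    mask = np.zeros(len(y), dtype=bool)
    i = 0
    while i < len(y):
        if support[i]:
            j = i
            while j < len(y) and support[j]:
                j += 1
            if j - i <= max_width and hot[i:j].any():
                mask[i:j] = True
            i = j
        else:
            i += 1
    return mask


def _interpolate_spikes(shift: np.ndarray, y: np.ndarray, mask: np.ndarray) -> np.ndarray:
    if not mask.any():
        return y
    out = y.copy()
    good = ~mask
    out[mask] = np.interp(shift[mask], shift[good], y[good])
    return out


def preprocess(
    raw: RamanSpectrum,
    response: np.ndarray | None = None,
    lam: float = 1e5,
    p: float = 0.001,
    sg_window: int = 7,
    sg_order: int = 2,
    n_iter: int = 10,
) -> RamanSpectrum:
    """Standard single-particle preprocessing chain.

    Order is fixed: truncate to 340-1825 cm-1, divide by the instrument
    response curve (if given, aligned with the *raw* grid), remove cosmic
    spikes, subtract the Whittaker asymmetric-least-squares baseline, and
    Savitzky-Golay smooth (defaults 7 points, second order).

    The returned spectrum's ``meta['spike_bins']`` records the indices (on
    the truncated grid) of spike-corrected bins.
    """
    lo, hi = TRUNCATION_RANGE
    if raw.shift[0] > lo or raw.shift[-1] < hi:
        raise ValueError(f"raw grid must cover {TRUNCATION_RANGE} cm-1")
    if sg_window % 2 != 1 or sg_window <= sg_order:
        raise ValueError("sg_window must be odd and greater than sg_order")

    keep = (raw.shift >= lo) & (raw.shift <= hi)
    shift = raw.shift[keep]
    y = raw.intensity[keep]

    if response is not None:
        response = np.asarray(response, dtype=float)
        if response.shape != raw.shift.shape:
            raise ValueError("response curve must be aligned with the raw grid")
        resp = response[keep]
        if np.any(resp == 0):
            raise ValueError("response curve has zeros on the grid")
        y = y / resp

    spikes = _find_spikes(y)
    y = _interpolate_spikes(shift, y, spikes)

    y = y - whittaker_asls_baseline(y, lam=lam, p=p, n_iter=n_iter)
    y = scipy.signal.savgol_filter(y, sg_window, sg_order)

    meta = dict(raw.meta)
    meta["spike_bins"] = np.flatnonzero(spikes).tolist()
    meta["preprocessed"] = True
    return RamanSpectrum(shift=shift, intensity=y, meta=meta)


def locate_peak(
    s: RamanSpectrum, nominal_center: float, half_window: float = 12.0
) -> PeakFeature:
    """Locate a band near ``nominal_center`` by local parabolic fitting.

    The maximum bin inside ``nominal_center +- half_window`` and its two
    neighbours define a parabola whose vertex gives the sub-bin centre and
    height; if the stencil has no downward curvature the bin value is
    returned unchanged.
    """
    lo = nominal_center - half_window
    hi = nominal_center + half_window
    if lo < s.shift[0] or hi > s.shift[-1]:
        raise ValueError(f"window [{lo}, {hi}] outside spectral grid")
    idx = np.flatnonzero((s.shift >= lo) & (s.shift <= hi))
    if len(idx) < 3:
        raise ValueError("window must contain at least 3 grid points")
    imax = idx[np.argmax(s.intensity[idx])]
    center, height = refine_peak(s.shift, s.intensity, imax)
    return PeakFeature(center=center, height=height, window=(lo, hi))


def band_ratio(
    s: RamanSpectrum,
    num: float,
    den: float,
    half_window: float = 2.0,
) -> BandRatio:
    """Ratio of baseline-subtracted parabolic peak heights.

    The numerator height is clipped at zero (absent bands read as 0); a
    non-positive denominator marks the spectrum unusable for this ratio and
    raises :class:`UnusableSpectrumError`. The default half-window (2 cm-1)
    is deliberately tight: it tolerates small nominal-centre error while
    still allowing sub-bin refinement, but keeps the search from riding up
    the partner band's flank in the closely spaced 703/718 cm-1 pair, which
    would otherwise make the ratio-composition relation nonlinear at low
    substrate content.
    """
    num_feat = locate_peak(s, num, half_window)
    den_feat = locate_peak(s, den, half_window)
    if den_feat.height <= 0:
        raise UnusableSpectrumError(
            f"denominator band at {den} cm-1 has non-positive height"
        )
    value = max(num_feat.height, 0.0) / den_feat.height
    return BandRatio(numerator_center=num, denominator_center=den, value=value)


def population_summary(
    spectra: Iterable[RamanSpectrum],
    num: float,
    den: float,
    half_window: float = 2.0,
) -> dict:
    """Median +- IQR of per-particle band ratios over a population.

    Spectra whose denominator band is unusable are excluded and counted in
    ``n_excluded``.
    """
    values = []
    n_excluded = 0
    for s in spectra:
        try:
            values.append(band_ratio(s, num, den, half_window).value)
        except UnusableSpectrumError:
            n_excluded += 1
    if not values:
        raise ValueError("no usable spectra in population")
    arr = np.asarray(values)
    q25, q50, q75 = np.percentile(arr, [25, 50, 75])
    return {
        "median": float(q50),
        "iqr": float(q75 - q25),
        "n": len(arr),
        "n_excluded": n_excluded,
        "values": arr,
    }


def feature_table(
    spectra: Sequence[RamanSpectrum],
    preprocess_kwargs: dict | None = None,
    already_preprocessed: bool = False,
) -> pd.DataFrame:
    """Per-particle feature table with the two standard band ratios.

    Columns: particle_id, time_min, ratio_718_703, ratio_718_990, qc_flag.
    Ratios that cannot be formed are NaN with a qc_flag naming the failure.
    """
    rows = []
    for i, raw in enumerate(spectra):
        s = raw if already_preprocessed else preprocess(raw, **(preprocess_kwargs or {}))
        row = {
            "particle_id": s.meta.get("particle_id", i),
            "time_min": s.meta.get("time_min", np.nan),
            "ratio_718_703": np.nan,
            "ratio_718_990": np.nan,
            "qc_flag": "",
        }
        flags = []
        for col, (num, den) in (
            ("ratio_718_703", CHOLINE_TO_CHOLESTEROL),
            ("ratio_718_990", CHOLINE_TO_BETA_CH),
        ):
            try:
                row[col] = band_ratio(s, num, den).value
            except UnusableSpectrumError:
                flags.append(f"no_denominator_{int(den)}")
        row["qc_flag"] = ";".join(flags)
        rows.append(row)
    return pd.DataFrame(rows)
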