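"""Bragg-peak detection and mesophase indexing of 1D SAXS patterns.

Lipid mesophases are identified by their characteristic reflection-spacing
ratios: for cubic phases the allowed reflections sit at q = 2 pi sqrt(N) / a
(Im3m: N = 2,4,6,8,10,12; Pn3m: 2,3,4,6,8,9; Ia3d: 6,8,14,16), the inverted
hexagonal phase at q1 * sqrt(M), M = 1,3,4,7 with q1 = 4 pi / (sqrt(3) a),
and the lamellar phase at integer multiples of 2 pi / d. Indexing is a
greedy multi-phase assignment so that coexisting phases (e.g. Im3m + H_II)
are resolved into separate assignments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.ndimage
import scipy.signal
import yaml

from ._peaks import refine_peak
from .sasfit import SASCurve, broadpeak_to_im3m_geometry, MINIMAL_SURFACE_CONSTANTS

__all__ = [
    "BraggPhase",
    "PhaseAssignment",
    "PHASES",
    "detect_bragg_peaks",
    "index_phases",
    "assignment_geometry",
    "load_phase_table",
]


@dataclass(frozen=True)
class BraggPhase:
    """A candidate mesophase: name, allowed sqrt(N) sequence, symmetry."""

    name: str
    n_allowed: tuple[int, ...]
    symmetry: str  # 'cubic' | 'hexagonal' | 'lamellar'

    def __post_init__(self) -> None:
        if self.symmetry not in ("cubic", "hexagonal", "lamellar"):
            raise ValueError(f"unknown symmetry {self.symmetry!r}")
        if any(b <= a for a, b in zip(self.n_allowed, self.n_allowed[1:])):
            raise ValueError("allowed N sequence must be strictly increasing")

    @property
    def sqrt_n(self) -> np.ndarray:
        return np.sqrt(np.asarray(self.n_allowed, dtype=float))

    @property
    def ratios(self) -> np.ndarray:
        """Reflection positions relative to the first allowed one."""
        s = self.sqrt_n
        return s / s[0]

    def peak_positions(self, lattice: float, n_reflections: int | None = None
                       ) -> np.ndarray:
        """Reflection positions (A^-1) for lattice parameter / d-spacing in A."""
        s = self.sqrt_n[: n_reflections or len(self.n_allowed)]
        if self.symmetry == "cubic":
            return 2.0 * math.pi * s / lattice
        if self.symmetry == "hexagonal":
            return 4.0 * math.pi / (math.sqrt(3.0) * lattice) * s
        return 2.0 * math.pi * s / lattice  # lamellar: lattice is d, s = 1,2,3

    def lattice_from_slope(self, slope: float) -> float:
        """Invert q = slope * sqrt(N) to the lattice parameter / d-spacing."""
        if self.symmetry == "cubic":
            return 2.0 * math.pi / slope
        if self.symmetry == "hexagonal":
            return 4.0 * math.pi / (math.sqrt(3.0) * slope)
        return 2.0 * math.pi / slope


PHASES: dict[str, BraggPhase] = {
    "Im3m": BraggPhase("Im3m", (2, 4, 6, 8, 10, 12), "cubic"),
    "Pn3m": BraggPhase("Pn3m", (2, 3, 4, 6, 8, 9), "cubic"),
    "Ia3d": BraggPhase("Ia3d", (6, 8, 14, 16), "cubic"),
    "H_II": BraggPhase("H_II", (1, 3, 4, 7), "hexagonal"),
    "lamellar": BraggPhase("lamellar", (1, 4, 9), "lamellar"),
}


def load_phase_table(path) -> dict[str, BraggPhase]:
    """Load a user-extensible candidate-phase table from YAML.

    Format::

        Im3m: {n: [2, 4, 6, 8, 10, 12], symmetry: cubic}
        my_phase: {n: [1, 2], symmetry: lamellar}
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {name: BraggPhase(name, tuple(spec["n"]), spec["symmetry"])
            for name, spec in raw.items()}


@dataclass
class PhaseAssignment:
    """An indexed mesophase with lattice parameter and matched reflections."""

    phase: BraggPhase
    lattice_a: float  # A (d-spacing for lamellar)
    matched_q: np.ndarray  # observed peak positions, A^-1
    matched_n: tuple[int, ...]  # allowed-N indices of the matches
    rms_residual: float  # rms relative residual of matched reflections
    n_matched: int
    tentative: bool = False

    def summary(self) -> str:
        kind = "d" if self.phase.symmetry == "lamellar" else "a"
        head = (f"{self.phase.name:<9} {kind} = {self.lattice_a:8.2f} A   "
                f"{self.n_matched} reflections, rms {self.rms_residual:.2e}"
                + ("  [tentative]" if self.tentative else ""))
        rows = [f"    N={n:<3d} q = {q:.5f} A^-1"
                for n, q in zip(self.matched_n, self.matched_q)]
        return "\n".join([head] + rows)


def detect_bragg_peaks(
    curve: SASCurve,
    min_prominence: float | None = None,
    noise_factor: float = 5.0,
) -> np.ndarray:
    """Sub-bin Bragg peak positions on the detrended curve.

    The smooth background is removed with a wide median filter; local maxima
    whose prominence exceeds ``min_prominence`` (default: ``noise_factor``
    times the robust noise of the detrended curve) are refined with the same
    3-point parabola used for Raman band localisation. An empty array is a
    valid result.
    """
    if len(curve) < 50:
        raise ValueError("need at least 50 points for peak detection")
    y = curve.I
    size = max(21, (len(y) // 25) | 1)
    trend = scipy.ndimage.median_filter(y, size=size, mode="nearest")
    resid = y - trend
    if min_prominence is None:
        sigma = 1.4826 * np.median(np.abs(resid - np.median(resid)))
        min_prominence = noise_factor * sigma + 1e-12 * max(abs(y).max(), 1.0)
    idx, _ = scipy.signal.find_peaks(resid, prominence=min_prominence)
    return np.array([refine_peak(curve.q, resid, i)[0] for i in idx])


def _match(peaks: np.ndarray, predicted: np.ndarray, rel_tol: float
           ) -> list[tuple[int, int, float]]:
    """Greedy nearest match of predicted reflections to unassigned peaks.

    Returns (peak_index, reflection_index, relative_residual) triples; each
    observed peak is used at most once.
    """
    used: set[int] = set()
    out = []
    for j, qp in enumerate(predicted):
        rel = np.abs(peaks - qp) / qp
        order = np.argsort(rel)
        for i in order:
            if rel[i] > rel_tol:
                break
            if i not in used:
                used.add(int(i))
                out.append((int(i), j, float(rel[i])))
                break
    return out


def index_phases(
    peaks: np.ndarray,
    candidates: dict[str, BraggPhase] | None = None,
    rel_tol: float = 0.01,
) -> list[PhaseAssignment]:
    """Greedy multi-phase indexing of a Bragg peak list.

    For each candidate phase and each choice of anchor peak as its first
    allowed reflection, the remaining reflections are predicted and matched
    within ``rel_tol``; assignments are scored lexicographically by
    (n_matched, -rms) and accepted greedily, removing matched peaks, until
    no candidate reaches the minimum evidence (2 matched reflections, or a
    single reflection for hexagonal/lamellar phases, then flagged
    tentative).
    """
    peaks = np.sort(np.asarray(peaks, dtype=float))
    if len(peaks) == 0:
        raise ValueError("need at least one detected peak")
    candidates = candidates or PHASES

    assignments: list[PhaseAssignment] = []
    remaining = peaks.copy()
    while len(remaining) > 0:
        best: PhaseAssignment | None = None
        best_score = (-1, 0.0)
        for phase in candidates.values():
            ratios = phase.ratios
            min_needed = 1 if phase.symmetry in ("hexagonal", "lamellar") else 2
            for anchor in remaining:
                matches = _match(remaining, anchor * ratios, rel_tol)
                if len(matches) < min_needed:
                    continue
                n_matched = len(matches)
                idx_p = [m[0] for m in matches]
                idx_r = [m[1] for m in matches]
                q_obs = remaining[idx_p]
                s = phase.sqrt_n[idx_r]
                slope = float(np.dot(s, q_obs) / np.dot(s, s))
                rel_resid = (q_obs - slope * s) / (slope * s)
                rms = float(np.sqrt(np.mean(rel_resid**2)))
                score = (n_matched, -rms)
                if score > best_score:
                    best_score = score
                    best = PhaseAssignment(
                        phase=phase,
                        lattice_a=phase.lattice_from_slope(slope),
                        matched_q=q_obs,
                        matched_n=tuple(int(phase.n_allowed[j]) for j in idx_r),
                        rms_residual=rms,
                        n_matched=n_matched,
                        tentative=False,
                    )
        if best is None:
            break
        if best.n_matched == 1:
            best.tentative = True
        assignments.append(best)
        keep = ~np.isin(remaining, best.matched_q)
        remaining = remaining[keep]
    return assignments


def assignment_geometry(
    assignment: PhaseAssignment, monolayer_length: float = 17.0
) -> dict:
    """Phase geometry report: water-channel diameter for cubic phases.

    Cubic assignments use the indexed lattice parameter directly (no
    reflection-factor step) with the phase's minimal-surface constants;
    hexagonal and lamellar assignments report lattice/d-spacing only.
    """
    if assignment.tentative:
        raise ValueError("geometry is not computed for tentative assignments")
    phase = assignment.phase
    out: dict = {"phase": phase.name, "symmetry": phase.symmetry}
    if phase.symmetry == "cubic":
        if phase.name not in MINIMAL_SURFACE_CONSTANTS:
            raise ValueError(f"no minimal-surface constants for {phase.name}")
        q_first = 2.0 * math.pi * phase.sqrt_n[0] / assignment.lattice_a
        geom = broadpeak_to_im3m_geometry(
            q_first, monolayer_length, phase=phase.name,
            lattice_a=assignment.lattice_a)
        out.update(
            lattice_a=assignment.lattice_a,
            lattice_a_nm=assignment.lattice_a / 10.0,
            water_channel_diameter=geom.water_channel_diameter,
            water_channel_diameter_nm=geom.water_channel_diameter_nm,
            monolayer_length=monolayer_length,
        )
    elif phase.symmetry == "hexagonal":
        d = assignment.lattice_a * math.sqrt(3.0) / 2.0
        out.update(lattice_a=assignment.lattice_a,
                   lattice_a_nm=assignment.lattice_a / 10.0,
                   d_spacing=d, d_spacing_nm=d / 10.0)
    else:
        out.update(d_spacing=assignment.lattice_a,
                   d_spacing_nm=assignment.lattice_a / 10.0)
    return out
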