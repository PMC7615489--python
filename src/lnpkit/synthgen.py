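"""Synthetic-data generation for every stage of the pipeline.

Generates, with known ground truth and full seed control:

* single-particle Raman spectra of monoolein/cholesterol/DOPC/DOPA
  nanoparticles (composition-dependent band amplitudes, fluorescence-like
  polynomial baselines, Gaussian noise, cosmic spikes),
* enzymatic time-courses in which each time point is a freshly trapped
  particle whose DOPC fraction decays as exp(-k t),
* 1D small-angle scattering curves from the broad-peak + Lorentz-peak
  forward model,
* Bragg patterns at the characteristic spacing ratios of lipid mesophases,
* saturating fluorescence-cascade traces whose plateau is proportional to
  the substrate amount.

Band weights are stylised (absolute Raman cross-sections per lipid are not
part of the model); they are calibrated only so band ratios vary
monotonically with composition, which is all the ratiometric readout uses.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .fluor import FluoCurve, cascade_model
from .raman import RamanSpectrum
from .sasfit import BroadPeakParams, SASCurve, model_intensity
from .saxsindex import PHASES, BraggPhase

__all__ = [
    "Formulation",
    "RamanPeakSpec",
    "AcquisitionModel",
    "ConversionScenario",
    "DEFAULT_BANDS",
    "gen_raman_spectrum",
    "gen_timecourse",
    "gen_sas_curve",
    "gen_bragg_pattern",
    "gen_fluor_curve",
    "write_spectrum_csv",
    "read_spectrum_csv",
    "write_manifest",
    "write_fluor_csv",
    "read_fluor_csv",
    "write_truth_json",
]

#: total phospholipid (DOPC + DOPA) mole fraction, conserved under conversion
PHOSPHOLIPID_TOTAL = 0.15


@dataclass(frozen=True)
class Formulation:
    """Mole fractions of the four lipid components (must sum to 1)."""

    mol_frac_MO: float
    mol_frac_CHOL: float
    mol_frac_DOPC: float
    mol_frac_DOPA: float

    def __post_init__(self) -> None:
        fracs = (self.mol_frac_MO, self.mol_frac_CHOL,
                 self.mol_frac_DOPC, self.mol_frac_DOPA)
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("mole fractions must lie in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("mole fractions must sum to 1")

    @classmethod
    def from_conversion(cls, x_converted: float) -> "Formulation":
        """MO:CHOL:DOPC:DOPA = 55:30:(15-X):X mol% control series."""
        dopa = x_converted / 100.0
        return cls(0.55, 0.30, PHOSPHOLIPID_TOTAL - dopa, dopa)

    def fraction(self, component: str) -> float:
        return getattr(self, f"mol_frac_{component}")


@dataclass(frozen=True)
class RamanPeakSpec:
    """One synthetic band: centre/FWHM (cm-1), weight per unit mole fraction."""

    center: float
    fwhm: float
    weight: float
    component: str  # 'MO' | 'CHOL' | 'DOPC' | 'DOPA'

    def __post_init__(self) -> None:
        if not (340.0 <= self.center <= 1825.0):
            raise ValueError("band centre must lie in the fingerprint window")
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.weight < 0:
            raise ValueError("weight must be non-negative")


#: stylised band table. 718 cm-1 choline reports DOPC; 703/548 cm-1 report
#: cholesterol; 990 cm-1 beta-CH reports DOPA (with a weak DOPC shoulder so
#: the 718/990 denominator stays usable at low conversion); 1445 cm-1
#: CH2/CH3 deformation is fed by every lipid; 1086/1302/1656 cm-1 are
#: monoolein backbone/C=C bands for realism.
DEFAULT_BANDS: tuple[RamanPeakSpec, ...] = (
    RamanPeakSpec(548.0, 10.0, 4.0, "CHOL"),
    RamanPeakSpec(703.0, 12.0, 6.0, "CHOL"),
    RamanPeakSpec(718.0, 12.0, 10.0, "DOPC"),
    RamanPeakSpec(990.0, 12.0, 6.0, "DOPA"),
    RamanPeakSpec(990.0, 12.0, 0.8, "DOPC"),
    RamanPeakSpec(1086.0, 14.0, 3.0, "MO"),
    RamanPeakSpec(1302.0, 20.0, 4.0, "MO"),
    RamanPeakSpec(1445.0, 18.0, 8.0, "MO"),
    RamanPeakSpec(1445.0, 18.0, 6.0, "CHOL"),
    RamanPeakSpec(1445.0, 18.0, 7.0, "DOPC"),
    RamanPeakSpec(1445.0, 18.0, 7.0, "DOPA"),
    RamanPeakSpec(1656.0, 16.0, 5.0, "MO"),
)


@dataclass(frozen=True)
class AcquisitionModel:
    """Acquisition grid, background, noise and spike statistics.

    ``baseline_coeffs`` are polynomial coefficients (constant first) of the
    slowly varying background, evaluated on the grid normalised to [0, 1];
    the default reaches roughly 10x the tallest lipid band. ``noise_sd`` is
    additive Gaussian noise in counts, ``spike_rate`` the expected number of
    cosmic spikes per spectrum and ``particle_scale_sd`` the sigma of the
    lognormal per-particle overall intensity factor.
    """

    grid_min: float = 320.0
    grid_max: float = 1840.0
    grid_step: float = 1.0
    baseline_coeffs: tuple[float, ...] = (70.0, -60.0, 25.0, -10.0)
    noise_sd: float = 0.02
    spike_rate: float = 0.05
    particle_scale_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.grid_min > 340.0 or self.grid_max < 1825.0:
            raise ValueError("grid must cover at least [340, 1825] cm-1")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if self.grid_step > 5.0:
            raise ValueError(
                "grid_step > 5 cm-1 cannot resolve the 703/718 cm-1 pair")
        if self.noise_sd < 0 or self.spike_rate < 0 or self.particle_scale_sd < 0:
            raise ValueError("noise_sd, spike_rate, particle_scale_sd must be >= 0")

    @property
    def grid(self) -> np.ndarray:
        n = int(math.floor((self.grid_max - self.grid_min) / self.grid_step)) + 1
        return self.grid_min + self.grid_step * np.arange(n)


@dataclass(frozen=True)
class ConversionScenario:
    """A single-particle enzymatic time-course design.

    One fresh particle is trapped per sampling time; the per-particle DOPC
    fraction follows 0.15 exp(-k t). ``enzyme_label`` is metadata only
    (nominal PLD activity, U/mL).
    """

    k: float  # first-order conversion rate, 1/min
    t_window: float = 30.0  # observation span, min
    n_particles: int = 60
    enzyme_label: float = 280.0

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be non-negative")
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if self.t_window <= 0:
            raise ValueError("t_window must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.linspace(0.0, self.t_window, self.n_particles)


def _pseudo_voigt(x: np.ndarray, center: float, fwhm: float,
                  eta: float = 0.5) -> np.ndarray:
    """Height-normalised pseudo-Voigt with fixed Gaussian fraction eta."""
    d2 = (x - center) ** 2
    gauss = np.exp(-4.0 * math.log(2.0) * d2 / fwhm**2)
    lorentz = 1.0 / (1.0 + 4.0 * d2 / fwhm**2)
    return eta * gauss + (1.0 - eta) * lorentz


def noiseless_raman_signal(
    formulation: Formulation,
    grid: np.ndarray,
    bands: Sequence[RamanPeakSpec] = DEFAULT_BANDS,
) -> np.ndarray:
    """Baseline-free, noise-free lipid signal on the given grid."""
    y = np.zeros_like(grid, dtype=float)
    for band in bands:
        amp = band.weight * formulation.fraction(band.component)
        if amp > 0:
            y += amp * _pseudo_voigt(grid, band.center, band.fwhm)
    return y


def gen_raman_spectrum(
    formulation: Formulation,
    acq: AcquisitionModel = AcquisitionModel(),
    seed: int = 0,
    bands: Sequence[RamanPeakSpec] = DEFAULT_BANDS,
) -> RamanSpectrum:
    """Forward-model one particle's raw spectrum.

    intensity = lognormal particle scale x sum of pseudo-Voigt bands
    (amplitude = weight x component mole fraction) + baseline polynomial
    + Gaussian noise + Poisson-count cosmic spikes. Bit-identical for
    identical seeds and inputs.
    """
    rng = np.random.default_rng(seed)
    grid = acq.grid
    scale = rng.lognormal(0.0, acq.particle_scale_sd) if acq.particle_scale_sd > 0 else 1.0
    y = scale * noiseless_raman_signal(formulation, grid, bands)

    u = (grid - grid[0]) / (grid[-1] - grid[0])
    baseline = np.zeros_like(grid)
    for k, c in enumerate(acq.baseline_coeffs):
        baseline += c * u**k
    y = y + baseline

    if acq.noise_sd > 0:
        y = y + rng.normal(0.0, acq.noise_sd, size=len(grid))

    n_spikes = rng.poisson(acq.spike_rate)
    spike_bins = []
    for _ in range(n_spikes):
        i = int(rng.integers(1, len(grid) - 1))
        amp = rng.lognormal(math.log(max(50.0 * acq.noise_sd, 1.0)), 0.5)
        y[i] += amp
        spike_bins.append(i)

    return RamanSpectrum(shift=grid, intensity=y,
                         meta={"formulation": asdict(formulation),
                               "true_spike_bins": spike_bins,
                               "particle_scale": float(scale)})


def gen_timecourse(
    scenario: ConversionScenario,
    acq: AcquisitionModel = AcquisitionModel(),
    seed: int = 0,
    bands: Sequence[RamanPeakSpec] = DEFAULT_BANDS,
) -> list[RamanSpectrum]:
    """One fresh particle per sampling time of an enzymatic conversion.

    At time t the particle's DOPC fraction is 0.15 exp(-k t) and DOPA is
    0.15 (1 - exp(-k t)); DOPC + DOPA is conserved at 0.15 throughout.
    Acquisition time (min) is recorded in each spectrum's metadata.
    """
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=scenario.n_particles)
    spectra = []
    for i, (t, s) in enumerate(zip(scenario.times, child_seeds)):
        remaining = PHOSPHOLIPID_TOTAL * math.exp(-scenario.k * t)
        form = Formulation(0.55, 0.30, remaining, PHOSPHOLIPID_TOTAL - remaining)
        spec = gen_raman_spectrum(form, acq, int(s), bands)
        spec.meta.update(particle_id=i, time_min=float(t),
                         enzyme_label=scenario.enzyme_label,
                         true_k=scenario.k)
        spectra.append(spec)
    return spectra


def gen_sas_curve(
    params: BroadPeakParams = BroadPeakParams(),
    q_grid: np.ndarray | None = None,
    rel_noise: float = 0.05,
    seed: int = 0,
) -> SASCurve:
    """Noisy scattering curve from the broad-peak forward model.

    Gaussian noise with sd = rel_noise * I(q); the dI column records the sd
    used (omitted entirely for rel_noise = 0, where the curve equals the
    forward model exactly).
    """
    if q_grid is None:
        q_grid = np.geomspace(0.005, 0.725, 200)
    q_grid = np.asarray(q_grid, dtype=float)
    if np.any(q_grid <= 0):
        raise ValueError("q grid must be strictly positive")
    if not np.all(np.diff(q_grid) > 0):
        raise ValueError("q grid must be strictly increasing")
    if rel_noise < 0:
        raise ValueError("rel_noise must be non-negative")
    intensity = model_intensity(q_grid, params)
    if rel_noise == 0:
        return SASCurve(q=q_grid, I=intensity, dI=None,
                        meta={"truth": asdict(params)})
    rng = np.random.default_rng(seed)
    sd = rel_noise * intensity
    noisy = intensity + rng.normal(0.0, 1.0, size=len(q_grid)) * sd
    return SASCurve(q=q_grid, I=noisy, dI=sd, meta={"truth": asdict(params)})


def gen_bragg_pattern(
    phase_name: str,
    lattice_a: float,
    n_reflections: int = 4,
    peak_fwhm: float = 0.004,
    seed: int = 0,
    q_grid: np.ndarray | None = None,
    amp0: float = 10.0,
    rel_noise: float = 0.0,
    background: float = 0.5,
) -> SASCurve:
    """Bragg pattern of a lipid mesophase: Gaussian peaks at 2 pi sqrt(N) / a.

    Amplitudes decay as 1/(1+j) with reflection order; a smooth q^-1
    background is added. Patterns for coexisting phases can be summed
    point-wise (same grid) before detection/indexing.
    """
    if phase_name not in PHASES:
        raise ValueError(f"unknown phase {phase_name!r}; known: {sorted(PHASES)}")
    if lattice_a <= 0:
        raise ValueError("lattice parameter must be positive")
    phase: BraggPhase = PHASES[phase_name]
    if q_grid is None:
        q_grid = np.linspace(0.01, 0.5, 2500)
    positions = phase.peak_positions(lattice_a, n_reflections)
    sigma = peak_fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    intensity = background * (1.0 + 0.02 / q_grid)
    for j, q0 in enumerate(positions):
        intensity += (amp0 / (1.0 + j)) * np.exp(-0.5 * ((q_grid - q0) / sigma) ** 2)
    if rel_noise > 0:
        rng = np.random.default_rng(seed)
        sd = rel_noise * intensity
        intensity = intensity + rng.normal(0.0, 1.0, size=len(q_grid)) * sd
        return SASCurve(q=q_grid, I=intensity, dI=sd,
                        meta={"phase": phase_name, "lattice_a": lattice_a})
    return SASCurve(q=q_grid, I=intensity,
                    meta={"phase": phase_name, "lattice_a": lattice_a})


def gen_fluor_curve(
    S0: float = 1.0,
    k_pld: float = 0.05,
    k_cascade: float = 0.5,
    noise_sd: float = 0.5,
    seed: int = 0,
    t: np.ndarray | None = None,
    fmax_per_substrate: float = 100.0,
) -> FluoCurve:
    """Fluorescence-cascade trace with plateau Fmax = c * S0.

    Defaults emulate a plate read every minute for 300 min with the PLD step
    rate-limiting (k_cascade = 10 x k_pld).
    """
    if t is None:
        t = np.arange(0.0, 301.0)
    t = np.asarray(t, dtype=float)
    fmax = fmax_per_substrate * S0
    intensity = cascade_model(t, fmax, k_pld, k_cascade)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sd, size=len(t))
    return FluoCurve(t=t, F=intensity,
                     meta={"substrate": S0, "k_pld": k_pld,
                           "k_cascade": k_cascade, "true_fmax": fmax})


# ---------------------------------------------------------------------------
# plain-text I/O

def write_spectrum_csv(spectrum: RamanSpectrum, path) -> None:
    """Two-column CSV: shift_cm1, intensity."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["shift_cm1", "intensity"])
        for s, i in zip(spectrum.shift, spectrum.intensity):
            writer.writerow([repr(float(s)), repr(float(i))])


def read_spectrum_csv(path, meta: dict | None = None) -> RamanSpectrum:
    data = np.genfromtxt(path, delimiter=",", skip_header=1)
    return RamanSpectrum(shift=data[:, 0], intensity=data[:, 1],
                         meta=dict(meta or {}))


def write_manifest(spectra: Sequence[RamanSpectrum], paths: Sequence[str],
                   manifest_path) -> None:
    """Manifest CSV linking spectra files to particles and times."""
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["particle_id", "time_min", "path"])
        for spec, p in zip(spectra, paths):
            writer.writerow([spec.meta.get("particle_id", ""),
                             spec.meta.get("time_min", ""), p])


def write_fluor_csv(curve: FluoCurve, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_min", "fluorescence_au"])
        for t, f in zip(curve.t, curve.F):
            writer.writerow([repr(float(t)), repr(float(f))])


def read_fluor_csv(path, meta: dict | None = None) -> FluoCurve:
    data = np.genfromtxt(path, delimiter=",", skip_header=1)
    return FluoCurve(t=data[:, 0], F=data[:, 1], meta=dict(meta or {}))


def write_truth_json(truth: dict, path) -> None:
    """Ground-truth parameters emitted alongside generated data."""
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True))
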