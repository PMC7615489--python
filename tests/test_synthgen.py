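import math

import numpy as np
import pytest
import scipy.signal
from hypothesis import given, settings, strategies as st

from lnpkit import synthgen as sg
from lnpkit.fluor import cascade_model
from lnpkit.sasfit import BroadPeakParams, model_intensity


class TestFormulation:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            sg.Formulation(0.5, 0.3, 0.1, 0.05)

    def test_fractions_must_be_in_unit_interval(self):
        with pytest.raises(ValueError):
            sg.Formulation(1.2, -0.2, 0.0, 0.0)

    @pytest.mark.parametrize("x", [0.0, 5.0, 7.5, 15.0])
    def test_conversion_series_conserves_phospholipid(self, x):
        f = sg.Formulation.from_conversion(x)
        assert f.mol_frac_DOPC + f.mol_frac_DOPA == pytest.approx(0.15)


class TestRamanGenerator:
    def test_local_maxima_at_band_centers(self, full_substrate, noiseless_acq):
        sig = sg.noiseless_raman_signal(full_substrate, noiseless_acq.grid)
        peaks = noiseless_acq.grid[scipy.signal.find_peaks(sig)[0]]
        for center in (548.0, 703.0, 718.0, 990.0, 1445.0):
            assert np.min(np.abs(peaks - center)) < 1.0

    def test_zero_dopc_gives_only_overlap_at_718(self, zero_substrate, noiseless_acq):
        sig = sg.noiseless_raman_signal(zero_substrate, noiseless_acq.grid)
        i718 = np.searchsorted(noiseless_acq.grid, 718.0)
        # remaining intensity at 718 comes from neighbouring-band tails only
        neighbours = [b for b in sg.DEFAULT_BANDS
                      if zero_substrate.fraction(b.component) > 0]
        assert sig[i718] < 0.2
        assert all(abs(b.center - 718.0) > 10 for b in neighbours)

    def test_determinism_bit_identical(self, full_substrate, default_acq):
        a = sg.gen_raman_spectrum(full_substrate, default_acq, seed=123)
        b = sg.gen_raman_spectrum(full_substrate, default_acq, seed=123)
        assert np.array_equal(a.intensity, b.intensity)
        assert np.array_equal(a.shift, b.shift)

    def test_different_seeds_differ(self, full_substrate, default_acq):
        a = sg.gen_raman_spectrum(full_substrate, default_acq, seed=1)
        b = sg.gen_raman_spectrum(full_substrate, default_acq, seed=2)
        assert not np.array_equal(a.intensity, b.intensity)

    def test_coarse_grid_rejected(self):
        with pytest.raises(ValueError, match="703/718"):
            sg.AcquisitionModel(grid_step=6.0)

    def test_weight_scaling_preserves_ratios(self, full_substrate, noiseless_acq):
        grid = noiseless_acq.grid
        base = sg.noiseless_raman_signal(full_substrate, grid)
        scaled_bands = tuple(
            sg.RamanPeakSpec(b.center, b.fwhm, 3.0 * b.weight, b.component)
            for b in sg.DEFAULT_BANDS)
        scaled = sg.noiseless_raman_signal(full_substrate, grid, scaled_bands)
        assert np.allclose(scaled, 3.0 * base, rtol=1e-12)


class TestTimecourse:
    def test_zero_rate_keeps_full_substrate(self, noiseless_acq):
        scen = sg.ConversionScenario(k=0.0, t_window=30.0, n_particles=5)
        specs = sg.gen_timecourse(scen, noiseless_acq, seed=0)
        for s in specs:
            assert s.meta["formulation"]["mol_frac_DOPC"] == pytest.approx(0.15)

    def test_half_conversion_at_half_life(self, noiseless_acq):
        k = 0.0693  # ln2 / 10 min
        scen = sg.ConversionScenario(k=k, t_window=10.0, n_particles=2)
        specs = sg.gen_timecourse(scen, noiseless_acq, seed=0)
        last = specs[-1]
        assert last.meta["time_min"] == pytest.approx(10.0)
        assert last.meta["formulation"]["mol_frac_DOPC"] == pytest.approx(
            0.075, rel=1e-3)

    def test_phospholipid_conserved_at_every_time(self, default_acq):
        scen = sg.ConversionScenario(k=0.2, t_window=30.0, n_particles=20)
        specs = sg.gen_timecourse(scen, default_acq, seed=3)
        for s in specs:
            f = s.meta["formulation"]
            assert f["mol_frac_DOPC"] + f["mol_frac_DOPA"] == pytest.approx(0.15)


class TestSASGenerator:
    def test_noiseless_equals_forward_model(self):
        params = BroadPeakParams()
        curve = sg.gen_sas_curve(params, rel_noise=0.0)
        assert np.array_equal(curve.I, model_intensity(curve.q, params))
        assert curve.dI is None

    def test_noise_sd_recorded_in_dI(self):
        curve = sg.gen_sas_curve(rel_noise=0.05, seed=0)
        truth = model_intensity(curve.q, BroadPeakParams())
        assert np.allclose(curve.dI, 0.05 * truth)

    def test_nonpositive_q_rejected(self):
        with pytest.raises(ValueError):
            sg.gen_sas_curve(q_grid=np.array([-0.01, 0.1, 0.2]))

    def test_no_narrow_peak_when_B_zero(self):
        params = BroadPeakParams(peak_scale_B=0.0)
        curve = sg.gen_sas_curve(params, rel_noise=0.0)
        sel = (curve.q > 0.095) & (curve.q < 0.105)
        # intensity strictly decreasing through 0.1 when no Bragg-like term
        assert np.all(np.diff(curve.I[sel]) < 0)


class TestBraggGenerator:
    def test_im3m_peak_positions(self):
        # q = 2 pi sqrt(N) / a for N = 2, 4, 6 at a = 100 A
        curve = sg.gen_bragg_pattern("Im3m", 100.0, n_reflections=3)
        for expected in (0.0889, 0.1257, 0.1539):
            i = np.argmin(np.abs(curve.q - expected))
            window = curve.I[max(i - 8, 0): i + 8]
            assert curve.I[i] > 2.0 * np.median(curve.I)
            assert window.max() == window[np.argmax(window)]

    def test_lamellar_integer_multiples(self):
        d = 60.0
        curve = sg.gen_bragg_pattern("lamellar", d, n_reflections=3)
        q1 = 2 * math.pi / d
        peaks, _ = scipy.signal.find_peaks(curve.I, prominence=1.0)
        found = curve.q[peaks]
        for mult in (1, 2, 3):
            assert np.min(np.abs(found - mult * q1)) < 5e-4

    def test_unknown_phase_rejected(self):
        with pytest.raises(ValueError, match="unknown phase"):
            sg.gen_bragg_pattern("Fd3m", 100.0)


class TestFluorGenerator:
    def test_plateau_equals_c_times_s0(self):
        t = np.array([0.0, 5000.0])
        curve = sg.gen_fluor_curve(S0=2.0, noise_sd=0.0, t=t)
        assert curve.F[-1] == pytest.approx(200.0, rel=1e-6)

    def test_plateau_linear_in_s0(self):
        t = np.linspace(0, 2000.0, 50)
        f1 = sg.gen_fluor_curve(S0=1.0, noise_sd=0.0, t=t).F
        f2 = sg.gen_fluor_curve(S0=2.0, noise_sd=0.0, t=t).F
        assert np.allclose(f2, 2.0 * f1, rtol=1e-12)

    def test_fast_cascade_limit_single_exponential(self):
        # k_cascade / k_pld = 100: within 1% of Fmax (1 - exp(-k_pld t))
        t = np.linspace(0.0, 120.0, 400)
        k1 = 0.05
        F = cascade_model(t, 1.0, k1, 100 * k1)
        single = 1.0 - np.exp(-k1 * t)
        assert np.max(np.abs(F - single)) < 0.01

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            sg.gen_fluor_curve(t=np.array([-1.0, 0.0, 1.0]))

    def test_equal_rates_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            sg.gen_fluor_curve(k_pld=0.1, k_cascade=0.1)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(seed=st.integers(min_value=0, max_value=2**31 - 1))
def test_every_generator_is_deterministic(seed):
    acq = sg.AcquisitionModel()
    f = sg.Formulation.from_conversion(5.0)
    a = sg.gen_raman_spectrum(f, acq, seed)
    b = sg.gen_raman_spectrum(f, acq, seed)
    assert np.array_equal(a.intensity, b.intensity)
    c1 = sg.gen_sas_curve(rel_noise=0.05, seed=seed)
    c2 = sg.gen_sas_curve(rel_noise=0.05, seed=seed)
    assert np.array_equal(c1.I, c2.I)
    f1 = sg.gen_fluor_curve(seed=seed)
    f2 = sg.gen_fluor_curve(seed=seed)
    assert np.array_equal(f1.F, f2.F)


class TestTextIO:
    def test_spectrum_csv_roundtrip(self, tmp_path, full_substrate, default_acq):
        spec = sg.gen_raman_spectrum(full_substrate, default_acq, seed=5)
        path = tmp_path / "spec.csv"
        sg.write_spectrum_csv(spec, path)
        back = sg.read_spectrum_csv(path)
        assert np.array_equal(back.shift, spec.shift)
        assert np.array_equal(back.intensity, spec.intensity)

    def test_fluor_csv_roundtrip(self, tmp_path):
        curve = sg.gen_fluor_curve(seed=1)
        path = tmp_path / "trace.csv"
        sg.write_fluor_csv(curve, path)
        back = sg.read_fluor_csv(path)
        assert np.array_equal(back.t, curve.t)
        assert np.array_equal(back.F, curve.F)
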