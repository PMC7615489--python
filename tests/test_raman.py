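import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lnpkit import raman, synthgen as sg
from lnpkit._peaks import parabolic_vertex


def _pv(x, c, w):
    d2 = (x - c) ** 2
    return 0.5 * np.exp(-4 * np.log(2) * d2 / w**2) + 0.5 / (1 + 4 * d2 / w**2)


class TestParabolicVertex:
    def test_symmetric_triple(self):
        c, h = parabolic_vertex(np.array([717.0, 718.0, 719.0]),
                                np.array([9.0, 10.0, 9.0]))
        assert c == pytest.approx(718.0)
        assert h == pytest.approx(10.0)

    def test_asymmetric_triple(self):
        # vertex offset = (y- - y+) / (2 (y- - 2 y0 + y+)) of the exact
        # quadratic through the stencil: (4, 10, 8) -> +0.25 bins
        c, h = parabolic_vertex(np.array([717.0, 718.0, 719.0]),
                                np.array([4.0, 10.0, 8.0]))
        assert c == pytest.approx(718.25)
        assert h == pytest.approx(10.25)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(y0=st.floats(1.0, 100.0), d1=st.floats(0.01, 50.0),
           d2=st.floats(0.01, 50.0))
    def test_matches_dense_quadratic_oracle(self, y0, d1, d2):
        """The closed-form vertex equals a brute-force dense quadratic fit."""
        x = np.array([0.0, 1.0, 2.0])
        y = np.array([y0 - d1, y0, y0 - d2])
        coeffs = np.polyfit(x, y, 2)
        grid = np.linspace(0.0, 2.0, 20001)
        dense = np.polyval(coeffs, grid)
        c, h = parabolic_vertex(x, y)
        i = np.argmax(dense)
        assert c == pytest.approx(grid[i], abs=1e-4)
        assert h == pytest.approx(dense[i], abs=1e-6)


class TestPreprocess:
    def test_flat_spectrum_maps_to_zero(self, noiseless_acq):
        g = noiseless_acq.grid
        out = raman.preprocess(raman.RamanSpectrum(g, np.full(len(g), 7.0)))
        assert np.max(np.abs(out.intensity)) < 1e-5

    def test_truncation_window(self, full_substrate, default_acq):
        out = raman.preprocess(sg.gen_raman_spectrum(full_substrate, default_acq, 0))
        assert out.shift[0] >= 340.0 and out.shift[-1] <= 1825.0

    def test_grid_not_covering_window_rejected(self):
        x = np.arange(400.0, 1800.0)
        with pytest.raises(ValueError, match="cover"):
            raman.preprocess(raman.RamanSpectrum(x, np.zeros(len(x))))

    def test_response_with_zeros_rejected(self, full_substrate, noiseless_acq):
        spec = sg.gen_raman_spectrum(full_substrate, noiseless_acq, 0)
        resp = np.ones(len(spec))
        resp[100] = 0.0
        with pytest.raises(ValueError, match="zeros"):
            raman.preprocess(spec, response=resp)

    def test_baseline_ten_times_peak_recovered(self, full_substrate):
        """718 cm-1 height within 5% of the baseline-free noiseless truth."""
        acq = sg.AcquisitionModel(noise_sd=0.0, spike_rate=0.0,
                                  particle_scale_sd=0.0)
        raw = sg.gen_raman_spectrum(full_substrate, acq, seed=1)
        grid = acq.grid
        keep = (grid >= 340) & (grid <= 1825)
        truth_spec = raman.RamanSpectrum(
            grid[keep], sg.noiseless_raman_signal(full_substrate, grid)[keep])
        h_true = raman.locate_peak(truth_spec, 718.0).height
        # baseline reaches ~10x the tallest band by construction
        assert max(acq.baseline_coeffs) >= 9 * truth_spec.intensity.max()
        h_rec = raman.locate_peak(raman.preprocess(raw), 718.0).height
        assert h_rec == pytest.approx(h_true, rel=0.05)

    def test_injected_spike_flagged_and_removed(self, full_substrate):
        acq = sg.AcquisitionModel(noise_sd=0.02, spike_rate=0.0,
                                  particle_scale_sd=0.0)
        raw = sg.gen_raman_spectrum(full_substrate, acq, seed=3)
        y = raw.intensity.copy()
        i = np.searchsorted(raw.shift, 900.0)
        y[i] += 50 * acq.noise_sd
        clean = raman.preprocess(raw)
        spiked = raman.preprocess(raman.RamanSpectrum(raw.shift, y, dict(raw.meta)))
        i_trunc = i - np.searchsorted(raw.shift, 340.0)
        assert i_trunc in spiked.meta["spike_bins"]
        # output within the noise of the spike-free run
        assert np.max(np.abs(clean.intensity - spiked.intensity)) < acq.noise_sd

    def test_idempotence_on_preprocessed_spectrum(self, full_substrate,
                                                  noiseless_acq):
        """A second pass changes standard band heights by less than 1%."""
        p1 = raman.preprocess(sg.gen_raman_spectrum(full_substrate,
                                                    noiseless_acq, 1))
        p2 = raman.preprocess(raman.RamanSpectrum(p1.shift, p1.intensity))
        for center in (703.0, 718.0, 1445.0):
            h1 = raman.locate_peak(p1, center).height
            h2 = raman.locate_peak(p2, center).height
            assert abs(h2 - h1) / h1 < 0.01


class TestLocatePeak:
    def test_sub_bin_center_of_offgrid_lorentzian(self):
        x = np.arange(320.0, 1841.0)
        s = raman.RamanSpectrum(x, 2.0 / (1 + 4 * (x - 718.4) ** 2 / 100.0))
        feat = raman.locate_peak(s, 718.0)
        assert feat.center == pytest.approx(718.4, abs=0.1)

    def test_window_outside_grid_errors(self):
        x = np.arange(340.0, 1826.0)
        s = raman.RamanSpectrum(x, np.zeros(len(x)))
        with pytest.raises(ValueError, match="outside"):
            raman.locate_peak(s, 350.0, half_window=20.0)

    def test_center_stays_inside_window_on_flank(self, zero_substrate,
                                                 noiseless_acq):
        # with no 718 band, the window maximum is a flank bin; the feature
        # must not extrapolate outside the search window
        spec = raman.preprocess(
            sg.gen_raman_spectrum(zero_substrate, noiseless_acq, 1))
        feat = raman.locate_peak(spec, 718.0, half_window=5.0)
        assert feat.window[0] <= feat.center <= feat.window[1]


class TestBandRatio:
    def test_scale_invariance(self, full_substrate, noiseless_acq):
        spec = raman.preprocess(
            sg.gen_raman_spectrum(full_substrate, noiseless_acq, 1))
        r1 = raman.band_ratio(spec, 718.0, 703.0).value
        scaled = raman.RamanSpectrum(spec.shift, spec.intensity * 3.7)
        r2 = raman.band_ratio(scaled, 718.0, 703.0).value
        assert r2 == pytest.approx(r1, rel=1e-12)

    def test_response_division_by_constant_preserves_ratio(
            self, full_substrate, noiseless_acq):
        raw = sg.gen_raman_spectrum(full_substrate, noiseless_acq, 1)
        r1 = raman.band_ratio(raman.preprocess(raw), 718.0, 703.0).value
        resp = np.full(len(raw), 2.5)
        r2 = raman.band_ratio(raman.preprocess(raw, response=resp),
                              718.0, 703.0).value
        assert r2 == pytest.approx(r1, rel=1e-9)

    def test_zero_dopc_ratio_below_full_dopc(self, noiseless_acq):
        specs = {}
        for x in (0.0, 15.0):
            raw = sg.gen_raman_spectrum(sg.Formulation.from_conversion(x),
                                        noiseless_acq, 1)
            specs[x] = raman.band_ratio(raman.preprocess(raw),
                                        718.0, 703.0).value
        assert 0 <= specs[15.0] < specs[0.0]

    def test_monotone_in_dopc_fraction(self, noiseless_acq):
        """Noiseless 718/703 ratio strictly increases with DOPC content."""
        ratios = []
        for x in (15.0, 10.0, 7.5, 5.0, 0.0):  # increasing DOPC
            raw = sg.gen_raman_spectrum(sg.Formulation.from_conversion(x),
                                        noiseless_acq, 1)
            ratios.append(raman.band_ratio(raman.preprocess(raw),
                                           718.0, 703.0).value)
        assert all(b > a for a, b in zip(ratios, ratios[1:]))

    def test_unusable_denominator_raises(self):
        x = np.arange(340.0, 1826.0)
        s = raman.RamanSpectrum(x, -0.01 * np.ones(len(x)) * _pv(x, 703.0, 10))
        with pytest.raises(raman.UnusableSpectrumError):
            raman.band_ratio(s, 718.0, 703.0)


class TestPopulationSummary:
    def test_identical_spectra_have_zero_iqr(self, full_substrate, noiseless_acq):
        spec = raman.preprocess(
            sg.gen_raman_spectrum(full_substrate, noiseless_acq, 1))
        out = raman.population_summary([spec] * 10, 718.0, 703.0)
        assert out["iqr"] == 0.0
        assert out["n"] == 10

    def test_single_spectrum_degenerate(self, full_substrate, noiseless_acq):
        spec = raman.preprocess(
            sg.gen_raman_spectrum(full_substrate, noiseless_acq, 1))
        out = raman.population_summary([spec], 718.0, 703.0)
        assert out["n"] == 1 and out["iqr"] == 0.0

    def test_median_stable_under_lognormal_scatter(self, full_substrate):
        """Ratio median insensitive to per-particle intensity scatter."""
        acq = sg.AcquisitionModel(noise_sd=0.0, spike_rate=0.0,
                                  particle_scale_sd=0.3)
        rng = np.random.default_rng(0)
        specs = [raman.preprocess(
            sg.gen_raman_spectrum(full_substrate, acq, int(s)))
            for s in rng.integers(0, 2**31 - 1, 60)]
        out = raman.population_summary(specs, 718.0, 703.0)
        noiseless = raman.preprocess(sg.gen_raman_spectrum(
            full_substrate, sg.AcquisitionModel(noise_sd=0.0, spike_rate=0.0,
                                                particle_scale_sd=0.0), 1))
        ref = raman.band_ratio(noiseless, 718.0, 703.0).value
        assert out["median"] == pytest.approx(ref, rel=0.02)

    def test_empty_population_errors(self):
        with pytest.raises(ValueError):
            raman.population_summary([], 718.0, 703.0)


def test_feature_table_columns(full_substrate, default_acq):
    specs = sg.gen_timecourse(sg.ConversionScenario(k=0.1, n_particles=5),
                              default_acq, seed=0)
    table = raman.feature_table(specs)
    assert list(table.columns) == ["particle_id", "time_min", "ratio_718_703",
                                   "ratio_718_990", "qc_flag"]
    assert len(table) == 5
    assert table["ratio_718_703"].notna().all()
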