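import numpy as np
import pytest

from lnpkit import synthgen as sg


@pytest.fixture(scope="session")
def noiseless_acq() -> sg.AcquisitionModel:
    """Acquisition with no noise, no spikes, no particle-to-particle scatter."""
    return sg.AcquisitionModel(noise_sd=0.0, spike_rate=0.0, particle_scale_sd=0.0)


@pytest.fixture(scope="session")
def default_acq() -> sg.AcquisitionModel:
    return sg.AcquisitionModel()


@pytest.fixture(scope="session")
def full_substrate() -> sg.Formulation:
    """MO:CHOL:DOPC:DOPA = 55:30:15:0 mol% (all substrate)."""
    return sg.Formulation.from_conversion(0.0)


@pytest.fixture(scope="session")
def zero_substrate() -> sg.Formulation:
    """MO:CHOL:DOPC:DOPA = 55:30:0:15 mol% (fully converted)."""
    return sg.Formulation.from_conversion(15.0)


def median_ratio(formulation, acq, n, seed, num=718.0, den=703.0):
    """Median preprocessed band ratio over a population of particles."""
    from lnpkit import raman

    rng = np.random.default_rng(seed)
    vals = [
        raman.band_ratio(
            raman.preprocess(sg.gen_raman_spectrum(formulation, acq, int(s))),
            num, den).value
        for s in rng.integers(0, 2**31 - 1, n)
    ]
    return float(np.median(vals))
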