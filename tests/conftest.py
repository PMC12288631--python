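import numpy as np
import pytest

from mcmrs.basis import load_default_basis
from mcmrs.config import brain_config
from mcmrs.preproc import fit_water_shot, reject_shots
from mcmrs.synthgen import GroundTruth, simulate_subject


@pytest.fixture(scope="session")
def basis():
    return load_default_basis()


@pytest.fixture(scope="session")
def brain_acq():
    return brain_config()


@pytest.fixture(scope="session")
def default_conc(basis):
    return {n: m.default_conc_mm for n, m in basis.metabolites.items()}


def make_truth(default_conc, **kwargs):
    base = dict(concentrations=dict(default_conc))
    base.update(kwargs)
    return GroundTruth(**base)


@pytest.fixture(scope="session")
def noisy_subject(brain_acq, default_conc, basis):
    """One simulated brain subject at the standard noise level, no corruption."""
    truth = GroundTruth(
        concentrations=dict(default_conc),
        noise_sd=25.0,
        gauss_lw=3.4,
        frequency_offset=2.0,
        zero_order_phase=15.0,
        water_echo_noise_frac=0.005,
    )
    transients, water = simulate_subject(truth, brain_acq, seed=11, basis=basis)
    return truth, transients, water


@pytest.fixture(scope="session")
def noisy_subject_fits(noisy_subject, brain_acq):
    _, transients, _ = noisy_subject
    fits = [fit_water_shot(t, brain_acq) for t in transients]
    kept, excluded, reasons = reject_shots(fits)
    return fits, kept, excluded, reasons
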