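from dataclasses import replace

import numpy as np
import pytest

import praakit as pk


@pytest.fixture(scope="session")
def quiet_params():
    """Default simulation parameters with read noise switched off."""
    return pk.SimulationParams(noise_sd=0.0)


@pytest.fixture(scope="session")
def control_curve(quiet_params):
    """Noise-free control well under the calibrated defaults (0-70 min)."""
    return pk.simulate_well(quiet_params, 0.0)


@pytest.fixture(scope="session")
def strong_scavenger_params(quiet_params):
    """Fast stoichiometric scavenger: k_ah >> k_abts, n = 2."""
    return replace(quiet_params, k_ah=quiet_params.k_abts * 1e4, n_stoich=2.0)


@pytest.fixture
def linear_curve():
    """Exactly linear ramp 0.06 -> 0.60 OD over 0-70 min, 1-min sampling."""
    t = np.arange(0.0, 71.0)
    return pk.KineticCurve("A1", t, 0.06 + (0.54 / 70.0) * t)


@pytest.fixture
def settings():
    return pk.ReductionSettings()
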