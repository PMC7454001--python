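import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import wismux as wm

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def flat_5k():
    """Purely resistive 5 kOhm interface (white thermal noise)."""
    return wm.ImpedanceSpectrum.from_resistance(5e3)


@pytest.fixture(scope="session")
def pbs_spectrum():
    return wm.pbs_interface().spectrum()


@pytest.fixture(scope="session")
def implanted_spectrum():
    return wm.implanted_interface().spectrum()


@pytest.fixture()
def quiet_electrode(flat_5k):
    return wm.ElectrodeState(1, flat_5k, v_offset=0.0, drift_rate=0.0,
                             temperature=295.0)


def single_electrode_mux(n_ave=1, n_tot=20, **kw):
    seq = wm.build_sequence({1: n_ave}, n_tot)
    return wm.MuxConfig(slice_sequence=seq, n_tot=n_tot, **kw)


@pytest.fixture(scope="session")
def noise_scene_stream(flat_5k):
    """One thermal-noise-only electrode acquired at the default operating
    point (n_ave=1); shared across tests that only need a realistic stream."""
    e = wm.ElectrodeState(1, flat_5k, v_offset=0.0, drift_rate=0.0,
                          temperature=295.0)
    scene = wm.render_scene([e], None, None, 0.5, f_sim=6e6, seed=101)
    mux = single_electrode_mux()
    raw = wm.simulate_acquisition(scene, mux, seed=102)
    return wm.demultiplex(raw)[0]
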