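import numpy as np
import pytest

import memprobe as mp


@pytest.fixture(scope="session")
def double_well():
    return mp.reference_surface("membrane_double_well", D=40.0, z_min=1.4, B=25.0)


@pytest.fixture(scope="session")
def flat_surface():
    return mp.reference_surface("flat")


@pytest.fixture(scope="session")
def toy_traj():
    """A modest toy bilayer trajectory shared across structure tests."""
    spec = mp.ToyBilayerSpec()
    traj = mp.generate_membrane_frames(spec, 25, seed=7)
    return spec, traj, mp.default_selections(traj)


@pytest.fixture(scope="session")
def umbrella_windows_small(double_well):
    """Cheap umbrella window set for WHAM plumbing tests."""
    biases = [mp.BiasSpec(z, 3000.0) for z in np.linspace(0.0, 4.0, 41)]
    return mp.sample_umbrella_windows(double_well, biases, 20_000, seed=11)


@pytest.fixture(scope="session")
def wham_profile_small(umbrella_windows_small):
    """WHAM solution of the cheap window set, solved once per session."""
    hists = mp.build_histograms(umbrella_windows_small)
    return mp.solve_wham(hists)
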