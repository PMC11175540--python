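"""Shared fixtures: small simulated acquisitions and the two canonical
desk-scale studies (run once per session; several tests inspect them)."""

import numpy as np
import pytest

from xdsimba import (
    clustering_study_config,
    default_phantom_spec,
    end_to_end_config,
    generate_trajectory,
    make_coil_maps,
    run_pipeline,
    simulate_acquisition,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_static_acq():
    """Dense, noiseless, static 2D acquisition on a 64-voxel grid
    (about twice Nyquist): the round-trip reference case."""
    n = 64
    spec = default_phantom_spec(n, ndim=2, cardiac_amplitude=0.0, resp_amplitude=0.0)
    traj = generate_trajectory(200, 2, 2 * n, ndim=2, include_si=False, tr=0.003)
    coils = make_coil_maps(n, 4, seed=1, ndim=2)
    kdata = simulate_acquisition(spec, traj, coils, seed=0)
    return spec, traj, coils, kdata


@pytest.fixture(scope="session")
def e2e():
    """The canonical end-to-end study (64^2 grid, four planted motion
    states at the in-vivo per-cluster undersampling regime)."""
    return run_pipeline(end_to_end_config(seed=1))


@pytest.fixture(scope="session")
def clustering_study():
    """The clustering-recovery study (240 interleaves, 8 coils,
    self-gating SNR about 20, unequal dwell)."""
    return run_pipeline(clustering_study_config(seed=2))
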