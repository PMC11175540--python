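import numpy as np
import pytest

from xdsimba import (
    CoilSensitivities,
    Ellipsoid,
    NufftOperator,
    PhantomSpec,
    default_phantom_spec,
    generate_trajectory,
    make_coil_maps,
    render_phantom,
    simulate_acquisition,
)


def test_static_phantom_is_time_invariant():
    spec = default_phantom_spec(48, ndim=2, cardiac_amplitude=0.0, resp_amplitude=0.0)
    v0, _ = render_phantom(spec, 0.0)
    v1, _ = render_phantom(spec, 1.7)
    assert np.array_equal(v0, v1)


def test_respiratory_shift_matches_fft_shift_oracle():
    """A phantom whose every structure breathes equals its own
    phase-ramp-shifted rendering."""
    els = [
        Ellipsoid((32, 30), (10, 8), 0.5, "liver"),
        Ellipsoid((20, 34), (6, 6), 1.0, "blood"),
    ]
    spec = PhantomSpec(64, els, cardiac_amplitude=0.0, resp_amplitude=3.0, ndim=2)
    t = spec.resp_period / (2 * np.pi) * np.arcsin(2.0 / 3.0)  # shift = +2 voxels
    v0, _ = render_phantom(spec, 0.0)
    vt, _ = render_phantom(spec, t)
    k = np.fft.fftfreq(64)
    shifted = np.fft.ifft(np.fft.fft(v0, axis=-1) * np.exp(-2j * np.pi * k * 2.0), axis=-1)
    assert np.linalg.norm(vt - shifted) / np.linalg.norm(v0) < 0.02


@pytest.mark.parametrize("ndim", [2, 3])
def test_systolic_contraction_volume_ratio(ndim):
    """At peak systole the blood-pool volume shrinks by (1-amp)^ndim."""
    amp = 0.3
    c = (24,) * ndim
    spec = PhantomSpec(
        48, [Ellipsoid(c, (8,) * ndim, 1.0, "blood")],
        cardiac_amplitude=amp, resp_amplitude=0.0, ndim=ndim,
    )
    t_peak = spec.cardiac_period / 6.0  # raised-cosine maximum
    v0, _ = render_phantom(spec, 0.0)
    v1, _ = render_phantom(spec, t_peak)
    ratio = np.abs(v1).sum() / np.abs(v0).sum()
    assert ratio == pytest.approx((1 - amp) ** ndim, rel=0.02)


def test_phantom_leaving_grid_rejected():
    with pytest.raises(ValueError):
        PhantomSpec(
            32, [Ellipsoid((30, 30), (6, 6), 1.0, "liver")],
            resp_amplitude=2.0, ndim=2,
        )


def test_coil_maps_deterministic_and_positive():
    a = make_coil_maps(32, 8, seed=3, ndim=2)
    b = make_coil_maps(32, 8, seed=3, ndim=2)
    assert np.array_equal(a.maps, b.maps)
    assert a.n_coils == 8
    assert np.all(a.rss() > 0)
    single = make_coil_maps(16, 1, seed=0, ndim=2)
    assert np.array_equal(single.maps, np.ones((1, 16, 16)))


def test_simulation_determinism_and_static_si():
    spec = default_phantom_spec(32, ndim=2, cardiac_amplitude=0.0, resp_amplitude=0.0)
    spec.noise_sigma = 0.01
    traj = generate_trajectory(12, 3, 64, ndim=2, include_si=True, tr=0.01)
    coils = make_coil_maps(32, 3, seed=0, ndim=2)
    a = simulate_acquisition(spec, traj, coils, seed=9)
    b = simulate_acquisition(spec, traj, coils, seed=9)
    assert np.array_equal(a.samples, b.samples)

    spec.noise_sigma = 0.0
    clean = simulate_acquisition(spec, traj, coils, seed=9)
    cols = clean.si_projections[:, :, 0]
    assert np.abs(cols - cols[:, :1]).max() < 1e-10  # static self-gating signal


def test_impulse_sampling_theorem():
    """Single-voxel image: |k-samples| equal the voxel magnitude, phase
    linear in k.r (the forward model is an exact Fourier sum)."""
    n = 32
    x = np.zeros((n, n), dtype=complex)
    r = np.array([20 - n // 2, 11 - n // 2])
    x[20, 11] = 0.7
    rng = np.random.default_rng(0)
    k = rng.uniform(-0.5, 0.4999, (40, 2))
    y = NufftOperator((n, n), k).forward(x)
    assert np.abs(np.abs(y) - 0.7).max() < 1e-6
    phase = np.angle(y * np.exp(2j * np.pi * (k @ r)) / 0.7)
    assert np.abs(phase).max() < 1e-6


def test_breathing_si_projection_oscillates_at_resp_frequency():
    spec = default_phantom_spec(48, ndim=2, states=None, noise_sigma=0.0)
    spec.resp_period = 1.0
    spec.cardiac_period = 0.33
    traj = generate_trajectory(128, 2, 96, ndim=2, include_si=True, tr=0.02)
    coils = make_coil_maps(48, 2, seed=1, ndim=2)
    kdata = simulate_acquisition(spec, traj, coils, seed=0)
    sig = np.abs(kdata.si_projections[:, :, 0])
    sig -= sig.mean(axis=1, keepdims=True)
    power = (np.abs(np.fft.rfft(sig, axis=1)) ** 2).sum(axis=0)
    power[0] = 0.0
    dt = traj.readouts_per_interleave * traj.tr
    freqs = np.fft.rfftfreq(sig.shape[1], d=dt)
    peak = freqs[np.argmax(power)]
    assert abs(peak - 1.0 / spec.resp_period) <= freqs[1] + 1e-12
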