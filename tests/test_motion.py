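import inspect

import numpy as np
import pytest

from xdsimba import (
    DeformationField,
    default_phantom_spec,
    estimate_deformation,
    render_phantom,
    warp,
    warp_adjoint,
)


def _phantom_image(n=64):
    from _oracles import textured_phantom_image

    return textured_phantom_image(n)


def test_zero_field_is_identity(rng):
    x = rng.standard_normal((12, 12)) + 1j * rng.standard_normal((12, 12))
    u = DeformationField.identity((12, 12))
    assert np.array_equal(warp(x, u), x)
    assert np.array_equal(warp_adjoint(x, u), x)


def test_warp_linearity(rng):
    u = DeformationField(rng.uniform(-2, 2, (10, 10, 2)))
    x = rng.standard_normal((10, 10)) + 1j * rng.standard_normal((10, 10))
    z = rng.standard_normal((10, 10))
    left = warp(2.0 * x + 3.0 * z, u)
    right = 2.0 * warp(x, u) + 3.0 * warp(z, u)
    assert np.allclose(left, right, atol=1e-12)


def test_warp_adjoint_matches_sparse_matrix_oracle(rng):
    """The scatter adjoint equals the literal transpose of the explicit
    interpolation matrix on a small grid, and passes the inner-product
    test to 1e-10."""
    shape = (8, 8)
    u = DeformationField(rng.uniform(-2.5, 2.5, shape + (2,)))
    n = np.prod(shape)
    M = np.zeros((n, n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        M[:, j] = warp(e.reshape(shape), u).ravel()
    x = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    y = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    assert np.allclose(warp_adjoint(y, u).ravel(), M.T @ y.ravel(), atol=1e-12)
    lhs = np.vdot(y, warp(x, u))
    rhs = np.vdot(warp_adjoint(y, u), x)
    assert abs(lhs - rhs) / (np.linalg.norm(warp(x, u)) * np.linalg.norm(y)) < 1e-10


def test_identity_registration_finds_no_motion():
    img = _phantom_image()
    f = estimate_deformation(img, img)
    assert np.median(np.abs(f.displacement)) < 0.1


def test_translation_recovery():
    """A global translation of up to 3 voxels is recovered with mean
    endpoint error below half a voxel on the phantom support."""
    img = _phantom_image()
    for shift in [(2, 0), (0, -3), (2, 2)]:
        reference = np.roll(img, shift, axis=(0, 1))
        f = estimate_deformation(img, reference)
        # warp(moving,u)=reference=moving(r-shift) -> u = -shift
        support = reference > 0.1
        err = f.displacement + np.array(shift)
        epe = np.linalg.norm(err, axis=-1)
        assert epe[support].mean() < 0.5, shift


def test_smooth_warp_recovery():
    img = _phantom_image()
    gx, gy = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
    u_true = np.zeros((64, 64, 2))
    u_true[..., 0] = 3.0 * np.sin(2 * np.pi * gy / 64)
    u_true[..., 1] = 3.0 * np.sin(2 * np.pi * gx / 64)
    reference = warp(img, DeformationField(u_true))
    f = estimate_deformation(img, reference)
    support = img > 0.1
    epe = np.linalg.norm(f.displacement - u_true, axis=-1)
    assert epe[support].mean() < 1.0
    # composition sanity: >= 80% endpoint-error reduction vs zero field
    epe0 = np.linalg.norm(u_true, axis=-1)
    assert epe[support].mean() < 0.2 * epe0[support].mean()


def test_registration_never_increases_residual():
    img = _phantom_image()
    spec = default_phantom_spec(64, ndim=2)
    moving = np.abs(render_phantom(spec, 0.05)[0])
    reference = np.abs(render_phantom(spec, 0.4)[0])
    f = estimate_deformation(moving, reference)
    before = np.linalg.norm(moving - reference)
    after = np.linalg.norm(warp(moving, f) - reference)
    assert after <= before


def test_registration_deterministic():
    img = _phantom_image(48)
    reference = np.roll(img, (1, 2), axis=(0, 1))
    f1 = estimate_deformation(img, reference, max_iters=50)
    f2 = estimate_deformation(img, reference, max_iters=50)
    assert np.array_equal(f1.displacement, f2.displacement)


def test_grid_mismatch_rejected(rng):
    with pytest.raises(ValueError):
        estimate_deformation(np.zeros((8, 8)), np.zeros((10, 10)))
    u = DeformationField.identity((8, 8))
    with pytest.raises(ValueError):
        warp(rng.standard_normal((10, 10)), u)


def test_default_iteration_cap_is_300():
    sig = inspect.signature(estimate_deformation)
    assert sig.parameters["max_iters"].default == 300
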