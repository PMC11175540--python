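import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xdsimba import (
    CoilSensitivities,
    DeformationField,
    NufftOperator,
    ReconConfig,
    VolumeSeries,
    cluster_difference,
    cluster_difference_adjoint,
    select_output,
    soft_threshold,
    solve_xd,
)

from _oracles import (
    cg_sense_reference,
    explicit_matrices,
    primal_dual_reference,
    toy_problem,
)


# -- soft thresholding -------------------------------------------------------

def test_soft_threshold_examples():
    assert soft_threshold(np.array([2.0 + 0j]), 0.5)[0] == pytest.approx(1.5 + 0j)
    assert soft_threshold(np.array([0.3 + 0.2j]), 0.5)[0] == 0.0
    assert soft_threshold(np.array([3j]), 1.0)[0] == pytest.approx(2j)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    re=st.floats(-5, 5, allow_nan=False),
    im=st.floats(-5, 5, allow_nan=False),
    tau=st.floats(0, 3, allow_nan=False),
)
def test_soft_threshold_shrinks_magnitude_preserves_phase(re, im, tau):
    v = np.array([re + 1j * im])
    out = soft_threshold(v, tau)[0]
    assert abs(out) == pytest.approx(max(abs(v[0]) - tau, 0.0), abs=1e-12)
    if abs(out) > 1e-12:
        assert np.angle(out) == pytest.approx(np.angle(v[0]), abs=1e-12)


# -- cyclic (motion-compensated) differences ---------------------------------

def test_constant_series_has_zero_difference():
    xs = [np.full((6, 6), 1.5 + 0.5j) for _ in range(4)]
    assert all(np.abs(d).max() == 0 for d in cluster_difference(xs))


def test_identity_fields_reduce_to_plain_difference(rng):
    xs = [rng.standard_normal((6, 6)) + 1j * rng.standard_normal((6, 6)) for _ in range(3)]
    ident = [DeformationField.identity((6, 6)) for _ in range(3)]
    plain = cluster_difference(xs, None)
    warped = cluster_difference(xs, ident)
    for a, b in zip(plain, warped):
        assert np.array_equal(a, b)


@pytest.mark.parametrize("with_fields", [False, True])
def test_difference_adjoint_inner_product(with_fields, rng):
    K, shape = 4, (8, 8)
    fields = (
        [DeformationField(rng.uniform(-2, 2, shape + (2,))) for _ in range(K)]
        if with_fields
        else None
    )
    xs = [rng.standard_normal(shape) + 1j * rng.standard_normal(shape) for _ in range(K)]
    ys = [rng.standard_normal(shape) + 1j * rng.standard_normal(shape) for _ in range(K)]
    dx = cluster_difference(xs, fields)
    dty = cluster_difference_adjoint(ys, fields)
    lhs = sum(np.vdot(y, d) for y, d in zip(ys, dx))
    rhs = sum(np.vdot(t, x) for t, x in zip(dty, xs))
    norm = np.sqrt(sum(np.linalg.norm(d) ** 2 for d in dx)) * np.sqrt(
        sum(np.linalg.norm(y) ** 2 for y in ys)
    )
    assert abs(lhs - rhs) / norm < 1e-10


def test_wrong_field_count_rejected(rng):
    xs = [rng.standard_normal((4, 4)) for _ in range(3)]
    with pytest.raises(ValueError):
        cluster_difference(xs, [DeformationField.identity((4, 4))])


# -- the ADMM solver ---------------------------------------------------------

def test_config_defaults_match_protocol():
    cfg = ReconConfig()
    assert cfg.lam == 0.3
    assert cfg.K == 4
    assert cfg.admm_iters == 40
    assert cfg.cg_iters == 3
    assert cfg.effective_rho == cfg.lam
    with pytest.raises(ValueError):
        ReconConfig(lam=-0.1)
    with pytest.raises(ValueError):
        ReconConfig(admm_iters=0)


def test_lam_zero_dense_matches_cg_sense():
    """With no regularization and fully sampled data the solver equals a
    plain CG-SENSE solution after equal total CG work."""
    n, K = 16, 3
    rng = np.random.default_rng(3)
    base = np.zeros(n, complex)
    base[4:9] = 1.0
    truth = [np.roll(base, r) for r in (0, 1, 2)]
    freqs = (np.arange(n) - n // 2) / n
    ops = [NufftOperator((n,), freqs[:, None]) for _ in range(K)]
    ys = [op.forward(t)[:, None] for op, t in zip(ops, truth)]
    sens = CoilSensitivities(np.ones((1, n), complex))
    cfg = ReconConfig(lam=0.0, K=K, admm_iters=10, cg_iters=3, rho=1e-9, normalize=False)
    series, _ = solve_xd(ys, ops, sens, None, cfg)
    for i in range(K):
        ref = cg_sense_reference(ops[i], ys[i][:, 0], iters=30)
        assert np.linalg.norm(series.volumes[i] - ref) / np.linalg.norm(ref) < 1e-3


def test_admm_converges_to_primal_dual_optimum():
    """Run long enough to converge, the ADMM objective matches the
    independent Chambolle-Pock optimum to well under 0.1%."""
    truth, ops, ys = toy_problem(seed=3)
    A, D = explicit_matrices(ops, 16, 3)
    yvec = np.concatenate([y[:, 0] for y in ys]) / np.sqrt(16)
    _, obj_ref = primal_dual_reference(A, D, yvec, 0.3)
    sens = CoilSensitivities(np.ones((1, 16), complex))
    cfg = ReconConfig(lam=0.3, K=3, admm_iters=160, cg_iters=3, normalize=False)
    _, log = solve_xd(ys, ops, sens, None, cfg)
    assert abs(log.objective[-1] - obj_ref) / obj_ref < 1e-3


def test_identity_fields_equal_no_fields_solution():
    truth, ops, ys = toy_problem(seed=5)
    sens = CoilSensitivities(np.ones((1, 16), complex))
    cfg = ReconConfig(lam=0.3, K=3, admm_iters=8, cg_iters=3)
    ident = [DeformationField.identity((16,)) for _ in range(3)]
    a, _ = solve_xd(ys, ops, sens, None, cfg)
    b, _ = solve_xd(ys, ops, sens, ident, cfg)
    for va, vb in zip(a.volumes, b.volumes):
        assert np.linalg.norm(va - vb) / np.linalg.norm(va) < 1e-10


def test_solution_improves_data_consistency_over_init():
    truth, ops, ys = toy_problem(seed=7)
    sens = CoilSensitivities(np.ones((1, 16), complex))
    cfg = ReconConfig(lam=0.3, K=3, admm_iters=40, cg_iters=3, normalize=False)
    _, log = solve_xd(ys, ops, sens, None, cfg)
    assert log.data_term[-1] <= log.data_term[0]


def test_primal_feasibility_trend():
    truth, ops, ys = toy_problem(seed=11)
    sens = CoilSensitivities(np.ones((1, 16), complex))
    cfg = ReconConfig(lam=0.3, K=3, admm_iters=40, cg_iters=3, normalize=False)
    _, log = solve_xd(ys, ops, sens, None, cfg)
    assert log.primal_residual[-1] < log.primal_residual[0]


def test_regularizer_monotone_in_lambda():
    """Raising lambda never raises the final L1-to-data-term ratio of the
    solution (the over/under-regularization trend)."""
    truth, ops, ys = toy_problem(seed=13)
    sens = CoilSensitivities(np.ones((1, 16), complex))
    ratios = []
    for lam in (0.03, 0.3, 3.0):
        cfg = ReconConfig(lam=lam, K=3, admm_iters=40, cg_iters=3)
        _, log = solve_xd(ys, ops, sens, None, cfg)
        ratios.append((log.l1_term[-1] / lam) / max(log.data_term[-1], 1e-30))
    assert ratios[0] >= ratios[1] >= ratios[2]


def test_nan_input_raises():
    truth, ops, ys = toy_problem(seed=1)
    ys = [y.copy() for y in ys]
    ys[0][0, 0] = np.nan
    sens = CoilSensitivities(np.ones((1, 16), complex))
    with pytest.raises(FloatingPointError):
        solve_xd(ys, ops, sens, None, ReconConfig(lam=0.3, K=3, admm_iters=2, cg_iters=2))


def test_select_output_contract(rng):
    vols = [rng.standard_normal((4, 4)) for _ in range(3)]
    series = VolumeSeries(vols, cluster_ids=[3, 1, 0])
    assert np.array_equal(select_output(series), vols[0])
    assert np.array_equal(select_output(series, rank_order=[3, 1, 0, 2]), vols[0])
    with pytest.raises(ValueError):
        select_output(series, rank_order=[1, 3, 0])
    single = VolumeSeries([vols[1]], cluster_ids=[0])
    assert np.array_equal(select_output(single), vols[1])
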