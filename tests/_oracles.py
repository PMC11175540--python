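"""Independent reference solvers and explicit-matrix builders used by the
solver tests (kept free of the package's ADMM code path)."""

import numpy as np
from scipy.linalg import block_diag

from xdsimba import NufftOperator


def toy_problem(seed=0, n=16, K=3, n_keep=10, rolls=(0, 1, 2)):
    """1D multi-cluster toy: cyclically shifted piecewise-constant signals
    observed through per-cluster undersampled FFT masks."""
    rng = np.random.default_rng(seed)
    base = np.zeros(n, complex)
    base[4:9] = 1.0
    base[10:13] = 0.5 + 0.3j
    truth = [np.roll(base, r) for r in rolls]
    freqs = (np.arange(n) - n // 2) / n
    ops, ys = [], []
    for i in range(K):
        sel = np.sort(rng.choice(n, n_keep, replace=False))
        op = NufftOperator((n,), freqs[sel][:, None])
        ops.append(op)
        ys.append(op.forward(truth[i])[:, None])
    return truth, ops, ys


def explicit_matrices(ops, n, K, unitary=True):
    """Dense (A, D) for the stacked problem, built by probing the
    operators with basis vectors. ``unitary`` applies the solver's
    1/sqrt(N) operator convention so both sides optimize the same
    objective."""
    scale = 1.0 / np.sqrt(n) if unitary else 1.0
    blocks = []
    for op in ops:
        M = np.zeros((op.n_samples, n), complex)
        for j in range(n):
            e = np.zeros(n, complex)
            e[j] = 1.0
            M[:, j] = op.forward(e) * scale
        blocks.append(M)
    A = block_diag(*blocks)
    D = np.zeros((K * n, K * n))
    for i in range(K):
        D[i * n : (i + 1) * n, i * n : (i + 1) * n] = np.eye(n)
        j = (i - 1) % K
        D[i * n : (i + 1) * n, j * n : (j + 1) * n] -= np.eye(n)
    return A, D


def primal_dual_reference(A, D, y, lam, iters=10_000):
    """Chambolle-Pock solution of min ||Ax-y||^2 + lam*||Dx||_1; the
    data-term prox is solved exactly through a precomputed inverse."""
    m = A.shape[1]
    L = np.linalg.norm(D, 2)
    tau = sigma = 1.0 / L
    M1 = np.linalg.inv(np.eye(m) + 2 * tau * (A.conj().T @ A))
    Aty = A.conj().T @ y
    x = np.zeros(m, complex)
    xb = x.copy()
    p = np.zeros(m, complex)
    for _ in range(iters):
        p = p + sigma * (D @ xb)
        mag = np.abs(p)
        p = p * np.minimum(1.0, lam / np.where(mag > 0, mag, 1.0))
        x_old = x
        x = M1 @ (x - tau * (D.T @ p) + 2 * tau * Aty)
        xb = 2 * x - x_old
    obj = np.linalg.norm(A @ x - y) ** 2 + lam * np.abs(D @ x).sum()
    return x, obj


def cg_sense_reference(op, y, iters):
    """Plain conjugate gradient on the (single-coil) normal equations,
    initialized from the adjoint image."""
    b = op.adjoint(y)
    x = b.copy()
    r = b - op.adjoint(op.forward(x))
    p = r.copy()
    rs = np.vdot(r, r).real
    for _ in range(iters):
        if rs < 1e-30:
            break
        ap = op.adjoint(op.forward(p))
        alpha = rs / np.vdot(p, ap).real
        x = x + alpha * p
        r = r - alpha * ap
        rs_new = np.vdot(r, r).real
        p = r + (rs_new / rs) * p
        rs = rs_new
    return x


def textured_phantom_image(n=64):
    """Static phantom magnitude with a smooth multiplicative texture:
    registration ground truth is then observable everywhere on the
    support (a piecewise-constant interior is blind to translation)."""
    from xdsimba import default_phantom_spec, render_phantom

    spec = default_phantom_spec(n, ndim=2, cardiac_amplitude=0.0, resp_amplitude=0.0)
    img = np.abs(render_phantom(spec, 0.0)[0])
    gx, gy = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    texture = 1.0 + 0.25 * np.sin(2 * np.pi * gx / 9.0) * np.sin(2 * np.pi * gy / 7.0)
    return img * texture
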