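import numpy as np
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from xdsimba import (
    ClusterAssignment,
    SIMatrix,
    assign_readouts,
    build_si_matrix,
    cluster_with_selection,
    generate_trajectory,
)
from xdsimba.clustering import pca_scores, selection_score
from xdsimba.phantom import KSpaceData


def _fake_kdata(n_z, n_si, n_coils, rng=None, static=False):
    if static:
        col = np.ones((n_z, 1, n_coils), dtype=complex)
        proj = np.repeat(col, n_si, axis=1)
    else:
        proj = rng.standard_normal((n_z, n_si, n_coils)) + 1j * rng.standard_normal(
            (n_z, n_si, n_coils)
        )
    return KSpaceData(samples=np.zeros((n_si, 2, n_coils), complex), traj=None, si_projections=proj)


def test_si_matrix_shapes_and_centering(rng):
    assert build_si_matrix(_fake_kdata(16, 3, 1, rng)).data.shape == (16, 3)
    assert build_si_matrix(_fake_kdata(16, 3, 2, rng)).data.shape == (32, 3)
    static = build_si_matrix(_fake_kdata(16, 5, 2, static=True))
    assert np.abs(static.data).max() == 0.0  # centering kills a static signal
    with pytest.raises(RuntimeError):
        build_si_matrix(KSpaceData(np.zeros((1, 2, 1), complex), None, None))


def test_pca_scores_match_svd_oracle(rng):
    mat = rng.standard_normal((20, 40)) + 1j * rng.standard_normal((20, 40))
    sim = SIMatrix(mat - mat.mean(axis=1, keepdims=True))
    scores = pca_scores(sim, n_components=4)
    u, s, vh = np.linalg.svd(sim.data, full_matrices=False)
    oracle = np.real((u[:, :4].conj().T @ sim.data).T)
    # per-component sign/phase of the real projection may flip
    for c in range(4):
        assert (
            np.abs(scores[:, c] - oracle[:, c]).max() < 1e-8
            or np.abs(scores[:, c] + oracle[:, c]).max() < 1e-8
        )


def test_selection_matches_brute_force_oracle(rng):
    """k selection and labels coincide with an independent loop that runs
    a fresh k-means per k and applies the mean-centroid-distance formula
    on the most populated cluster."""
    centers = np.array([[0, 0], [6, 0], [0, 6], [6, 6]], dtype=float)
    sizes = [80, 50, 40, 30]
    pts = np.vstack(
        [c + rng.standard_normal((s, 2)) for c, s in zip(centers, sizes)]
    )
    seed = 7
    assign = cluster_with_selection(pts, k_range=(2, 6), seed=seed)

    order = np.lexsort(pts.T[::-1])  # the documented canonical order
    best_k, best_score, best_labels = None, np.inf, None
    for k in range(2, 7):
        km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
        lab_sorted = km.fit_predict(pts[order])
        labels = np.empty(len(pts), dtype=int)
        labels[order] = lab_sorted
        counts = np.bincount(labels, minlength=k)
        big = int(np.argmax(counts))
        score = float(
            np.mean(np.linalg.norm(pts[labels == big] - km.cluster_centers_[big], axis=1))
        )
        if score < best_score:
            best_k, best_score, best_labels = k, score, labels
    assert assign.k_selected == best_k
    assert assign.selection_scores[best_k] == pytest.approx(best_score, abs=1e-12)
    assert np.array_equal(assign.labels, best_labels)


def test_zero_distance_cluster_wins(rng):
    # a k where the largest cluster collapses onto its centroid scores 0
    pts = np.vstack([np.zeros((60, 2)), rng.standard_normal((30, 2)) + 8])
    assign = cluster_with_selection(pts, k_range=(2, 4), seed=0)
    assert assign.selection_scores[assign.k_selected] == pytest.approx(0.0, abs=1e-9)


def test_default_search_range_is_10_to_14():
    import inspect

    sig = inspect.signature(cluster_with_selection)
    assert sig.parameters["k_range"].default == (10, 14)


def test_degenerate_data_returns_k_min_with_flag():
    pts = np.ones((30, 3))
    with pytest.warns(UserWarning):
        assign = cluster_with_selection(pts, k_range=(2, 4), seed=0)
    assert assign.k_selected == 2
    assert assign.degenerate


def test_infeasible_k_range_rejected(rng):
    with pytest.raises(ValueError):
        cluster_with_selection(rng.standard_normal((5, 2)), k_range=(2, 6), seed=0)
    with pytest.raises(ValueError):
        cluster_with_selection(rng.standard_normal((50, 2)), k_range=(1, 3), seed=0)


def test_permutation_invariance(rng):
    pts = np.vstack(
        [c + 0.5 * rng.standard_normal((40, 2)) for c in ([0, 0], [5, 0], [0, 5])]
    )
    a = cluster_with_selection(pts, k_range=(2, 4), seed=3)
    perm = rng.permutation(len(pts))
    b = cluster_with_selection(pts[perm], k_range=(2, 4), seed=3)
    assert a.k_selected == b.k_selected
    assert adjusted_rand_score(a.labels[perm], b.labels) == 1.0


def test_labels_partition_and_rank_order(rng):
    pts = rng.standard_normal((60, 3))
    assign = cluster_with_selection(pts, k_range=(2, 5), seed=1, readouts_per_member=4)
    assert assign.populations.sum() == 60 * 4
    pops = np.bincount(assign.labels, minlength=assign.k_selected) * 4
    assert np.array_equal(np.sort(assign.populations), np.sort(pops))
    assert np.array_equal(
        assign.rank_order, np.argsort(-assign.populations, kind="stable")
    )


def test_readout_inheritance_excludes_si():
    # 3 interleaves of 22 readouts labeled (a, a, b)
    traj = generate_trajectory(3, 22, 2, ndim=3, include_si=True, tr=0.003)
    assign = ClusterAssignment(
        labels=np.array([0, 0, 1]),
        k_selected=2,
        populations=np.array([44, 22]),
        rank_order=np.array([0, 1]),
        centroids=np.zeros((2, 1)),
        seed=0,
    )
    subsets = assign_readouts(assign, traj, n_select=2)
    assert len(subsets[0]) == 42  # 2 interleaves x 21 imaging readouts
    assert len(subsets[1]) == 21
    assert not np.isin(subsets[0], np.flatnonzero(traj.is_si)).any()
    with pytest.raises(ValueError):
        assign_readouts(assign, traj, n_select=3)


def test_default_n_select_is_four():
    import inspect

    assert inspect.signature(assign_readouts).parameters["n_select"].default == 4
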