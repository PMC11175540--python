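"""Similarity-driven binning (SIMBA) of self-gating SI projections.

The SI projections acquired at the interleave rate are concatenated into
one feature-by-time matrix, reduced by PCA, and the real part of the PCA
scores is clustered with k-means. The cluster count k is chosen within a
search range (default 10..14) to minimize the mean Euclidean distance
between the most populated cluster's points and its centroid; whole
interleaves inherit their SI readout's cluster label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .phantom import KSpaceData
from .trajectory import RadialTrajectory


@dataclass
class SIMatrix:
    """Feature x time matrix of SI projections (z-positions stacked over
    coils), columns in acquisition order, rows mean-centered."""

    data: np.ndarray

    @property
    def n_si(self) -> int:
        return self.data.shape[1]


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # cluster id per interleave / per point
    k_selected: int
    populations: np.ndarray  # readout count per cluster
    rank_order: np.ndarray  # cluster ids by descending population
    centroids: np.ndarray  # (k, n_components) in PCA-score space
    seed: int
    scores: np.ndarray = field(default=None, repr=False)  # real PCA scores
    selection_scores: dict = field(default_factory=dict)  # k -> criterion
    degenerate: bool = False

    def validate(self) -> None:
        if not np.array_equal(np.sort(np.unique(self.labels)), np.arange(self.k_selected)):
            counts = np.bincount(self.labels, minlength=self.k_selected)
            if counts.size > self.k_selected or np.any(self.labels < 0):
                raise ValueError("labels must partition points into k clusters")
        order = np.argsort(-self.populations, kind="stable")
        if not np.array_equal(order, self.rank_order):
            raise ValueError("rank_order inconsistent with populations")


def build_si_matrix(kdata: KSpaceData, combine: str = "stack") -> SIMatrix:
    """Concatenate SI projections into the SIMBA input matrix.

    ``combine="stack"`` concatenates the complex per-coil z-profiles
    (features = n_z * n_coils); ``"rss"`` uses the coil
    root-sum-of-squares magnitude profile instead. Every feature row is
    mean-centered, so a static noiseless acquisition yields the zero
    matrix.
    """
    if kdata.si_projections is None or kdata.si_projections.shape[1] == 0:
        raise RuntimeError("acquisition contains no SI projections")
    proj = kdata.si_projections  # (n_z, n_si, n_coils)
    if combine == "stack":
        mat = np.concatenate([proj[:, :, c] for c in range(proj.shape[2])], axis=0)
    elif combine == "rss":
        mat = np.sqrt(np.sum(np.abs(proj) ** 2, axis=2))
    else:
        raise ValueError(f"unknown combine mode {combine!r}")
    mat = np.asarray(mat, dtype=complex)
    if np.any(~np.isfinite(mat)):
        raise ValueError("SI matrix contains non-finite entries")
    return SIMatrix(mat - mat.mean(axis=1, keepdims=True))


def pca_scores(sim: SIMatrix, n_components: int | None = None, var_threshold: float = 0.95, max_components: int = 10):
    """Real part of the PCA projection of the SI matrix columns.

    Components are the left singular vectors of the centered matrix; when
    ``n_components`` is not given, the smallest number explaining at
    least ``var_threshold`` of the variance is kept, capped at
    ``max_components``.
    """
    u, s, _ = np.linalg.svd(sim.data, full_matrices=False)
    if n_components is None:
        var = s**2
        total = var.sum()
        if total == 0:
            n_components = 1
        else:
            cum = np.cumsum(var) / total
            n_components = int(np.searchsorted(cum, var_threshold) + 1)
        n_components = min(n_components, max_components, len(s))
    scores = (u[:, :n_components].conj().T @ sim.data).T  # (n_si, n_comp)
    return np.real(scores)


def selection_score(points: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> float:
    """Mean centroid distance within the most populated cluster,
    (1/|C|) * sum_{s in C} ||mu - s||_2 — the cluster-count criterion."""
    counts = np.bincount(labels, minlength=centroids.shape[0])
    big = int(np.argmax(counts))
    pts = points[labels == big]
    return float(np.mean(np.linalg.norm(pts - centroids[big], axis=1)))


def cluster_with_selection(
    sim: SIMatrix | np.ndarray,
    k_range: tuple[int, int] = (10, 14),
    n_components: int | None = None,
    seed: int = 0,
    readouts_per_member: int = 1,
) -> ClusterAssignment:
    """PCA + k-means with automatic cluster-count selection.

    Runs k-means (k-means++ init, 10 restarts, seeded) on the real PCA
    scores for every k in ``k_range`` inclusive, and keeps the k that
    minimizes :func:`selection_score` (ties -> smaller k). A raw 2D
    point array may be passed instead of an SIMatrix, in which case PCA
    is skipped (used for desk-scale and oracle tests).
    """
    k_min, k_max = int(k_range[0]), int(k_range[1])
    if k_min < 2 or k_max < k_min:
        raise ValueError("invalid k_range")
    if isinstance(sim, SIMatrix):
        pts = pca_scores(sim, n_components=n_components)
    else:
        pts = np.asarray(sim, dtype=float)
    n = pts.shape[0]
    if n <= k_max:
        raise ValueError(f"need more than {k_max} points, got {n}")

    degenerate = np.allclose(pts, pts[0])
    if degenerate:
        warnings.warn("degenerate (identical) SI data; returning k_min")
        ks = [k_min]
    else:
        ks = range(k_min, k_max + 1)

    # canonical (lexicographic) point order: the clustering result is then
    # invariant to a permutation of the acquisition order
    order = np.lexsort(pts.T[::-1])
    pts_sorted = pts[order]

    best = None
    sel = {}
    for k in ks:
        km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
        labels_sorted = km.fit_predict(pts_sorted)
        labels = np.empty(n, dtype=int)
        labels[order] = labels_sorted
        sc = selection_score(pts, labels, km.cluster_centers_)
        sel[k] = sc
        if best is None or sc < best[0]:
            best = (sc, k, labels, km.cluster_centers_)

    _, k_sel, labels, centroids = best
    pops = np.bincount(labels, minlength=k_sel) * readouts_per_member
    assign = ClusterAssignment(
        labels=labels,
        k_selected=k_sel,
        populations=pops,
        rank_order=np.argsort(-pops, kind="stable"),
        centroids=centroids,
        seed=seed,
        scores=pts,
        selection_scores=sel,
        degenerate=degenerate,
    )
    assign.validate()
    return assign


def assign_readouts(
    assign: ClusterAssignment,
    traj: RadialTrajectory,
    n_select: int = 4,
) -> list[np.ndarray]:
    """Imaging-readout index lists for the ``n_select`` most populated
    clusters, in descending-population order.

    Every imaging (non-SI) readout inherits its interleave's label; SI
    readouts are self-gating, not imaging, data and are excluded. The
    returned order is the cyclic adjacency used by the reconstruction
    (last adjacent to first).
    """
    if n_select > assign.k_selected:
        raise ValueError("n_select exceeds the number of clusters")
    if len(assign.labels) != traj.n_interleaves:
        raise ValueError("assignment does not match trajectory interleaves")
    out = []
    imaging = ~traj.is_si
    for cid in assign.rank_order[:n_select]:
        mask = imaging & (assign.labels[traj.interleave_id] == cid)
        out.append(np.flatnonzero(mask))
    return out
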