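"""K-means for longitudinal exposure trajectories with quality scoring.

Trajectories of different lengths (deliveries before week 38) are padded
with zeros onto a common week grid: exposure attributable to a pregnancy is
zero after it ends, which keeps Euclidean distances well-defined.
Trajectories are clustered raw (unstandardized) so clusters separate by
exposure magnitude, and cluster letters A..D are assigned in ascending order
of centroid mean, A being the least exposed group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import ValidationError, WeeklyTrajectory

__all__ = [
    "TrajectoryMatrix",
    "ClusterModel",
    "pad_to_grid",
    "fit_kmeans",
    "calinski_harabasz",
    "LETTERS",
]

LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass
class TrajectoryMatrix:
    """Rectangular pregnancies x weeks matrix of weekly DDD values.

    ``padding_mask[i, j]`` is True where week j lies past pregnancy i's end
    (the cell holds 0 by construction).
    """

    pregnancy_ids: list[str]
    grid: np.ndarray  # week axis
    matrix: np.ndarray  # (n_pregnancies, n_weeks)
    padding_mask: np.ndarray  # bool, same shape

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.pregnancy_ids), len(self.grid)):
            raise ValidationError("matrix shape does not match ids x grid")


@dataclass
class ClusterModel:
    """Fitted longitudinal k-means partition with ordered letters.

    ``centroids[i]`` is the average trajectory of the cluster labelled
    ``LETTERS[i]``; mean(centroid A) <= mean(centroid B) <= ... holds by
    construction.  ``inertia_trace`` records within-cluster inertia at each
    Lloyd iteration of the winning start (non-increasing).
    """

    k: int
    grid: np.ndarray
    centroids: np.ndarray  # (k, n_weeks), ordered A..D by ascending mean
    labels: dict[str, str]  # pregnancy_id -> letter
    label_array: np.ndarray  # letters aligned with the input row order
    seed: int
    n_starts: int
    inertia: float
    n_iter: int = 0
    inertia_trace: list[float] = field(default_factory=list)

    def letter_index(self, letter: str) -> int:
        return LETTERS.index(letter)


def pad_to_grid(trajectories: Sequence[WeeklyTrajectory]) -> TrajectoryMatrix:
    """Stack trajectories on a shared week axis, zero-padding short rows.

    All trajectories must share the same start week; the grid runs to the
    latest end week present.  The padding mask marks post-delivery cells.
    """
    if not trajectories:
        return TrajectoryMatrix([], np.arange(0), np.zeros((0, 0)), np.zeros((0, 0), bool))
    starts = {t.start_week for t in trajectories}
    if len(starts) > 1:
        raise ValidationError(f"mixed start weeks: {sorted(starts)}")
    start = starts.pop()
    n_weeks = max(len(t.values) for t in trajectories)
    grid = np.arange(start, start + n_weeks)
    matrix = np.zeros((len(trajectories), n_weeks))
    mask = np.zeros_like(matrix, dtype=bool)
    ids = []
    for i, t in enumerate(trajectories):
        matrix[i, : len(t.values)] = t.values
        mask[i, len(t.values):] = True
        ids.append(t.pregnancy_id)
    return TrajectoryMatrix(ids, grid, matrix, mask)


def _lloyd(
    X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float, int, list[float]]:
    """One run of Lloyd's algorithm from a random k-point initialization.

    Nearest-centroid ties break toward the lower cluster index (argmin); a
    cluster emptied during iteration is re-seeded with the point farthest
    from its own centroid.
    """
    n = X.shape[0]
    centroids = X[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1)
    trace: list[float] = []
    for it in range(max_iter):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        inertia = float(d2[np.arange(n), new_labels].sum())
        trace.append(inertia)
        for j in range(k):
            if not np.any(new_labels == j):
                worst = int(d2[np.arange(n), new_labels].argmax())
                new_labels[worst] = j
        if np.array_equal(new_labels, labels):
            labels = new_labels
            break
        labels = new_labels
        for j in range(k):
            centroids[j] = X[labels == j].mean(axis=0)
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    inertia = float(d2[np.arange(n), labels].sum())
    return labels, centroids, inertia, it + 1, trace


def fit_kmeans(
    matrix: TrajectoryMatrix,
    k: int = 4,
    n_starts: int = 20,
    seed: int = 0,
    max_iter: int = 300,
) -> ClusterModel:
    """Longitudinal k-means: best of ``n_starts`` Lloyd runs, letters A..D.

    Deterministic given the seed.  Raises if there are fewer rows than
    clusters.
    """
    X = matrix.matrix
    n = X.shape[0]
    if n < k:
        raise ValidationError(f"need at least k={k} trajectories, got {n}")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_starts):
        run = _lloyd(X, k, rng, max_iter)
        if best is None or run[2] < best[2]:
            best = run
    labels, centroids, inertia, n_iter, trace = best

    order = np.argsort(centroids.mean(axis=1), kind="stable")
    letter_of = {int(cluster): LETTERS[rank] for rank, cluster in enumerate(order)}
    label_array = np.array([letter_of[int(c)] for c in labels])
    return ClusterModel(
        k=k,
        grid=matrix.grid,
        centroids=centroids[order],
        labels=dict(zip(matrix.pregnancy_ids, label_array)),
        label_array=label_array,
        seed=seed,
        n_starts=n_starts,
        inertia=inertia,
        n_iter=n_iter,
        inertia_trace=trace,
    )


def calinski_harabasz(X: np.ndarray, labels: Sequence) -> float:
    """Calinski-Harabasz variance-ratio criterion of a partition.

    (B / (k-1)) / (W / (n-k)) with B the between-cluster sum of squared
    centroid deviations (weighted by cluster size) and W the within-cluster
    sum of squared distances to own centroids.  Higher is better; a
    partition with W = 0 (duplicated points) is degenerate and scores
    infinity.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(labels):
        X = X.T  # allow 1-D column input
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    k, n = len(uniq), X.shape[0]
    if k < 2:
        raise ValidationError("calinski_harabasz needs at least 2 clusters")
    if k >= n:
        raise ValidationError("calinski_harabasz needs n > k")
    overall = X.mean(axis=0)
    B = 0.0
    W = 0.0
    for u in uniq:
        pts = X[labels == u]
        if len(pts) == 0:
            raise ValidationError(f"empty cluster {u!r}")
        c = pts.mean(axis=0)
        B += len(pts) * float(((c - overall) ** 2).sum())
        W += float(((pts - c) ** 2).sum())
    if W == 0.0:
        return float("inf")
    return (B / (k - 1)) / (W / (n - k))
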