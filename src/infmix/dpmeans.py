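"""DP-means hard clustering under an information-loss + lambda*K objective.

DP-means is the small-variance (hard) limit of a Dirichlet-process Gaussian
mixture: a nonparametric variant of K-means that spawns a new cluster
whenever a point lies farther than a penalty threshold ``lam`` from every
existing centroid. The objective minimized is

    J(M) = sum_k sum_{x in cluster k} ||x - mu_k||^2  +  lam * K,

i.e. within-cluster squared error ("information loss") plus a memory cost
proportional to the number of stored centroids. Two limits bracket the
model family: at ``lam = 0`` every distinct point becomes its own cluster
(the exemplar representation), and once ``lam`` exceeds the maximum
pairwise squared distance a single cluster at the global mean survives
(the prototype representation). The spawn rule here uses the *squared*
Euclidean distance threshold, which is the reading under which both limits
and per-iteration objective descent hold exactly.

The algorithm is deterministic: it starts from one cluster at the global
mean and scans points in input order, so no random seeding is involved.
Because the spawn move can only ever add clusters, the plain algorithm has
a known over-splitting artifact: two clusters spawned inside one true
component can never heal. Each iteration therefore also applies greedy
merge moves — two clusters are merged whenever doing so lowers the
objective (the within-pair scatter added by the merge is less than the
``lam`` saved) — which keeps the objective non-increasing, is equally
deterministic, and leaves both model limits untouched.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import silhouette_score
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "DPMeans",
    "dp_means",
    "clustering_objective",
    "mean_silhouette",
    "select_lambda",
]


def clustering_objective(
    points: np.ndarray,
    labels: np.ndarray,
    centroids: np.ndarray,
    lam: float,
) -> float:
    """Information loss plus memory penalty: sum ||x - mu_label||^2 + lam*K."""
    points = np.asarray(points, dtype=np.float64)
    labels = np.asarray(labels)
    centroids = np.atleast_2d(np.asarray(centroids, dtype=np.float64))
    if labels.min() < 0 or labels.max() >= len(centroids):
        raise ValueError("label out of range for centroid list")
    diff = points - centroids[labels]
    return float(np.einsum("ij,ij->", diff, diff) + lam * len(centroids))


class DPMeans(ClusterMixin, BaseEstimator):
    """DP-means clustering estimator.

    Parameters
    ----------
    lam : float, default=1.0
        Cluster-spawn penalty (weight on the number of clusters). Must be
        non-negative. A point spawns a new cluster when its squared
        Euclidean distance to every current centroid exceeds ``lam``.
    max_iter : int, default=100
        Maximum number of assign/update passes.
    tol : float, default=1e-9
        Convergence threshold on objective improvement; the algorithm also
        stops as soon as a full pass leaves all labels unchanged.

    Attributes
    ----------
    labels_ : ndarray of shape (n,)
        Cluster index per input point, each in ``[0, n_clusters_)``.
    cluster_centers_ : ndarray of shape (n_clusters_, d)
        Mean of the points assigned to each cluster.
    n_clusters_ : int
    objective_ : float
        Final value of the loss + lam*K objective.
    objective_trace_ : list of float
        Objective after each assign/update pass; non-increasing.
    n_iter_ : int
    """

    def __init__(self, lam: float = 1.0, max_iter: int = 100, tol: float = 1e-9):
        self.lam = lam
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X: np.ndarray, y: None = None) -> "DPMeans":
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[0] < 1:
            raise ValueError("X must be a non-empty 2-D array")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite coordinates")
        if self.lam < 0:
            raise ValueError("lam must be non-negative")
        n = X.shape[0]

        centroids = X.mean(axis=0, keepdims=True).copy()
        labels = np.zeros(n, dtype=np.intp)
        trace: list[float] = []
        n_iter = 0
        prev_objective = np.inf

        for n_iter in range(1, self.max_iter + 1):
            old_labels = labels.copy()
            # Sequential assignment pass: each point either joins its nearest
            # centroid or, if even the nearest is more than lam away (squared),
            # spawns a cluster at its own location. Spawned centroids are
            # visible to the points scanned after it within the same pass.
            for i in range(n):
                d2 = np.einsum("ij,ij->i", centroids - X[i], centroids - X[i])
                j = int(np.argmin(d2))
                if d2[j] > self.lam:
                    centroids = np.vstack([centroids, X[i]])
                    labels[i] = len(centroids) - 1
                else:
                    labels[i] = j
            # Update step: recompute centroids as assigned means; drop empties.
            keep = np.unique(labels)
            remap = {old: new for new, old in enumerate(keep)}
            labels = np.array([remap[l] for l in labels], dtype=np.intp)
            centroids = np.vstack(
                [X[labels == k].mean(axis=0) for k in range(len(keep))]
            )
            merged = self._merge_pass(X, labels, centroids)
            if merged is not None:
                labels, centroids = merged
            objective = clustering_objective(X, labels, centroids, self.lam)
            trace.append(objective)
            if np.array_equal(labels, old_labels):
                break
            # a merge leaves labels mid-move, so convergence on a small
            # objective step is only declared on merge-free iterations
            if merged is None and prev_objective - objective < self.tol:
                break
            prev_objective = objective

        self.labels_ = labels
        self.cluster_centers_ = centroids
        self.n_clusters_ = len(centroids)
        self.objective_ = trace[-1]
        self.objective_trace_ = trace
        self.n_iter_ = n_iter
        return self

    def _merge_pass(
        self, X: np.ndarray, labels: np.ndarray, centroids: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray] | None:
        """Greedily merge cluster pairs while doing so lowers the objective.

        Merging clusters of sizes n1, n2 with centroids mu1, mu2 raises the
        loss by n1*n2/(n1+n2) * ||mu1 - mu2||^2 and saves lam; the pair with
        the most negative net change is merged first. Returns the updated
        (labels, centroids) or None when no merge applies.
        """
        changed = False
        while len(centroids) > 1:
            sizes = np.bincount(labels, minlength=len(centroids)).astype(float)
            diff = centroids[:, None, :] - centroids[None, :, :]
            scatter = (
                sizes[:, None] * sizes[None, :] / (sizes[:, None] + sizes[None, :])
            ) * np.einsum("ijk,ijk->ij", diff, diff)
            np.fill_diagonal(scatter, np.inf)
            j, k = np.unravel_index(np.argmin(scatter), scatter.shape)
            if scatter[j, k] >= self.lam:  # no merge lowers the objective
                break
            j, k = min(j, k), max(j, k)
            labels = labels.copy() if not changed else labels
            labels[labels == k] = j
            labels[labels > k] = labels[labels > k] - 1
            centroids = np.vstack(
                [X[labels == c].mean(axis=0) for c in range(len(centroids) - 1)]
            )
            changed = True
        return (labels, centroids) if changed else None

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Assign new points to the nearest fitted centroid (no spawning)."""
        check_is_fitted(self, "cluster_centers_")
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        d2 = ((X[:, None, :] - self.cluster_centers_[None]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)


def dp_means(
    points: np.ndarray, lam: float, max_iter: int = 100, tol: float = 1e-9
) -> DPMeans:
    """Functional wrapper: fit a :class:`DPMeans` and return the fitted model."""
    return DPMeans(lam=lam, max_iter=max_iter, tol=tol).fit(points)


def mean_silhouette(points: np.ndarray, labels: np.ndarray) -> float | None:
    """Mean silhouette coefficient (Euclidean), or None when undefined.

    Undefined when there are fewer than 2 clusters or every point is its own
    cluster (K = n), the two regimes in which the silhouette carries no
    information about cluster coherence.
    """
    points = np.asarray(points, dtype=np.float64)
    labels = np.asarray(labels)
    if points.shape[0] < 2:
        raise ValueError("silhouette needs at least 2 points")
    k = len(np.unique(labels))
    if k < 2 or k >= points.shape[0]:
        return None
    return float(silhouette_score(points, labels, metric="euclidean"))


def select_lambda(
    support_sets: Sequence[np.ndarray],
    grid: Iterable[float],
    max_iter: int = 100,
    tol: float = 1e-9,
) -> tuple[float, list[tuple[float, float | None]]]:
    """Pick the penalty lambda maximizing mean silhouette across support sets.

    For each lambda in ``grid``, every support set is clustered with DP-means
    and the silhouette scores of the *defined* clusterings (2 <= K < n) are
    averaged. Returns ``(lam_star, table)`` where ``table`` lists
    ``(lam, mean_silhouette_or_None)`` per grid value in input order. A
    lambda with no defined clustering is excluded; ties break toward the
    smaller lambda; if every lambda is excluded a ValueError is raised.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("lambda grid is empty")
    table: list[tuple[float, float | None]] = []
    for lam in grid:
        scores = []
        for pts in support_sets:
            model = dp_means(pts, lam, max_iter=max_iter, tol=tol)
            s = mean_silhouette(pts, model.labels_) if len(pts) >= 2 else None
            if s is not None:
                scores.append(s)
        table.append((lam, float(np.mean(scores)) if scores else None))
    defined = [(lam, s) for lam, s in table if s is not None]
    if not defined:
        raise ValueError("silhouette undefined for every lambda in the grid")
    best_score = max(s for _, s in defined)
    lam_star = min(lam for lam, s in defined if s == best_score)
    return lam_star, table
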