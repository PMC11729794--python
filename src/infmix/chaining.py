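"""The chaining model family: exemplar, 1-nearest-neighbor, prototype and
infinite mixture, unified through one similarity kernel over cluster
centroids.

A head-relation category (e.g. *store* + direct object) is represented at
time ``t`` by a set of centroids ``M = {mu_1, ..., mu_K}`` inferred from its
support nouns' embeddings. The similarity of a query noun ``q`` to the
category is the mean negative-exponential squared Euclidean distance

    sim(q, M) = (1/K) * sum_k exp(-||phi(q) - mu_k||^2 / beta),

with sensitivity ``beta`` controlling how fast similarity decays with
distance (the Generalized Context Model kernel). The four model kinds
differ only in how the centroids are formed:

* ``exemplar``  — every support vector is its own centroid (K = |S|);
* ``onenn``     — support vectors are the centroids but the kernel takes the
  max term instead of the mean (1-nearest-neighbor chaining);
* ``prototype`` — a single centroid, the mean support vector (K = 1);
* ``infmix``    — centroids from DP-means at penalty ``lam``, run in a
  PCA-reduced space with centroids re-averaged in the full space.

The infinite mixture model interpolates between the extremes: ``lam = 0``
reproduces the exemplar model exactly and ``lam`` above the maximum
pairwise squared distance (in the clustering space) reproduces the
prototype model.

Head prediction scores a query noun against many candidate categories
(normalized over candidates); argument prediction scores many candidate
nouns against one category with a frequency prior ``N(w, r)^t`` — a prior
that is constant across the candidate nouns of a fixed category and so
leaves their ranking equal to the similarity ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .dpmeans import dp_means
from .embeddings import Projection

__all__ = [
    "ChainingConfig",
    "Category",
    "ChainingModel",
    "infer_centroids",
    "similarity",
    "head_scores",
    "argument_scores",
    "fit_beta",
]

ModelKind = Literal["exemplar", "onenn", "prototype", "infmix"]
MODEL_KINDS: tuple[str, ...] = ("exemplar", "onenn", "prototype", "infmix")


@dataclass
class ChainingConfig:
    """Model kind plus its parameters.

    ``lam`` is the DP-means memory penalty (used by ``infmix`` only),
    ``beta`` the similarity sensitivity, and ``reduced_dim`` the PCA
    dimensionality used for clustering (centroids are still full-space).
    """

    kind: str = "infmix"
    lam: float = 0.24
    beta: float = 0.45
    reduced_dim: int = 30

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.lam < 0:
            raise ValueError("lam must be non-negative")


@dataclass
class Category:
    """A head-relation pair with its dated support set.

    ``support`` maps each support argument to the bin of its first
    attestation above threshold; ``frequency`` holds the cumulative head
    count N(w, r)^t per bin.
    """

    head: str
    relation: str
    support: dict[str, int] = field(default_factory=dict)
    frequency: dict[int, int] = field(default_factory=dict)
    queries: dict[int, list[str]] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, str]:
        return (self.head, self.relation)

    def support_at(self, t: int) -> list[str]:
        """Support arguments attested (above threshold) strictly before bin t."""
        return sorted(w for w, b in self.support.items() if b <= t)

    def frequency_at(self, t: int) -> int:
        """Cumulative head-relation count through bin t."""
        return sum(c for b, c in self.frequency.items() if b <= t)


class ChainingModel(BaseEstimator):
    """Scikit-learn style estimator for one chaining model.

    ``fit`` consumes the support vectors of a single category (optionally
    with a parallel reduced-space matrix for clustering) and infers the
    centroid representation; ``score_queries`` evaluates the similarity
    kernel for query vectors.

    Parameters
    ----------
    kind : {"exemplar", "onenn", "prototype", "infmix"}
    lam : float
        DP-means penalty; only used when ``kind="infmix"``.
    beta : float
        Kernel sensitivity (> 0).

    Attributes
    ----------
    centroids_ : ndarray of shape (K, d)
        Full-space centroid matrix.
    n_centroids_ : int
    labels_ : ndarray or None
        Cluster label per support vector (infmix only).
    """

    def __init__(self, kind: str = "infmix", lam: float = 0.24, beta: float = 0.45):
        self.kind = kind
        self.lam = lam
        self.beta = beta

    def fit(
        self,
        X: np.ndarray,
        y: None = None,
        *,
        X_reduced: np.ndarray | None = None,
    ) -> "ChainingModel":
        """Infer centroids from support vectors ``X`` (one row per item).

        ``X_reduced`` supplies the clustering-space coordinates for the
        infmix model; when omitted, clustering runs on ``X`` itself.
        """
        config = ChainingConfig(kind=self.kind, lam=self.lam, beta=self.beta)
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[0] == 0:
            raise ValueError("empty support set")
        self.labels_ = None
        if config.kind in ("exemplar", "onenn"):
            self.centroids_ = X.copy()
        elif config.kind == "prototype":
            self.centroids_ = X.mean(axis=0, keepdims=True)
        else:  # infmix
            space = X if X_reduced is None else np.atleast_2d(np.asarray(X_reduced))
            if space.shape[0] != X.shape[0]:
                raise ValueError("X_reduced must align with X row for row")
            clustering = dp_means(space, config.lam)
            self.labels_ = clustering.labels_
            self.centroids_ = np.vstack(
                [
                    X[self.labels_ == k].mean(axis=0)
                    for k in range(clustering.n_clusters_)
                ]
            )
        self.n_centroids_ = self.centroids_.shape[0]
        return self

    def score_queries(self, Q: np.ndarray) -> np.ndarray:
        """Kernel similarity of each query row to the fitted category."""
        check_is_fitted(self, "centroids_")
        return similarity(Q, self.centroids_, self.beta, kind=self.kind)


def infer_centroids(
    support_vectors: np.ndarray,
    config: ChainingConfig,
    projection: Projection | None = None,
) -> np.ndarray:
    """Centroids for one category under ``config``.

    For the infinite mixture model the DP-means labels are computed on the
    PCA-projected vectors (when a projection is given) while the returned
    centroids are means of the *full-space* vectors per label.
    """
    reduced = None
    if config.kind == "infmix" and projection is not None:
        reduced = projection.transform(np.atleast_2d(support_vectors))
    model = ChainingModel(kind=config.kind, lam=config.lam, beta=config.beta)
    model.fit(support_vectors, X_reduced=reduced)
    return model.centroids_


def similarity(
    query: np.ndarray,
    centroids: np.ndarray,
    beta: float,
    kind: str = "infmix",
) -> np.ndarray | float:
    """Mean (or, for ``onenn``, max) of exp(-||q - mu_k||^2 / beta).

    Accepts a single query vector or a matrix of queries; returns a scalar
    or a vector accordingly. Values lie in (0, 1].
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    centroids = np.atleast_2d(np.asarray(centroids, dtype=np.float64))
    if centroids.shape[0] == 0:
        raise ValueError("centroid set is empty")
    query = np.asarray(query, dtype=np.float64)
    squeeze = query.ndim == 1
    Q = np.atleast_2d(query)
    if Q.shape[1] != centroids.shape[1]:
        raise ValueError("query / centroid dimension mismatch")
    # (n_query, K) squared distances
    d2 = (
        np.einsum("ij,ij->i", Q, Q)[:, None]
        - 2.0 * Q @ centroids.T
        + np.einsum("ij,ij->i", centroids, centroids)[None, :]
    )
    np.maximum(d2, 0.0, out=d2)
    kernel = np.exp(-d2 / beta)
    sims = kernel.max(axis=1) if kind == "onenn" else kernel.mean(axis=1)
    return float(sims[0]) if squeeze else sims


def _log_similarity(
    query: np.ndarray, centroids: np.ndarray, beta: float, kind: str
) -> np.ndarray:
    """log of the kernel similarity, stable under exp underflow."""
    centroids = np.atleast_2d(np.asarray(centroids, dtype=np.float64))
    Q = np.atleast_2d(np.asarray(query, dtype=np.float64))
    if Q.shape[1] != centroids.shape[1]:
        raise ValueError("query / centroid dimension mismatch")
    d2 = (
        np.einsum("ij,ij->i", Q, Q)[:, None]
        - 2.0 * Q @ centroids.T
        + np.einsum("ij,ij->i", centroids, centroids)[None, :]
    )
    np.maximum(d2, 0.0, out=d2)
    if kind == "onenn":
        return (-d2 / beta).max(axis=1)
    return logsumexp(-d2 / beta, axis=1) - np.log(centroids.shape[0])


def head_scores(
    query_vector: np.ndarray,
    candidate_centroids: Sequence[np.ndarray],
    beta: float,
    kind: str = "infmix",
) -> np.ndarray:
    """Normalized head-prediction scores for one query over candidate
    categories, each given by its centroid matrix. Scores sum to 1.

    Normalization happens in the log domain so that very small sensitivity
    values (where every raw similarity underflows) still yield a proper
    distribution.
    """
    if len(candidate_centroids) == 0:
        raise ValueError("candidate list is empty")
    if beta <= 0:
        raise ValueError("beta must be positive")
    logs = np.array(
        [_log_similarity(query_vector, M, beta, kind)[0]
         for M in candidate_centroids]
    )
    w = np.exp(logs - logs.max())
    return w / w.sum()


def argument_scores(
    candidate_vectors: np.ndarray,
    centroids: np.ndarray,
    beta: float,
    kind: str = "infmix",
    prior: float = 1.0,
) -> np.ndarray:
    """Normalized argument-prediction scores for candidate nouns against one
    category.

    The unnormalized score is ``prior * sim(noun, M)`` with ``prior`` the
    category's cumulative frequency N(w, r)^t. Because the prior does not
    vary across the candidate nouns of a fixed category, it cancels in the
    normalization and the ranking equals the similarity ranking.
    """
    if prior <= 0:
        raise ValueError("frequency prior must be positive")
    if beta <= 0:
        raise ValueError("beta must be positive")
    centroids = np.atleast_2d(np.asarray(centroids, dtype=np.float64))
    if centroids.shape[0] == 0:
        raise ValueError("centroid set is empty")
    logs = _log_similarity(np.atleast_2d(candidate_vectors), centroids, beta, kind)
    w = np.exp(logs - logs.max())  # prior cancels in the normalization
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("zero total score over candidates")
    return w / total


@dataclass
class BetaFitResult:
    beta: float
    objective: float
    mode: str


def _beta_objective(
    beta: float,
    trials: Sequence[tuple[np.ndarray, Sequence[np.ndarray], int]],
    kind: str,
) -> float:
    """Mean normalized predicted probability of the true candidate."""
    probs = []
    for query, cand_centroids, truth_idx in trials:
        scores = head_scores(query, cand_centroids, beta, kind=kind)
        probs.append(scores[truth_idx])
    return float(np.mean(probs))


def fit_beta(
    trials: Sequence[tuple[np.ndarray, Sequence[np.ndarray], int]],
    kind: str = "infmix",
    beta_range: tuple[float, float] = (1e-3, 100.0),
    n_grid: int = 25,
    mode: str = "grid",
    sgd_steps: int = 200,
    sgd_lr: float = 0.3,
    seed: int = 0,
) -> BetaFitResult:
    """Tune the sensitivity ``beta`` to maximize the mean normalized
    probability assigned to the true answer across trials.

    Each trial is ``(query_vector, candidate_centroid_list, truth_index)``.
    The default optimizer is deterministic: a coarse log-spaced grid scan
    followed by bounded golden-section refinement. ``mode="sgd"`` instead
    runs stochastic gradient ascent on log(beta) with a central-difference
    gradient on shuffled mini-batches, seeded for reproducibility; both
    optimizers target the same objective and agree closely on smooth
    problems.
    """
    if len(trials) == 0:
        raise ValueError("need at least one trial")
    lo, hi = beta_range
    if not (0 < lo < hi):
        raise ValueError("beta search interval must be positive and ordered")
    obj = lambda b: _beta_objective(b, trials, kind)

    grid = np.geomspace(lo, hi, n_grid)
    values = np.array([obj(b) for b in grid])
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite objective on the beta grid")
    i = int(np.argmax(values))

    if mode == "grid":
        lo_b = grid[max(i - 1, 0)]
        hi_b = grid[min(i + 1, n_grid - 1)]
        if lo_b < hi_b:
            res = minimize_scalar(
                lambda b: -obj(b), bounds=(lo_b, hi_b), method="bounded",
                options={"xatol": 1e-6},
            )
            best_b, best_v = float(res.x), float(-res.fun)
            if best_v < values[i]:  # guard against a flat bracket
                best_b, best_v = float(grid[i]), float(values[i])
        else:
            best_b, best_v = float(grid[i]), float(values[i])
        return BetaFitResult(beta=best_b, objective=best_v, mode="grid")

    if mode != "sgd":
        raise ValueError(f"unknown optimizer mode {mode!r}")
    rng = np.random.default_rng(seed)
    log_b = float(np.log(grid[i]))  # warm start at the coarse-grid best
    batch = max(1, len(trials) // 4)
    eps = 1e-3
    for step in range(sgd_steps):
        idx = rng.choice(len(trials), size=batch, replace=False)
        sub = [trials[j] for j in idx]
        up = _beta_objective(np.exp(log_b + eps), sub, kind)
        dn = _beta_objective(np.exp(log_b - eps), sub, kind)
        grad = (up - dn) / (2 * eps)
        log_b += sgd_lr / (1 + 0.05 * step) * grad
        log_b = float(np.clip(log_b, np.log(lo), np.log(hi)))
    beta = float(np.exp(log_b))
    return BetaFitResult(beta=beta, objective=obj(beta), mode="sgd")
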