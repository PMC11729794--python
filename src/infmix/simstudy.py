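"""Two-category Gaussian-mixture simulation of category extension.

Two competing categories are each generated from a planted Gaussian
mixture in 2-D: the number of components is drawn uniformly from 1..10,
component means from the uniform box [-1, 1]^2, all components isotropic
with shared variance (0.1 by default), components equiprobable, N = 500
points per category. A chaining model sees 80% of each category's points,
infers its centroid representation, and classifies each held-out point to
the category of higher kernel similarity. Plotting accuracy against
normalized complexity (inferred clusters / training size) traces the
efficiency trade-off: the prototype sits at minimal memory and near-chance
accuracy on multi-component structure, the exemplar at maximal memory, and
intermediate mixtures typically match the exemplar's accuracy at a
fraction of its memory.

The model spectrum is swept in two modes: ``k`` (default) pins the number
of centroids directly via constrained squared-loss clustering (K-means),
reproducing a 1..N_train-by-10 spectrum; ``lam`` sweeps the DP-means
penalty and records the K it induces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment, minimize_scalar
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted

from .dpmeans import dp_means

__all__ = [
    "SimCategorySpec",
    "gen_category",
    "gen_two_categories",
    "GaussianCategoryClassifier",
    "run_sim",
    "centroid_recovery",
]


@dataclass
class SimCategorySpec:
    """Ground truth for one simulated category."""

    means: np.ndarray  # (G, 2) component means in [-1, 1]^2
    variance: float = 0.1
    n_points: int = 500

    def __post_init__(self) -> None:
        self.means = np.atleast_2d(np.asarray(self.means, dtype=np.float64))
        if self.variance <= 0:
            raise ValueError("variance must be positive")
        if not (1 <= len(self.means) <= 10):
            raise ValueError("component count must lie in [1, 10]")

    @property
    def n_components(self) -> int:
        return len(self.means)


def random_spec(
    rng: np.random.Generator,
    n_components: int | None = None,
    variance: float = 0.1,
    n_points: int = 500,
    min_separation: float = 0.0,
) -> SimCategorySpec:
    """Draw a category spec: G ~ U{1..10} unless given, means ~ U[-1,1]^2.

    ``min_separation`` enforces a minimum pairwise distance between
    component means via rejection sampling (used by recovery experiments).
    """
    g = int(rng.integers(1, 11)) if n_components is None else n_components
    for _ in range(10_000):
        means = rng.uniform(-1, 1, size=(g, 2))
        if g == 1 or min_separation <= 0:
            break
        d = cdist(means, means)
        if d[np.triu_indices(g, 1)].min() >= min_separation:
            break
    else:
        raise ValueError("could not place components at requested separation")
    return SimCategorySpec(means=means, variance=variance, n_points=n_points)


def gen_category(spec: SimCategorySpec, rng: np.random.Generator) -> np.ndarray:
    """Sample points from the spec's equiprobable isotropic mixture."""
    comp = rng.integers(spec.n_components, size=spec.n_points)
    noise = rng.normal(0.0, np.sqrt(spec.variance), size=(spec.n_points, 2))
    return spec.means[comp] + noise


def gen_two_categories(
    seed: int = 0,
    specs: tuple[SimCategorySpec, SimCategorySpec] | None = None,
    variance: float = 0.1,
    n_points: int = 500,
) -> tuple[np.ndarray, np.ndarray, tuple[SimCategorySpec, SimCategorySpec]]:
    """Generate the two competing categories (points_a, points_b, specs)."""
    rng = np.random.default_rng(seed)
    if specs is None:
        specs = (
            random_spec(rng, variance=variance, n_points=n_points),
            random_spec(rng, variance=variance, n_points=n_points),
        )
    return gen_category(specs[0], rng), gen_category(specs[1], rng), specs


class GaussianCategoryClassifier(ClassifierMixin, BaseEstimator):
    """Two-class (or multi-class) classifier over chaining representations.

    Each class's training points are summarized by centroids — all points
    (``exemplar``), their mean (``prototype``), DP-means clusters
    (``infmix`` with penalty ``lam``), or exactly ``n_centroids`` K-means
    clusters (``fixed_k``) — and a test point is assigned to the class of
    higher mean exponential kernel similarity. ``beta="fit"`` tunes the
    sensitivity on the training points by bounded search; a float fixes it.
    """

    def __init__(
        self,
        kind: str = "infmix",
        lam: float = 0.1,
        n_centroids: int | None = None,
        beta: float | str = "fit",
        random_state: int = 0,
    ):
        self.kind = kind
        self.lam = lam
        self.n_centroids = n_centroids
        self.beta = beta
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GaussianCategoryClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.centroids_: dict = {}
        for c in self.classes_:
            pts = X[y == c]
            if self.kind == "exemplar":
                M = pts
            elif self.kind == "prototype":
                M = pts.mean(axis=0, keepdims=True)
            elif self.kind == "fixed_k":
                k = min(self.n_centroids or 1, len(pts))
                if k == 1:
                    M = pts.mean(axis=0, keepdims=True)
                elif k >= len(pts):
                    M = pts
                else:
                    km = KMeans(n_clusters=k, n_init=3,
                                random_state=self.random_state).fit(pts)
                    M = km.cluster_centers_
            elif self.kind == "infmix":
                M = dp_means(pts, self.lam).cluster_centers_
            else:
                raise ValueError(f"unknown kind {self.kind!r}")
            self.centroids_[c] = M
        self.beta_ = (
            self._fit_beta(X, y) if self.beta == "fit" else float(self.beta)
        )
        self.n_centroids_ = float(
            np.mean([len(M) for M in self.centroids_.values()])
        )
        return self

    def _class_similarities(self, X: np.ndarray, beta: float) -> np.ndarray:
        sims = np.empty((len(X), len(self.classes_)))
        for j, c in enumerate(self.classes_):
            d2 = cdist(X, self.centroids_[c], metric="sqeuclidean")
            sims[:, j] = np.exp(-d2 / beta).mean(axis=1)
        return sims

    def _fit_beta(self, X: np.ndarray, y: np.ndarray) -> float:
        # Squared distances to each class's centroids are computed once;
        # each beta evaluation is then a cheap exp + mean. A training point
        # that is itself a stored centroid of its own class (exemplar-like
        # representations) is excluded from that class's kernel mean
        # (leave-one-out), otherwise the self term at distance zero drives
        # beta toward zero.
        d2 = {
            c: cdist(X, self.centroids_[c], metric="sqeuclidean")
            for c in self.classes_
        }
        y_idx = np.searchsorted(self.classes_, y)
        weights = {}
        for c in self.classes_:
            w = np.ones_like(d2[c])
            if len(self.centroids_[c]) > 1:
                own = (y == c)[:, None] & (d2[c] <= 1e-18)
                w[own] = 0.0
            weights[c] = w / w.sum(axis=1, keepdims=True)

        def neg_mean_prob(log_beta: float) -> float:
            beta = np.exp(log_beta)
            sims = np.column_stack(
                [(np.exp(-d2[c] / beta) * weights[c]).sum(axis=1)
                 for c in self.classes_]
            )
            total = sims.sum(axis=1)
            total[total == 0] = np.finfo(float).tiny
            probs = sims[np.arange(len(X)), y_idx] / total
            return -float(probs.mean())

        res = minimize_scalar(
            neg_mean_prob, bounds=(np.log(1e-3), np.log(10.0)),
            method="bounded", options={"xatol": 1e-3},
        )
        return float(np.exp(res.x))

    def predict(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "centroids_")
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        sims = self._class_similarities(X, self.beta_)
        return self.classes_[sims.argmax(axis=1)]

    def score(self, X: np.ndarray, y: np.ndarray, sample_weight=None) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


def _split(
    points: np.ndarray, frac: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    n = len(points)
    n_train = int(round(frac * n))
    if n_train in (0, n):
        raise ValueError("degenerate train/test split")
    perm = rng.permutation(n)
    return points[perm[:n_train]], points[perm[n_train:]]


def run_sim(
    points_a: np.ndarray,
    points_b: np.ndarray,
    train_frac: float = 0.8,
    k_grid: Sequence[int] | None = None,
    lam_grid: Sequence[float] | None = None,
    beta: float | str = "fit",
    split_seed: int = 0,
) -> pd.DataFrame:
    """Evaluate the model spectrum on one generated dataset.

    Splits each category (stratified) into train/test, fits every model on
    the training points and reports test accuracy and normalized complexity
    K / N_train per model. The spectrum always contains the prototype and
    exemplar endpoints; intermediate models come from ``k_grid``
    (fixed-centroid-count mode, default 10..N_train step 10) and/or
    ``lam_grid`` (DP-means penalty mode).
    """
    rng = np.random.default_rng(split_seed)
    a_tr, a_te = _split(np.asarray(points_a, float), train_frac, rng)
    b_tr, b_te = _split(np.asarray(points_b, float), train_frac, rng)
    X_tr = np.vstack([a_tr, b_tr])
    y_tr = np.array([0] * len(a_tr) + [1] * len(b_tr))
    X_te = np.vstack([a_te, b_te])
    y_te = np.array([0] * len(a_te) + [1] * len(b_te))
    n_train = min(len(a_tr), len(b_tr))

    if k_grid is None and lam_grid is None:
        k_grid = range(10, n_train + 1, 10)

    rows = []

    def add(model: str, clf: GaussianCategoryClassifier, lam=np.nan, k=np.nan):
        clf.fit(X_tr, y_tr)
        rows.append(
            {
                "model": model,
                "lam": lam,
                "k_requested": k,
                "mean_centroids": clf.n_centroids_,
                "complexity": clf.n_centroids_ / n_train,
                "accuracy": clf.score(X_te, y_te),
                "beta": clf.beta_,
            }
        )

    add("prototype", GaussianCategoryClassifier(kind="prototype", beta=beta))
    add("exemplar", GaussianCategoryClassifier(kind="exemplar", beta=beta))
    for k in k_grid or []:
        add(
            "infmix",
            GaussianCategoryClassifier(kind="fixed_k", n_centroids=int(k),
                                       beta=beta),
            k=int(k),
        )
    for lam in lam_grid or []:
        add(
            "infmix",
            GaussianCategoryClassifier(kind="infmix", lam=float(lam), beta=beta),
            lam=float(lam),
        )
    return pd.DataFrame(rows)


def centroid_recovery(
    inferred: np.ndarray, true_means: np.ndarray
) -> tuple[float, int]:
    """Mean Euclidean error over optimally matched centroid pairs, plus the
    cardinality gap |K_inferred - G|.

    Matching is the minimum-cost one-to-one assignment; when the two sets
    differ in size, the surplus centroids are left unmatched and reported
    only through the gap.
    """
    inferred = np.atleast_2d(np.asarray(inferred, float))
    true_means = np.atleast_2d(np.asarray(true_means, float))
    if len(inferred) == 0 or len(true_means) == 0:
        raise ValueError("both centroid sets must be non-empty")
    cost = cdist(inferred, true_means)
    ri, ci = linear_sum_assignment(cost)
    mean_err = float(cost[ri, ci].mean())
    gap = abs(len(inferred) - len(true_means))
    return mean_err, gap
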