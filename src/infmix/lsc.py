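"""Centroid-based lexical semantic change (LSC) scoring.

A target word's usages in each of two periods are given as precomputed
contextual embedding matrices (one row per usage occurrence; any upstream
encoder). DP-means clusters each period's usages into sense centroids
``H1`` and ``H2``, and the change score is derived from the mean pairwise
cosine similarity between the two centroid sets:

    m = (1 / (|H1| |H2|)) * sum_{h1, h2} cos(h1, h2)

``mode="distance"`` (default) reports ``1 - m`` so that larger scores mean
more change; ``mode="similarity"`` reports ``m`` itself. The two modes rank
words in exactly reversed order. Setting the DP-means penalty to zero
gives an exemplar-based LSC model (every usage its own centroid); a large
penalty gives a prototype-based one (one centroid per period). In between,
the penalty is selected by the mean silhouette of the per-word clusterings,
and the selected model is evaluated by Spearman rank correlation against
gold human change judgments (two-column lemma/score tables, as in
SemEval-2020 Task 1 subtask 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .dpmeans import dp_means, mean_silhouette

__all__ = [
    "UsageSet",
    "ChangeScore",
    "load_usage_sets",
    "load_gold_scores",
    "lsc_score",
    "rank_words",
    "spearman_eval",
]


@dataclass
class UsageSet:
    """Usage-occurrence embedding matrix for one (word, period)."""

    word: str
    period: str
    vectors: np.ndarray  # (n_usages, d)

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=np.float64))
        if self.vectors.shape[0] < 1:
            raise ValueError(f"{self.word}/{self.period}: empty usage set")
        norms = np.linalg.norm(self.vectors, axis=1)
        if np.any(norms == 0):
            raise ValueError(f"{self.word}/{self.period}: zero-norm usage row")


@dataclass
class ChangeScore:
    word: str
    score: float
    k1: int
    k2: int
    lam: float
    mode: str


def load_usage_sets(directory: str | Path) -> dict[tuple[str, str], UsageSet]:
    """Load every ``<word>.<period>.mat`` delimited matrix in a directory."""
    out: dict[tuple[str, str], UsageSet] = {}
    for path in sorted(Path(directory).glob("*.mat")):
        word, period = path.stem.rsplit(".", 1)
        out[(word, period)] = UsageSet(word, period, np.loadtxt(path, ndmin=2))
    if not out:
        raise FileNotFoundError(f"no .mat usage files under {directory}")
    return out


def load_gold_scores(path: str | Path) -> pd.Series:
    """Two-column TSV (lemma, score) -> Series indexed by lemma."""
    df = pd.read_csv(path, sep="\t", names=["lemma", "score"], header=None)
    return df.set_index("lemma")["score"].astype(float)


def _centroid_cosine_mean(h1: np.ndarray, h2: np.ndarray) -> float:
    u = h1 / np.linalg.norm(h1, axis=1, keepdims=True)
    v = h2 / np.linalg.norm(h2, axis=1, keepdims=True)
    return float((u @ v.T).mean())


def lsc_score(
    usages1: UsageSet | np.ndarray,
    usages2: UsageSet | np.ndarray,
    lam: float,
    mode: str = "distance",
    normalize: bool = False,
) -> ChangeScore:
    """Change score between two periods' usage sets at DP-means penalty
    ``lam``.

    ``normalize=True`` length-normalizes usage vectors before clustering
    (off by default; clustering is Euclidean, scoring is cosine either
    way). The score is symmetric in its two arguments.
    """
    if mode not in ("distance", "similarity"):
        raise ValueError(f"unknown mode {mode!r}")
    if lam < 0:
        raise ValueError("lam must be non-negative")
    word = usages1.word if isinstance(usages1, UsageSet) else "?"
    X1 = usages1.vectors if isinstance(usages1, UsageSet) else np.atleast_2d(usages1)
    X2 = usages2.vectors if isinstance(usages2, UsageSet) else np.atleast_2d(usages2)
    if normalize:
        X1 = X1 / np.linalg.norm(X1, axis=1, keepdims=True)
        X2 = X2 / np.linalg.norm(X2, axis=1, keepdims=True)
    h1 = dp_means(X1, lam).cluster_centers_
    h2 = dp_means(X2, lam).cluster_centers_
    m = _centroid_cosine_mean(h1, h2)
    score = (1.0 - m) if mode == "distance" else m
    return ChangeScore(word=word, score=score, k1=len(h1), k2=len(h2),
                       lam=lam, mode=mode)


def rank_words(
    usage_sets: Mapping[tuple[str, str], UsageSet],
    lam_grid: Sequence[float],
    periods: tuple[str, str] | None = None,
    mode: str = "distance",
    normalize: bool = False,
) -> tuple[pd.DataFrame, float]:
    """Score every word at the silhouette-selected penalty.

    The penalty is chosen to maximize the mean silhouette over all per-word
    per-period clusterings (both periods pooled into the candidate set of
    support sets), then every word is scored at that penalty. Returns a
    DataFrame sorted by descending score plus the selected lambda.
    """
    words = sorted({w for (w, _) in usage_sets})
    if len(words) < 2:
        raise ValueError("need at least 2 words to rank")
    if periods is None:
        ps = sorted({p for (_, p) in usage_sets})
        if len(ps) != 2:
            raise ValueError(f"expected exactly 2 periods, found {ps}")
        periods = (ps[0], ps[1])

    def prep(X: np.ndarray) -> np.ndarray:
        return X / np.linalg.norm(X, axis=1, keepdims=True) if normalize else X

    # silhouette-based selection over all per-word clusterings
    lam_grid = list(lam_grid)
    table = []
    for lam in lam_grid:
        scores = []
        for key in sorted(usage_sets):
            X = prep(usage_sets[key].vectors)
            if len(X) < 2:
                continue
            model = dp_means(X, lam)
            s = mean_silhouette(X, model.labels_)
            if s is not None:
                scores.append(s)
        table.append((lam, float(np.mean(scores)) if scores else None))
    defined = [(lam, s) for lam, s in table if s is not None]
    if not defined:
        raise ValueError("silhouette undefined at every lambda in the grid")
    best = max(s for _, s in defined)
    lam_star = min(lam for lam, s in defined if s == best)

    rows = []
    for w in words:
        cs = lsc_score(
            usage_sets[(w, periods[0])], usage_sets[(w, periods[1])],
            lam_star, mode=mode, normalize=normalize,
        )
        rows.append({"word": w, "score": cs.score, "k1": cs.k1, "k2": cs.k2,
                     "lam": lam_star, "mode": mode})
    df = pd.DataFrame(rows).sort_values("score", ascending=False,
                                        kind="mergesort").reset_index(drop=True)
    return df, lam_star


def spearman_eval(
    predicted: Mapping[str, float] | pd.Series,
    gold: Mapping[str, float] | pd.Series,
) -> tuple[float, float]:
    """Spearman rank correlation (tie-corrected) on the word intersection."""
    pred = pd.Series(predicted, dtype=float)
    gold = pd.Series(gold, dtype=float)
    common = pred.index.intersection(gold.index)
    if len(common) < 3:
        raise ValueError(f"only {len(common)} overlapping words; need >= 3")
    rho, p = spearmanr(pred.loc[common], gold.loc[common])
    return float(rho), float(p)
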