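"""Diachronic category construction and temporal prediction experiments.

The input is a stream of head-relation-argument co-occurrence tuples with
per-bin counts (the layout derived from Google Syntactic N-grams style
resources). From it we build time-varying categories: for a head-relation
pair (w, r) and bin ``t``,

* the **support set** holds arguments whose cumulative count with (w, r)
  strictly before ``t`` exceeds ``theta_s`` (conventionalized usages), and
* the **query set** at ``t`` holds arguments whose cumulative count through
  ``t`` is at most ``theta_q`` but exceeds ``theta_q`` through ``t + delta``
  (usages that emerge and conventionalize at the next step).

A category enters evaluation at a bin only when it has at least
``min_support`` supports and ``min_query`` queries there. Each retained
query becomes a forced-choice trial: the truth plus ``m - 1`` negatives
sampled (seeded, without replacement) from a pool of items never attested
with the target. Models are scored by the fraction of trials whose truth
receives a strictly higher score than every negative; ties count as
failures so a degenerate constant scorer earns ~1/m.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .chaining import (
    Category,
    ChainingConfig,
    argument_scores,
    head_scores,
    infer_centroids,
)
from .embeddings import Projection, TimeSlicedEmbeddings, fit_projection

__all__ = [
    "DatasetConfig",
    "Trial",
    "read_tuples",
    "build_categories",
    "HistoricalEvaluator",
    "make_trials",
    "evaluate",
    "memory_complexity",
    "tradeoff_sweep",
]

logger = logging.getLogger(__name__)

TUPLE_COLUMNS = ["head", "pos", "relation", "argument", "bin", "count"]


@dataclass
class DatasetConfig:
    """Thresholds and caps for building categories from a tuple stream.

    ``delta`` is the bin width in years, ``theta_q`` / ``theta_s`` the
    query / support cumulative-count thresholds, and the caps mirror the
    corpus-level pruning (top-N nouns, minimum head count, top-K relations);
    caps of ``None`` disable pruning.
    """

    delta: int = 10
    theta_q: int = 10
    theta_s: int = 100
    min_support: int = 10
    min_query: int = 1
    top_nouns: int | None = None
    min_head_count: int | None = None
    top_relations: int | None = None

    def __post_init__(self) -> None:
        if not (self.theta_s > self.theta_q > 0):
            raise ValueError("need theta_s > theta_q > 0")
        if self.delta <= 0:
            raise ValueError("delta must be positive")


@dataclass
class Trial:
    """One forced-choice prediction trial.

    ``mode="argument"``: candidates are nouns, the category is fixed.
    ``mode="head"``: candidates are (head, relation) keys, the query noun is
    fixed.
    """

    time_bin: int
    mode: Literal["head", "argument"]
    truth: object
    candidates: list
    category: tuple[str, str] | None = None
    query_word: str | None = None

    def __post_init__(self) -> None:
        if self.truth not in self.candidates:
            raise ValueError("truth must be among the candidates")
        if len(set(map(str, self.candidates))) != len(self.candidates):
            raise ValueError("candidates must be unique")


def read_tuples(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated tuple file (head, POS, relation, argument, bin,
    count); transparently handles gzip via the file extension."""
    df = pd.read_csv(
        path,
        sep="\t",
        names=TUPLE_COLUMNS,
        header=None,
        compression="infer",
        dtype={"head": str, "pos": str, "relation": str, "argument": str},
    )
    df["bin"] = df["bin"].astype(int)
    df["count"] = df["count"].astype(int)
    if (df["count"] < 0).any():
        raise ValueError("negative counts in tuple stream")
    return df


def _apply_caps(records: pd.DataFrame, config: DatasetConfig) -> pd.DataFrame:
    df = records
    if config.top_relations is not None:
        keep = (
            df.groupby("relation")["count"].sum().nlargest(config.top_relations).index
        )
        df = df[df["relation"].isin(keep)]
    if config.top_nouns is not None:
        keep = df.groupby("argument")["count"].sum().nlargest(config.top_nouns).index
        df = df[df["argument"].isin(keep)]
    if config.min_head_count is not None:
        totals = df.groupby("head")["count"].sum()
        df = df[df["head"].isin(totals[totals >= config.min_head_count].index)]
    return df


def build_categories(
    records: pd.DataFrame, config: DatasetConfig | None = None
) -> dict[tuple[str, str], Category]:
    """Build dated support/query sets for every head-relation pair.

    Returns a map from (head, relation) to a :class:`Category` whose
    ``support`` maps each argument to the first bin at which it qualifies as
    support, ``queries`` maps each evaluation bin to its emergent arguments,
    and ``frequency`` holds per-bin summed counts. Only bins passing the
    ``min_support`` / ``min_query`` retention rule appear in ``queries``.
    """
    config = config or DatasetConfig()
    if len(records) == 0:
        raise ValueError("empty record stream")
    records = _apply_caps(records, config)
    bins = np.sort(records["bin"].unique())
    if len(bins) > 1 and np.any(np.diff(bins) % config.delta != 0):
        raise ValueError(f"bins {bins} not alignable to delta={config.delta}")

    categories: dict[tuple[str, str], Category] = {}
    grouped = records.groupby(["head", "relation"], sort=True)
    for (head, rel), cat_df in grouped:
        # per-argument cumulative counts over the global bin axis
        pivot = (
            cat_df.pivot_table(
                index="argument", columns="bin", values="count", aggfunc="sum"
            )
            .reindex(columns=bins)
            .fillna(0)
        )
        cum = pivot.cumsum(axis=1).to_numpy()  # (n_args, n_bins)
        args = list(pivot.index)
        cat = Category(head=head, relation=rel)
        cat.frequency = {
            int(b): int(c) for b, c in cat_df.groupby("bin")["count"].sum().items()
        }
        # first bin t at which cumulative count strictly before t > theta_s
        for i, arg in enumerate(args):
            for j in range(1, len(bins)):
                if cum[i, j - 1] > config.theta_s:
                    cat.support[arg] = int(bins[j])
                    break
        # queries: <= theta_q through t, > theta_q through t + delta
        for j in range(len(bins) - 1):
            t = int(bins[j])
            qs = [
                args[i]
                for i in range(len(args))
                if cum[i, j] <= config.theta_q and cum[i, j + 1] > config.theta_q
            ]
            supports = cat.support_at(t)
            if len(qs) >= config.min_query and len(supports) >= config.min_support:
                cat.queries[t] = sorted(qs)
        if cat.queries:
            categories[(head, rel)] = cat
    if not categories:
        logger.warning("no category survived the retention thresholds")
    return categories


class HistoricalEvaluator:
    """Wires categories, time-sliced embeddings, per-slice PCA projections
    and a centroid cache into one evaluation surface.

    The PCA projection for a bin is fit on that slice's analysis vocabulary
    (all support, query and candidate words present in the slice), centering
    without scaling; clustering labels are computed in the projected space
    and centroids averaged in the full space.
    """

    def __init__(
        self,
        categories: dict[tuple[str, str], Category],
        embeddings: TimeSlicedEmbeddings,
        reduced_dim: int = 30,
        noun_frequencies: pd.DataFrame | None = None,
    ):
        self.categories = categories
        self.embeddings = embeddings
        self.reduced_dim = reduced_dim
        self._projections: dict[int, Projection] = {}
        self._centroid_cache: dict[tuple, np.ndarray] = {}
        # cumulative per-noun corpus frequency through each bin, for the
        # frequency baseline; derived from the tuple stream when given
        self._noun_cumfreq: dict[int, dict[str, int]] = {}
        if noun_frequencies is not None:
            per_bin = noun_frequencies.groupby(["bin", "argument"])["count"].sum()
            running: dict[str, int] = {}
            for b in sorted(noun_frequencies["bin"].unique()):
                for noun, c in per_bin.loc[b].items():
                    running[noun] = running.get(noun, 0) + int(c)
                self._noun_cumfreq[int(b)] = dict(running)

    # -- projections ----------------------------------------------------
    def projection_for(self, t: int) -> Projection | None:
        if self.reduced_dim is None:
            return None
        if t not in self._projections:
            slice_ = self.embeddings[t]
            vocab = self._analysis_vocabulary(t)
            matrix = slice_.get_matrix(vocab)
            k = min(self.reduced_dim, matrix.shape[0], matrix.shape[1])
            self._projections[t] = fit_projection(matrix, k=k)
        return self._projections[t]

    def _analysis_vocabulary(self, t: int) -> list[str]:
        slice_ = self.embeddings[t]
        vocab: set[str] = set()
        for cat in self.categories.values():
            vocab.update(cat.support_at(t))
            vocab.update(cat.queries.get(t, ()))
        vocab = {w for w in vocab if w in slice_}
        if len(vocab) < 2:  # fall back to the whole slice vocabulary
            return list(slice_.words)
        return sorted(vocab)

    # -- centroids ------------------------------------------------------
    def centroids_for(
        self, key: tuple[str, str], t: int, config: ChainingConfig
    ) -> np.ndarray | None:
        """Full-space centroid matrix for category ``key`` at bin ``t``;
        None when no support word has an embedding in the slice (logged)."""
        cache_key = (key, t, config.kind, config.lam, config.reduced_dim)
        if cache_key in self._centroid_cache:
            return self._centroid_cache[cache_key]
        cat = self.categories[key]
        slice_ = self.embeddings[t]
        support = [w for w in cat.support_at(t) if w in slice_]
        dropped = len(cat.support_at(t)) - len(support)
        if dropped:
            logger.debug("%s@%s: dropped %d support words missing from slice",
                         key, t, dropped)
        if not support:
            self._centroid_cache[cache_key] = None
            return None
        X = slice_.get_matrix(support)
        projection = (
            self.projection_for(t)
            if (config.kind == "infmix" and config.reduced_dim is not None)
            else None
        )
        centroids = infer_centroids(X, config, projection=projection)
        self._centroid_cache[cache_key] = centroids
        return centroids

    # -- baselines ------------------------------------------------------
    def noun_frequency(self, noun: str, t: int) -> int:
        bins = [b for b in self._noun_cumfreq if b <= t]
        if not bins:
            return 0
        return self._noun_cumfreq[max(bins)].get(noun, 0)


def make_trials(
    categories: dict[tuple[str, str], Category],
    embeddings: TimeSlicedEmbeddings,
    m: int = 100,
    mode: str = "argument",
    pool: Sequence | None = None,
    seed: int = 0,
    attested: dict | None = None,
) -> list[Trial]:
    """Build forced-choice trials for every (category, bin, query) item.

    ``pool`` is the candidate vocabulary (nouns for argument mode,
    (head, relation) keys for head mode); defaults to all nouns / all
    categories present. Negatives are drawn uniformly without replacement,
    excluding items attested with the target: in argument mode, nouns that
    ever co-occur with the category; in head mode, categories that ever take
    the query noun. ``attested`` may override the attestation map
    (category key -> set of nouns). Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    if attested is None:
        attested = {
            key: set(cat.support) | {q for qs in cat.queries.values() for q in qs}
            for key, cat in categories.items()
        }
    trials: list[Trial] = []
    if mode == "argument":
        if pool is None:
            pool = sorted({n for s in attested.values() for n in s})
        pool = list(pool)
        for key in sorted(categories):
            cat = categories[key]
            for t in sorted(cat.queries):
                slice_ = embeddings[t]
                eligible = [
                    n for n in pool if n not in attested[key] and n in slice_
                ]
                for q in cat.queries[t]:
                    if q not in slice_:
                        continue
                    if len(eligible) < m - 1:
                        raise ValueError(
                            f"pool too small for category {key} at {t}: "
                            f"{len(eligible)} eligible negatives, need {m - 1}"
                        )
                    negs = rng.choice(len(eligible), size=m - 1, replace=False)
                    cands = [q] + [eligible[i] for i in negs]
                    order = rng.permutation(m)
                    cands = [cands[i] for i in order]
                    trials.append(
                        Trial(time_bin=t, mode="argument", truth=q,
                              candidates=cands, category=key)
                    )
    elif mode == "head":
        if pool is None:
            pool = sorted(categories)
        pool = list(pool)
        for key in sorted(categories):
            cat = categories[key]
            for t in sorted(cat.queries):
                slice_ = embeddings[t]
                for q in cat.queries[t]:
                    if q not in slice_:
                        continue
                    eligible = [
                        k for k in pool
                        if q not in attested.get(k, set())
                        and categories[k].support_at(t)
                    ]
                    if len(eligible) < m - 1:
                        raise ValueError(
                            f"head pool too small for query {q!r} at {t}"
                        )
                    negs = rng.choice(len(eligible), size=m - 1, replace=False)
                    cands = [key] + [eligible[i] for i in negs]
                    order = rng.permutation(m)
                    cands = [cands[i] for i in order]
                    trials.append(
                        Trial(time_bin=t, mode="head", truth=key,
                              candidates=cands, query_word=q)
                    )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return trials


def _score_trial(
    trial: Trial, evaluator: HistoricalEvaluator, config: ChainingConfig
) -> np.ndarray | None:
    """Normalized score per candidate, or None if the trial is unscorable."""
    t = trial.time_bin
    slice_ = evaluator.embeddings[t]
    if trial.mode == "argument":
        centroids = evaluator.centroids_for(trial.category, t, config)
        if centroids is None:
            return None
        vecs = slice_.get_matrix(trial.candidates)
        cat = evaluator.categories[trial.category]
        prior = max(cat.frequency_at(t), 1)
        return argument_scores(vecs, centroids, config.beta, kind=config.kind,
                               prior=prior)
    # head mode: one similarity per candidate category
    query_vec = slice_[trial.query_word]
    kept, mats = [], []
    for key in trial.candidates:
        M = evaluator.centroids_for(key, t, config)
        if M is None:
            warnings.warn(f"candidate {key} has no centroids at {t}; excluded")
            if key == trial.truth:
                return None
            continue
        kept.append(key)
        mats.append(M)
    scores = head_scores(query_vec, mats, config.beta, kind=config.kind)
    full = np.zeros(len(trial.candidates))
    for k, s in zip(kept, scores):
        full[trial.candidates.index(k)] = s
    return full


@dataclass
class EvaluationResult:
    model: str
    aggregate: float
    by_bin: dict[int, float]
    n_trials: int
    details: pd.DataFrame | None = None


def evaluate(
    trials: Sequence[Trial],
    evaluator: HistoricalEvaluator,
    config: ChainingConfig,
    baselines: bool = True,
    seed: int = 0,
) -> dict[str, EvaluationResult]:
    """Score trials under ``config`` plus frequency and random baselines.

    A trial counts as correct only when the truth's score strictly exceeds
    every negative's score (ties fail). Returns per-model results keyed by
    model name; the frequency baseline picks the candidate with the highest
    cumulative corpus frequency through the trial's bin, the random baseline
    picks uniformly (seeded).
    """
    if len(trials) == 0:
        raise ValueError("no trials to evaluate")
    rng = np.random.default_rng(seed)
    correct = {config.kind: [], "frequency": [], "random": []}
    bins_of = []
    for trial in trials:
        scores = _score_trial(trial, evaluator, config)
        truth_idx = trial.candidates.index(trial.truth)
        bins_of.append(trial.time_bin)
        if scores is None:
            correct[config.kind].append(False)
        else:
            s_truth = scores[truth_idx]
            others = np.delete(scores, truth_idx)
            correct[config.kind].append(bool(np.all(s_truth > others)))
        if baselines:
            if trial.mode == "argument":
                freqs = np.array(
                    [evaluator.noun_frequency(c, trial.time_bin)
                     for c in trial.candidates], dtype=float)
            else:
                freqs = np.array(
                    [evaluator.categories[c].frequency_at(trial.time_bin)
                     for c in trial.candidates], dtype=float)
            f_truth = freqs[truth_idx]
            correct["frequency"].append(
                bool(np.all(f_truth > np.delete(freqs, truth_idx)))
            )
            pick = rng.integers(len(trial.candidates))
            correct["random"].append(pick == truth_idx)

    out: dict[str, EvaluationResult] = {}
    models = [config.kind] + (["frequency", "random"] if baselines else [])
    bins_arr = np.array(bins_of)
    for name in models:
        flags = np.array(correct[name], dtype=bool)
        by_bin = {
            int(b): float(flags[bins_arr == b].mean()) for b in np.unique(bins_arr)
        }
        out[name] = EvaluationResult(
            model=name, aggregate=float(flags.mean()), by_bin=by_bin,
            n_trials=len(trials),
        )
    return out


def memory_complexity(
    evaluator: HistoricalEvaluator,
    config: ChainingConfig,
    pairs: Sequence[tuple[tuple[str, str], int]] | None = None,
) -> float:
    """Mean number of stored centroids over (category, evaluation-bin) pairs.

    Exemplar gives the mean support-set size, prototype exactly 1, and the
    infinite mixture model a value in between governed by lambda.
    """
    if pairs is None:
        pairs = [
            (key, t)
            for key, cat in evaluator.categories.items()
            for t in cat.queries
        ]
    sizes = []
    for key, t in pairs:
        M = evaluator.centroids_for(key, t, config)
        if M is not None:
            sizes.append(M.shape[0])
    if not sizes:
        raise ValueError("no centroid sets available")
    return float(np.mean(sizes))


def tradeoff_sweep(
    lam_grid: Sequence[float],
    trials: Sequence[Trial],
    evaluator: HistoricalEvaluator,
    beta: float,
    reduced_dim: int | None = 30,
) -> pd.DataFrame:
    """Accuracy vs. memory complexity along the lambda spectrum.

    Produces one row per lambda plus labeled ``exemplar`` and ``prototype``
    endpoint rows, all evaluated on the same trials. Columns: model, lam,
    mean_centroids, accuracy.
    """
    rows = []
    endpoint_kinds = [("exemplar", None), ("prototype", None)]
    for kind, _ in endpoint_kinds:
        cfg = ChainingConfig(kind=kind, beta=beta, reduced_dim=reduced_dim)
        res = evaluate(trials, evaluator, cfg, baselines=False)[kind]
        rows.append(
            {"model": kind, "lam": np.nan,
             "mean_centroids": memory_complexity(evaluator, cfg),
             "accuracy": res.aggregate}
        )
    for lam in lam_grid:
        cfg = ChainingConfig(kind="infmix", lam=float(lam), beta=beta,
                             reduced_dim=reduced_dim)
        res = evaluate(trials, evaluator, cfg, baselines=False)["infmix"]
        rows.append(
            {"model": "infmix", "lam": float(lam),
             "mean_centroids": memory_complexity(evaluator, cfg),
             "accuracy": res.aggregate}
        )
    return pd.DataFrame(rows)
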