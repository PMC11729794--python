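"""Seeded synthetic-data generators with known ground truth.

These generators produce every external input the pipeline consumes —
time-sliced embedding tables, diachronic head-relation-argument tuple
streams, and paired usage-embedding sets — in the exact text formats the
readers expect, with planted structure recorded alongside:

* **Diachronic corpora**: each head-relation category owns a set of planted
  Gaussian clusters in embedding space. Its initial support nouns are drawn
  from those clusters with counts placed above the support threshold in a
  history bin; in each later bin new query nouns attach either to an
  already-active cluster (chaining-consistent extension) or to a previously
  inactive planted cluster (an emergent sense), with counts that cross the
  query threshold exactly at their labeled bin and the support threshold
  two bins later. The generator's own support/query labels therefore
  coincide exactly with what the category builder derives from the tuple
  stream.
* **Usage sets**: each word's period-1 usages come from one sense
  component; in period 2 a planted fraction (the divergence magnitude) of
  usages is replaced by a second, near-orthogonal sense, so the recorded
  divergence rank should be recovered by the centroid-based change score.

All randomness flows from one master seed through named substreams, so any
artifact is reproducible in isolation. Embeddings are identical across
bins by default, isolating chaining effects from embedding drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .embeddings import EmbeddingSlice, TimeSlicedEmbeddings, save_embeddings
from .lsc import UsageSet

__all__ = [
    "DiachronicSpec",
    "UsageSpec",
    "gen_diachronic_corpus",
    "gen_usage_sets",
    "write_corpus",
    "write_usage_sets",
]


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _substreams(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


@dataclass
class DiachronicSpec:
    """Parameters of a planted-cluster diachronic corpus.

    ``separation`` is the radius at which cluster centers are placed (mean
    inter-center distance ~ separation * sqrt(2) in high dimension);
    ``spread`` the within-cluster standard deviation. Counts are placed
    relative to the query/support thresholds so that every threshold rule
    is exercised on both sides (each category also gets one near-miss noun
    whose cumulative count equals the support threshold exactly, and one
    spontaneous noun that never crosses the query threshold).
    """

    seed: int = 0
    dim: int = 8
    n_categories: int = 6
    clusters_per_category: tuple[int, int] = (4, 6)
    separation: float = 2.0
    spread: float = 0.25
    start_bin: int = 1900
    n_bins: int = 5
    delta: int = 10
    initial_supports: int = 12
    queries_per_bin: int = 2
    emergent_fraction: float = 0.25
    n_distractors: int = 250
    theta_q: int = 10
    theta_s: int = 100
    relation: str = "dobj"

    def __post_init__(self) -> None:
        if self.separation <= 0 or self.spread <= 0:
            raise ValueError("separation and spread must be positive")
        lo, hi = self.clusters_per_category
        if not (1 <= lo <= hi):
            raise ValueError("invalid clusters_per_category range")
        if self.n_bins < 3:
            raise ValueError("need at least 3 bins (history, eval, horizon)")


@dataclass
class CategoryTruth:
    """Generator-side labels for one category."""

    head: str
    relation: str
    cluster_centers: np.ndarray
    cluster_of: dict[str, int] = field(default_factory=dict)
    support_first_bin: dict[str, int] = field(default_factory=dict)
    queries: dict[int, list[str]] = field(default_factory=dict)

    def support_at(self, t: int) -> list[str]:
        return sorted(w for w, b in self.support_first_bin.items() if b <= t)


def gen_diachronic_corpus(
    spec: DiachronicSpec,
) -> tuple[pd.DataFrame, TimeSlicedEmbeddings, dict[tuple[str, str], CategoryTruth]]:
    """Generate (tuple records, per-slice embeddings, ground-truth map)."""
    rngs = _substreams(spec.seed, ["structure", "embeddings", "counts"])
    rs, re_, rc = rngs["structure"], rngs["embeddings"], rngs["counts"]

    bins = [spec.start_bin + i * spec.delta for i in range(spec.n_bins)]
    eval_bins = bins[1:-1]  # history bin first, conventionalization horizon last
    lo, hi = spec.clusters_per_category

    records: list[tuple] = []
    vectors: dict[str, np.ndarray] = {}
    truth: dict[tuple[str, str], CategoryTruth] = {}

    for c in range(spec.n_categories):
        head = f"head{c:02d}"
        g = int(rs.integers(lo, hi + 1))
        centers = np.vstack(
            [spec.separation * _unit(rs.normal(size=spec.dim)) for _ in range(g)]
        )
        if g > spec.initial_supports:
            raise ValueError("more clusters than initial support nouns")
        cat = CategoryTruth(head=head, relation=spec.relation,
                            cluster_centers=centers)
        truth[(head, spec.relation)] = cat

        # initially active clusters: enough to host the initial supports but
        # leaving at least one inactive cluster for emergent senses when g > 1
        n_active = g if g == 1 else max(1, g - max(1, g // 3))
        active = list(range(n_active))
        inactive = list(range(n_active, g))

        # seed supports in the history bin, round-robin over active clusters
        for i in range(spec.initial_supports):
            k = active[i % len(active)]
            noun = f"n_c{c:02d}s{i:02d}"
            vectors[noun] = centers[k] + spec.spread * re_.normal(size=spec.dim)
            cat.cluster_of[noun] = k
            cat.support_first_bin[noun] = bins[1]
            count = spec.theta_s + 1 + int(rc.integers(0, 100))
            records.append((head, "NOUN", spec.relation, noun, bins[0], count))

        # threshold edge cases: a near-miss support and a spontaneous usage
        near = f"n_c{c:02d}_nearmiss"
        k = active[0]
        vectors[near] = centers[k] + spec.spread * re_.normal(size=spec.dim)
        records.append((head, "NOUN", spec.relation, near, bins[0], spec.theta_s))
        spont = f"n_c{c:02d}_spont"
        vectors[spont] = centers[k] + spec.spread * re_.normal(size=spec.dim)
        records.append((head, "NOUN", spec.relation, spont, bins[0], spec.theta_q))

        # emergent queries per evaluation bin
        qi = 0
        for t in eval_bins:
            qs: list[str] = []
            for _ in range(spec.queries_per_bin):
                if inactive and rc.uniform() < spec.emergent_fraction:
                    k = inactive.pop(0)
                    active.append(k)
                else:
                    k = active[int(rc.integers(len(active)))]
                noun = f"n_c{c:02d}q{qi:02d}"
                qi += 1
                vectors[noun] = centers[k] + spec.spread * re_.normal(size=spec.dim)
                cat.cluster_of[noun] = k
                # one attestation at t, conventionalization burst at t + delta
                records.append((head, "NOUN", spec.relation, noun, t, 1))
                burst = spec.theta_s + 20 + int(rc.integers(0, 50))
                records.append((head, "NOUN", spec.relation, noun,
                                t + spec.delta, burst))
                qs.append(noun)
                support_bin = t + 2 * spec.delta
                if support_bin <= bins[-1]:
                    cat.support_first_bin[noun] = support_bin
            cat.queries[t] = sorted(qs)

    # distractor nouns: placed around random planted centers so that
    # candidate pools are semantically structured rather than uniform noise
    all_centers = np.vstack([t_.cluster_centers for t_ in truth.values()])
    for i in range(spec.n_distractors):
        noun = f"n_bg{i:03d}"
        center = all_centers[int(rs.integers(len(all_centers)))]
        vectors[noun] = center + 2.0 * spec.spread * re_.normal(size=spec.dim)
        # background corpus counts keep distractors in the noun vocabulary
        records.append(("bg_head", "NOUN", "misc", noun, bins[0],
                        1 + int(rc.integers(0, 5))))

    records_df = pd.DataFrame(
        records, columns=["head", "pos", "relation", "argument", "bin", "count"]
    ).sort_values(["head", "relation", "argument", "bin"], kind="mergesort")
    records_df = records_df.reset_index(drop=True)

    words = sorted(vectors)
    matrix = np.vstack([vectors[w] for w in words])
    embeddings = TimeSlicedEmbeddings()
    for b in bins:
        embeddings.add(b, EmbeddingSlice(list(words), matrix.copy()))
    return records_df, embeddings, truth


def write_corpus(
    records: pd.DataFrame,
    embeddings: TimeSlicedEmbeddings,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the tuple TSV and per-bin embedding text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tuples_path = outdir / "tuples.tsv"
    records.to_csv(tuples_path, sep="\t", header=False, index=False)
    emb_dir = outdir / "embeddings"
    emb_dir.mkdir(exist_ok=True)
    for b in embeddings.bins:
        save_embeddings(embeddings[b], emb_dir / f"{b}.txt")
    return {"tuples": tuples_path, "embeddings": emb_dir}


@dataclass
class UsageSpec:
    """Parameters of the paired usage-set generator with planted divergence."""

    seed: int = 0
    n_words: int = 30
    usages_per_period: int = 50
    dim: int = 10
    spread: float = 0.15
    max_divergence: float = 0.9

    def __post_init__(self) -> None:
        if self.n_words < 2:
            raise ValueError("need at least 2 words")
        if not (0 < self.max_divergence <= 1):
            raise ValueError("max_divergence must lie in (0, 1]")


def gen_usage_sets(
    spec: UsageSpec,
) -> tuple[dict[tuple[str, str], UsageSet], pd.Series]:
    """Generate usage matrices per (word, period) plus planted divergences.

    Word ``i``'s divergence is ``d = i / (n_words - 1) * max_divergence``.
    The divergence is planted both as a weight shift and a component
    replacement: a fraction ``d`` of period-2 usages is drawn from a second
    sense whose direction sits at angle ``d * 90°`` from the first (so
    ``d = 1`` means all usages replaced by a fully orthogonal sense, with
    centroid cosine distance 1). Period-1 usages all come from the first
    sense. The resulting centroid-set cosine distance grows monotonically
    with ``d``, which is what a rank-recovery evaluation needs. Returns the
    usage-set map and a Series of divergences by word.
    """
    rngs = _substreams(spec.seed, ["senses", "usages"])
    rs, ru = rngs["senses"], rngs["usages"]
    out: dict[tuple[str, str], UsageSet] = {}
    divergences = {}
    n_per = spec.usages_per_period
    for i in range(spec.n_words):
        word = f"w{i:02d}"
        c1 = _unit(rs.normal(size=spec.dim))
        raw = rs.normal(size=spec.dim)
        perp = _unit(raw - (raw @ c1) * c1)
        div = spec.max_divergence * i / (spec.n_words - 1)
        divergences[word] = div
        angle = div * np.pi / 2
        c2 = np.cos(angle) * c1 + np.sin(angle) * perp
        u1 = c1 + spec.spread * ru.normal(size=(n_per, spec.dim))
        n_new = int(round(div * n_per))
        u2 = np.vstack(
            [
                c1 + spec.spread * ru.normal(size=(n_per - n_new, spec.dim)),
                c2 + spec.spread * ru.normal(size=(n_new, spec.dim)),
            ]
        )
        out[(word, "1")] = UsageSet(word, "1", u1)
        out[(word, "2")] = UsageSet(word, "2", u2)
    return out, pd.Series(divergences, name="divergence")


def write_usage_sets(
    usage_sets: dict[tuple[str, str], UsageSet],
    divergences: pd.Series,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write ``<word>.<period>.mat`` matrices and the gold two-column TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (word, period), us in sorted(usage_sets.items()):
        np.savetxt(outdir / f"{word}.{period}.mat", us.vectors, fmt="%.12g")
    gold_path = outdir / "gold.tsv"
    divergences.sort_index().to_csv(gold_path, sep="\t", header=False)
    return {"usages": outdir, "gold": gold_path}
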