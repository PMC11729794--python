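import numpy as np
import pandas as pd
import pytest

from infmix.chaining import ChainingConfig
from infmix.embeddings import EmbeddingSlice, TimeSlicedEmbeddings
from infmix.histeval import (
    DatasetConfig,
    HistoricalEvaluator,
    Trial,
    build_categories,
    evaluate,
    make_trials,
    memory_complexity,
    read_tuples,
    tradeoff_sweep,
)


def _records(rows):
    return pd.DataFrame(
        rows, columns=["head", "pos", "relation", "argument", "bin", "count"]
    )


def hand_table():
    """30 hand-written tuple records exercising every threshold rule.

    With theta_q=10, theta_s=100, delta=10 and bins 1900/1910/1920:

    * ``run`` has 10 supports (count 150 each in 1900 -> support from 1910),
      one query ``qa`` (5 in 1910, 15 in 1920 -> cumulative 5 <= 10 through
      1910 and 20 > 10 through 1920, hence a query at 1910);
    * ``edge_s`` reaches cumulative exactly 100 before 1910 (not > theta_s,
      so not yet support) and 101 before 1920 (support from 1920);
    * ``multi`` accumulates 60 + 50 across two bins (support from 1920,
      never a query since its cumulative exceeds theta_q from the start);
    * ``edge_q`` reaches cumulative exactly 10 (never exceeds theta_q ->
      never a query); ``spont`` stays at 3 (never a query);
    * ``walk`` has only 9 supports, so despite having a query ``qb`` it is
      dropped by the >= 10-support retention rule.
    """
    rows = []
    for i in range(10):
        rows.append(("run", "VERB", "dobj", f"s{i:02d}", 1900, 150))
    rows += [
        ("run", "VERB", "dobj", "qa", 1910, 5),
        ("run", "VERB", "dobj", "qa", 1920, 15),
        ("run", "VERB", "dobj", "edge_s", 1900, 100),
        ("run", "VERB", "dobj", "edge_s", 1910, 1),
        ("run", "VERB", "dobj", "multi", 1900, 60),
        ("run", "VERB", "dobj", "multi", 1910, 50),
        ("run", "VERB", "dobj", "edge_q", 1900, 4),
        ("run", "VERB", "dobj", "edge_q", 1910, 6),
        ("run", "VERB", "dobj", "spont", 1910, 3),
    ]
    for i in range(9):
        rows.append(("walk", "VERB", "dobj", f"w{i:02d}", 1900, 150))
    rows += [
        ("walk", "VERB", "dobj", "qb", 1910, 5),
        ("walk", "VERB", "dobj", "qb", 1920, 15),
    ]
    assert len(rows) == 30
    return _records(rows)


class TestBuildCategories:
    def test_hand_table_support_and_query_sets(self):
        cats = build_categories(hand_table(), DatasetConfig())
        # walk dropped by the 10-support retention rule
        assert set(cats) == {("run", "dobj")}
        cat = cats[("run", "dobj")]
        assert cat.queries == {1910: ["qa"]}
        expected_support = {f"s{i:02d}": 1910 for i in range(10)}
        expected_support.update({"edge_s": 1920, "multi": 1920})
        assert cat.support == expected_support
        assert cat.support_at(1910) == sorted(f"s{i:02d}" for i in range(10))
        # per-bin frequency is the summed record count
        assert cat.frequency_at(1900) == 10 * 150 + 100 + 60 + 4
        assert cat.frequency_at(1910) == cat.frequency_at(1900) + 5 + 1 + 50 + 6 + 3

    def test_query_threshold_edges(self):
        # cumulative 5 then 15 across the boundary -> query; exactly
        # theta_q at t+delta -> not a query (rule is strict >)
        rows = [("h", "V", "r", f"x{i}", 1900, 150) for i in range(10)]
        rows += [("h", "V", "r", "q1", 1910, 5), ("h", "V", "r", "q1", 1920, 5),
                 ("h", "V", "r", "q2", 1910, 5), ("h", "V", "r", "q2", 1920, 6)]
        cats = build_categories(_records(rows), DatasetConfig())
        assert cats[("h", "r")].queries == {1910: ["q2"]}

    def test_support_threshold_is_strict(self):
        rows = [("h", "V", "r", "a", 1900, 100), ("h", "V", "r", "b", 1900, 101)]
        cats = build_categories(
            _records(rows), DatasetConfig(min_support=1, min_query=1)
        )
        # neither head has queries -> no kept bins at all
        assert cats == {}

    def test_empty_stream_raises(self):
        with pytest.raises(ValueError):
            build_categories(_records([]), DatasetConfig())

    def test_vocab_caps(self):
        rows = [
            ("h1", "V", "r1", "a", 1900, 500),
            ("h1", "V", "r2", "b", 1900, 5),
            ("h2", "V", "r1", "a", 1900, 3),
        ]
        cfg = DatasetConfig(top_relations=1, min_head_count=10, min_support=1)
        # caps are applied before thresholding; surviving stream only holds
        # h1/r1 (top relation, head count >= 10)
        from infmix.histeval import _apply_caps

        capped = _apply_caps(_records(rows), cfg)
        assert set(capped["head"]) == {"h1"}
        assert set(capped["relation"]) == {"r1"}

    def test_misaligned_bins_raise(self):
        rows = [("h", "V", "r", "a", 1900, 5), ("h", "V", "r", "a", 1905, 5)]
        with pytest.raises(ValueError):
            build_categories(_records(rows), DatasetConfig(delta=10))

    def test_gzip_round_trip(self, tmp_path):
        df = hand_table()
        path = tmp_path / "tuples.tsv.gz"
        df.to_csv(path, sep="\t", header=False, index=False, compression="gzip")
        back = read_tuples(path)
        pd.testing.assert_frame_equal(back, df.reset_index(drop=True))


def _toy_world(n_extra=30, seed=0):
    """A 2-category world with clearly separated semantic clusters."""
    rng = np.random.default_rng(seed)
    rows = []
    words, vecs = [], []

    def add_word(w, center):
        words.append(w)
        vecs.append(center + 0.05 * rng.normal(size=2))

    for c, (head, center) in enumerate(
        [("eat", np.array([0.0, 0.0])), ("read", np.array([8.0, 8.0]))]
    ):
        for i in range(10):
            w = f"{head}_s{i}"
            add_word(w, center)
            rows.append((head, "V", "dobj", w, 1900, 150))
        q = f"{head}_q"
        add_word(q, center)
        rows += [(head, "V", "dobj", q, 1910, 5),
                 (head, "V", "dobj", q, 1920, 20)]
    for i in range(n_extra):
        w = f"bg{i}"
        add_word(w, np.array([4.0, -4.0]))
        rows.append(("bg", "V", "misc", w, 1900, 2))
    emb = TimeSlicedEmbeddings()
    for b in (1900, 1910, 1920):
        emb.add(b, EmbeddingSlice(list(words), np.array(vecs)))
    records = _records(rows)
    cats = build_categories(records, DatasetConfig())
    ev = HistoricalEvaluator(cats, emb, reduced_dim=2, noun_frequencies=records)
    pool = sorted(records["argument"].unique())
    return records, emb, cats, ev, pool


class TestMakeTrials:
    def test_same_seed_same_trials(self):
        _, emb, cats, _, pool = _toy_world()
        t1 = make_trials(cats, emb, m=10, pool=pool, seed=7)
        t2 = make_trials(cats, emb, m=10, pool=pool, seed=7)
        assert [t.candidates for t in t1] == [t.candidates for t in t2]

    def test_forced_draw_with_minimal_pool(self):
        _, emb, cats, _, _ = _toy_world(n_extra=1)
        trials = make_trials(cats, emb, m=2, pool=["bg0"], seed=0)
        for t in trials:
            assert len(t.candidates) == 2 and "bg0" in t.candidates

    def test_negatives_never_attested_with_category(self):
        _, emb, cats, _, pool = _toy_world()
        for t in make_trials(cats, emb, m=10, pool=pool, seed=1):
            attested = set(cats[t.category].support) | {
                q for qs in cats[t.category].queries.values() for q in qs
            }
            negs = [c for c in t.candidates if c != t.truth]
            assert not (set(negs) & attested)

    def test_insufficient_pool_raises(self):
        _, emb, cats, _, _ = _toy_world(n_extra=2)
        with pytest.raises(ValueError, match="pool too small"):
            make_trials(cats, emb, m=10, pool=["bg0", "bg1"], seed=0)

    def test_head_mode_truth_is_category_key(self):
        _, emb, cats, _, _ = _toy_world()
        trials = make_trials(cats, emb, m=2, mode="head", seed=3)
        for t in trials:
            assert t.truth in cats and t.truth in t.candidates

    def test_trial_invariants(self):
        with pytest.raises(ValueError):
            Trial(1900, "argument", "x", ["a", "b"])  # truth not in candidates
        with pytest.raises(ValueError):
            Trial(1900, "argument", "a", ["a", "a"])  # duplicates


class TestEvaluate:
    def test_separable_world_perfect_accuracy(self):
        _, emb, cats, ev, pool = _toy_world()
        trials = make_trials(cats, emb, m=10, pool=pool, seed=2)
        for kind in ("exemplar", "prototype", "infmix", "onenn"):
            cfg = ChainingConfig(kind=kind, lam=0.5, beta=1.0, reduced_dim=2)
            res = evaluate(trials, ev, cfg, seed=0)
            assert res[kind].aggregate == 1.0

    def test_candidate_order_invariance(self):
        _, emb, cats, ev, pool = _toy_world()
        trials = make_trials(cats, emb, m=10, pool=pool, seed=2)
        shuffled = [
            Trial(t.time_bin, t.mode, t.truth, list(reversed(t.candidates)),
                  category=t.category)
            for t in trials
        ]
        cfg = ChainingConfig(kind="exemplar", beta=1.0, reduced_dim=2)
        a = evaluate(trials, ev, cfg, seed=0)["exemplar"].aggregate
        b = evaluate(shuffled, ev, cfg, seed=0)["exemplar"].aggregate
        assert a == b

    def test_exact_tie_counts_as_failure(self):
        # two candidates at mirror-image positions score identically
        words = ["truth", "neg", "s0"] + [f"s{i}" for i in range(1, 10)]
        vecs = np.array([[1.0, 0.0], [-1.0, 0.0]] + [[0.0, 0.0]] * 10)
        emb = TimeSlicedEmbeddings()
        for b in (1900, 1910, 1920):
            emb.add(b, EmbeddingSlice(words, vecs))
        rows = [("h", "V", "r", f"s{i}", 1900, 150) for i in range(10)]
        rows += [("h", "V", "r", "truth", 1910, 5),
                 ("h", "V", "r", "truth", 1920, 20)]
        cats = build_categories(_records(rows), DatasetConfig())
        ev = HistoricalEvaluator(cats, emb, reduced_dim=None)
        trial = Trial(1910, "argument", "truth", ["truth", "neg"],
                      category=("h", "r"))
        cfg = ChainingConfig(kind="prototype", beta=1.0, reduced_dim=None)
        res = evaluate([trial], ev, cfg, baselines=False)
        assert res["prototype"].aggregate == 0.0

    def test_random_baseline_near_chance(self):
        _, emb, cats, ev, pool = _toy_world()
        base = make_trials(cats, emb, m=10, pool=pool, seed=2)
        trials = base * 400  # 800 trials at m=10
        res = evaluate(trials, ev,
                       ChainingConfig(kind="prototype", beta=1.0,
                                      reduced_dim=2), seed=11)
        p = 1 / 10
        se = np.sqrt(p * (1 - p) / len(trials))
        assert abs(res["random"].aggregate - p) < 4 * se

    def test_by_bin_partition(self):
        _, emb, cats, ev, pool = _toy_world()
        trials = make_trials(cats, emb, m=10, pool=pool, seed=2)
        cfg = ChainingConfig(kind="exemplar", beta=1.0, reduced_dim=2)
        res = evaluate(trials, ev, cfg, seed=0)["exemplar"]
        weights = {
            b: sum(t.time_bin == b for t in trials) / len(trials)
            for b in res.by_bin
        }
        recombined = sum(res.by_bin[b] * weights[b] for b in res.by_bin)
        assert recombined == pytest.approx(res.aggregate)


class TestComplexityAndSweep:
    def test_prototype_complexity_exactly_one(self):
        _, emb, cats, ev, _ = _toy_world()
        cfg = ChainingConfig(kind="prototype", beta=1.0, reduced_dim=2)
        assert memory_complexity(ev, cfg) == 1.0

    def test_exemplar_complexity_is_mean_support_size(self):
        _, emb, cats, ev, _ = _toy_world()
        cfg = ChainingConfig(kind="exemplar", beta=1.0, reduced_dim=2)
        assert memory_complexity(ev, cfg) == 10.0

    def test_infmix_complexity_between_limits(self):
        _, emb, cats, ev, _ = _toy_world()
        cfg = ChainingConfig(kind="infmix", lam=0.5, beta=1.0, reduced_dim=2)
        assert 1.0 <= memory_complexity(ev, cfg) <= 10.0

    def test_sweep_endpoints_match_pure_models(self):
        _, emb, cats, ev, pool = _toy_world()
        trials = make_trials(cats, emb, m=10, pool=pool, seed=2)
        lam_big = 1e6
        table = tradeoff_sweep([0.0, lam_big], trials, ev, beta=1.0,
                               reduced_dim=2)
        ex = table[table.model == "exemplar"].iloc[0]
        pr = table[table.model == "prototype"].iloc[0]
        inf0 = table[(table.model == "infmix") & (table.lam == 0.0)].iloc[0]
        infL = table[(table.model == "infmix") & (table.lam == lam_big)].iloc[0]
        assert inf0.accuracy == ex.accuracy
        assert inf0.mean_centroids == ex.mean_centroids
        assert infL.accuracy == pr.accuracy
        assert infL.mean_centroids == pr.mean_centroids == 1.0
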