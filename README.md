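# infmix

Infinite-mixture chaining models of word meaning extension and lexical
semantic change.

## The problem

Words extend to new meanings over time: *store* once took arguments like
*corn* and *flour*, and later acquired *electricity* and *password*.
Semantic chaining models explain this as new items attaching to
semantically close existing usages. The two classic accounts sit at
opposite ends of a cognitive-efficiency trade-off: the **exemplar** model
represents a category by every stored usage (accurate but memory-hungry),
the **prototype** model by a single mean vector (cheap but coarse). This
package implements a unified family in which a category's support set
S (the arguments already attested for a head word *w* under syntactic
relation *r*) is summarized by a set of cluster centroids
M = {μ₁, …, μ_K} minimizing

    J(M) = Σ_k Σ_{x ∈ cluster k} ‖x − μ_k‖² + λ·K,

an information loss plus a memory penalty, optimized by deterministic
DP-means clustering. λ = 0 recovers the exemplar model, λ beyond the
maximum pairwise squared distance recovers the prototype, and intermediate
λ gives the **infinite mixture** model whose cluster count adapts to the
category's internal sense structure. Similarity of a query noun *q* to a
category follows the Generalized Context Model kernel

    sim(q, M) = (1/K) Σ_k exp(−‖φ(q) − μ_k‖² / β),

with sensitivity β, and prediction is a normalized score over a candidate
set (heads for a novel noun, or nouns for a head). A companion
lexical-semantic-change score compares the DP-means centroid sets of a
word's usage embeddings from two periods by mean pairwise cosine distance.

It is written for computational linguists and cognitive scientists who
want to run (or extend) chaining analyses on diachronic co-occurrence data
and embeddings, at the scale of their own corpora.

## Worked example

Everything below runs on seeded synthetic data shipped with the package
(the generators plant known cluster structure, so accuracy has a ground
truth). Estimators follow scikit-learn conventions:

```python
import numpy as np
from infmix import DPMeans, ChainingConfig, infer_centroids, similarity

pts = np.array([[0.0], [0.1], [10.0], [10.1]])
model = DPMeans(lam=1.0).fit(pts)
print(model.n_clusters_, model.cluster_centers_.ravel(), model.objective_)
# 2 [ 0.05 10.05] 2.01
```

The full diachronic experiment, end to end:

```python
from infmix import (DiachronicSpec, gen_diachronic_corpus, DatasetConfig,
                    build_categories, HistoricalEvaluator, make_trials,
                    evaluate, memory_complexity, ChainingConfig)

records, embeddings, truth = gen_diachronic_corpus(DiachronicSpec(seed=3))
cats = build_categories(records, DatasetConfig())
ev = HistoricalEvaluator(cats, embeddings, reduced_dim=5,
                         noun_frequencies=records)
pool = sorted(records["argument"].unique())
trials = make_trials(cats, embeddings, m=50, pool=pool, seed=1)
for kind, lam in [("exemplar", 0.0), ("prototype", 0.0), ("infmix", 1.0)]:
    cfg = ChainingConfig(kind=kind, lam=lam, beta=0.5, reduced_dim=5)
    res = evaluate(trials, ev, cfg, seed=2)[kind]
    print(f"{kind:9s} accuracy={res.aggregate:.3f} "
          f"K={memory_complexity(ev, cfg):.2f}")
```

prints

```
exemplar  accuracy=0.417 K=12.67
prototype accuracy=0.139 K=1.00
infmix    accuracy=0.472 K=5.50
```

Each trial asks a model to rank the one truly emerging argument above 49
random nouns never attested with the category; `accuracy` is the fraction
of trials where the truth wins outright, `K` the mean number of stored
centroids per category. The infinite mixture model here matches the
exemplar's accuracy with under half its memory, while the prototype — one
centroid stranded between a category's distinct senses — falls far behind.

The same stages are exposed as a CLI (`infmix fixtures | build | cluster |
predict | sweep | simulate | lsc`); every run writes a `manifest.json`
from which `infmix replay` reproduces its outputs byte for byte.

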