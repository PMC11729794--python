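# Methods

## Model family

A time-varying category is a head-relation pair (w, r) — e.g. a verb and
the *direct object* relation — whose support set S^t holds the noun
arguments attested above a frequency threshold by time t, each noun
represented by a vector φ(n)^t from that time slice's embedding table.
The category is summarized by centroids M^t minimizing the information
loss plus memory objective

    J(M) = Σ_k Σ_{n ∈ cluster k} ‖φ(n) − μ_k‖² + λ·K.

Model kinds differ only in how M^t is formed:

| kind      | centroids                         | K          |
|-----------|-----------------------------------|------------|
| exemplar  | every support vector              | n          |
| onenn     | support vectors, max-kernel       | n          |
| prototype | mean support vector               | 1          |
| infmix    | DP-means minimizer of J at λ      | 1 … n      |

Query similarity is the mean (max for `onenn`) of exp(−‖φ(q) − μ_k‖²/β).
Head prediction normalizes this similarity over candidate categories.
Argument prediction multiplies by the category's cumulative frequency
prior N(w, r)^t before normalizing over candidate nouns; since the prior
does not vary within a fixed category it cannot change the ranking of
those nouns — it is kept because it is part of the posterior's definition,
and the implementation asserts the constancy rather than silently
dropping the factor.

Two exact equivalences anchor the family and are unit-tested to 1e-12:
infmix(λ=0) reproduces the exemplar model (every distinct support vector
its own cluster), and infmix with λ above the maximum pairwise squared
distance reproduces the prototype (a single cluster at the global mean —
the bound holds for *squared* distance because a point's squared distance
to the mean never exceeds the maximum pairwise squared distance).

## DP-means

DP-means is the hard, small-variance limit of a Dirichlet-process
Gaussian mixture: deterministic, initialized with one cluster at the
global mean, scanning points in input order and spawning a cluster
whenever a point's squared distance to every centroid exceeds λ; cluster
means are then recomputed and empty clusters dropped. The spawn threshold
is squared distance, the reading under which the objective descends
monotonically and the λ-limits above are exact.

Because spawning can only add clusters, the textbook algorithm cannot
heal an early double-spawn inside one true component — on planted
4-component data it returned K = 5 in roughly half the runs at any fixed
λ. Each iteration therefore also applies greedy **merge moves**: two
clusters are merged whenever the scatter the merge adds,
n₁n₂/(n₁+n₂)·‖μ₁−μ₂‖², is less than the λ it saves. Merges strictly
decrease the same objective, keep the algorithm deterministic, and leave
both λ-limits untouched (at λ = 0 no merge ever pays). Convergence is
declared at a label fixpoint, or when a merge-free iteration improves the
objective by less than `tol` (default 1e-9); `max_iter` defaults to 100.
Against exhaustive partition enumeration at n ≤ 8 the returned objective
never beats the global minimum and attains it on well-separated fixtures.

λ is selected without labels by the mean silhouette coefficient over the
clusterings of all support sets, computed in the same (reduced) space as
the clustering; silhouettes are undefined (and excluded) when K < 2 or
K = n, and ties break toward smaller λ.

## Semantic space

Embedding tables are read from the word2vec plain-text dialect, one file
per time bin (bins are half-open [t, t+Δ), labeled by start year). Since
squared-Euclidean clustering degenerates in high dimension, DP-means
labels are computed in a PCA subspace (30 components by default; fewer
when the analysis vocabulary is smaller) fit per time slice on the
analysis vocabulary with centering but no scaling, while centroids and
kernel similarities use the full-space vectors. Per-slice fitting keeps
each decade's geometry free of future co-occurrence information; fitting
one pooled projection instead is a one-line change in
`HistoricalEvaluator`. Words missing from a slice are dropped from that
slice's categories and logged, not imputed.

## Diachronic evaluation

From tuple records (head, POS, relation, argument, bin, count), an
argument is **support** for (w, r) at bin t when its cumulative count
strictly before t exceeds θ_s = 100, and a **query** at t when its
cumulative count is ≤ θ_q = 10 through t but > θ_q through t+Δ — an
emerging usage that conventionalizes at the next step rather than a
one-off. Both thresholds are strict. A category enters evaluation at a
bin only with ≥ 10 supports and ≥ 1 query. Corpus-level pruning (top-N
noun vocabulary, minimum head count, top-K relations) is configurable
rather than hard-coded because the published cut-offs are corpus-specific;
Δ = 10 (years) by default, Δ = 5 with a single relation for
classifier-style data.

Each query yields a forced-choice trial: the truth plus m−1 = 99
negatives drawn uniformly without replacement (seeded) from the candidate
pool, excluding items ever attested with the target. The same negatives
are reused across model kinds so comparisons are paired. A trial is
correct only when the truth's score strictly exceeds every negative's —
ties count as failures, so a constant scorer earns ≈ 1/m, and the uniform
random baseline is calibrated against exactly that. The frequency
baseline picks the candidate with the highest cumulative corpus frequency
through the trial's bin. Memory complexity is the mean centroid count
over (category, evaluation-bin) pairs; the trade-off sweep evaluates a λ
grid plus labeled exemplar and prototype endpoint rows on identical
trials.

β is tuned to maximize the mean normalized probability assigned to the
truth within each trial's candidate set (normalized, so the objective is
scale-free), separately per model kind. The default optimizer is a
deterministic coarse log-grid scan plus bounded golden-section
refinement; a stochastic-gradient mode (central differences on log β over
shuffled mini-batches, seeded) is provided and agrees with the
deterministic optimizer to ~1e-3 on smooth objectives. Score
normalization runs in the log domain (logsumexp) so extreme β values
cannot underflow to an undefined distribution.

## Simulation study

Two competing categories are sampled from planted 2-D Gaussian mixtures:
component count uniform on 1..10, means uniform in [−1, 1]², shared
isotropic variance 0.1, equiprobable components, N = 500 points per
category, 80/20 stratified train/test split (split seed separate from
generation seed). Models fit per-category centroids on the training
points and classify each test point to the category with higher kernel
similarity; complexity is K/N_train. The spectrum between prototype
(K = 1) and exemplar (K = N_train) is traced in two modes: pinning K
directly via constrained squared-loss clustering (K-means; the default,
since λ cannot dial an exact K) on a 10..400-by-10 grid, or sweeping λ and
recording the K it induces. β is fit on the training points per model by
default, with exemplar-like representations scored leave-one-out so the
zero self-distance cannot drive β to zero; a fixed shared β is available.
Centroid recovery against the planted means uses minimum-cost one-to-one
assignment, reporting the mean matched Euclidean error and the
cardinality gap |K − G| separately.

## Semantic change

For a target word with usage-embedding matrices from two periods
(precomputed by any contextual encoder upstream; the package defines the
input contract and ships a generator, not an encoder), DP-means clusters
each period's usages and the change score is 1 minus the mean pairwise
cosine similarity between the two centroid sets — distance, so that more
change scores higher; the raw similarity form is available as a mode and
ranks words in exactly reversed order. Scores are symmetric, invariant to
uniform positive rescaling of the usage vectors, and lie in [0, 2] in
distance mode. Usage vectors are clustered un-normalized by default
(clustering is Euclidean); length-normalization before clustering is a
flag. λ is selected by mean silhouette over all per-word per-period
clusterings from a 0.05..0.70 grid in steps of 0.05, and the ranking is
evaluated by tie-corrected Spearman correlation against a two-column
gold table.

## Synthetic data generators

All randomness flows from one master seed through named substreams, so
every artifact is reproducible in isolation, and the generators write the
exact text formats the readers consume (embedding text files, tuple TSV,
per-(word, period) usage matrices, gold TSV).

The diachronic generator plants per-category Gaussian clusters (centers
on a sphere of radius `separation` = 2, within-cluster spread 0.25, in 8
dimensions) and schedules counts so every threshold rule is exercised on
both sides: initial supports exceed θ_s in a history bin; each query noun
receives one attestation at its labeled bin and a conventionalization
burst at the next, making it a query exactly once and a support two bins
later; each category also gets a near-miss noun that reaches exactly θ_s
(never support) and a spontaneous noun that never crosses θ_q (never
query). The category builder's output on a generated corpus therefore
matches the generator's own labels exactly, which is asserted. Embeddings
are identical across bins by default, isolating chaining effects from
embedding drift. Distractor nouns are placed around randomly chosen
planted centers so candidate pools are semantically structured rather
than uniform noise.

The usage-set generator (30 words, 50 usages per period, 10 dimensions,
spread 0.15) plants a divergence d per word, spaced evenly over 0..0.9:
a fraction d of period-2 usages is replaced by a second sense at angle
d·90° from the first. Tying both the replaced weight and the sense angle
to d makes the centroid-cosine score increase monotonically with d —
weight alone saturates the score as soon as a second cluster appears —
so rank recovery (Spearman ρ ≥ 0.8 at defaults) is a meaningful check.

## What the synthetic evaluations do not show

The generators emulate clean, well-separated sense structure with
stationary embeddings and exactly scheduled counts. Real diachronic data
have drifting embedding spaces, heavy-tailed frequencies, OCR and
tokenization noise, senses of very unequal size, and categories whose
supports are missing from embedding vocabularies. Passing tests
demonstrate that the machinery is correct and that the efficiency
trade-off behaves as designed under planted structure — not that any
particular accuracy level transfers to a specific corpus. Problem sizes
throughout (8 categories, 100-candidate trials, 10–20 simulation
replicates, 30-word change rankings) are the package's default desk-scale
conditions; all are configurable upward.

## Other numerical choices

- Ties in candidate scores are preserved and resolved by the strict-win
  rule at evaluation time (configurable in principle; deterministic by
  design).
- Degenerate inputs fail loudly: empty support sets, empty tuple streams,
  zero-norm usage rows, misaligned bins, negative λ, non-positive β and
  undefined silhouettes all raise with a message naming the offender.
- Centroid caches are keyed by (category, bin, kind, λ, reduced
  dimension) and never shared across differing parameters.
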