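# Methods

This note documents the model as implemented, the defaults and why,
what the synthetic benchmark does and does not establish, and the
numerical and design choices made where the method description leaves
room.

## Model

### Similarity sources and fusion

Four similarity families feed the heterogeneous network:

* **GIP kernel** — `GM(i,j) = exp(-α_m ||R_i - R_j||²)` over binary
  interaction profiles (rows of A for miRNAs, columns for diseases),
  with `α_m = α'_m / mean_i ||R_i||²` and `α'_m = β'_m = 1`.  All-zero
  profiles are handled without special-casing (their distance to any
  other profile is that profile's norm); an entirely zero A has no
  defined bandwidth and is rejected.
* **Semantic similarity** — diseases sit in an acyclic is-a hierarchy.
  A contribution scheme assigns each ancestor term a weight relative to
  a target disease; pairwise similarity is the shared-ancestor weight
  mass over the two diseases' total masses.  Two schemes are averaged:
  the decay recursion (target scores 1, each ancestor the decayed
  maximum over its children, Δ = 0.5) and a frequency scheme weighting
  a term by −log(fraction of disease hierarchies containing it).
  Natural log is used; the base rescales both numerator and
  denominator of the similarity ratio, so the choice is nearly neutral
  and affects only the mixing with the decay scheme.
* **lncRNA profile similarity** — `1 − ED/L` where ED is the unit-cost
  Levenshtein distance between two entities' length-L binary lncRNA
  association strings.  The source description names only "an
  edit-distance algorithm"; this normalization is our choice: it is
  bounded in [0,1], symmetric, and reduces to normalized Hamming
  agreement for equal-length binary strings.  The diagonal is forced
  to 1.
* **Functional similarity** — an input, never computed here.

Fusion is a convex combination per side; missing sources drop out and
the remaining weights renormalize, which gives the per-source
ablations a single code path.  The default fixed weights
α = (0.77, 0.19, 0.04), β = (0.16, 0.82, 0.02) are the converged
learnable-fusion values reported for the reference corpus; a
`learnable=True` mode re-parameterizes the weights through a softmax so
they stay on the simplex while gradients reach them through the
reassembled adjacency at every step.

### Walk initialization

Node features are the converged restart distributions of a random walk
on the bipartite association graph `[[0, A], [Aᵀ, 0]]`, column
normalized; isolated nodes get a self-loop so the matrix stays
stochastic.  The restart probability is not fixed by the method
description; the default is r = 0.7, chosen once as a standard value
for biological network diffusion and exposed in config.  The iteration
`D ← (1−r) A_N D + r I` contracts at rate (1−r) and stops at Frobenius
update ≤ 10⁻⁶ (cap 1000 iterations, error on failure).  H⁽⁰⁾ stays
(Nm+Nd)-dimensional; the first convolution layer maps it to the
embedding width.

### Encoder

Strictly linear, by construction: no bias, no activation, no degree
normalization of M (a symmetric normalization is available but off by
default, because the layer-collapse identity `H⁽ˡ⁾ = Mˡ H⁽⁰⁾ W⁽¹⁾⋯W⁽ˡ⁾`
is the method's core and holds only for the plain product).  `Mˡ` is
the meta-path weight matrix: its (u,v) entry sums edge-weight products
over all length-ℓ paths, which is what gives each layer its
interpretation.  Defaults: ℓ = 2 layers, embedding width 256, Glorot
uniform initialization from a stated seed.  Layer outputs combine
through fixed or softmax-learnable coefficients γ; the "attention" here
is a learned scalar per layer, the simplest form consistent with the
weighted-sum combination.  No normalization or activation is applied
to H before the decoder.

### Negative screening

Pairs are represented by length-(Nm+Nd) vectors; the default
construction concatenates row i of IM with row j of ID
(config-switchable to the association-profile concatenation — the
dimensionality constraint admits both and the description fixes
neither).  The screen is a 2-means-style iteration anchored by the
positive set: initial centroids from the positive and unlabeled sets,
one cosine partition of the unlabeled pool, then repeated
nearest-centroid (Euclidean) partitions with centroids recomputed from
the current likely-positive/likely-negative sides, until both centroid
shifts are ≤ 10⁻³ (Frobenius) or 100 iterations.  Ties and zero-norm
features go to the likely-negative side — ambiguous pairs should stay
available as negative candidates rather than be promoted.  An emptied
side freezes its centroid.  By default centroids are recomputed from
the partition alone; a flag augments the positive-side centroid with
the known positives (the text admits both readings).  Plain 2-means
and uniform-random baselines are provided for comparison experiments.

### Training and decoding

`σ(⟨H_m, H_d⟩)` scores a pair; the loss is the summed BCE over
positives and screened negatives, logs clamped at 10⁻¹², full batch.
The optimizer is Adam (the de-facto choice for this model family; the
description names only the rates) at lr = 5·10⁻⁴ and L2 weight decay
5·10⁻⁴ folded into the gradient, torch-style.  Because the encoder is
linear, every gradient — layer weights, layer-attention logits, fusion
logits (through the matrix-power recurrence) — is computed in closed
form; the test suite validates all of them against central finite
differences.  Note the clamp means the *reported* loss saturates while
gradients follow the unclamped objective, exactly as common framework
implementations do.  Training is deterministic given the seed.

## Evaluation protocol

Five folds.  The screen runs once on the full data; ratio·|P|
negatives are sampled (seeded) from the pool; positives and sampled
negatives are shuffled into folds.  Metrics: AUC (rank statistic), AUPR
(step-wise precision–recall integration, no interpolation — this is
average precision), ACC at threshold 0.5 on the probability (the
canonical cut for a probabilistic output; the source states none).

Two protocol switches matter:

* **`nsst_scope`** — `train_and_test` (default, matching the reference
  protocol) screens the test negatives too; `train_only` samples test
  negatives uniformly from the unlabeled pool, so the test set may
  contain likely positives.
* **`mask_test_positives`** — `True` (default) removes each fold's test
  positives from A before the GIP kernels, block adjacency and walk
  features are rebuilt, so no test label reaches the encoder input.
  `False` reproduces the reference protocol, in which the full A feeds
  the encoder.

The masked protocol is the honest one and is the library default, but
it is strictly harder: a masked within-block test positive is
*information-theoretically indistinguishable* from a within-block pool
negative (both are unassociated in the training A with identical
neighborhood structure), so whenever the screened pool retains
within-block pairs the achievable AUC is capped below 1 by
construction.  On the default benchmark the masked protocol yields
AUC ≈ 0.89 / AUPR ≈ 0.92 while the unmasked reference protocol yields
AUC ≈ 0.98 / AUPR ≈ 0.98 (both computed by `tests/test_acceptance.py`
and `scripts/acceptance.py`); the gap measures exactly the information
the reference protocol lets through.

## Synthetic benchmark

The generator states a world in which the model's premise holds by
construction: near-equal miRNA and disease blocks; within-block pairs
positive with probability `density` (default 0.3), off-block with
probability `noise` (default 0.02); functional similarity = block
agreement plus Gaussian jitter (sd = `noise`), clipped and
symmetrized; lncRNA profiles = per-block random prototypes with
bit-flip probability `noise`; a disease hierarchy hanging each block's
diseases under a shared ancestor chain.  Default size 100×80 with 5
blocks trains in seconds on one CPU; that, plus block counts small
enough for every block to be well populated, is why these defaults
were chosen.

What a green benchmark run establishes: the full pipeline recovers a
planted similarity-association coupling from seeded data, end to end,
deterministically.  What it does not establish: performance on real
corpora.  Real functional-similarity matrices are noisy and partially
missing rather than near-oracle block indicators; real association
matrices are much sparser and degree-skewed; real ontologies are deep
and unbalanced.  Two known consequences, verified in testing:

* Because every synthetic source derives from the same block labels,
  the sources are *redundant*, not complementary — so fusing them
  cannot beat the single most informative source (functional
  similarity under the masked protocol, GIP under the unmasked one).
  The corresponding multi-source acceptance check fails on this world
  by design of the world, not of the code; the other ablation
  directions (screened negatives > random negatives; meta-path set
  {1,2} ≥ length-3 alone) reproduce with wide margins.
* The off-block positives (rate `noise`) are unlearnable coin flips
  and bound the masked-protocol AUC away from 1.

## Numerical choices

* Similarity validation: symmetry within 10⁻⁹, unit diagonal, range
  [0,1]; fused outputs are re-symmetrized and clipped against rounding.
* Squared distances in the GIP kernel come from the Gram expansion with
  negatives clipped at 0.
* Batched Levenshtein uses a row-wise DP with the insertion recurrence
  resolved by a prefix-minimum scan; it is tested against the classic
  O(L²) DP.
* Ranking ties (score tables, candidate lists) break by identifier
  order, so outputs are deterministic files.
* FD2 with a vanishing denominator (every shared term ubiquitous) is 1
  on the diagonal and 0 off it.
* Degenerate screen partitions freeze the emptied centroid and log a
  warning rather than abort.

## Known limitations

* Dense matrices throughout: fine to a few thousand nodes, not beyond.
* The learnable fusion weights move slowly at the default learning
  rate; within short epoch budgets they stay near their initialization.
* No GPU path, no minibatching, no early stopping — by design, for
  exactness and reproducibility at this scale.
* MeSH XML parsing and any corpus download are out of scope; real data
  enters as TSV matrices and an edge-list hierarchy.
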