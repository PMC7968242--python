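# Methods

## The problem

Two weighted gene co-expression networks (GCNs) — built from different
tissues, species, or sample subsets — cannot be compared edge-by-edge:
their gene sets differ, edge weights are noisy, and graph embeddings
trained separately live in unrelated coordinate systems. `coexalign`
compares GCNs *purely topologically*: it embeds the genes of both networks
in one vector space, reads off local similarity as a cosine distance
between any cross-network gene pair, reduces the whole comparison to a
single global distance via an optimal one-to-one matching, and maps
conserved versus diverged regions by biclustering the cross-network
distance matrix.

## Pipeline

1. **Network construction.** For every gene pair, the Pearson correlation
   (PCC) of their expression profiles is computed across samples. An edge
   is created when `|PCC| >= t` (default `t = 0.8`, applied to the
   *original* correlation, two-sided), and the stored weight is the affine
   transform `w = 0.5 + 0.5 * PCC`, mapping `[-1, 1]` onto `[0, 1]`.
   Strong negative co-expression therefore survives thresholding as a
   weight near 0 rather than being discarded; it is preserved in the
   graph but carries no random-walk mass (below). Genes whose
   correlations all fall below the threshold — and zero-variance genes,
   whose correlations are undefined — remain as isolated nodes so that
   every gene is embedded.

2. **Anchors and dangling structures.** A set of anchor genes present in
   every network (for real data: genes from conserved cellular-homeostasis
   processes, whose network position is expected to be stable) each
   receive a *dangling structure*: a random sparse connected graph of
   `gamma` artificial nodes (default 8), wired with 15% of its potential
   edges (with uniformly random repair edges added until connected — a
   connected graph on `n` nodes needs `n - 1` edges, i.e. a fraction
   `2/n` of the potential edges), all weights 1.0, attached to the anchor
   by a single unit-weight edge. The *identical* structure — same
   artificial node IDs, same edges — is attached to the matching anchor
   in every network; structures of different anchors are pairwise
   distinct. Sparse structures are used because the nodes of a dense
   graph are topologically interchangeable and would make poor landmarks.

   Anchor placement matters: landmarks clustered in one region leave
   symmetries elsewhere unbroken (e.g. both copies of a symmetric arm can
   flip jointly). The pipeline therefore defaults to a greedy
   farthest-point placement over shortest-path distance ("spread"
   strategy; different connected components count as maximally far apart,
   ties break by degree), with uniform random selection available.

3. **Weighted random walks.** Edge weights are row-normalised into
   transition probabilities, `P(j|i) = w_ij / sum_k w_ik`, so walks
   preferentially traverse strong co-expression. From every node of every
   augmented network, `walks_per_node` first-order walks (default 1000)
   of up to `walk_length` tokens (default 20) are generated; a walk stops
   early at a node with no positive-weight edge, and an isolated node
   emits length-1 walks. Gene IDs are translated to integer tokens first;
   under the default `dangling-only` tying policy each network's real
   genes get network-private tokens while artificial dangling nodes share
   one token across all networks (`dangling-anchors` additionally shares
   anchor tokens). The walks of all networks are pooled and shuffled into
   a single corpus.

4. **Joint skip-gram embedding.** A skip-gram model with negative
   sampling (SGNS) is trained on the pooled corpus: token vectors are fit
   so that inner products predict co-occurrence within a `window`
   (default 5) along walks. We rely on a large corpus (1000 walks/node)
   with a single pass rather than many epochs over a small corpus.

   Training is deterministic and full-batch: one pass over the corpus
   accumulates window-weighted co-occurrence counts (a pair at offset `d`
   counts `(window + 1 - d)/window`, the expectation under a uniformly
   shrunk dynamic window), and the exact expected SGNS loss defined by
   these counts is minimised by momentum gradient descent (learning rate
   0.3, momentum 0.9, logits clipped at ±30, float64). Three choices make
   the joint space genuinely joint:

   * **Per-network negatives.** Each walk's `negative = 5` noise tokens
     are drawn from its *origin network's* unigram^0.75 distribution.
     Genes of different networks never co-occur; if they could also be
     sampled as each other's negatives, their inner products would be
     pushed toward the constant `-log k` — an active force *against*
     aligning the two networks. With per-network negatives those inner
     products are unconstrained by the data and free to be set by the
     regulariser.
   * **Annealed ridge penalty.** An L2 penalty on both factor matrices is
     annealed over stages: λ = 1.0, 0.3, 0.1, 0.03 for 1000 iterations
     each, then 0.01 for 500. Among the factorizations that fit each
     network individually, the penalty selects the minimum-norm one,
     which reuses the dimensions pinned by the shared dangling tokens —
     i.e. the solution in which corresponding genes of statistically
     identical networks coincide. The strong opening stage commits the
     optimization to that basin before refinement; the late low-penalty
     stages restore distance discrimination, and the weakest stage is
     kept short because weakly pinned directions drift if it runs long.
   * **Landmark-seeded initialisation.** All rows start at zero except
     the shared dangling-token rows (seeded Gaussian, scale 0.1).
     Optimization then follows the copy-symmetric trajectory: structure
     propagates outward from the landmarks, and the misaligned local
     minima reachable from generic random initialisation are avoided.

   **Embedding dimension.** The default is deliberately small
   (`n_dim = 6`). The shared landmarks pin only a low-rank subspace
   (roughly one strong direction per anchored structure); any dimensions
   beyond that rank are free to rotate independently per network, which
   leaves each network's internal geometry intact while silently
   destroying cross-network comparability. Keep `n_dim` at or below the
   landmark rank; raising it (e.g. to 16+) measurably breaks alignment
   long before it helps representation.

   Tokens with no co-occurrences at all (isolated genes) receive a tiny
   seeded random vector after training so cosine distances stay defined;
   such vectors carry no information and such genes match essentially at
   random.

5. **Distances, matching, global score.** Local similarity between genes
   `a`, `b` of the two networks is the rescaled cosine distance
   `d(a, b) = 0.5 - 0.5 * <a, b>/(|a||b|)` (0 identical direction, 0.5
   orthogonal, 1 opposite). Dangling nodes are scaffolding and excluded
   from the reported distance matrix by default. The Hungarian algorithm
   (`scipy.optimize.linear_sum_assignment`, rectangular-capable) produces
   the minimum-total-distance one-to-one matching; surplus genes of the
   larger network are reported unmatched, never force-matched. The
   *global distance* is the mean matched distance — mean rather than sum
   so differently sized comparisons stay on one scale. Against a known
   correspondence, alignment accuracy is the *match fraction*: the
   proportion of matched pairs agreeing with the truth map.

6. **Anchored-landmark diagnostic.** To check that the scaffolding is
   doing its job, the mean cross-network distance of the landmark nodes
   to their counterparts is compared with the same statistic over
   `n_random = 1000` random equal-size gene sets; the permutation p-value
   uses the add-one estimator `(1 + #{null <= obs})/(1 + n_random)` and
   is never exactly zero (minimum 1/1001 ≈ 0.001).

7. **Biclustering.** The cross-network distance matrix is partitioned
   into an `n_row x n_col` checkerboard by spectral biclustering
   (scikit-learn, log normalisation), so each row gene belongs to
   `n_col` biclusters and vice versa. Biclusters are summarised by mean
   distance and ranked most-conserved first; mean distance above 0.5
   flags a "relatively distant" block. Cluster counts are analysis
   choices (default 5x5); scan a small grid and inspect the block means.
   Gene lists per bicluster are exported as plain text for external
   enrichment tools — over-representation analysis itself is out of
   scope. A constant matrix cannot be biclustered and falls back to a
   single block with a logged warning.

## Synthetic data

`synth_fixtures` makes the pipeline testable end-to-end without any
external download.

* `make_topology` builds the unit-weight benchmark graphs — line (path),
  circle (cycle), cross (two equal paths sharing a centre node) — whose
  self-alignment has a known answer: every gene must match itself.
  Default sizes are 50/50/51 nodes; the behaviour is size-insensitive at
  this scale.
* `simulate_expression` draws a block-structured Gaussian expression
  matrix: genes in a block share a latent factor per sample
  (`x = sqrt(rho) z + sqrt(1-rho) * noise_sd * eps`), so within-block
  pairwise correlation is `rho` (at `noise_sd = 1`) and cross-block
  correlation is 0. Thresholding yields near-clique modules — the
  minimal stand-in for modular co-expression structure. It does *not*
  emulate count noise, library-size effects, correlated blocks, hub
  genes, or scale-free degree distributions; passing tests on these
  fixtures demonstrate the pipeline's mechanics (gluing, matching,
  scoring), not performance on real RNA-seq.
* `split_replicates` cuts the sample columns into disjoint equal parts,
  emulating replicate networks from one population.

The replicate-versus-different contrast experiment (tests and the
acceptance script) uses 6 blocks x 4 genes, 200 samples, `rho = 0.95`,
`noise_sd = 1`, a 2-way split, and one anchor per module (6 anchors,
spread placement): replicate splits of one population must align at least
twice as well (mean over 5 seeds, non-anchor genes) as networks from two
populations with permuted block membership. Within a near-clique module
the genes are topologically interchangeable, so the within-replicate
match fraction is dominated by module-level correspondence plus the
fixed points of an arbitrary within-module assignment — a purely
topological method cannot do better on interchangeable nodes, which is
the honest analogue of comparing replicate networks without sequence
information.

## Parameters that matter

| parameter | default | meaning / why |
|---|---|---|
| `pcc_threshold` | 0.8 | two-sided cut on original PCC; standard stringency for GCNs |
| `gamma` | 8 | dangling-structure size; larger pins more directions, costs walk mass |
| `sparsity` | 0.15 | fraction of potential dangling edges; sparse = distinguishable landmarks |
| `n_anchors` | 3 | landmarks; scale with the number of network modules/regions |
| `anchor_strategy` | spread | farthest-point placement; random available |
| `walks_per_node` | 1000 | corpus size is the quality lever (with 1 data pass) |
| `walk_length` | 20 | walks diffuse ~sqrt(length); longer reaches landmarks from farther |
| `n_dim` | 6 | keep at/below the landmark-pinned rank (see above) |
| `window` | 5 | context reach along a walk; the most interpretation-sensitive knob |
| `epochs` | 1 | single data pass; corpus size substitutes for epochs |
| `negative` | 5 | negative samples per positive pair |
| `n_random` | 1000 | permutation-test null sets |

## Numerical choices and degenerate inputs

* PCC is computed on all samples; missing values are a precondition
  violation, zero-variance genes become isolated nodes with a warning.
* Per-node transition tables sum to 1 within 1e-12; zero-weight edges
  (PCC = -1) are preserved in the graph but can never be traversed.
* Every stochastic stage (anchor choice, structure generation, walks,
  training init, permutation test) draws its own sub-seed from the run
  seed via `SeedSequence`, so stages are decorrelated but the whole run
  is reproducible bit-for-bit; training itself is full-batch and
  single-threaded.
* Cosine distances are clipped into [0, 1] against float rounding;
  self-distance of a shared token is 0 up to float64 rounding (< 1e-12).
* Ties in the assignment problem are broken deterministically by the
  solver; two genes at exactly equal distance may swap between runs with
  different seeds (visible on interchangeable clique members).

## Known limitations

* The full-batch trainer materialises a dense vocabulary x vocabulary
  count matrix: fine to a few thousand genes per network, too large for
  whole-transcriptome GCNs (tens of thousands of genes) without chunking
  or a sparse-count refactor.
* Spectral biclustering's checkerboard model is multiplicative: row or
  column clusters whose blocks differ by a purely additive offset are
  invisible to its normalisation and merge. The planted-recovery tests
  therefore plant outer-product block means.
* Anchors must actually occupy conserved positions; anchoring genes whose
  co-expression context differs between networks drags their
  neighbourhoods toward false similarity. The permutation diagnostic
  (step 6) is the guard: run it before trusting a comparison.
* Interchangeable nodes (members of a symmetric module) cannot be
  individually matched by any topology-only method; match fractions on
  such structures measure module correspondence, not gene identity.
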