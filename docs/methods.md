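# Methods

## The multipartite network

Each omics layer is a nonnegative feature-by-sample matrix in its own units.
After per-branch filtering and an optional `ln(x+1)` transform, every weight
is rounded half away from zero into an integer edge multiplicity; a weight
rounding to zero produces no edge, and features left with no edge are
dropped (and reported). The resulting multigraph is star-shaped: samples in
the center, one branch of feature nodes per layer, no edges within a branch
and none between samples. Unfolding weights into unit edges makes every
count in the model and in the topic distributions an integer number of
half-edges, and the log transform keeps the total edge count `E` — the main
driver of fitting cost — manageable for heavy-tailed expression data.

Cross-branch feature–feature links (e.g. curated gene–miRNA target
interactions) may be added as unit edges; they are the only permitted
deviation from the star and let prior regulatory knowledge pull regulating
and regulated features toward mutually consistent topics.

### Preprocessing defaults

- **Highly-variable selection**: dispersion = variance/mean (sample variance,
  ddof = 1), z-scored within 20 equal-count bins of features ranked by mean;
  top `n_top` kept, ties broken lexicographically by feature id. Features
  with zero mean are never candidates. The rule is deterministic and
  invariant to sample order and to a global rescaling of the matrix.
- **Copy-number branch**: keep features with mean copy number strictly
  greater than 3.5, i.e. at least two extra copies on average over a diploid
  baseline.
- **Order of operations**: select features on the raw weights, then
  transform, then round. Selection runs separately per branch; branches are
  never normalized against each other.

## The block model

Blocks are *hard* and *type-pure*: every node belongs to exactly one block
and every block holds nodes of one kind. Sample blocks are clusters; feature
blocks are topics of their branch. For a partition `b` the description
length in nats is

    Σ = −ln P(A|k,e,b) − ln P(k|e,b) − ln P(e|b) − ln P(b)

with the microcanonical degree-corrected multigraph likelihood (no
same-kind edges, hence no within-block edges or self-loops)

    P(A|k,e,b) = [ Π_{r<s} e_rs! · Π_i k_i! ] / [ Π_{i<j} A_ij! · Π_r e_r! ]

and uniform priors: degree sequences `P(k|e,b) = Π_r multiset(n_r, e_r)^-1`;
edge-count matrices `P(e|b) = multiset(N_pairs, E)^-1`, where `N_pairs` sums
`B_a·B_b` over the kind pairs that carry edges in the data; and partitions
`P(b) = Π_kinds (Π_r n_r!)/n! · C(n−1, B−1)^-1 · n^-1`. Degree correction
matters because expression totals are heavy-tailed: the likelihood
conditions on node degrees instead of forcing degree homogeneity within
blocks.

The hierarchy is nested: the block multigraph of one level (nodes = blocks,
edge counts = `e_rs`) becomes the data of the next, whose likelihood
replaces the flat `P(e|b)` term below it; only the top level keeps the
uniform edge-matrix prior. A candidate level is kept only if it lowers the
total nested Σ. Levels are synchronized across kinds: each level
repartitions the blocks of all kinds at once.

## Inference

Each restart runs:

1. **Agglomerative descent** from the all-singleton partition: repeatedly
   apply the cheapest available block merges — about a quarter of the excess
   block count per step, chosen among neighbor-guided candidates (all
   same-kind pairs when a kind has ≤ 12 blocks) — down to one block per
   kind, with short node-move polish passes at each plateau. Merges are
   forced even when mildly worsening, because sibling merges have an energy
   barrier: the best state seen along the trajectory is kept, not the final
   one.
2. **Refinement sweeps** at the selected resolution: zero-temperature
   single-node moves proposed with the smoothed kernel
   `P(r→s|t) = (e_ts + ε)/(e_t + εB)` (a random neighbor's block `t`, target
   kinds restricted to the moving node's kind; ε defaults to 1), greedy
   best-move passes that include a fresh-block target, improving merges, and
   random-bisection split attempts. Sweeps stop after 10 consecutive passes
   without improvement, or immediately once a fully exhaustive pass finds no
   improving move.

`fit` runs `n_init = 10` restarts (the first from singletons, the rest from
random type-pure partitions with random block counts) on seeds derived from
the master seed, and returns the shortest total Σ, ties going to the lowest
restart index. Fits are bit-reproducible given a seed. ΔΣ is maintained
incrementally during moves and merges; the suite asserts agreement with a
from-scratch recomputation to 1e-9 relative after arbitrary move sequences.

`merge_split_refine` reuses the same move set (merges, splits, node moves)
on the finest level of an existing fit — typically after feature links have
been added, which changes the description-length landscape — keeps the best
state seen, refits the upper levels, and never returns a longer description
than the input partition scored on the given network.

## Topic outputs

`P(topic|sample)` and `P(feature|topic)` are half-edge ratios per branch and
level; rows and columns sum to one by construction, and multiplying back by
the totals recovers the integer counts. Samples with no edges toward a
branch (possible after rounding) have an undefined mixture there; they are
excluded from that branch's table and listed in its metadata rather than
imputed. Topics are indexed 0, 1, … by decreasing feature count (block id
breaks ties); the index carries no meaning across levels or runs. Centered
profiles subtract the cohort mean from each topic column — so each column
sums to zero — and average within subtype labels, flagging subtype-enriched
topics as the most positive entries.

## Evaluation

NMI is the harmonic mean of homogeneity and completeness computed from
Shannon entropies; it is 1 exactly for a relabeling of the annotation and 0
by convention for the degenerate single-cluster partition. Because a random
partition retains residual mutual information — increasingly so at fine
resolutions — NMI is reported against NMI*, its mean over 50 label shuffles
that preserve cluster sizes and label counts (the standard deviation is
logged too); the NMI/NMI* ratio measures information above chance and is
only meaningful for comparing models on the same data. AMI (permutation
null, max normalization) compares two labelings symmetrically. Topic
enrichment against an annotation set uses the one-sided upper-tail
hypergeometric test (enrichment only, no depletion).

Model comparison reports per-edge description lengths `Σ/E` and their
difference Δ, exponentiated to a Bayes factor `Λ = exp(Δ)` with
`log10 Λ = Δ/ln 10`. Exponentiating a *per-edge* difference mixes units —
a total-Σ difference would be the strict posterior-odds reading — but it is
the convention this package reproduces for comparability; both the per-edge
lengths and Δ are reported so either reading can be applied.

## Survival analysis

Lifetimes come from days-to-death (event = 1) for deceased patients and
days-to-last-follow-up (event = 0, censored) for living ones; records
missing the required field or with nonpositive lifetime are dropped and
logged. Tumor stages are canonicalized to stage i–iv by stripping sub-stage
letters; unmappable values become missing.

A topic is *upregulated* in a sample when `P(topic|sample)` strictly exceeds
the cohort's 35th percentile (linear interpolation between order
statistics); the flag is rank-based, hence invariant to monotone transforms
of the weights, and constant weights flag nobody. The Cox model maximizes
the Breslow-tie partial likelihood by damped Newton iteration to gradient
norm < 1e-8; `exp(coef)` is the hazard ratio of flagged vs unflagged
patients. Complete separation (monotone likelihood) and singular information
matrices raise errors naming the covariate. Breslow ties were chosen as the
simplest consistent rule; on tie-free data the estimates coincide with
Efron-based fits, which the suite uses as an independent cross-check.
Kaplan–Meier curves use the product-limit estimator (censored subjects
leave the risk set without a step).

Cluster prognosis is the fraction of a cluster's patients alive 3 years
(1095 days) after diagnosis. Patients censored before the horizon are not
evaluable and are excluded from the fraction (counting them as
non-survivors is available via the evaluability rule, not the default). The
Z-score standardizes the cluster's fraction against 100 size-matched random
patient draws from the whole cohort; the whole cohort as one cluster gives
Z = 0 by construction.

## Synthetic data

The generator plants the structure the model assumes: samples in clusters,
features in per-branch topics, and a binary cluster-by-topic affinity
deciding where weight concentrates. Weights are Poisson with mean `mu_high`
on affine (cluster, topic) pairs and `mu_low` elsewhere, so multiplicities
are natively integers and inference correctness is tested without a
discretization confound; a log-normal mode produces continuous weights to
exercise the transform-and-round path. Defaults are the study conditions
used throughout the tests: 60 samples in 3 equal clusters, two branches of
40 features in 4 equal topics (topic `t` affine to cluster `t mod 3`), and
`mu_high/mu_low = 8/0.5`. With 4 topics and 3 clusters, two topics of each
branch share an affinity column and are statistically exchangeable, so a
correct fit merges them: cluster recovery is the primary target, topic
recovery is only defined up to that merge.

Survival outcomes are exponential lifetimes with per-cluster hazard
multipliers over a baseline of 5e-4 events/day (mean lifetime 2000 days;
the default poor-prognosis cluster has multiplier 4, mean 500 days).
Censoring is independent: censor times are uniform on `(0, u)` with `u`
solved so the expected censored fraction matches the requested 20%;
censoring times are never drawn conditional on the lifetime, which would
bias hazard-ratio estimates. Regulatory links join features whose topics
share an affine cluster with probability `fraction_consistent`, otherwise
uniformly at random.

What the generator does not emulate: empirical FPKM distributions,
overdispersion beyond Poisson, batch effects, missing data, or correlated
features within a topic. Passing tests demonstrate correct inference under
the planted model, not performance on real cohorts.

## Numerical choices and limitations

- Improvement threshold 1e-10 nats on ΔΣ; equal-Σ restarts resolve to the
  lowest restart index, so results are deterministic given a seed.
- Log-factorials come from a precomputed `gammaln` table sized by the
  worst-case multiset index, shared across hierarchy levels.
- Problem sizes in the tests and the acceptance script (60–300 samples,
  tens of features per branch, 20 exhaustively enumerable toy networks)
  were chosen so the full suite runs in a few minutes on one CPU; the
  engine itself is O(E) per sweep with dense block-pair bookkeeping, and
  has been exercised up to a few hundred nodes and ~15k edges.
- Blocks are hard; overlapping or fuzzy memberships are out of scope, as
  are GPU execution and external enrichment databases (topic membership
  lists are the hand-off point for GSEA-style tools).
- The optimizer is a stochastic heuristic: exactness is verified
  exhaustively only on tiny networks, and on larger data the usual caveats
  of description-length local minima apply — hence the 10-restart default.
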