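# mosbm — multipartite SBM topic modeling for multi-omics data

`mosbm` clusters samples and groups omics features into *topics* at the same
time, from any number of omics layers, without reweighting them against each
other. Samples (e.g. tumor biopsies) sit at the center of a star-shaped
multipartite network; each layer — protein-coding gene expression in FPKM,
miRNA counts per million, per-gene copy numbers — is a branch of feature
nodes, and a weight `w_ij` becomes `w_ij` parallel unit edges. A nested
degree-corrected stochastic block model (SBM) is fitted to this multigraph by
minimizing its description length, yielding a hierarchy of sample clusters
and per-branch topics together with the probabilistic outputs

```
P(topic|sample)  = half-edges on the sample from the topic's features
                   ─────────────────────────────────────────────────
                   half-edges on the sample toward that branch

P(feature|topic) = half-edges of the topic going to the feature
                   ─────────────────────────────────────────
                   total half-edges of the topic
```

It is aimed at transcriptomics practitioners who want subtype discovery and
signature extraction from joint mRNA + miRNA (+ CNV, ...) data with a
nonparametric model: no preset number of clusters or topics, no parametric
topic prior, and no per-layer weighting, since each branch enters the
likelihood with its own normalization.

## The model

For a type-pure partition `b` (sample blocks = clusters, feature blocks =
topics) the posterior `P(b|A) ∝ P(A|b) P(b)` is scored by the description
length in nats, `Σ = −ln P(A|b) − ln P(b)`, under the microcanonical
degree-corrected SBM for multigraphs, with uniform priors over degree
sequences, edge-count matrices, and partitions (the exact decomposition is
documented in `mosbm/sbm.py` and `docs/methods.md`). Inference uses
agglomerative descent plus greedy sweeps of single-node moves proposed with
the smoothed kernel

```
P(r→s|t) = (e_ts + ε) / (e_t + εB)
```

restricted to the moving node's kind, over `n_init` restarts; the shortest Σ
wins. Coarser levels are fitted recursively on the block multigraph and kept
only when they lower the total nested Σ. Two fits of the same data can be
compared by their per-edge lengths: `Δ = Σ_a/E − Σ_b/E` exponentiates to a
Bayes factor `Λ = exp(Δ)`.

Evaluation tools (NMI as the homogeneity/completeness harmonic mean, its
shuffled null NMI*, AMI, hypergeometric topic enrichment), centered subtype
profiles `P̄(topic|subtype)`, and a survival module (35th-percentile topic
upregulation flags, Breslow-tie Cox regression, Kaplan–Meier curves, 3-year
cluster prognosis with random-cluster Z-scores) complete the pipeline, and a
planted-block generator provides ground-truthed synthetic data for all of it.

## Worked example

```python
import pandas as pd
from mosbm import (PlantedModel, generate_layers, generate_survival,
                   build_network, fit_blockmodel)
from mosbm.evaluation import score_partition
from mosbm.topics import topic_sample_distribution
from mosbm.survival import cluster_prognosis

model = PlantedModel()          # 60 samples, 3 clusters, 2 branches x 4 topics
layers, truth = generate_layers(model, seed=0)
network = build_network(layers)
print(f"network: V={network.V} nodes, E={network.E} unit edges")

hierarchy = fit_blockmodel(network, n_init=10, seed=0)
print(f"description length: {hierarchy.sigma:.1f} nats "
      f"({hierarchy.sigma / network.E:.3f} nats/edge), {hierarchy.n_levels} level(s)")
clusters = hierarchy.sample_clusters(0)

score = score_partition(clusters, truth["cluster_labels"], n_shuffles=50, seed=0)
print(f"NMI={score.nmi:.3f}  NMI*={score.nmi_star:.3f}  NMI/NMI*={score.ratio:.1f}")

p_ts = topic_sample_distribution(network, hierarchy, level=0, branch="mirna")
print("P(miRNA-topic|sample), first sample:", p_ts.iloc[0].round(3).tolist())

survival = generate_survival(model, truth["cluster_labels"], seed=0)
print(cluster_prognosis(survival, clusters, seed=0).round(2))
```

prints

```
network: V=140 nodes, E=14490 unit edges
description length: 7495.9 nats (0.517 nats/edge), 1 level(s)
NMI=1.000  NMI*=0.029  NMI/NMI*=34.2
P(miRNA-topic|sample), first sample: [0.93, 0.025, 0.045]
          n  n_evaluable  fraction_surviving  z_score
cluster
0        20           18                0.67     2.11
1        20           19                0.11    -4.03
2        20           17                0.65     1.78
```

The fit recovers the three planted clusters exactly (NMI = 1 against the
ground truth, 34× above the shuffled-label null); the first sample draws 93%
of its miRNA half-edges from one topic; and the cluster holding the planted
high-hazard samples shows poor prognosis (11% alive at three years,
Z ≈ −4 against size-matched random patient draws).

The same pipeline is scriptable from the shell via the `mosbm` command
(`simulate`, `preprocess`, `fit`, `topics`, `evaluate`, `survival`,
`compare`); run `mosbm --help` for the artifact formats.

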