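"""Partition scoring and model comparison.

NMI here is the harmonic mean of homogeneity and completeness computed from
Shannon entropies (the V-measure): a partition scores 1 only when it matches
the annotation up to renaming, and 0 in the degenerate one-cluster case.
Because even random partitions retain residual mutual information — more so
at fine resolutions with many clusters — NMI is reported against NMI*, its
mean over label shuffles that preserve both the cluster sizes and the label
counts; the ratio NMI/NMI* measures information learned above chance.

Models fitted to the same data are compared on their per-edge description
length Σ/E: the difference Δ exponentiates to a Bayes factor Λ = exp(Δ)
(posterior odds, the posterior being exp(−Σ)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.metrics import adjusted_mutual_info_score, v_measure_score

__all__ = [
    "nmi",
    "nmi_star",
    "ami",
    "score_partition",
    "PartitionScore",
    "hypergeom_enrichment",
    "compare_models",
    "ModelComparison",
]


def _as_labels(x) -> np.ndarray:
    arr = np.asarray(x.to_numpy() if isinstance(x, pd.Series) else x)
    if arr.ndim != 1:
        raise ValueError("labelings must be one-dimensional")
    return arr


def nmi(partition, labels) -> float:
    """Harmonic mean of homogeneity and completeness of ``partition`` vs ``labels``."""
    p, l = _as_labels(partition), _as_labels(labels)
    if p.size != l.size:
        raise ValueError("partition and labels must cover the same samples")
    if p.size < 2:
        raise ValueError("need at least two samples")
    return float(v_measure_score(l, p))


def nmi_star(partition, labels, n_shuffles: int = 50, seed: int | None = None) -> float:
    """Mean NMI after shuffling labels across samples, cluster sizes untouched."""
    p, l = _as_labels(partition), _as_labels(labels)
    rng = np.random.default_rng(seed)
    return float(np.mean([nmi(p, rng.permutation(l)) for _ in range(n_shuffles)]))


def ami(labels_a, labels_b) -> float:
    """Mutual information adjusted for chance (permutation model, max-normalized)."""
    a, b = _as_labels(labels_a), _as_labels(labels_b)
    return float(adjusted_mutual_info_score(a, b, average_method="max"))


@dataclass
class PartitionScore:
    """NMI, its shuffled null NMI*, their ratio, and AMI for one partition."""

    nmi: float
    nmi_star: float
    nmi_star_std: float
    ratio: float
    ami: float
    n_shuffles: int
    seed: int | None


def score_partition(
    partition, labels, n_shuffles: int = 50, seed: int | None = None
) -> PartitionScore:
    """Score a sample partition against an annotation, with its shuffled null."""
    p, l = _as_labels(partition), _as_labels(labels)
    value = nmi(p, l)
    rng = np.random.default_rng(seed)
    null = np.array([nmi(p, rng.permutation(l)) for _ in range(n_shuffles)])
    star = float(null.mean())
    ratio = value / star if star > 0 else np.inf
    return PartitionScore(value, star, float(null.std()), ratio, ami(p, l), n_shuffles, seed)


def hypergeom_enrichment(topic_features, annotation_set, universe) -> float:
    """Upper-tail hypergeometric p-value for a topic/annotation overlap.

    Population = the feature universe, successes = annotated features, draws
    = the topic; returns P(X >= observed overlap), i.e. enrichment only.
    """
    universe = set(universe)
    topic = set(topic_features)
    if not topic <= universe:
        raise ValueError("topic features must be a subset of the universe")
    annotation = set(annotation_set) & universe
    M, K, n = len(universe), len(annotation), len(topic)
    k = len(topic & annotation)
    return float(hypergeom.sf(k - 1, M, K, n))


@dataclass
class ModelComparison:
    """Per-edge description lengths of two models and their Bayes factor."""

    sigma_per_edge_a: float
    sigma_per_edge_b: float
    delta: float
    bayes_factor: float
    log10_bayes_factor: float


def compare_models(sigma_a: float, e_a: int, sigma_b: float, e_b: int) -> ModelComparison:
    """Compare two fits on the information needed to describe one edge.

    ``delta = sigma_a/e_a − sigma_b/e_b``; positive values favor model b
    (shorter description). The Bayes factor is ``exp(delta)`` with its
    base-10 logarithm ``delta/ln 10``; the exponentiated per-edge difference
    follows the convention of reporting compressibility per edge.
    """
    if e_a <= 0 or e_b <= 0:
        raise ValueError("edge counts must be positive")
    per_a = sigma_a / e_a
    per_b = sigma_b / e_b
    delta = per_a - per_b
    return ModelComparison(per_a, per_b, delta, float(np.exp(delta)), delta / np.log(10))
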