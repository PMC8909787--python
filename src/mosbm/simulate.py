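"""Planted-block synthetic multiomics data with known ground truth.

The generator emulates the structure the block model assumes: samples fall
into clusters, each branch's features fall into topics, and a binary
cluster-by-topic affinity matrix decides where weight concentrates. The
weight of feature *f* (topic *t*) in sample *s* (cluster *c*) is Poisson with
mean ``mu_high`` when ``affinity[c, t] = 1`` and ``mu_low`` otherwise, so
multiplicities are natively integers and inference can be tested without a
discretization confound. A log-normal mode produces continuous weights for
exercising the log-transform + rounding path. Survival outcomes are
exponential lifetimes whose hazard is scaled per cluster, with independent
uniform censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .layers import OmicsLayer

__all__ = [
    "PlantedModel",
    "generate_layers",
    "generate_survival",
    "generate_regulatory_links",
    "default_affinity",
]


def default_affinity(n_clusters: int, n_topics: int) -> np.ndarray:
    """Binary affinity assigning topic t to cluster t mod n_clusters."""
    aff = np.zeros((n_clusters, n_topics), dtype=int)
    for t in range(n_topics):
        aff[t % n_clusters, t] = 1
    return aff


@dataclass
class PlantedModel:
    """Ground-truth configuration of a planted multiomics dataset.

    Defaults follow the desk-scale study conditions used throughout the test
    suite: 60 samples in 3 equal clusters, two branches of 40 features in 4
    equal topics each, strong contrast ``mu_high/mu_low = 8/0.5``, and a
    poor-prognosis third cluster (hazard multiplier 4 over a baseline rate of
    5e-4 events/day, i.e. a mean lifetime of 2000 days vs 500 days) with 20%
    uniform censoring.
    """

    n_samples: int = 60
    cluster_sizes: tuple[int, ...] = (20, 20, 20)
    branches: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: {"genes": (10, 10, 10, 10), "mirna": (10, 10, 10, 10)}
    )
    affinity: dict[str, np.ndarray] | None = None
    mu_high: float = 8.0
    mu_low: float = 0.5
    weight_mode: str = "poisson"  # or "lognormal"
    lognormal_sigma: float = 0.5
    baseline_rate: float = 5e-4  # events per day
    hazard_multipliers: tuple[float, ...] = (1.0, 1.0, 4.0)
    censoring_fraction: float = 0.2
    seed: int | None = 0

    def __post_init__(self) -> None:
        if sum(self.cluster_sizes) != self.n_samples:
            raise ValueError("cluster sizes must sum to n_samples")
        if any(s <= 0 for s in self.cluster_sizes):
            raise ValueError("cluster sizes must be positive")
        if not self.mu_high > self.mu_low >= 0:
            raise ValueError("need mu_high > mu_low >= 0")
        if len(self.hazard_multipliers) != len(self.cluster_sizes):
            raise ValueError("one hazard multiplier per cluster")
        if any(h <= 0 for h in self.hazard_multipliers):
            raise ValueError("hazard multipliers must be positive")
        n_clusters = len(self.cluster_sizes)
        if self.affinity is None:
            self.affinity = {
                name: default_affinity(n_clusters, len(sizes))
                for name, sizes in self.branches.items()
            }
        for name, sizes in self.branches.items():
            aff = np.asarray(self.affinity[name])
            if aff.shape != (n_clusters, len(sizes)):
                raise ValueError(f"affinity shape mismatch for branch {name!r}")

    @property
    def cluster_labels(self) -> np.ndarray:
        return np.repeat(np.arange(len(self.cluster_sizes)), self.cluster_sizes)

    def topic_labels(self, branch: str) -> np.ndarray:
        sizes = self.branches[branch]
        return np.repeat(np.arange(len(sizes)), sizes)


def generate_layers(
    model: PlantedModel, seed: int | None = None
) -> tuple[list[OmicsLayer], dict]:
    """Draw the per-branch weight matrices and return them with ground truth.

    Returns ``(layers, truth)`` where ``truth`` holds ``cluster_labels``
    (per sample) and ``topic_labels`` (per branch, per feature).
    """
    rng = np.random.default_rng(model.seed if seed is None else seed)
    clusters = model.cluster_labels
    sample_ids = [f"sample_{i:03d}" for i in range(model.n_samples)]
    layers = []
    truth = {
        "cluster_labels": pd.Series(clusters, index=sample_ids, name="cluster"),
        "topic_labels": {},
    }
    for name, sizes in model.branches.items():
        topics = model.topic_labels(name)
        aff = np.asarray(model.affinity[name])
        mu = np.where(aff[np.ix_(clusters, topics)] == 1, model.mu_high, model.mu_low).T
        if model.weight_mode == "poisson":
            weights = rng.poisson(mu).astype(float)
        elif model.weight_mode == "lognormal":
            # log-normal with mean mu (zero where mu == 0)
            s = model.lognormal_sigma
            with np.errstate(divide="ignore"):
                logmu = np.where(mu > 0, np.log(np.maximum(mu, 1e-300)) - s * s / 2, -np.inf)
            weights = np.where(mu > 0, rng.lognormal(np.where(mu > 0, logmu, 0.0), s), 0.0)
        else:
            raise ValueError(f"unknown weight_mode {model.weight_mode!r}")
        feature_ids = [f"{name}_{f:03d}" for f in range(len(topics))]
        layers.append(
            OmicsLayer(name, pd.DataFrame(weights, index=feature_ids, columns=sample_ids))
        )
        truth["topic_labels"][name] = pd.Series(topics, index=feature_ids, name="topic")
    return layers, truth


def generate_survival(
    model: PlantedModel, cluster_labels: pd.Series, seed: int | None = None
) -> pd.DataFrame:
    """Exponential lifetimes with per-cluster hazards and uniform censoring.

    Returns a survival table with columns ``lifetime`` (days), ``event``
    (1 = death observed), ``cluster``, ``stage``, ``age``, ``gender``.
    """
    rng = np.random.default_rng(model.seed if seed is None else seed)
    labels = cluster_labels.to_numpy()
    rates = model.baseline_rate * np.asarray(model.hazard_multipliers)[labels]
    lifetime = rng.exponential(1.0 / rates)
    event = np.ones(labels.size, dtype=int)
    if model.censoring_fraction > 0:
        # independent censoring: C ~ U(0, u) drawn independently of the
        # lifetime, with u solved so the expected censored fraction matches;
        # for T ~ Exp(rate), P(C < T) = (1 - exp(-rate*u)) / (rate*u)
        from scipy.optimize import brentq

        def frac_censored(u: float) -> float:
            return float(np.mean((1.0 - np.exp(-rates * u)) / (rates * u)))

        hi = 1.0 / rates.min()
        while frac_censored(hi) > model.censoring_fraction:
            hi *= 2
        u = brentq(lambda x: frac_censored(x) - model.censoring_fraction, 1e-9, hi)
        ctime = rng.uniform(0, u, labels.size)
        event = (lifetime <= ctime).astype(int)
        lifetime = np.minimum(lifetime, ctime)
    lifetime = np.maximum(lifetime, 1e-3)  # keep lifetimes strictly positive
    table = pd.DataFrame(
        {
            "lifetime": lifetime,
            "event": event,
            "cluster": labels,
            "stage": rng.choice(["stage i", "stage ii", "stage iii", "stage iv"], labels.size),
            "age": np.round(rng.normal(60, 10, labels.size), 1),
            "gender": rng.choice(["female", "male"], labels.size, p=[0.99, 0.01]),
        },
        index=cluster_labels.index,
    )
    table.index.name = "sample_id"
    return table


def generate_regulatory_links(
    model: PlantedModel,
    n_links: int,
    fraction_consistent: float = 1.0,
    branches: tuple[str, str] | None = None,
    seed: int | None = None,
) -> list[tuple[str, str, str, str]]:
    """Cross-branch feature-feature links mirroring (or ignoring) the planting.

    A link is *consistent* when the two features' topics are affine to at
    least one common cluster; each link is consistent with probability
    ``fraction_consistent`` and uniform noise otherwise.
    """
    if len(model.branches) < 2:
        raise ValueError("need at least two branches for regulatory links")
    if branches is None:
        names = list(model.branches)
        branches = (names[0], names[1])
    ba, bb = branches
    rng = np.random.default_rng(model.seed if seed is None else seed)
    topics_a = model.topic_labels(ba)
    topics_b = model.topic_labels(bb)
    aff_a = np.asarray(model.affinity[ba])
    aff_b = np.asarray(model.affinity[bb])
    # topic-topic consistency: share at least one affine cluster
    consistent_tt = (aff_a.T @ aff_b) > 0
    pairs_all = [(fa, fb) for fa in range(topics_a.size) for fb in range(topics_b.size)]
    pairs_cons = [
        (fa, fb) for fa, fb in pairs_all if consistent_tt[topics_a[fa], topics_b[fb]]
    ]
    if fraction_consistent > 0 and not pairs_cons:
        raise ValueError("no consistent feature pairs exist under the planted affinity")
    links = []
    for _ in range(n_links):
        pool = pairs_cons if rng.random() < fraction_consistent else pairs_all
        fa, fb = pool[rng.integers(len(pool))]
        links.append((f"{ba}_{fa:03d}", ba, f"{bb}_{fb:03d}", bb))
    return links
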