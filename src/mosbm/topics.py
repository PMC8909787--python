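"""Probabilistic topic outputs of a fitted block hierarchy.

A topic is a block of feature nodes of one branch at one hierarchy level.
Because weights are unfolded into unit edges, the topic mixtures are simple
half-edge ratios:

    P(topic|sample)  = half-edges on the sample coming from the topic's
                       features / half-edges on the sample toward that branch
    P(feature|topic) = half-edges of the topic going to the feature /
                       total half-edges of the topic

Topics are indexed 0, 1, ... by decreasing feature count (stable: block id
breaks ties), mirroring the "gene-topic 8 / miRNA-topic 7" naming style.
Samples with no edge toward a branch (possible after rounding) have an
undefined mixture there and are excluded from that branch's tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import MultipartiteNetwork
from .sbm import BlockHierarchy

__all__ = [
    "topic_members",
    "topic_sample_distribution",
    "feature_topic_distribution",
    "centered_profile",
    "CenteredProfile",
]


def _topic_order(hierarchy: BlockHierarchy, level: int, branch: str) -> dict[int, int]:
    """Map branch block id -> topic index (0.. by decreasing size)."""
    blocks = hierarchy.branch_blocks(level, branch)
    sizes = blocks.value_counts()
    ordered = sorted(sizes.index, key=lambda blk: (-sizes[blk], blk))
    return {int(blk): idx for idx, blk in enumerate(ordered)}


def topic_members(hierarchy: BlockHierarchy, level: int, branch: str) -> dict[int, list[str]]:
    """Feature ids per topic; disjoint and exhaustive over the branch."""
    blocks = hierarchy.branch_blocks(level, branch)
    order = _topic_order(hierarchy, level, branch)
    members: dict[int, list[str]] = {t: [] for t in range(len(order))}
    for fid, blk in blocks.items():
        members[order[int(blk)]].append(fid)
    return members


def _branch_half_edges(
    network: MultipartiteNetwork, hierarchy: BlockHierarchy, level: int, branch: str
) -> pd.DataFrame:
    """Samples x topics table of half-edge counts toward one branch."""
    order = _topic_order(hierarchy, level, branch)
    labels = hierarchy.assignments[level]
    kinds = np.asarray(network.node_kinds, dtype=object)
    sample_idx = np.flatnonzero(kinds == "sample")
    sample_pos = {int(n): p for p, n in enumerate(sample_idx)}
    counts = np.zeros((sample_idx.size, len(order)), dtype=np.int64)
    for u, v, m in network.edges:
        ku, kv = kinds[u], kinds[v]
        if ku == "sample" and kv == branch:
            s, f = int(u), int(v)
        elif kv == "sample" and ku == branch:
            s, f = int(v), int(u)
        else:
            continue
        counts[sample_pos[s], order[int(labels[f])]] += int(m)
    ids = [network.node_ids[i] for i in sample_idx]
    return pd.DataFrame(counts, index=pd.Index(ids, name="sample_id"), columns=range(len(order)))


def topic_sample_distribution(
    network: MultipartiteNetwork, hierarchy: BlockHierarchy, level: int, branch: str
) -> pd.DataFrame:
    """P(topic|sample): samples x topics, rows summing to one.

    Samples without edges toward the branch are dropped from the table (their
    mixture is undefined); the drop is recorded in ``df.attrs['excluded']``.
    """
    counts = _branch_half_edges(network, hierarchy, level, branch)
    totals = counts.sum(axis=1)
    defined = totals > 0
    out = counts.loc[defined].div(totals[defined], axis=0)
    out.attrs["excluded"] = totals.index[~defined].tolist()
    return out


def feature_topic_distribution(
    network: MultipartiteNetwork, hierarchy: BlockHierarchy, level: int, branch: str
) -> pd.DataFrame:
    """P(feature|topic): features x topics, columns summing to one."""
    order = _topic_order(hierarchy, level, branch)
    labels = hierarchy.assignments[level]
    kinds = np.asarray(network.node_kinds, dtype=object)
    feat_idx = np.flatnonzero(kinds == branch)
    feat_pos = {int(n): p for p, n in enumerate(feat_idx)}
    half = np.zeros(feat_idx.size, dtype=np.int64)
    for u, v, m in network.edges:
        if int(u) in feat_pos:
            half[feat_pos[int(u)]] += int(m)
        if int(v) in feat_pos:
            half[feat_pos[int(v)]] += int(m)
    table = np.zeros((feat_idx.size, len(order)), dtype=float)
    topic_tot = np.zeros(len(order), dtype=np.int64)
    for p, n in enumerate(feat_idx):
        t = order[int(labels[n])]
        table[p, t] = half[p]
        topic_tot[t] += half[p]
    if (topic_tot == 0).any():
        empty = [t for t in range(len(order)) if topic_tot[t] == 0]
        raise ValueError(f"empty topic(s) {empty} have no half-edges")
    table /= topic_tot[np.newaxis, :]
    ids = [network.node_ids[i] for i in feat_idx]
    return pd.DataFrame(table, index=pd.Index(ids, name="feature_id"), columns=range(len(order)))


@dataclass
class CenteredProfile:
    """Topic mixtures centered on the dataset-wide mean.

    ``per_sample`` is P̄(topic|sample) = P(topic|sample) − mean over samples,
    so each topic column sums to zero; ``per_subtype`` averages the centered
    values within each subtype label, flagging topics enriched or depleted in
    a subtype relative to the cohort.
    """

    per_sample: pd.DataFrame
    per_subtype: pd.DataFrame
    n_samples: int


def centered_profile(p_topic_given_sample: pd.DataFrame, subtype_labels: pd.Series) -> CenteredProfile:
    """Center the topic mixtures and average them per subtype."""
    missing = p_topic_given_sample.index.difference(subtype_labels.index)
    if len(missing):
        raise ValueError(f"samples without a subtype label: {list(missing[:5])}")
    labels = subtype_labels.loc[p_topic_given_sample.index]
    centered = p_topic_given_sample - p_topic_given_sample.mean(axis=0)
    per_subtype = centered.groupby(labels).mean()
    per_subtype.index.name = "subtype"
    return CenteredProfile(centered, per_subtype, len(centered))
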