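"""The multipartite star multigraph joining samples to omics features.

Samples sit at the center; each omics layer contributes one branch of feature
nodes. A weight ``w_ij`` between feature *i* and sample *j* is interpreted as
``w_ij`` parallel unit edges, so every count entering the block-model
likelihood and the topic distributions is an integer number of half-edges.
The topology is star-like: features never connect within a branch and samples
never connect to samples. Cross-branch feature-feature links (e.g. known
gene-miRNA regulatory interactions) may be added explicitly and are the only
permitted deviation from the star.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .layers import OmicsLayer

SAMPLE_KIND = "sample"

__all__ = ["MultipartiteNetwork", "build_network", "add_feature_links", "SAMPLE_KIND"]


@dataclass
class MultipartiteNetwork:
    """Typed multigraph with integer edge multiplicities.

    Nodes are indexed ``0..V-1``; ``node_ids`` holds their external names and
    ``node_kinds`` their type (``"sample"`` or a branch name). ``edges`` is an
    ``(n_distinct, 3)`` integer array of ``(u, v, multiplicity)`` rows with
    ``u < v`` and multiplicity >= 1.
    """

    node_ids: list[str]
    node_kinds: list[str]
    edges: np.ndarray
    branch_names: list[str]
    dropped_features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 3)
        if len(self.node_ids) != len(self.node_kinds):
            raise ValueError("node_ids and node_kinds length mismatch")
        if self.edges.size:
            if self.edges[:, :2].min() < 0 or self.edges[:, :2].max() >= self.V:
                raise ValueError("edge endpoint out of range")
            if (self.edges[:, 2] < 1).any():
                raise ValueError("edge multiplicities must be >= 1")
        self._check_topology()

    def _check_topology(self) -> None:
        kinds = np.asarray(self.node_kinds, dtype=object)
        for u, v, _ in self.edges:
            ku, kv = kinds[u], kinds[v]
            if ku == kv:
                raise ValueError(
                    f"forbidden edge between two {ku!r} nodes "
                    f"({self.node_ids[u]!r}, {self.node_ids[v]!r})"
                )

    @property
    def V(self) -> int:
        return len(self.node_ids)

    @property
    def E(self) -> int:
        return int(self.edges[:, 2].sum()) if self.edges.size else 0

    @property
    def sample_nodes(self) -> np.ndarray:
        kinds = np.asarray(self.node_kinds, dtype=object)
        return np.flatnonzero(kinds == SAMPLE_KIND)

    def nodes_of_kind(self, kind: str) -> np.ndarray:
        kinds = np.asarray(self.node_kinds, dtype=object)
        return np.flatnonzero(kinds == kind)

    def index_of(self, node_id: str, kind: str) -> int:
        try:
            return self._index[(kind, node_id)]
        except AttributeError:
            self._index = {
                (k, i): n for n, (i, k) in enumerate(zip(self.node_ids, self.node_kinds))
            }
            return self.index_of(node_id, kind)
        except KeyError:
            raise KeyError(f"unknown node {node_id!r} of kind {kind!r}") from None

    def to_edge_table(self) -> pd.DataFrame:
        """Typed edge list: source_id, target_id, node_kinds, multiplicity."""
        rows = [
            (
                self.node_ids[u],
                self.node_ids[v],
                f"{self.node_kinds[u]}-{self.node_kinds[v]}",
                int(m),
            )
            for u, v, m in self.edges
        ]
        return pd.DataFrame(rows, columns=["source_id", "target_id", "node_kinds", "multiplicity"])


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (2.5 -> 3), unlike numpy's banker's rounding."""
    return np.floor(np.abs(x) + 0.5).astype(np.int64) * np.sign(x).astype(np.int64)


def build_network(layers: list[OmicsLayer]) -> MultipartiteNetwork:
    """Discretize layers sharing one sample set into a star multigraph.

    Each (possibly log-transformed) weight becomes an edge multiplicity by
    rounding half away from zero; weights rounding to zero produce no edge.
    Features left without any edge are dropped from the network and recorded
    in ``dropped_features``.
    """
    if not layers:
        raise ValueError("no layers given")
    sample_ids = layers[0].sample_ids
    for layer in layers[1:]:
        if layer.sample_ids != sample_ids:
            raise ValueError(
                "layers must share identical, identically ordered sample ids; "
                "run intersect_samples first"
            )
    names = [layer.branch_name for layer in layers]
    if len(set(names)) != len(names):
        raise ValueError("duplicate branch names")

    node_ids: list[str] = list(sample_ids)
    node_kinds: list[str] = [SAMPLE_KIND] * len(sample_ids)
    edges: list[tuple[int, int, int]] = []
    dropped: list[str] = []
    for layer in layers:
        mult = _round_half_away(layer.data.to_numpy(dtype=float))
        for row, fid in enumerate(layer.feature_ids):
            nz = np.flatnonzero(mult[row])
            if nz.size == 0:
                dropped.append(fid)
                continue
            fidx = len(node_ids)
            node_ids.append(fid)
            node_kinds.append(layer.branch_name)
            edges.extend((s, fidx, int(mult[row, s])) for s in nz)
    if not edges:
        raise ValueError("empty network: all multiplicities rounded to zero")
    if dropped:
        warnings.warn(
            f"{len(dropped)} features dropped with zero rounded weight", stacklevel=2
        )
    return MultipartiteNetwork(node_ids, node_kinds, np.asarray(edges), names, dropped)


def add_feature_links(
    network: MultipartiteNetwork,
    links: list[tuple[str, str, str, str]],
) -> MultipartiteNetwork:
    """Add unit-multiplicity cross-branch feature-feature edges.

    ``links`` rows are ``(feature_a, branch_a, feature_b, branch_b)`` with
    ``branch_a != branch_b``; duplicated links accumulate multiplicity. This
    is how prior regulatory knowledge (gene-miRNA target interactions) enters
    the model: the extra edges reward block assignments in which regulating
    and regulated features land in mutually consistent topics.
    """
    extra: dict[tuple[int, int], int] = {}
    for fa, ba, fb, bb in links:
        if ba == bb:
            raise ValueError(f"same-branch link {fa!r}-{fb!r} within {ba!r}")
        u = network.index_of(fa, ba)
        v = network.index_of(fb, bb)
        u, v = min(u, v), max(u, v)
        extra[(u, v)] = extra.get((u, v), 0) + 1
    if not extra:
        return MultipartiteNetwork(
            list(network.node_ids),
            list(network.node_kinds),
            network.edges.copy(),
            list(network.branch_names),
            list(network.dropped_features),
        )
    merged: dict[tuple[int, int], int] = {
        (int(u), int(v)): int(m) for u, v, m in network.edges
    }
    for key, m in extra.items():
        merged[key] = merged.get(key, 0) + m
    edges = np.asarray([(u, v, m) for (u, v), m in sorted(merged.items())], dtype=np.int64)
    return MultipartiteNetwork(
        list(network.node_ids),
        list(network.node_kinds),
        edges,
        list(network.branch_names),
        list(network.dropped_features),
    )
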