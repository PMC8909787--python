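"""Degree-corrected stochastic block modeling of multipartite multigraphs.

The model
---------

Nodes carry a *kind* (sample, or one branch per omics layer) and every block
is type-pure: sample blocks are "clusters", feature blocks are "topics". For
a partition ``b`` the posterior is ``P(b|A) ∝ P(A|k,e,b) P(k|e,b) P(e|b) P(b)``
and inference minimizes the description length (in nats)

    Σ = −ln P(A|k,e,b) − ln P(k|e,b) − ln P(e|b) − ln P(b)

under the microcanonical degree-corrected likelihood for multigraphs without
same-kind edges (so no within-block edges and no self-loops),

    P(A|k,e,b) = [ Π_{r<s} e_rs! · Π_i k_i! ] / [ Π_{i<j} A_ij! · Π_r e_r! ]

where ``e_rs`` is the number of edges between blocks *r* and *s*, ``e_r`` the
number of half-edges attached to block *r*, and ``k_i`` the node degrees.
The priors are uniform:

    P(k|e,b) = Π_r multiset(n_r, e_r)^-1            (degree sequences)
    P(e|b)   = multiset(N_pairs, E)^-1              (edge-count matrices,
                N_pairs = Σ over permitted kind pairs of B_a·B_b)
    P(b)     = Π_kinds  (Π_r n_r!)/n! · C(n-1, B-1)^-1 · n^-1   (partitions)

with ``multiset(n, k) = C(n+k-1, k)``. The hierarchy is nested: the block
multigraph of one level becomes the data of the next, whose likelihood
replaces the flat ``P(e|b)`` term below it; only the top level keeps the
uniform edge-matrix prior. A candidate level is kept only when it lowers the
total Σ.

Optimization runs ``n_init`` restarts of an agglomerative initialization
(every node its own block, merges guided by the empirical proposal kernel)
followed by greedy zero-temperature sweeps of single-node moves proposed with

    P(r→s|t) = (e_ts + ε) / (e_t + εB)

restricted to same-kind target blocks, where *t* is the block of a randomly
chosen neighbor; the restart with the shortest description length wins, ties
going to the lowest restart index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .network import SAMPLE_KIND, MultipartiteNetwork

__all__ = [
    "MoveContext",
    "move_probability",
    "description_length",
    "BlockHierarchy",
    "fit_blockmodel",
    "merge_split_refine",
    "MultipartiteBlockModel",
]

_EPS_IMPROVE = 1e-10


# --------------------------------------------------------------------------
# proposal kernel
# --------------------------------------------------------------------------


@dataclass
class MoveContext:
    """Ingredients of the move proposal ``P(r→s|t)``.

    e_ts: edges between the neighbor's block *t* and the candidate block *s*;
    e_t: half-edges of *t* toward blocks of the moving node's kind;
    B: number of candidate blocks of that kind; epsilon: smoothing > 0.
    """

    e_ts: float
    e_t: float
    B: int
    epsilon: float = 1.0


def move_probability(ctx: MoveContext) -> float:
    """Probability of proposing candidate block *s* given neighbor block *t*."""
    if ctx.epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if ctx.B < 1:
        raise ValueError("need at least one candidate block")
    return (ctx.e_ts + ctx.epsilon) / (ctx.e_t + ctx.epsilon * ctx.B)


# --------------------------------------------------------------------------
# internal graph representation
# --------------------------------------------------------------------------


class _Graph:
    """Static adjacency view used by the block state (any level)."""

    __slots__ = (
        "n",
        "kind",
        "n_kinds",
        "kind_names",
        "adj_idx",
        "adj_mult",
        "deg",
        "E",
        "const_A",
        "const_degfact",
        "allowed_pairs",
        "n_per_kind",
        "lgf",
    )

    def __init__(self, kind, edges, n_kinds, kind_names, allowed_pairs=None, lgf=None):
        self.kind = np.asarray(kind, dtype=np.int64)
        self.n = self.kind.size
        self.n_kinds = n_kinds
        self.kind_names = list(kind_names)
        edges = np.asarray(edges, dtype=np.int64).reshape(-1, 3)
        nbrs: list[list[tuple[int, int]]] = [[] for _ in range(self.n)]
        pairs = set()
        for u, v, m in edges:
            nbrs[u].append((v, m))
            nbrs[v].append((u, m))
            ku, kv = self.kind[u], self.kind[v]
            pairs.add((min(ku, kv), max(ku, kv)))
        self.adj_idx = [np.array([j for j, _ in a], dtype=np.int64) for a in nbrs]
        self.adj_mult = [np.array([m for _, m in a], dtype=np.int64) for a in nbrs]
        self.deg = np.array([a.sum() if a.size else 0 for a in self.adj_mult], dtype=np.int64)
        self.E = int(edges[:, 2].sum()) if edges.size else 0
        self.allowed_pairs = sorted(pairs) if allowed_pairs is None else sorted(allowed_pairs)
        self.n_per_kind = np.bincount(self.kind, minlength=n_kinds)
        # worst-case multiset index: all-singleton partition's block-pair count
        max_pairs = sum(
            int(self.n_per_kind[a]) * int(self.n_per_kind[b]) for a, b in self.allowed_pairs
        )
        need = self.E + self.n + max_pairs + 4
        if lgf is None or lgf.size < need:
            # lgf[k] = ln k!
            lgf = gammaln(np.arange(need, dtype=np.float64) + 1.0)
        self.lgf = lgf
        self.const_A = float(self.lgf[edges[:, 2]].sum()) if edges.size else 0.0
        self.const_degfact = float(self.lgf[self.deg].sum())


def _graph_from_network(network: MultipartiteNetwork) -> _Graph:
    kind_names = [SAMPLE_KIND] + list(network.branch_names)
    kind_index = {k: i for i, k in enumerate(kind_names)}
    kind = np.array([kind_index[k] for k in network.node_kinds], dtype=np.int64)
    return _Graph(kind, network.edges, len(kind_names), kind_names)


# --------------------------------------------------------------------------
# mutable block state with incremental description length
# --------------------------------------------------------------------------


class _BlockState:
    """Partition of one graph level plus incremental Σ bookkeeping."""

    def __init__(self, graph: _Graph, b: np.ndarray):
        self.g = graph
        n = graph.n
        self.n_slots = n
        self.b = np.asarray(b, dtype=np.int64).copy()
        if self.b.min() < 0 or self.b.max() >= n:
            raise ValueError("block labels must be in [0, V)")
        self.ee = np.zeros((n, n), dtype=np.int64)
        self.er = np.zeros(n, dtype=np.int64)
        self.nr = np.zeros(n, dtype=np.int64)
        self.kind_of_slot = np.full(n, -1, dtype=np.int64)
        for i in range(n):
            r = self.b[i]
            self.nr[r] += 1
            self.er[r] += graph.deg[i]
            k = graph.kind[i]
            if self.kind_of_slot[r] == -1:
                self.kind_of_slot[r] = k
            elif self.kind_of_slot[r] != k:
                raise ValueError(f"block {r} mixes node kinds — blocks must be type-pure")
        for i in range(n):
            r = self.b[i]
            for j, m in zip(self.g.adj_idx[i], self.g.adj_mult[i]):
                if i < j:
                    s = self.b[j]
                    self.ee[r, s] += m
                    self.ee[s, r] += m
        self.active = self.nr > 0
        self.B_per_kind = np.zeros(graph.n_kinds, dtype=np.int64)
        for r in np.flatnonzero(self.active):
            self.B_per_kind[self.kind_of_slot[r]] += 1
        self.free = [int(r) for r in np.flatnonzero(~self.active)[::-1]]
        self.sigma = self.sigma_scratch()

    # ---- Σ terms -------------------------------------------------------

    def _lnC(self, a: int, k: int) -> float:
        lgf = self.g.lgf
        return float(lgf[a] - lgf[k] - lgf[a - k])

    def _blk(self, n: int, e: int) -> float:
        """Per-block contribution: ln e_r! + ln multiset(n_r, e_r) − ln n_r!.

        The ``ln e_r!`` from the likelihood denominator cancels against the
        multiset coefficient, leaving ``ln (n+e−1)! − ln (n−1)! − ln n!``.
        """
        if n == 0:
            return 0.0
        lgf = self.g.lgf
        return float(lgf[n + e - 1] - lgf[n - 1] - lgf[n])

    def _n_pairs(self, B_per_kind=None) -> int:
        B = self.B_per_kind if B_per_kind is None else B_per_kind
        return int(sum(B[a] * B[b] for a, b in self.g.allowed_pairs))

    def _global_term(self, B_per_kind=None) -> float:
        """Terms depending only on the block counts: P(e|b) and C(n−1, B−1)."""
        B = self.B_per_kind if B_per_kind is None else B_per_kind
        np_ = self._n_pairs(B)
        out = self._lnC(np_ + self.g.E - 1, self.g.E) if self.g.E else 0.0
        for k in range(self.g.n_kinds):
            nk = int(self.g.n_per_kind[k])
            if nk > 0:
                out += self._lnC(nk - 1, int(B[k]) - 1)
        return out

    def sigma_scratch(self) -> float:
        """Recompute Σ from scratch (reference for the incremental updates)."""
        g = self.g
        lgf = g.lgf
        act = np.flatnonzero(self.active)
        sub = self.ee[np.ix_(act, act)]
        pair_term = float(lgf[sub[np.triu_indices(len(act), k=1)]].sum())
        sigma = g.const_A - g.const_degfact - pair_term
        for r in act:
            sigma += self._blk(int(self.nr[r]), int(self.er[r]))
        sigma += self._global_term()
        for k in range(g.n_kinds):
            nk = int(g.n_per_kind[k])
            if nk > 0:
                sigma += float(lgf[nk]) + np.log(nk)
        return float(sigma)

    # ---- single-node moves --------------------------------------------

    def _neighbor_blocks(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        m = np.zeros(self.n_slots, dtype=np.int64)
        np.add.at(m, self.b[self.g.adj_idx[i]], self.g.adj_mult[i])
        ts = np.flatnonzero(m)
        return ts, m[ts]

    def deltas_move(self, i: int, cands: np.ndarray, ts=None, mt=None) -> np.ndarray:
        """ΔΣ for moving node *i* to each candidate block (same kind)."""
        if ts is None:
            ts, mt = self._neighbor_blocks(i)
        lgf = self.g.lgf
        r = int(self.b[i])
        deg = int(self.g.deg[i])
        nr_r, er_r = int(self.nr[r]), int(self.er[r])
        ee_rt = self.ee[r, ts]
        side_r = float((lgf[ee_rt - mt] - lgf[ee_rt]).sum())
        d_r_blk = self._blk(nr_r - 1, er_r - deg) - self._blk(nr_r, er_r)
        vanish = nr_r == 1
        g_old = None
        out = np.empty(len(cands), dtype=np.float64)
        for idx, s in enumerate(cands):
            s = int(s)
            if s == r:
                out[idx] = 0.0
                continue
            fresh = not self.active[s]
            ee_st = self.ee[s, ts]
            d_pair = -(side_r + float((lgf[ee_st + mt] - lgf[ee_st]).sum()))
            nr_s, er_s = int(self.nr[s]), int(self.er[s])
            d = (
                d_pair
                + d_r_blk
                + self._blk(nr_s + 1, er_s + deg)
                - self._blk(nr_s, er_s)
            )
            if fresh or vanish:
                if g_old is None:
                    g_old = self._global_term()
                B = self.B_per_kind.copy()
                k = self.g.kind[i]
                if fresh:
                    B[k] += 1
                if vanish:
                    B[k] -= 1
                d += self._global_term(B) - g_old
            out[idx] = d
        return out

    def apply_move(self, i: int, s: int, delta: float) -> None:
        r = int(self.b[i])
        s = int(s)
        if s == r:
            return
        ts, mt = self._neighbor_blocks(i)
        self.ee[r, ts] -= mt
        self.ee[ts, r] -= mt
        self.ee[s, ts] += mt
        self.ee[ts, s] += mt
        deg = int(self.g.deg[i])
        k = int(self.g.kind[i])
        self.er[r] -= deg
        self.er[s] += deg
        self.nr[r] -= 1
        if not self.active[s]:
            self.active[s] = True
            self.kind_of_slot[s] = k
            self.B_per_kind[k] += 1
            if s in self.free:
                self.free.remove(s)
        self.nr[s] += 1
        self.b[i] = s
        if self.nr[r] == 0:
            self.active[r] = False
            self.kind_of_slot[r] = -1
            self.B_per_kind[k] -= 1
            self.free.append(r)
        self.sigma += delta

    # ---- block merges --------------------------------------------------

    def delta_merge(self, r: int, s: int) -> float:
        """ΔΣ for merging block *r* into same-kind block *s*."""
        lgf = self.g.lgf
        row = self.ee[r]
        ts = np.flatnonzero(row)
        mt = row[ts]
        ee_st = self.ee[s, ts]
        d = -float((lgf[ee_st + mt] - lgf[ee_st] - lgf[mt]).sum())
        d += (
            self._blk(int(self.nr[r] + self.nr[s]), int(self.er[r] + self.er[s]))
            - self._blk(int(self.nr[r]), int(self.er[r]))
            - self._blk(int(self.nr[s]), int(self.er[s]))
        )
        B = self.B_per_kind.copy()
        B[self.kind_of_slot[r]] -= 1
        d += self._global_term(B) - self._global_term()
        return d

    def apply_merge(self, r: int, s: int, delta: float) -> None:
        row = self.ee[r].copy()
        ts = np.flatnonzero(row)
        self.ee[s, ts] += row[ts]
        self.ee[ts, s] += row[ts]
        self.ee[r, :] = 0
        self.ee[:, r] = 0
        self.b[self.b == r] = s
        self.er[s] += self.er[r]
        self.nr[s] += self.nr[r]
        self.er[r] = 0
        self.nr[r] = 0
        self.active[r] = False
        self.B_per_kind[self.kind_of_slot[r]] -= 1
        self.kind_of_slot[r] = -1
        self.free.append(r)
        self.sigma += delta

    # ---- bookkeeping ---------------------------------------------------

    def snapshot(self):
        return (
            self.b.copy(),
            self.ee.copy(),
            self.er.copy(),
            self.nr.copy(),
            self.kind_of_slot.copy(),
            self.active.copy(),
            self.B_per_kind.copy(),
            list(self.free),
            self.sigma,
        )

    def restore(self, snap) -> None:
        (
            self.b,
            self.ee,
            self.er,
            self.nr,
            self.kind_of_slot,
            self.active,
            self.B_per_kind,
            self.free,
            self.sigma,
        ) = (
            snap[0].copy(),
            snap[1].copy(),
            snap[2].copy(),
            snap[3].copy(),
            snap[4].copy(),
            snap[5].copy(),
            snap[6].copy(),
            list(snap[7]),
            snap[8],
        )

    def candidates_of_kind(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.active & (self.kind_of_slot == k))

    def fresh_slot(self) -> int | None:
        return self.free[-1] if self.free else None


# --------------------------------------------------------------------------
# optimizer
# --------------------------------------------------------------------------


def _propose_block(state: _BlockState, i: int, rng: np.random.Generator, epsilon: float):
    """Sample a target block for node *i* with the smoothed proposal kernel."""
    g = state.g
    nbrs = g.adj_idx[i]
    if nbrs.size == 0:
        return None
    mult = g.adj_mult[i]
    j = nbrs[rng.choice(nbrs.size, p=mult / mult.sum())]
    t = int(state.b[j])
    cands = state.candidates_of_kind(int(g.kind[i]))
    B = cands.size
    if B == 0:
        return None
    e_ts = state.ee[t, cands].astype(np.float64)
    e_t = float(e_ts.sum())
    if rng.random() < epsilon * B / (e_t + epsilon * B):
        return int(cands[rng.integers(B)])
    return int(cands[rng.choice(B, p=e_ts / e_t)])


def _mh_sweep(state: _BlockState, rng: np.random.Generator, epsilon: float) -> bool:
    """One zero-temperature sweep of kernel-proposed single-node moves."""
    changed = False
    for i in rng.permutation(state.g.n):
        s = _propose_block(state, int(i), rng, epsilon)
        if s is None or s == state.b[i]:
            continue
        d = state.deltas_move(int(i), np.array([s]))[0]
        if d < -_EPS_IMPROVE:
            state.apply_move(int(i), s, float(d))
            changed = True
    return changed


def _polish_sweep(state: _BlockState, rng: np.random.Generator) -> bool:
    """Greedy best-move pass over all nodes, including a fresh-block target."""
    changed = False
    for i in rng.permutation(state.g.n):
        i = int(i)
        k = int(state.g.kind[i])
        cands = list(state.candidates_of_kind(k))
        if state.nr[state.b[i]] > 1:
            f = state.fresh_slot()
            if f is not None:
                cands.append(f)
        cands = np.asarray(cands, dtype=np.int64)
        ts, mt = state._neighbor_blocks(i)
        deltas = state.deltas_move(i, cands, ts, mt)
        best = int(np.argmin(deltas))
        if deltas[best] < -_EPS_IMPROVE:
            state.apply_move(i, int(cands[best]), float(deltas[best]))
            changed = True
    return changed


def _merge_candidates(
    state: _BlockState, r: int, rng: np.random.Generator, epsilon: float, n_cand: int = 10
) -> set[int]:
    """Neighbor-guided merge partners for block *r* (same kind)."""
    k = int(state.kind_of_slot[r])
    same = state.candidates_of_kind(k)
    if same.size <= 12:
        return {int(s) for s in same if s != r}
    out: set[int] = set()
    row = state.ee[r]
    ts = np.flatnonzero(row)
    if ts.size == 0:
        return out
    w = row[ts] / row[ts].sum()
    for _ in range(n_cand):
        t = int(ts[rng.choice(ts.size, p=w)])
        e_ts = state.ee[t, same].astype(np.float64)
        e_t = float(e_ts.sum())
        B = same.size
        if rng.random() < epsilon * B / (e_t + epsilon * B):
            s = int(same[rng.integers(B)])
        else:
            s = int(same[rng.choice(B, p=e_ts / e_t)])
        if s != r:
            out.add(s)
    return out


def _merge_sweep(state: _BlockState, rng: np.random.Generator, epsilon: float) -> tuple[bool, bool]:
    """Greedy improving merges; returns (changed, exhaustive)."""
    changed = False
    exhaustive = True
    improved = True
    while improved:
        improved = False
        for r in rng.permutation(state.n_slots):
            r = int(r)
            if not state.active[r]:
                continue
            cands = _merge_candidates(state, r, rng, epsilon)
            if state.candidates_of_kind(int(state.kind_of_slot[r])).size > 12:
                exhaustive = False
            best_s, best_d = None, -_EPS_IMPROVE
            for s in cands:
                d = state.delta_merge(r, s)
                if d < best_d:
                    best_s, best_d = s, d
            if best_s is not None:
                state.apply_merge(r, best_s, best_d)
                changed = improved = True
    return changed, exhaustive


def _forced_merge_step(
    state: _BlockState, rng: np.random.Generator, epsilon: float, n_merge: int
) -> int:
    """Apply up to ``n_merge`` cheapest block merges, even mildly worsening ones.

    Description-length landscapes have merge barriers (the first of several
    sibling merges can cost a little before the rest pay off), so the
    agglomerative descent forces the best available merges and relies on the
    caller to keep the best state seen along the trajectory.
    """
    proposals: list[tuple[float, int, int]] = []
    for r in np.flatnonzero(state.active):
        r = int(r)
        for s in _merge_candidates(state, r, rng, epsilon):
            proposals.append((state.delta_merge(r, s), r, s))
    proposals.sort()
    applied = 0
    for _, r, s in proposals:
        if applied >= n_merge:
            break
        if not (state.active[r] and state.active[s]):
            continue
        k = int(state.kind_of_slot[r])
        if state.B_per_kind[k] <= 1:
            continue
        state.apply_merge(r, s, state.delta_merge(r, s))
        applied += 1
    return applied


def _split_sweep(state: _BlockState, rng: np.random.Generator) -> bool:
    """Try a random bisection of every block, kept only when Σ improves.

    Each attempt moves a random half of the block's nodes to a fresh block
    and lets the members settle between the two halves before deciding.
    """
    changed = False
    for r in list(np.flatnonzero(state.active)):
        r = int(r)
        if state.nr[r] < 2:
            continue
        f = state.fresh_slot()
        if f is None:
            continue
        snap = state.snapshot()
        members = np.flatnonzero(state.b == r)
        half = rng.choice(members, size=members.size // 2, replace=False)
        for i in half:
            d = state.deltas_move(int(i), np.array([f]))[0]
            state.apply_move(int(i), int(f), float(d))
        for _ in range(3):
            moved = False
            for i in rng.permutation(members):
                i = int(i)
                cur = int(state.b[i])
                other = f if cur == r else r
                if state.nr[cur] == 1 or not state.active[other] or not state.active[cur]:
                    continue
                d = state.deltas_move(i, np.array([other]))[0]
                if d < -_EPS_IMPROVE:
                    state.apply_move(i, int(other), float(d))
                    moved = True
            if not moved:
                break
        if state.sigma >= snap[-1] - _EPS_IMPROVE:
            state.restore(snap)
        else:
            changed = True
    return changed


def _random_init(graph: _Graph, rng: np.random.Generator) -> np.ndarray:
    """Type-pure random partition with a random block count per kind."""
    b = np.empty(graph.n, dtype=np.int64)
    offset = 0
    for k in range(graph.n_kinds):
        nodes = np.flatnonzero(graph.kind == k)
        if nodes.size == 0:
            continue
        B = int(rng.integers(1, nodes.size + 1))
        b[nodes] = offset + rng.integers(0, B, size=nodes.size)
        offset += B
    # compact to the [0, n) slot range
    uniq = {lab: idx for idx, lab in enumerate(dict.fromkeys(b.tolist()))}
    return np.array([uniq[lab] for lab in b.tolist()], dtype=np.int64)


def _minimize_level(
    graph: _Graph,
    rng: np.random.Generator,
    epsilon: float,
    max_stall: int,
    init: np.ndarray | None = None,
) -> _BlockState:
    """Agglomerative descent over block counts + greedy sweeps on one level."""
    state = _BlockState(graph, np.arange(graph.n) if init is None else init)
    best = state.snapshot()
    # descend from all-singletons to one block per kind, polishing at each
    # plateau and recording the best state on the way; the node-move polish
    # may re-split blocks, so descent is enforced on the running minimum of
    # the block count
    n_min = int((graph.n_per_kind > 0).sum())
    low_water = int(state.active.sum()) + 1
    while True:
        for _ in range(3):
            if not _polish_sweep(state, rng):
                break
        if state.sigma < best[-1] - _EPS_IMPROVE:
            best = state.snapshot()
        n_blocks = int(state.active.sum())
        if n_blocks <= n_min or n_blocks >= low_water:
            break
        low_water = n_blocks
        n_merge = max(1, int(round((n_blocks - n_min) * 0.25)))
        if _forced_merge_step(state, rng, epsilon, n_merge) == 0:
            break
    state.restore(best)
    # refinement sweeps at the selected resolution
    stall = 0
    while stall < max_stall:
        moved = _mh_sweep(state, rng, epsilon)
        moved |= _polish_sweep(state, rng)
        merged, exhaustive = _merge_sweep(state, rng, epsilon)
        split = _split_sweep(state, rng)
        if state.sigma < best[-1] - _EPS_IMPROVE:
            best = state.snapshot()
            stall = 0
        else:
            stall += 1
        if not (moved or merged or split) and exhaustive:
            break
    state.restore(best)
    return state


def _block_graph(state: _BlockState) -> tuple[_Graph, np.ndarray]:
    """Collapse a level into its block multigraph (nodes = blocks)."""
    act = sorted(
        np.flatnonzero(state.active), key=lambda r: (int(state.kind_of_slot[r]), int(r))
    )
    remap = {int(r): idx for idx, r in enumerate(act)}
    kind = np.array([state.kind_of_slot[r] for r in act], dtype=np.int64)
    edges = []
    for r in act:
        for s in act:
            if r < s and state.ee[r, s] > 0:
                edges.append((remap[r], remap[s], int(state.ee[r, s])))
    graph = _Graph(
        kind,
        np.asarray(edges, dtype=np.int64).reshape(-1, 3),
        state.g.n_kinds,
        state.g.kind_names,
        allowed_pairs=state.g.allowed_pairs,
        lgf=state.g.lgf,
    )
    parent_to_child = np.array([remap[int(state.b[i])] for i in range(state.g.n)])
    return graph, parent_to_child


def _edges_prior(state: _BlockState) -> float:
    np_ = state._n_pairs()
    return state._lnC(np_ + state.g.E - 1, state.g.E) if state.g.E else 0.0


def _states_from_hierarchy(graph: _Graph, hierarchy: "BlockHierarchy") -> list[_BlockState]:
    """Rebuild the per-level block states of a hierarchy on a given graph."""
    states = [_BlockState(graph, hierarchy.assignments[0])]
    node_to_g: np.ndarray | None = None
    for level in range(1, hierarchy.n_levels):
        bg, p2c = _block_graph(states[-1])
        node_to_g = p2c if node_to_g is None else p2c[node_to_g]
        b = np.empty(bg.n, dtype=np.int64)
        for k in range(bg.n):
            i = int(np.flatnonzero(node_to_g == k)[0])
            b[k] = hierarchy.assignments[level][i]
        states.append(_BlockState(bg, b))
    return states


def _nested_sigma(states: list[_BlockState]) -> float:
    """Total description length of a hierarchy of states.

    Each non-top flat Σ has its uniform edge-matrix prior replaced by the
    next level's full description of that matrix.
    """
    total = sum(s.sigma for s in states)
    total -= sum(_edges_prior(s) for s in states[:-1])
    return float(total)


# --------------------------------------------------------------------------
# public results container
# --------------------------------------------------------------------------


@dataclass
class BlockHierarchy:
    """Fitted hierarchy: per-level node→block labels over the original nodes.

    Level 0 is the finest. ``assignments[l]`` maps every node of the network
    to a block label in ``0..B_l-1``; coarser levels are exact merges of finer
    ones. ``block_kinds[l]`` names the kind of each block. ``sigma`` is the
    total nested description length in nats.
    """

    node_ids: list[str]
    node_kinds: list[str]
    assignments: list[np.ndarray]
    block_kinds: list[list[str]]
    sigma: float
    sigma_levels: list[float]
    seed: int | None
    restart_index: int
    n_init: int

    @property
    def n_levels(self) -> int:
        return len(self.assignments)

    def n_blocks(self, level: int, kind: str | None = None) -> int:
        if kind is None:
            return len(self.block_kinds[level])
        return sum(1 for k in self.block_kinds[level] if k == kind)

    def sample_clusters(self, level: int) -> pd.Series:
        kinds = np.asarray(self.node_kinds, dtype=object)
        mask = kinds == SAMPLE_KIND
        ids = [i for i, m in zip(self.node_ids, mask) if m]
        return pd.Series(self.assignments[level][mask], index=ids, name=f"cluster_l{level}")

    def branch_blocks(self, level: int, branch: str) -> pd.Series:
        kinds = np.asarray(self.node_kinds, dtype=object)
        mask = kinds == branch
        if not mask.any():
            raise KeyError(f"unknown branch {branch!r}")
        ids = [i for i, m in zip(self.node_ids, mask) if m]
        return pd.Series(self.assignments[level][mask], index=ids, name=f"topic_l{level}")

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for level, labels in enumerate(self.assignments):
            pd.DataFrame(
                {
                    "node_id": self.node_ids,
                    "node_kind": self.node_kinds,
                    "block_id": labels,
                }
            ).to_csv(outdir / f"hierarchy_level_{level}.csv", index=False)
        summary = {
            "sigma": self.sigma,
            "sigma_levels": list(map(float, self.sigma_levels)),
            "n_levels": self.n_levels,
            "seed": self.seed,
            "restart_index": self.restart_index,
            "n_init": self.n_init,
            "block_kinds": self.block_kinds,
        }
        (outdir / "run_summary.json").write_text(json.dumps(summary, indent=2))

    @classmethod
    def load(cls, outdir) -> "BlockHierarchy":
        outdir = Path(outdir)
        summary = json.loads((outdir / "run_summary.json").read_text())
        assignments = []
        node_ids: list[str] = []
        node_kinds: list[str] = []
        for level in range(summary["n_levels"]):
            df = pd.read_csv(outdir / f"hierarchy_level_{level}.csv")
            if level == 0:
                node_ids = df["node_id"].astype(str).tolist()
                node_kinds = df["node_kind"].astype(str).tolist()
            assignments.append(df["block_id"].to_numpy(dtype=np.int64))
        return cls(
            node_ids,
            node_kinds,
            assignments,
            summary["block_kinds"],
            summary["sigma"],
            summary["sigma_levels"],
            summary["seed"],
            summary["restart_index"],
            summary["n_init"],
        )


def _compact_level(state: _BlockState, node_labels: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Relabel a level's blocks as 0..B-1 ordered by (kind, slot)."""
    act = sorted(
        np.flatnonzero(state.active), key=lambda r: (int(state.kind_of_slot[r]), int(r))
    )
    remap = {int(r): idx for idx, r in enumerate(act)}
    labels = np.array([remap[int(r)] for r in node_labels], dtype=np.int64)
    kinds = [state.g.kind_names[int(state.kind_of_slot[r])] for r in act]
    return labels, kinds


def _states_to_hierarchy(
    network: MultipartiteNetwork,
    states: list[_BlockState],
    seed,
    restart_index: int,
    n_init: int,
) -> BlockHierarchy:
    assignments = []
    block_kinds = []
    node_labels = states[0].b.copy()
    labels, kinds = _compact_level(states[0], node_labels)
    assignments.append(labels)
    block_kinds.append(kinds)
    # compose through the upper levels: node -> graph node of level l -> block
    chain = np.arange(network.V)
    for lower, upper in zip(states[:-1], states[1:]):
        _, parent_to_child = _block_graph(lower)
        chain = parent_to_child[chain]
        labels, kinds = _compact_level(upper, upper.b[chain])
        assignments.append(labels)
        block_kinds.append(kinds)
    return BlockHierarchy(
        [str(i) for i in network.node_ids],
        [str(k) for k in network.node_kinds],
        assignments,
        block_kinds,
        _nested_sigma(states),
        [s.sigma for s in states],
        seed,
        restart_index,
        n_init,
    )


# --------------------------------------------------------------------------
# public entry points
# --------------------------------------------------------------------------


def description_length(network: MultipartiteNetwork, assignment) -> float:
    """Flat (single-level) description length Σ of a type-pure partition.

    ``assignment`` maps node id -> block label (dict) or is an integer array
    aligned with ``network.node_ids``. Raises if a block mixes node kinds or
    a node is missing.
    """
    if isinstance(assignment, dict):
        missing = [i for i in network.node_ids if i not in assignment]
        if missing:
            raise ValueError(f"assignment does not cover nodes: {missing[:5]}")
        raw = [assignment[i] for i in network.node_ids]
    else:
        raw = np.asarray(assignment)
        if raw.shape[0] != network.V:
            raise ValueError("assignment does not cover all nodes")
    uniq = {lab: idx for idx, lab in enumerate(dict.fromkeys(raw))}
    b = np.array([uniq[lab] for lab in raw], dtype=np.int64)
    graph = _graph_from_network(network)
    return _BlockState(graph, b).sigma


def _build_levels(
    graph: _Graph,
    rng: np.random.Generator,
    epsilon: float,
    max_stall: int,
    max_levels: int,
    init: np.ndarray | None = None,
) -> list[_BlockState]:
    states = [_minimize_level(graph, rng, epsilon, max_stall, init=init)]
    while len(states) < max_levels:
        top = states[-1]
        n_blocks = int(top.active.sum())
        if n_blocks <= top.g.n_kinds or n_blocks == top.g.n:
            break
        block_graph, _ = _block_graph(top)
        cand = _minimize_level(block_graph, rng, epsilon, max_stall)
        if int(cand.active.sum()) == cand.g.n:
            break  # no coarsening found
        if _nested_sigma(states + [cand]) < _nested_sigma(states) - _EPS_IMPROVE:
            states.append(cand)
        else:
            break
    return states


def fit_blockmodel(
    network: MultipartiteNetwork,
    n_init: int = 10,
    seed: int | None = None,
    epsilon: float = 1.0,
    max_stall: int = 10,
    max_levels: int = 10,
) -> BlockHierarchy:
    """Infer the block hierarchy minimizing the nested description length.

    Runs ``n_init`` independent restarts with seeds derived from ``seed`` and
    returns the hierarchy with the smallest total Σ (lowest restart index on
    ties). Deterministic given ``seed``.
    """
    if network.E == 0:
        raise ValueError("empty network")
    graph = _graph_from_network(network)
    seed_seq = np.random.SeedSequence(seed)
    children = seed_seq.spawn(n_init)
    best: tuple[float, int, list[_BlockState]] | None = None
    for idx in range(n_init):
        rng = np.random.default_rng(children[idx])
        # first restart descends from singletons; the rest explore from
        # random type-pure partitions to diversify the search
        init = None if idx == 0 else _random_init(graph, rng)
        states = _build_levels(graph, rng, epsilon, max_stall, max_levels, init=init)
        total = _nested_sigma(states)
        if best is None or total < best[0] - _EPS_IMPROVE:
            best = (total, idx, states)
    assert best is not None
    return _states_to_hierarchy(network, best[2], seed, best[1], n_init)


def merge_split_refine(
    network: MultipartiteNetwork,
    hierarchy: BlockHierarchy,
    n_sweeps: int = 10,
    seed: int | None = None,
    epsilon: float = 1.0,
) -> BlockHierarchy:
    """Merge-split refinement of the finest level of a fitted hierarchy.

    Each sweep proposes single-node moves, improving block merges, and random
    bisection splits of existing blocks, keeping the best state seen. The
    returned hierarchy never has a larger Σ than the input. ``n_sweeps=0``
    returns the input unchanged. Typically used after adding cross-branch
    feature links, whose extra edges reshape the description-length landscape.
    """
    if n_sweeps == 0:
        return hierarchy
    graph = _graph_from_network(network)
    baseline_total = _nested_sigma(_states_from_hierarchy(graph, hierarchy))
    state = _BlockState(graph, hierarchy.assignments[0])
    base_flat = state.sigma
    rng = np.random.default_rng(seed)
    best = state.snapshot()
    for _ in range(n_sweeps):
        _polish_sweep(state, rng)
        _merge_sweep(state, rng, epsilon)
        _split_sweep(state, rng)
        if state.sigma < best[-1] - _EPS_IMPROVE:
            best = state.snapshot()
    def _fallback() -> BlockHierarchy:
        # keep the input partition, but with Σ evaluated on *this* network
        return _states_to_hierarchy(
            network,
            _states_from_hierarchy(graph, hierarchy),
            seed,
            hierarchy.restart_index,
            hierarchy.n_init,
        )

    state.restore(best)
    if state.sigma > base_flat + _EPS_IMPROVE:
        return _fallback()
    rng2 = np.random.default_rng(seed)
    states = [state]
    # rebuild the upper levels greedily on the refined base
    while True:
        top = states[-1]
        n_blocks = int(top.active.sum())
        if n_blocks <= top.g.n_kinds or n_blocks == top.g.n:
            break
        block_graph, _ = _block_graph(top)
        cand = _minimize_level(block_graph, rng2, epsilon, 10)
        if int(cand.active.sum()) == cand.g.n:
            break
        if _nested_sigma(states + [cand]) < _nested_sigma(states) - _EPS_IMPROVE:
            states.append(cand)
        else:
            break
    refined = _states_to_hierarchy(
        network, states, seed, hierarchy.restart_index, hierarchy.n_init
    )
    if refined.sigma > baseline_total + _EPS_IMPROVE:
        return _fallback()
    return refined


class MultipartiteBlockModel:
    """Scikit-learn-style estimator wrapping :func:`fit_blockmodel`.

    Parameters
    ----------
    n_init:
        Independent restarts of the optimization; the shortest description
        length wins.
    epsilon:
        Smoothing of the move-proposal kernel (> 0).
    max_stall:
        Consecutive sweeps without improvement before a level stops.
    max_levels:
        Cap on hierarchy depth.
    random_state:
        Seed for all randomness; fits are bit-reproducible given a seed.

    Attributes
    ----------
    hierarchy_ : BlockHierarchy
    sigma_ : float
        Total nested description length in nats.
    labels_ : ndarray
        Sample-cluster labels at the finest level, aligned with the sample
        nodes of the fitted network.
    n_levels_ : int
    """

    def __init__(
        self,
        n_init: int = 10,
        epsilon: float = 1.0,
        max_stall: int = 10,
        max_levels: int = 10,
        random_state: int | None = None,
    ):
        self.n_init = n_init
        self.epsilon = epsilon
        self.max_stall = max_stall
        self.max_levels = max_levels
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_init": self.n_init,
            "epsilon": self.epsilon,
            "max_stall": self.max_stall,
            "max_levels": self.max_levels,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "MultipartiteBlockModel":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, y=None) -> "MultipartiteBlockModel":
        from .layers import OmicsLayer  # local import to avoid cycle at module load

        if isinstance(X, MultipartiteNetwork):
            network = X
        elif isinstance(X, (list, tuple)) and all(isinstance(l, OmicsLayer) for l in X):
            from .network import build_network

            network = build_network(list(X))
        else:
            raise TypeError("X must be a MultipartiteNetwork or a list of OmicsLayer")
        self.network_ = network
        self.hierarchy_ = fit_blockmodel(
            network,
            n_init=self.n_init,
            seed=self.random_state,
            epsilon=self.epsilon,
            max_stall=self.max_stall,
            max_levels=self.max_levels,
        )
        self.sigma_ = self.hierarchy_.sigma
        self.n_levels_ = self.hierarchy_.n_levels
        self.labels_ = self.hierarchy_.sample_clusters(0).to_numpy()
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_
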