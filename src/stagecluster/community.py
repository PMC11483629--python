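"""Resolution-scaled modularity, Louvain optimization, and a brute-force oracle.

Modularity of a partition C on a graph with m edges is

    Q = sum_c [ e_c / m  -  gamma * (d_c / 2m)^2 ]

where e_c counts intra-community edges, d_c sums the degrees of community
c, and gamma is the resolution (gamma = 1 recovers Newman--Girvan; larger
gamma favors smaller communities).  ``louvain`` implements the standard
two-phase heuristic — seeded node-order shuffling, greedy local moves with
ties broken toward the lowest community id, then graph aggregation,
repeated until no gain above 1e-12 — so results are deterministic under a
seed.  ``exhaustive_best_partition`` enumerates all set partitions of
graphs with at most 10 nodes and serves as an independent optimum oracle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .data import ValidationError


@dataclass
class Partition:
    """Node -> community assignment (dense ids from 0) with its modularity."""

    membership: dict
    modularity: float
    resolution: float

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))

    def communities(self) -> list[set]:
        out: dict[int, set] = {}
        for node, c in self.membership.items():
            out.setdefault(c, set()).add(node)
        return [out[c] for c in sorted(out)]


def _as_nx(graph) -> nx.Graph:
    if isinstance(graph, nx.Graph):
        return graph
    return graph.graph


def modularity(graph, membership: dict, resolution: float = 0.75) -> float:
    """Resolution-scaled modularity Q of a partition on the unweighted edge set."""
    g = _as_nx(graph)
    m = g.number_of_edges()
    if m < 1:
        raise ValidationError("modularity is undefined on an edgeless graph")
    missing = [v for v in g.nodes if v not in membership]
    if missing:
        raise ValidationError(f"partition misses nodes: {missing[:10]}")
    e_c: dict = {}
    d_c: dict = {}
    for u, v in g.edges:
        if membership[u] == membership[v]:
            e_c[membership[u]] = e_c.get(membership[u], 0) + 1
    for v, d in g.degree:
        d_c[membership[v]] = d_c.get(membership[v], 0) + d
    q = 0.0
    for c, dc in d_c.items():
        q += e_c.get(c, 0) / m - resolution * (dc / (2.0 * m)) ** 2
    return q


def _dense_relabel(membership: dict, nodes) -> dict:
    """Relabel communities 0..k-1 in order of first appearance over sorted nodes."""
    mapping: dict = {}
    out = {}
    for v in sorted(nodes, key=str):
        c = membership[v]
        if c not in mapping:
            mapping[c] = len(mapping)
        out[v] = mapping[c]
    return out


def _one_level(adj, self_w, k, two_m, gamma, rng):
    """Greedy local moving; returns community dict keyed like ``adj``.

    Equal-gain moves are tied-broken by a seeded random draw: a fixed
    deterministic rule (e.g. lowest community id) can systematically steer
    every run into the same suboptimal basin on symmetric graphs.
    """
    nodes = list(adj)
    comm = {u: u for u in nodes}
    tot = {u: k[u] for u in nodes}
    fresh = max(nodes) + 1  # next unused community label
    order = list(nodes)
    rng.shuffle(order)
    improved = True
    any_move = False
    while improved:
        improved = False
        for u in order:
            cu = comm[u]
            links: dict = {}
            for v, w in adj[u].items():
                links[comm[v]] = links.get(comm[v], 0.0) + w
            tot[cu] -= k[u]
            # candidates: stay, a fresh singleton, or any neighbor community
            stay_gain = links.get(cu, 0.0) - gamma * k[u] * tot[cu] / two_m
            candidates = []
            if tot[cu] > 0:
                candidates.append((fresh, 0.0))
            for c, l in links.items():
                if c != cu:
                    candidates.append((c, l - gamma * k[u] * tot[c] / two_m))
            best_gain = max((gain for _, gain in candidates), default=-np.inf)
            if best_gain <= stay_gain + 1e-12:
                best_c = cu  # ties with staying resolve to staying (no churn)
            else:
                tied = [c for c, gain in candidates if gain >= best_gain - 1e-12]
                best_c = tied[0] if len(tied) == 1 else tied[rng.integers(len(tied))]
            if best_c == fresh:
                tot[fresh] = 0.0
                fresh += 1
            comm[u] = best_c
            tot[best_c] = tot.get(best_c, 0.0) + k[u]
            if best_c != cu:
                improved = True
                any_move = True
    return comm, any_move


def louvain(
    graph, resolution: float = 0.75, seed: int = 0, restarts: int = 8
) -> Partition:
    """Two-phase Louvain modularity optimization with seeded restarts.

    Runs the greedy two-phase heuristic ``restarts`` times with
    independent (but seed-derived) node orders and tie-break draws and
    keeps the highest-modularity result, so the output is deterministic
    under ``seed``.  The returned partition is additionally guaranteed not
    to score below the one-community and all-singleton baselines.
    """
    g = _as_nx(graph)
    if g.number_of_nodes() == 0:
        raise ValidationError("empty graph")
    if g.number_of_edges() == 0:
        raise ValidationError("graph has no edges")
    best_part: Partition | None = None
    for r in range(max(restarts, 1)):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), r]))
        cand = _louvain_once(g, resolution, rng)
        if best_part is None or cand.modularity > best_part.modularity + 1e-15:
            best_part = cand
    return best_part


def _louvain_once(g: nx.Graph, resolution: float, rng) -> Partition:
    nodes = sorted(g.nodes, key=str)
    index = {v: i for i, v in enumerate(nodes)}
    adj = {i: {} for i in range(len(nodes))}
    self_w = {i: 0.0 for i in range(len(nodes))}
    for u, v in g.edges:
        iu, iv = index[u], index[v]
        if iu == iv:
            self_w[iu] += 1.0
        else:
            adj[iu][iv] = adj[iu].get(iv, 0.0) + 1.0
            adj[iv][iu] = adj[iv].get(iu, 0.0) + 1.0
    k = {i: sum(adj[i].values()) + 2.0 * self_w[i] for i in adj}
    two_m = sum(k.values())

    # assignment of the original node index to the current-level community
    node_to_comm = {i: i for i in range(len(nodes))}
    while True:
        comm, moved = _one_level(adj, self_w, k, two_m, resolution, rng)
        labels = sorted(set(comm.values()))
        relabel = {c: i for i, c in enumerate(labels)}
        node_to_comm = {v: relabel[comm[node_to_comm[v]]] for v in node_to_comm}
        if not moved or len(labels) == len(adj):
            break
        # aggregate the graph on communities
        new_adj = {relabel[c]: {} for c in labels}
        new_self = {relabel[c]: 0.0 for c in labels}
        for u in adj:
            cu = relabel[comm[u]]
            new_self[cu] += self_w[u]
            for v, w in adj[u].items():
                cv = relabel[comm[v]]
                if cu == cv:
                    new_self[cu] += w / 2.0
                else:
                    new_adj[cu][cv] = new_adj[cu].get(cv, 0.0) + w
        adj, self_w = new_adj, new_self
        k = {i: sum(adj[i].values()) + 2.0 * self_w[i] for i in adj}

    membership = {nodes[i]: c for i, c in node_to_comm.items()}
    membership = _dense_relabel(membership, g.nodes)
    q = modularity(g, membership, resolution)

    # never return below the trivial baselines
    one = {v: 0 for v in g.nodes}
    singles = {v: i for i, v in enumerate(sorted(g.nodes, key=str))}
    best, best_q = membership, q
    for cand in (one, singles):
        cq = modularity(g, cand, resolution)
        if cq > best_q + 1e-12:
            best, best_q = cand, cq
    return Partition(
        membership=_dense_relabel(best, g.nodes),
        modularity=best_q,
        resolution=resolution,
    )


def _set_partitions(items: list):
    """Yield all set partitions of ``items`` (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1 :]
        yield [[first]] + part


def exhaustive_best_partition(graph, resolution: float = 0.75) -> Partition:
    """Modularity-maximal partition by full enumeration (<= 10 nodes).

    Ties are broken toward the lexicographically smallest canonical
    labeling over the sorted node list.
    """
    g = _as_nx(graph)
    nodes = sorted(g.nodes, key=str)
    if len(nodes) > 10:
        raise ValidationError("exhaustive search is limited to 10 nodes")
    m = g.number_of_edges()
    if m < 1:
        raise ValidationError("modularity is undefined on an edgeless graph")
    edges = [(u, v) for u, v in g.edges]
    degree = dict(g.degree)
    best_q = -np.inf
    best_canon = None
    for part in _set_partitions(nodes):
        memb = {}
        for ci, block in enumerate(part):
            for v in block:
                memb[v] = ci
        e_c: dict = {}
        d_c: dict = {}
        for u, v in edges:
            if memb[u] == memb[v]:
                e_c[memb[u]] = e_c.get(memb[u], 0) + 1
        for v in nodes:
            d_c[memb[v]] = d_c.get(memb[v], 0) + degree[v]
        q = sum(
            e_c.get(c, 0) / m - resolution * (dc / (2.0 * m)) ** 2
            for c, dc in d_c.items()
        )
        canon = tuple(_dense_relabel(memb, nodes)[v] for v in nodes)
        if q > best_q + 1e-15 or (abs(q - best_q) <= 1e-15 and canon < best_canon):
            best_q = q
            best_canon = canon
    membership = {v: c for v, c in zip(nodes, best_canon)}
    return Partition(membership=membership, modularity=best_q, resolution=resolution)
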