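"""Random-walk diffusion over the interaction network and Artery Networks.

For every (effector, target) association pair (s, t), a random walker
starts at s, moves to each out-neighbour with equal probability and is
absorbed at t or at sink (out-degree 0) nodes.  The weight an edge e
receives from the pair is the conditional probability of traversing e
given that the walker reaches t; short connecting paths and paths avoiding
high-degree hubs therefore contribute more.  Edge weights accumulate over
all pairs, high-weight edges span the Artery Network, the cross-cohort
common portion forms the Consensus Artery Network, and nodes are stratified
into levels 1-4 by their distance from effector anchor nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

L_MAX = 8  # walk-length cap used by the power-iteration fallback on
# networks where the absorbing-chain system is singular


@dataclass
class DiffusionResult:
    edge_weights: dict[tuple[str, str], float]
    per_pair: dict[tuple[str, str], dict[tuple[str, str], float]] = field(default_factory=dict)
    unreachable_pairs: list[tuple[str, str]] = field(default_factory=list)
    failed_pairs: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class ArteryNetwork:
    cohort: str
    edges: dict[tuple[str, str], float]
    levels: dict[str, int] = field(default_factory=dict)

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for (u, v), w in self.edges.items():
            g.add_edge(u, v, weight=w)
        return g


def _pair_edge_weights(
    graph: nx.DiGraph, source: str, target: str
) -> dict[tuple[str, str], float] | None:
    """Conditional edge-traversal probabilities for one (s, t) pair.

    Solves the absorbing-chain linear system: h(u) = P(reach t from u),
    v(u) = expected visits to u starting from s before absorption.  The
    contribution of edge (u, w) is v(u) * (1/outdeg(u)) * h(w) / h(s).
    Returns None when t is unreachable (h(s) = 0).
    """
    nodes = list(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    out = {u: list(graph.successors(u)) for u in nodes}
    # transient nodes: everything except t and sinks (absorbing states)
    absorbing = {target} | {u for u in nodes if not out[u]}
    transient = [u for u in nodes if u not in absorbing]
    t_idx = {u: i for i, u in enumerate(transient)}
    Q = np.zeros((len(transient), len(transient)))
    R_t = np.zeros(len(transient))  # one-step probability into t
    for u in transient:
        p = 1.0 / len(out[u])
        for w in out[u]:
            if w == target:
                R_t[t_idx[u]] += p
            elif w in t_idx:
                Q[t_idx[u], t_idx[w]] += p
    try:
        h_vec = np.linalg.solve(np.eye(len(transient)) - Q, R_t)
    except np.linalg.LinAlgError:
        # recurrent class without absorption: cap the walk length instead
        h_vec = R_t.copy()
        for _ in range(L_MAX - 1):
            h_vec = R_t + Q @ h_vec
    h = {u: float(h_vec[t_idx[u]]) for u in transient}
    h[target] = 1.0
    for u in absorbing - {target}:
        h[u] = 0.0
    if source == target or h.get(source, 0.0) <= 0.0:
        return None
    # expected visits from s (row of the fundamental matrix)
    e_s = np.zeros(len(transient))
    if source in t_idx:
        e_s[t_idx[source]] = 1.0
        try:
            visits = np.linalg.solve((np.eye(len(transient)) - Q).T, e_s)
        except np.linalg.LinAlgError:
            visits = e_s.copy()
            acc = e_s.copy()
            for _ in range(L_MAX - 1):
                acc = Q.T @ acc
                visits += acc
        v = {u: float(visits[t_idx[u]]) for u in transient}
    else:  # source is absorbing but not t -> cannot reach t
        return None
    weights: dict[tuple[str, str], float] = {}
    hs = h[source]
    for u in transient:
        if v[u] <= 0:
            continue
        p = 1.0 / len(out[u])
        for w in out[u]:
            contrib = v[u] * p * h[w] / hs
            if contrib > 0:
                weights[(u, w)] = weights.get((u, w), 0.0) + contrib
    return weights


def diffusion_edge_weights(
    graph: nx.DiGraph,
    pairs: list[tuple[str, str]],
    keep_per_pair: bool = False,
    normalize_by_pairs: bool = False,
) -> DiffusionResult:
    """Accumulate conditional edge-traversal weights over association pairs.

    Pairs with absent endpoints are recorded in ``failed_pairs``; pairs
    whose target is unreachable contribute nothing and are recorded in
    ``unreachable_pairs``.  With ``normalize_by_pairs`` the accumulated
    weights are divided by the number of contributing pairs.
    """
    total: dict[tuple[str, str], float] = {}
    result = DiffusionResult(edge_weights=total)
    n_contributing = 0
    for s, t in pairs:
        if s == t or s not in graph or t not in graph:
            result.failed_pairs.append((s, t))
            continue
        w = _pair_edge_weights(graph, s, t)
        if w is None:
            result.unreachable_pairs.append((s, t))
            continue
        n_contributing += 1
        if keep_per_pair:
            result.per_pair[(s, t)] = w
        for e, val in w.items():
            total[e] = total.get(e, 0.0) + val
    if normalize_by_pairs and n_contributing:
        for e in total:
            total[e] /= n_contributing
    return result


def extract_artery_network(
    weights: DiffusionResult | dict[tuple[str, str], float],
    cohort: str = "",
    threshold: float | None = None,
    top_fraction: float | None = 0.05,
) -> ArteryNetwork:
    """Retain high-weight edges: either ``W(e) >= threshold`` or the top
    ``top_fraction`` of positive-weight edges by weight."""
    ew = weights.edge_weights if isinstance(weights, DiffusionResult) else weights
    positive = {e: w for e, w in ew.items() if w > 0}
    if threshold is not None:
        kept = {e: w for e, w in positive.items() if w >= threshold}
    else:
        if top_fraction is None:
            raise ValueError("give either threshold or top_fraction")
        k = int(np.ceil(top_fraction * len(positive)))
        ranked = sorted(positive.items(), key=lambda kv: (-kv[1], kv[0]))
        kept = dict(ranked[:k])
    return ArteryNetwork(cohort=cohort, edges=kept)


def consensus_artery(
    arteries: list[ArteryNetwork], m: int | None = None
) -> ArteryNetwork:
    """Edges present in at least ``m`` cohort arteries (default: majority);
    consensus weight is the mean over the cohorts containing the edge."""
    if not arteries:
        raise ValueError("need at least one artery network")
    n = len(arteries)
    if m is None:
        m = -(-n // 2)
    if m > n:
        import warnings

        warnings.warn("m exceeds the number of cohorts; consensus is empty")
        return ArteryNetwork(cohort="consensus", edges={})
    counts: dict[tuple[str, str], list[float]] = {}
    for art in arteries:
        for e, w in art.edges.items():
            counts.setdefault(e, []).append(w)
    edges = {e: float(np.mean(ws)) for e, ws in counts.items() if len(ws) >= m}
    return ArteryNetwork(cohort="consensus", edges=edges)


def assign_node_levels(
    artery: ArteryNetwork, effector_anchors: set[str], max_level: int = 4
) -> dict[str, int]:
    """Node level = 1 + shortest distance (within the artery) from the
    nearest effector anchor, capped at ``max_level``; unreachable nodes get
    the cap."""
    if not artery.edges:
        raise ValueError("artery network is empty")
    g = artery.graph()
    sources = [a for a in effector_anchors if a in g]
    dist: dict[str, int] = {}
    if sources:
        for src in sources:
            for node, d in nx.single_source_shortest_path_length(g, src).items():
                if node not in dist or d < dist[node]:
                    dist[node] = d
    levels = {
        node: min(1 + dist[node], max_level) if node in dist else max_level
        for node in g.nodes
    }
    artery.levels = levels
    return levels
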