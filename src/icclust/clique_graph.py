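"""Thresholded co-expression graph and maximal-clique search.

Steps 3-4 of interconnected correlation clustering: among the genes
selected against the target, build an undirected graph with an edge
wherever the pairwise Pearson |r| exceeds the threshold (edge indicator
E=1; the signed r is kept as the edge weight), then enumerate maximal
cliques with the Bron-Kerbosch algorithm and report the largest one,
re-attached to the target gene, as the interconnected correlated gene
cluster (ICGC).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable

import networkx as nx
import numpy as np

from ._errors import ValidationError
from .correlation_stats import CorrelationProfile
from .expression_io import ExpressionMatrix, logger


@dataclass
class CoexpressionGraph:
    """Undirected graph over selected genes; edges carry signed Pearson r.

    Only E=1 pairs (|r| > threshold) are stored.  The target gene is held
    separately: by construction it is correlated above threshold with every
    node, so it is re-attached to the chosen clique rather than carried
    through the search.
    """

    graph: nx.Graph
    threshold: float
    target_gene: str

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def edge_table(self) -> list[dict]:
        rows = [
            {"gene_a": a, "gene_b": b, "r": d["weight"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        rows.sort(key=lambda r: (r["gene_a"], r["gene_b"]))
        return rows

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


@dataclass
class ICGC:
    """The largest maximally interconnected correlated gene cluster.

    ``members`` includes the target gene; every pair of non-target members
    is correlated above threshold, and no outside gene is adjacent to all
    of them.  ``signs`` maps each non-target member to the sign of its
    correlation with the target.
    """

    target_gene: str
    members: list[str]
    threshold: float
    mean_abs_r: float
    signs: dict[str, int] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.members)


def build_graph(
    m: ExpressionMatrix, selected: Iterable[str], threshold: float
) -> CoexpressionGraph:
    """All-pairs Pearson correlation among selected genes, thresholded on |r|.

    The edge rule ignores sign exactly as the selection step does, so a
    cluster may mix genes positively and negatively correlated with the
    target.  Node order is lexicographic for determinism.
    """
    target = getattr(selected, "target_gene", "")
    sel = sorted(set(selected))
    missing = [g for g in sel if g not in m.gene_ids]
    if missing:
        raise ValidationError(f"selected genes not in matrix: {missing[:5]}")
    if not sel:
        raise ValidationError("need at least one selected gene")
    idx = [m.gene_ids.index(g) for g in sel]
    x = m.values[idx]
    sd = x.std(axis=1, ddof=1)
    if np.any(sd == 0):
        bad = [sel[i] for i in np.where(sd == 0)[0]]
        raise ValidationError(f"zero-variance selected gene(s): {bad[:5]}")
    std = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    r = std @ std.T / (m.n_samples - 1)
    np.clip(r, -1.0, 1.0, out=r)

    g = nx.Graph()
    g.add_nodes_from(sel)
    n = len(sel)
    ii, jj = np.triu_indices(n, k=1)
    hit = np.abs(r[ii, jj]) > threshold
    for a, b in zip(ii[hit], jj[hit]):
        g.add_edge(sel[a], sel[b], weight=float(r[a, b]))
    return CoexpressionGraph(g, float(threshold), target)


def _bron_kerbosch_pivot(adj: dict[int, set[int]], R: set, P: set, X: set, out: list,
                         max_cliques: int) -> None:
    if not P and not X:
        out.append(frozenset(R))
        if len(out) > max_cliques:
            raise ValidationError(
                f"clique enumeration exceeded the cap of {max_cliques}; "
                "the graph is too dense"
            )
        return
    # pivot: vertex of P|X with most neighbours in P prunes the most branches
    pivot = max(P | X, key=lambda v: len(adj[v] & P))
    for v in list(P - adj[pivot]):
        _bron_kerbosch_pivot(adj, R | {v}, P & adj[v], X & adj[v], out, max_cliques)
        P.remove(v)
        X.add(v)


def _degeneracy_order(adj: dict[int, set[int]]) -> list[int]:
    deg = {v: len(nb) for v, nb in adj.items()}
    buckets: dict[int, set] = {}
    for v, d in deg.items():
        buckets.setdefault(d, set()).add(v)
    order, seen = [], set()
    while len(order) < len(adj):
        d = min(k for k, b in buckets.items() if b)
        v = min(buckets[d])  # deterministic tie-break
        buckets[d].remove(v)
        order.append(v)
        seen.add(v)
        for u in adj[v]:
            if u not in seen:
                buckets[deg[u]].remove(u)
                deg[u] -= 1
                buckets.setdefault(deg[u], set()).add(u)
    return order


def enumerate_maximal_cliques(
    g: CoexpressionGraph | nx.Graph, max_cliques: int = 10**6
) -> list[list[str]]:
    """All maximal cliques via Bron-Kerbosch with pivoting.

    On graphs with more than 200 nodes the outer recursion level follows a
    degeneracy ordering, which bounds the recursion on sparse graphs.
    Output is canonically ordered (size descending, then lexicographic),
    so results are identical across runs and platforms.  Dense graphs can
    hold exponentially many maximal cliques; enumeration aborts beyond
    ``max_cliques``.
    """
    graph = g.graph if isinstance(g, CoexpressionGraph) else g
    nodes = sorted(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    adj = {i: {index[u] for u in graph.neighbors(v)} for v, i in index.items()}
    out: list[frozenset] = []
    if len(nodes) > 200:
        order = _degeneracy_order(adj)
        pos = {v: i for i, v in enumerate(order)}
        for v in order:
            later = {u for u in adj[v] if pos[u] > pos[v]}
            earlier = adj[v] - later
            _bron_kerbosch_pivot(adj, {v}, set(later), set(earlier), out, max_cliques)
    else:
        _bron_kerbosch_pivot(adj, set(), set(adj), set(), out, max_cliques)
    cliques = [sorted(nodes[i] for i in c) for c in out]
    cliques.sort(key=lambda c: (-len(c), c))
    return cliques


def brute_force_maximal_cliques(g: CoexpressionGraph | nx.Graph) -> list[list[str]]:
    """Maximal cliques by exhaustive subset enumeration (test oracle, <= 20 nodes)."""
    graph = g.graph if isinstance(g, CoexpressionGraph) else g
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n > 20:
        raise ValidationError("brute force refuses graphs with more than 20 nodes")
    index = {v: i for i, v in enumerate(nodes)}
    # bitmask adjacency, self-bit set so clique test is mask-containment
    adj = [1 << i for i in range(n)]
    for a, b in graph.edges:
        adj[index[a]] |= 1 << index[b]
        adj[index[b]] |= 1 << index[a]
    cliques_mask = []
    for mask in range(1, 1 << n):
        bits = [i for i in range(n) if mask >> i & 1]
        if any(mask & ~adj[i] for i in bits):
            continue
        # maximal iff no outside vertex adjacent to every member
        if any(
            not (mask >> j & 1) and all(adj[j] >> i & 1 for i in bits)
            for j in range(n)
        ):
            continue
        cliques_mask.append(mask)
    cliques = [
        sorted(nodes[i] for i in range(n) if mask >> i & 1) for mask in cliques_mask
    ]
    cliques.sort(key=lambda c: (-len(c), c))
    return cliques


def _mean_abs_r(graph: nx.Graph, members: list[str]) -> float:
    weights = [
        abs(graph[a][b]["weight"])
        for a, b in combinations(members, 2)
        if graph.has_edge(a, b)
    ]
    return float(np.mean(weights)) if weights else float("nan")


def largest_icgc(
    g: CoexpressionGraph, profile: CorrelationProfile, max_cliques: int = 10**6
) -> ICGC:
    """The maximum-size maximal clique, re-attached to the target gene.

    Ties in size are broken by larger mean |r| over within-clique edges,
    then lexicographically, so the result is deterministic.  Because every
    selected gene is correlated with the target above threshold, appending
    the target to any clique keeps both the clique and maximality
    properties.
    """
    target = profile.target_gene
    if g.graph.number_of_nodes() == 0:
        logger.warning("empty co-expression graph: ICGC contains only the target")
        return ICGC(target, [target], g.threshold, float("nan"), {})
    cliques = enumerate_maximal_cliques(g, max_cliques=max_cliques)
    best_size = len(cliques[0])
    candidates = [c for c in cliques if len(c) == best_size]
    if len(candidates) > 1:
        candidates.sort(key=lambda c: (-_mean_abs_r(g.graph, c), c))
    members = candidates[0]
    signs = {gene: (1 if profile.r_of(gene) > 0 else -1) for gene in members}
    return ICGC(
        target_gene=target,
        members=sorted(members) + [target] if target not in members else sorted(members),
        threshold=g.threshold,
        mean_abs_r=_mean_abs_r(g.graph, members),
        signs=signs,
    )
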