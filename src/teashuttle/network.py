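"""PPI network construction and hub-gene ranking by four centralities.

Edges arrive as STRING-dialect rows (protein1, protein2, combined_score on
a 0-1000 scale).  The network keeps edges at or above a 70% confidence
cutoff (combined_score >= 700) and then discards weakly connected nodes
(degree <= 2, single pass by default; an iterated 3-core mode exists).

Hub genes are ranked by four topological scores, each implemented
directly on the adjacency structure:

* **degree** -- number of incident edges;
* **closeness** -- harmonic centrality, sum over reachable vertices of
  1/d(v, u) (well defined on disconnected graphs, unlike the classic
  Freeman form, which is available behind a flag);
* **MCC** (maximal clique centrality) -- sum over maximal cliques C
  containing v of (|C|-1)!, with maximal cliques enumerated by
  Bron-Kerbosch with pivoting;
* **MNC** (maximal neighborhood component) -- order of the largest
  connected component of the subgraph induced by v's neighbors.

The per-algorithm top-15 lists are intersected into a consensus, and
consensus sets across the four tumor subtypes intersect into the key hub
genes per regulation direction.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from math import factorial

import networkx as nx
import pandas as pd

from .errors import EdgeListParseError, ResourceLimitError

SCORE_CUTOFF = 700
MIN_DEGREE_KEEP = 3
TOP_K = 15
ALGORITHMS = ("mcc", "mnc", "degree", "closeness")
MCC_NODE_CAP = 5000


def build_network(edges: pd.DataFrame, score_cutoff: int = SCORE_CUTOFF,
                  min_degree_keep: int = MIN_DEGREE_KEEP,
                  prune: str = "once") -> nx.Graph:
    """Confidence-filtered PPI graph from a STRING-style edge table.

    Drops self-loops and duplicate pairs, removes edges scoring below the
    cutoff, then prunes nodes of degree < ``min_degree_keep`` -- in a
    single pass (default) or iterated to the k-core (``prune="kcore"``).
    """
    required = {"protein1", "protein2", "combined_score"}
    if not required <= set(edges.columns):
        raise ValueError(f"edge table needs columns {sorted(required)}")
    g = nx.Graph()
    for lineno, row in enumerate(edges.itertuples(index=False), start=1):
        a, b = str(row.protein1), str(row.protein2)
        try:
            score = float(row.combined_score)
        except (TypeError, ValueError) as exc:
            raise EdgeListParseError(lineno, f"bad score {row!r}") from exc
        if not 0 <= score <= 1000:
            raise EdgeListParseError(lineno,
                                     f"score {score} outside [0, 1000]")
        if a == b or score < score_cutoff:
            continue
        g.add_edge(a, b, combined_score=score)
    if prune == "kcore":
        g = nx.k_core(g, k=min_degree_keep).copy()
    else:
        weak = [v for v in g if g.degree(v) < min_degree_keep]
        g.remove_nodes_from(weak)
    return g


def degree_centrality(net: nx.Graph) -> dict[str, float]:
    """Raw degree (edge count), the cytoHubba convention."""
    return {v: float(net.degree(v)) for v in net}


def _bfs_distances(net: nx.Graph, source) -> dict:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for w in net[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                queue.append(w)
    return dist


def closeness_centrality(net: nx.Graph,
                         variant: str = "harmonic") -> dict[str, float]:
    """Harmonic closeness by BFS; ``variant="classic"`` gives Freeman
    closeness (n-1 over the sum of distances within the component)."""
    out = {}
    for v in net:
        dist = _bfs_distances(net, v)
        if variant == "harmonic":
            out[v] = float(sum(1.0 / d for u, d in dist.items() if u != v))
        else:
            total = sum(d for u, d in dist.items() if u != v)
            out[v] = (len(dist) - 1) / total if total > 0 else 0.0
    return out


def _bron_kerbosch_pivot(adj: dict, r: set, p: set, x: set, out: list):
    if not p and not x:
        out.append(frozenset(r))
        return
    pivot = max(p | x, key=lambda u: len(adj[u] & p))
    for v in list(p - adj[pivot]):
        _bron_kerbosch_pivot(adj, r | {v}, p & adj[v], x & adj[v], out)
        p.remove(v)
        x.add(v)


def maximal_cliques(net: nx.Graph) -> list[frozenset]:
    """All maximal cliques via Bron-Kerbosch with pivoting.

    Isolated vertices count as their own maximal 1-cliques.
    """
    adj = {v: set(net[v]) for v in net}
    out: list[frozenset] = []
    _bron_kerbosch_pivot(adj, set(), set(adj), set(), out)
    return out


def mcc(net: nx.Graph, node_cap: int = MCC_NODE_CAP) -> dict[str, float]:
    """Maximal clique centrality: sum of (|C|-1)! over maximal cliques
    containing each vertex."""
    if net.number_of_nodes() > node_cap:
        raise ResourceLimitError(
            f"{net.number_of_nodes()} nodes exceeds MCC cap {node_cap}")
    scores = {v: 0.0 for v in net}
    for clique in maximal_cliques(net):
        w = float(factorial(len(clique) - 1))
        for v in clique:
            scores[v] += w
    return scores


def mnc(net: nx.Graph) -> dict[str, float]:
    """Maximal neighborhood component: size of the largest connected
    component among each vertex's neighbors (the vertex excluded)."""
    out = {}
    for v in net:
        nbrs = set(net[v])
        best, seen = 0, set()
        for start in nbrs:
            if start in seen:
                continue
            comp, queue = 0, deque([start])
            seen.add(start)
            while queue:
                u = queue.popleft()
                comp += 1
                for w in net[u]:
                    if w in nbrs and w not in seen:
                        seen.add(w)
                        queue.append(w)
            best = max(best, comp)
        out[v] = float(best)
    return out


def centrality_table(net: nx.Graph) -> pd.DataFrame:
    """All four scores per node, one column per algorithm."""
    cols = {"degree": degree_centrality(net),
            "closeness": closeness_centrality(net),
            "mcc": mcc(net),
            "mnc": mnc(net)}
    return pd.DataFrame(cols).rename_axis("gene").sort_index()


@dataclass
class HubConsensus:
    """Per-algorithm top-k rankings and their intersection."""

    top_lists: dict[str, list[str]]
    consensus: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.top_lists and not self.consensus:
            sets = [set(lst) for lst in self.top_lists.values()]
            self.consensus = sorted(set.intersection(*sets))


def rank_nodes(scores: dict[str, float], k: int = TOP_K) -> list[str]:
    """Top-k by score descending, ties broken by gene symbol ascending
    (strict cut: exactly k names even when scores tie at the boundary)."""
    ordered = sorted(scores, key=lambda v: (-scores[v], v))
    return ordered[:k]


def top_k_consensus(tables: pd.DataFrame | dict[str, dict[str, float]],
                    k: int = TOP_K,
                    algorithms: tuple[str, ...] = ALGORITHMS
                    ) -> HubConsensus:
    """Intersect the per-algorithm top-k hub lists.

    ``tables`` is a centrality table (columns per algorithm) or a mapping
    algorithm -> node scores.  The consensus is invariant to the order in
    which algorithms are listed.
    """
    if isinstance(tables, pd.DataFrame):
        score_maps = {a: tables[a].to_dict() for a in algorithms}
    else:
        score_maps = {a: tables[a] for a in algorithms}
    top = {a: rank_nodes(score_maps[a], k) for a in algorithms}
    return HubConsensus(top)


def key_hub_intersection(consensus_per_subtype: dict[str, list[str]]
                         ) -> list[str]:
    """Genes present in every subtype's consensus list, sorted."""
    if not consensus_per_subtype:
        return []
    sets = [set(v) for v in consensus_per_subtype.values()]
    return sorted(set.intersection(*sets))
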