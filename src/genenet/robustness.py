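"""Graph metrics and node-removal attacks, with ER baselines.

All analyses run on the symmetrized, deduplicated, loop-free view of a
graph (the convention shared with the RG analytics).  Attacks remove nodes
one at a time — uniformly at random, or greedily by current degree with
degrees recomputed after every removal — and record the size of the
largest connected component relative to the initial one.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .barcodes import GeneticGraph

__all__ = [
    "AttackTrace",
    "MetricsReport",
    "graph_metrics",
    "attack",
    "er_graph",
]


def adjacency_from_packed(packed, n: int) -> dict:
    """Adjacency dict over nodes 0..n-1 from packed undirected keys u*n+v."""
    adj = {u: set() for u in range(n)}
    for key in packed:
        u, v = divmod(int(key), n)
        adj[u].add(v)
        adj[v].add(u)
    return adj


def _adjacency(g) -> dict:
    """Symmetrized simple loop-free adjacency (dict of sets) from a
    :class:`GeneticGraph`, a networkx graph, or an adjacency dict."""
    if isinstance(g, dict):
        return {u: set(vs) - {u} for u, vs in g.items()}
    if isinstance(g, GeneticGraph):
        adj = {int(u): set() for u in g.universe}
        for u, v in g.undirected_edges():
            adj[int(u)].add(int(v))
            adj[int(v)].add(int(u))
        return adj
    adj = {u: set() for u in g.nodes}
    for u, v in g.edges:
        if u != v:
            adj[u].add(v)
            adj[v].add(u)
    return adj


def _components(adj: dict) -> list[set]:
    seen = set()
    comps = []
    for start in adj:
        if start in seen:
            continue
        stack = [start]
        comp = {start}
        seen.add(start)
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in comp:
                    comp.add(v)
                    seen.add(v)
                    stack.append(v)
        comps.append(comp)
    return comps


def _largest_component(adj: dict) -> set:
    comps = _components(adj)
    return max(comps, key=len) if comps else set()


@dataclass
class MetricsReport:
    """Summary metrics of the symmetrized simple loop-free graph."""

    node_count: int
    density: float
    lcc: int
    ncc: int
    ncc_positive: int
    mean_clustering: float
    mean_path_length: float  # averaged over the LCC; nan for LCC < 2
    degree_histogram: np.ndarray = field(repr=False, default=None)


def graph_metrics(g, path_length: bool = True) -> MetricsReport:
    """Compute the standard report; path length is averaged on the LCC only.

    ``path_length=False`` skips the all-pairs computation (quadratic in the
    LCC) and reports nan.
    """
    adj = _adjacency(g)
    n = len(adj)
    comps = _components(adj)
    lcc_nodes = max(comps, key=len) if comps else set()
    m = sum(len(s) for s in adj.values()) // 2
    density = 0.0 if n < 2 else m / (n * (n - 1) / 2)
    ncc_positive = sum(1 for c in comps if len(c) > 1 or adj[next(iter(c))])
    sg = nx.Graph((u, v) for u in adj for v in adj[u] if u < v)
    sg.add_nodes_from(adj)
    clustering = nx.average_clustering(sg) if n else float("nan")
    if path_length and len(lcc_nodes) > 1:
        mean_path = nx.average_shortest_path_length(sg.subgraph(lcc_nodes))
    else:
        mean_path = float("nan")
    deg = np.array([len(adj[u]) for u in adj], dtype=np.int64)
    hist = np.bincount(deg, minlength=1) if n else np.zeros(1, dtype=np.int64)
    return MetricsReport(
        node_count=n,
        density=density,
        lcc=len(lcc_nodes) if n else 0,
        ncc=len(comps),
        ncc_positive=ncc_positive,
        mean_clustering=clustering,
        mean_path_length=float(mean_path),
        degree_histogram=hist,
    )


@dataclass
class AttackTrace:
    """Relative-LCC trajectory of one attack run.

    ``fraction_removed`` and ``rel_lcc`` are aligned samples; the trace
    starts at (0, 1) and, under full removal, ends at relative LCC 0.
    """

    strategy: str
    seed: int | None
    fraction_removed: np.ndarray
    rel_lcc: np.ndarray

    def rel_lcc_at(self, fraction: float) -> float:
        """Relative LCC at the last sample with fraction <= ``fraction``."""
        idx = np.searchsorted(self.fraction_removed, fraction, side="right") - 1
        return float(self.rel_lcc[max(idx, 0)])


def attack(
    g,
    strategy: str = "random",
    seed: int | None = None,
    stop_fraction: float = 1.0,
    record_fractions=None,
) -> AttackTrace:
    """Remove nodes and track the LCC relative to the initial giant component.

    ``strategy="random"`` removes uniformly without replacement;
    ``"targeted"`` removes the current highest-degree node, recomputing
    degrees after every removal (ties broken toward the smallest node
    label, so runs replay deterministically).  By default the trace is
    recorded after every removal; ``record_fractions`` restricts LCC
    evaluation to those removal fractions (cheaper on dense graphs), and
    ``stop_fraction`` truncates the attack early.
    """
    if strategy not in ("random", "targeted"):
        raise ValueError("strategy must be 'random' or 'targeted'")
    adj = _adjacency(g)
    n0 = len(adj)
    if n0 == 0:
        raise ValueError("attack needs a non-empty graph")
    rng = np.random.default_rng(seed)
    lcc_nodes = _largest_component(adj)
    initial = max(len(lcc_nodes), 1)
    n_remove = int(round(stop_fraction * n0))
    if strategy == "random":
        nodes_sorted = sorted(adj)
        order = [nodes_sorted[i] for i in rng.permutation(n0)]
    checkpoints = None
    if record_fractions is not None:
        checkpoints = sorted(set(record_fractions))
    fractions = [0.0]
    rel = [len(lcc_nodes) / initial]
    deg = {u: len(adj[u]) for u in adj}
    if strategy == "targeted":
        # lazy-deletion max-heap; (-degree, node) orders ties toward the
        # smallest node label
        heap = [(-d, u) for u, d in deg.items()]
        heapq.heapify(heap)
    for step in range(1, n_remove + 1):
        if strategy == "random":
            node = order[step - 1]
        else:
            while True:
                d, node = heapq.heappop(heap)
                if node in deg and deg[node] == -d:
                    break
        for nb in adj.pop(node):
            adj[nb].discard(node)
            deg[nb] -= 1
            if strategy == "targeted":
                heapq.heappush(heap, (-deg[nb], nb))
        del deg[node]
        frac = step / n0
        if checkpoints is None:
            # recompute only when the LCC could have changed
            if node in lcc_nodes:
                lcc_nodes = _largest_component(adj)
            fractions.append(frac)
            rel.append(len(lcc_nodes) / initial)
        elif checkpoints and frac >= checkpoints[0] - 1e-12:
            while checkpoints and frac >= checkpoints[0] - 1e-12:
                checkpoints.pop(0)
            lcc_nodes = _largest_component(adj)
            fractions.append(frac)
            rel.append(len(lcc_nodes) / initial)
    return AttackTrace(
        strategy=strategy,
        seed=seed,
        fraction_removed=np.array(fractions),
        rel_lcc=np.array(rel),
    )


def er_graph(n: int, density: float, seed: int | None = None) -> nx.Graph:
    """G(n, p) baseline with p = density: undirected, simple, seeded."""
    if not (0.0 <= density <= 1.0):
        raise ValueError("density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    g = nx.fast_gnp_random_graph(n, density, seed=int(rng.integers(2**31)))
    return g
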