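"""Non-overlapping set-to-node mapping and its GM(ER) analytics.

When every rule fixes the same bit positions, each node belongs to exactly
one set and the encoding reduces to expanding a *set-level* graph: a link
between sets of sizes ``s_i`` and ``s_j`` becomes the full ``s_i * s_j``
biclique between their member nodes.  With an Erdos-Renyi graph at the set
level, the expanded node-level family is called GM(ER).

The analytics cover the constant-size case (all sets of ``2**x`` nodes,
``2**(b-x)`` sets) — density at both levels, their ratio (which tends to 1
for large spaces), and the node-level degree law whose support is the
multiples of ``2**x`` — and the variable-size case with sizes drawn from a
distribution q(s), where the node-level degree K inherits mean
``<k><s>``, variance ``<k> var(s) + <s>^2 var(k)``, and (for a Poisson set
level) Fano factor ``<s^2>/<s>``.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.stats import binom

from .distributions import DegreePMF

__all__ = [
    "SetLevelGraph",
    "SizeDistribution",
    "random_set_graph",
    "expand_set_graph",
    "node_degrees",
    "gmer_density_constant",
    "gmer_degree_pmf_constant",
    "gmer_moments_variable",
    "gmer_degree_pmf_variable",
]


@dataclass(frozen=True)
class SizeDistribution:
    """Finite discrete distribution of set sizes."""

    values: tuple[int, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.probs):
            raise ValueError("values and probs must have equal length")
        if any(v < 1 for v in self.values):
            raise ValueError("set sizes must be positive integers")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")

    @classmethod
    def constant(cls, s0: int) -> "SizeDistribution":
        return cls(values=(s0,), probs=(1.0,))

    def moment(self, order: int) -> float:
        return float(
            sum(p * v**order for v, p in zip(self.values, self.probs))
        )

    @property
    def mean(self) -> float:
        return self.moment(1)

    @property
    def var(self) -> float:
        return self.moment(2) - self.mean**2

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(self.values, size=n, p=self.probs)

    def pmf_array(self) -> np.ndarray:
        out = np.zeros(max(self.values) + 1)
        for v, p in zip(self.values, self.probs):
            out[v] += p
        return out


@dataclass
class SetLevelGraph:
    """Undirected set-level graph (self-loops allowed) with per-set sizes."""

    sizes: np.ndarray
    edges: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=np.int64)
        if np.any(self.sizes < 1):
            raise ValueError("set sizes must be positive")
        n = self.n_sets
        norm = []
        for i, j in self.edges:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"edge ({i}, {j}) outside 0..{n - 1}")
            norm.append((min(i, j), max(i, j)))
        if len(set(norm)) != len(norm):
            raise ValueError("duplicate set-level edges")
        self.edges = norm

    @property
    def n_sets(self) -> int:
        return len(self.sizes)

    @property
    def n_nodes(self) -> int:
        return int(self.sizes.sum())

    def set_degrees(self) -> np.ndarray:
        """Set-level degree; a self-loop counts once."""
        deg = np.zeros(self.n_sets, dtype=np.int64)
        for i, j in self.edges:
            deg[i] += 1
            if j != i:
                deg[j] += 1
        return deg


def random_set_graph(
    n_sets: int,
    n_links: int | None = None,
    size_dist: SizeDistribution = SizeDistribution.constant(1),
    seed: int | None = None,
    allow_loops: bool = True,
    p: float | None = None,
) -> SetLevelGraph:
    """ER set-level graph with sizes drawn from ``size_dist``.

    Exactly one of ``n_links`` (that many distinct edges drawn uniformly)
    or ``p`` (each candidate edge present independently) must be given.
    Self-loop slots are part of the candidate pool when ``allow_loops`` (so
    there are ``n(n-1)/2 + n`` slots), matching the density convention of
    the constant-size analytics; under ``p`` each set's degree is then
    exactly Binomial(n_sets, p).
    """
    if (n_links is None) == (p is None):
        raise ValueError("give exactly one of n_links or p")
    rng = np.random.default_rng(seed)
    pairs = [
        (i, j)
        for i in range(n_sets)
        for j in range(i if allow_loops else i + 1, n_sets)
    ]
    if n_links is not None:
        if not (0 <= n_links <= len(pairs)):
            raise ValueError(f"n_links must be in 0..{len(pairs)}")
        chosen = rng.choice(len(pairs), size=n_links, replace=False)
        edges = [pairs[c] for c in chosen]
    else:
        if not (0.0 <= p <= 1.0):
            raise ValueError("p must be a probability")
        keep = rng.random(len(pairs)) < p
        edges = [pair for pair, k in zip(pairs, keep) if k]
    sizes = size_dist.sample(n_sets, rng)
    return SetLevelGraph(sizes=sizes, edges=edges)


def expand_set_graph(g: SetLevelGraph) -> nx.Graph:
    """Node-level expansion: each set edge becomes the full biclique.

    Nodes are 0 .. sum(sizes) - 1, consecutive per set, each carrying a
    ``"set"`` attribute.  A set-level self-loop expands to the clique on
    that set including per-node self-loops.
    """
    out = nx.Graph()
    starts = np.concatenate([[0], np.cumsum(g.sizes)[:-1]])
    for s, (start, size) in enumerate(zip(starts, g.sizes)):
        for u in range(start, start + size):
            out.add_node(int(u), set=s)
    for i, j in g.edges:
        nodes_i = range(int(starts[i]), int(starts[i] + g.sizes[i]))
        if i == j:
            for u in nodes_i:
                for v in nodes_i:
                    if v >= u:
                        out.add_edge(u, v)
        else:
            nodes_j = range(int(starts[j]), int(starts[j] + g.sizes[j]))
            for u in nodes_i:
                for v in nodes_j:
                    out.add_edge(u, v)
    return out


def node_degrees(g: SetLevelGraph) -> np.ndarray:
    """Node-level degrees K_j = sum of neighbor-set sizes, per node.

    Every node of set j has the same degree: the sum of ``s_i`` over the
    set-level neighbors i of j (a self-loop makes j its own neighbor).
    Self-loop edges at the node level count once.
    """
    k_set = np.zeros(g.n_sets, dtype=np.int64)
    for i, j in g.edges:
        k_set[i] += g.sizes[j]
        if j != i:
            k_set[j] += g.sizes[i]
    return np.repeat(k_set, g.sizes)


def gmer_density_constant(
    b: int, x: int, n_links: int
) -> tuple[float, float, float]:
    """Set-level density, node-level density, and their exact ratio.

    With R links among ``2**(b-x)`` sets (loops allowed in the slot count):
    rho_set = 2R / (2^(b-x) (1 + 2^(b-x))); the expansion has N = 2^b and
    L = R 4^x, giving rho_node = 2R 4^x / (2^b (1 + 2^b)).  Their ratio
    ``2^b (2^b + 1) / (2^(b+x) (2^(b-x) + 1))`` tends to 1 when both
    ``2^b`` and ``2^(b-x)`` are large: the mapping preserves density.
    """
    if x > b:
        raise ValueError("x must be <= b")
    n_set = 2.0 ** (b - x)
    n_node = 2.0**b
    rho_set = 2.0 * n_links / (n_set * (1.0 + n_set))
    rho_node = 2.0 * n_links * 4.0**x / (n_node * (1.0 + n_node))
    ratio = n_node * (n_node + 1.0) / (2.0 ** (b + x) * (n_set + 1.0))
    return float(rho_set), float(rho_node), float(ratio)


def gmer_degree_pmf_constant(b: int, x: int, rho: float) -> DegreePMF:
    """Node-level degree law at constant set size 2**x.

    Non-overlapping sets mean a node's degree is ``2**x`` times its set's
    degree, so the support is the multiples of ``2**x`` and the mass there
    is Binomial(2^(b-x), rho) on the set-level degree; all other degrees
    have probability exactly 0.
    """
    if not (0.0 <= rho <= 1.0):
        raise ValueError("rho must be a probability")
    n_set = 1 << (b - x)
    s0 = 1 << x
    p = np.zeros((1 << b) + 1)
    set_deg = np.arange(n_set + 1)
    p[set_deg * s0] = binom.pmf(set_deg, n_set, rho)
    return DegreePMF(p)


def gmer_moments_variable(
    mean_k: float, var_k: float, size_dist: SizeDistribution
) -> tuple[float, float, float]:
    """Node-degree moments under variable set sizes.

    By total expectation/variance: <K> = <k><s> and
    var(K) = <k> var(s) + <s>^2 var(k).  Returns (mean_K, var_K, Fano(K));
    when the set level is Poisson (var_k == mean_k) the Fano factor
    reduces to <s^2>/<s>.
    """
    mean_s = size_dist.mean
    mean_K = mean_k * mean_s
    var_K = mean_k * size_dist.var + mean_s**2 * var_k
    fano = var_K / mean_K if mean_K > 0 else float("nan")
    return float(mean_K), float(var_K), float(fano)


def gmer_degree_pmf_variable(
    set_degree_pmf: np.ndarray, size_dist: SizeDistribution
) -> DegreePMF:
    """Full node-level degree law: mixture of k-fold size convolutions.

    p_K(K) = sum_k p_k(k) P(s_1 + ... + s_k = K), computed by exact
    convolution of q(s) — feasible because set-level degrees are small.
    """
    set_degree_pmf = np.asarray(set_degree_pmf, dtype=float)
    q = size_dist.pmf_array()
    max_k = len(set_degree_pmf) - 1
    max_K = max_k * (len(q) - 1)
    out = np.zeros(max_K + 1)
    conv = np.array([1.0])  # 0-fold convolution: point mass at 0
    for k in range(max_k + 1):
        if set_degree_pmf[k] > 0:
            out[: len(conv)] += set_degree_pmf[k] * conv
        if k < max_k:
            conv = np.convolve(conv, q)
    return DegreePMF(out)
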