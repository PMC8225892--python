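"""The Random Genetic (RG) model: rule sampling and its analytic companion.

An RG network on ``N = 2**b`` nodes is built from ``r`` wiring rules.  Each
rule side independently places ``x`` passive (X) bits on a uniformly random
subset of the ``b`` positions and fair-coins the remaining active bits, so
each side names a uniformly random ``2**x``-member set and each rule drops
a directed biclique of ``2**(2x)`` links into the graph.  The probability
that a fixed node lands on one side of one rule is ``pi = 2**(x - b)``.

All analytics (density, degree law, component phases, attack behavior)
work on the symmetrized, deduplicated, loop-free view of the graph: the
``2r`` exponent in the density derivation counts rule *sides*, i.e. a node
pair is linked if either orientation of any rule covers it.

Analytic surface
----------------
* :func:`rg_density` — expected density ``1 - (1 - pi^2)**(2r)``.
* :func:`rg_degree_pmf` — binomial-mixture degree law: the number of rule
  sides containing a node is Binomial(2r, pi); given ``r_i`` sides, a
  random other node is captured with probability ``q = 1 - (1-pi)**r_i``
  and the degree is Binomial(N, q).
* :func:`rg_thresholds` — the rule counts at the subcritical/supercritical
  (mean degree 1) and supercritical/connected (node coverage) transitions.
* :func:`rg_saturation` — with-replacement saturation forms for density,
  LCC/N and #CC/N, functions of ``b - x`` only.
* :func:`rules_for_degree` — rules needed for a target mean degree, with
  its two scaling limits.
* :func:`phase_scan` — seeded Monte-Carlo grid of component statistics
  over (x, r).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import binom

from .barcodes import BarcodeSpace, Pattern, RuleSet, WiringRule
from .distributions import DegreePMF

__all__ = [
    "RGParams",
    "PhaseDiagram",
    "sample_rg_ruleset",
    "sample_rg_undirected_edges",
    "rg_density",
    "rg_degree_pmf",
    "rg_thresholds",
    "rg_saturation",
    "rules_for_degree",
    "rules_for_degree_limit",
    "simulate_density",
    "simulate_degree_counts",
    "simulate_component_stats",
    "empirical_ccdf",
    "phase_scan",
]


@dataclass(frozen=True)
class RGParams:
    """Parameters (b, x, r) of the random genetic model, plus a seed."""

    b: int
    x: int
    r: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.b):
            raise ValueError("b must be positive")
        if not (0 <= self.x <= self.b):
            raise ValueError(f"x must be in 0..b={self.b}, got {self.x}")
        if self.r < 0:
            raise ValueError("r must be non-negative")

    @property
    def n(self) -> int:
        return 1 << self.b

    @property
    def pi(self) -> float:
        """Probability 2**(x-b) that a node lies on one side of one rule."""
        return 2.0 ** (self.x - self.b)


def _rng(params_or_seed) -> np.random.Generator:
    if isinstance(params_or_seed, np.random.Generator):
        return params_or_seed
    return np.random.default_rng(params_or_seed)


def _random_sides(
    b: int, x: int, r: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample r rule sides: returns (passive bit-values (r, x), active bits (r,)).

    Passive positions are a uniform size-x subset of the b positions per
    side; the remaining active bits are fair coins.
    """
    if r == 0:
        return np.empty((0, x), dtype=np.int64), np.empty(0, dtype=np.int64)
    order = np.argsort(rng.random((r, b)), axis=1)
    passive_pos = order[:, :x]  # column index, 0 = leftmost = MSB
    bitvals = (np.int64(1) << (b - 1 - passive_pos)).astype(np.int64)
    passive_mask = bitvals.sum(axis=1) if x else np.zeros(r, dtype=np.int64)
    full = (np.int64(1) << b) - 1
    active = rng.integers(0, 1 << b, size=r, dtype=np.int64) & ~passive_mask & full
    return bitvals, active


def _side_members(bitvals: np.ndarray, active: np.ndarray) -> np.ndarray:
    """Member barcodes of each side: (r, 2^x) from (r, x) passive bit-values."""
    r, x = bitvals.shape
    combos = (np.arange(1 << x, dtype=np.int64)[:, None] >> np.arange(x)) & 1
    # (2^x, x) @ (x, r) -> offsets per member per side
    return active[:, None] + (combos @ bitvals.T).T


def sample_rg_ruleset(
    params: RGParams, rng: np.random.Generator | None = None
) -> RuleSet:
    """Draw r random rules; reproducible from ``params.seed`` (or ``rng``)."""
    rng = _rng(params.seed if rng is None else rng)
    b, x, r = params.b, params.x, params.r
    full = (1 << b) - 1
    rules = []
    for _ in range(r):
        sides = []
        for _side in range(2):
            bitvals, active = _random_sides(b, x, 1, rng)
            passive_mask = int(bitvals.sum()) if x else 0
            sides.append(
                Pattern(b=b, mask=full & ~passive_mask, bits=int(active[0]))
            )
        rules.append(WiringRule(sides[0], sides[1]))
    return RuleSet(BarcodeSpace(b), rules)


def sample_rg_undirected_edges(
    params: RGParams, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Unique undirected non-loop edges of one sampled RG network.

    Returns a sorted array of packed keys ``min*N + max``; this vectorized
    path is what the Monte-Carlo estimators use for large ``r``.
    """
    rng = _rng(params.seed if rng is None else rng)
    b, x, r = params.b, params.x, params.r
    if r == 0:
        return np.empty(0, dtype=np.int64)
    n = np.int64(1) << b
    sb, sa = _random_sides(b, x, r, rng)
    db, da = _random_sides(b, x, r, rng)
    src = _side_members(sb, sa)  # (r, 2^x)
    dst = _side_members(db, da)
    u = src[:, :, None]
    v = dst[:, None, :]
    lo = np.minimum(u, v).ravel()
    hi = np.maximum(u, v).ravel()
    keep = lo < hi
    return np.unique(lo[keep] * n + hi[keep])


def rg_density(params: RGParams) -> float:
    """Expected undirected density: 1 - (1 - pi^2)**(2r)."""
    return float(1.0 - (1.0 - params.pi**2) ** (2 * params.r))


def rg_degree_pmf(params: RGParams) -> DegreePMF:
    """Binomial-mixture degree distribution of the RG model.

    P(k) = sum_{r_i=0}^{2r} Binom(2r, pi).pmf(r_i) * Binom(N, q(r_i)).pmf(k)
    with q(r_i) = 1 - (1 - pi)**r_i.  The mixture treats rule overlaps only
    through q, so it is smoother than the empirical law at small r and
    tightens as overlaps proliferate.
    """
    n, pi, r = params.n, params.pi, params.r
    ri = np.arange(2 * r + 1)
    w = binom.pmf(ri, 2 * r, pi)  # P(r_i)
    q = 1.0 - (1.0 - pi) ** ri
    k = np.arange(n + 1)
    # (len(ri), n+1) conditional pmfs, mixed by w
    cond = binom.pmf(k[None, :], n, q[:, None])
    return DegreePMF(w @ cond)


def rg_thresholds(b: int, x: int) -> tuple[float, float]:
    """Critical rule counts (subcritical->supercritical, ->connected).

    The first solves mean degree 1, ``N (1 - (1-pi^2)^(2r)) = 1``, giving
    ``r = log(1 - 2^-b) / (2 log(1 - 2^(2(x-b))))``.  The second is the
    coverage condition: enough rules for every node to sit in one rule
    absent overlap, ``r = 2^b / 2^(x+1) = 2^(b-x-1)``.
    """
    if not (0 <= x < b):
        raise ValueError("thresholds require 0 <= x < b")
    r1 = np.log1p(-(2.0**-b)) / (2.0 * np.log1p(-(2.0 ** (2 * (x - b)))))
    r2 = 2.0 ** (b - x - 1)
    return float(r1), float(r2)


def rg_saturation(b: int, x: int, r: int | float) -> tuple[float, float, float]:
    """Saturation (with-replacement) forms of density, LCC/N and #CC/N.

    Density treats the r rules as draws from the pool of
    ``m = 2^(b-x-1) (2^(b-x) - 1)`` distinct set-level pairs:
    ``D = 1 - ((m-1)/m)**r``.  LCC/N and #CC/N treat the 2r rule sides as
    draws from the ``m = 2^(b-x)`` possible sets:
    ``LCC/N = 1 - ((m-1)/m)**(2r)`` and ``#CC/N = ((m-1)/m)**(2r)``, which
    sum to 1 exactly.  All three depend on b - x only.
    """
    m_d = 2.0 ** (b - x - 1) * (2.0 ** (b - x) - 1.0)
    density = 1.0 - ((m_d - 1.0) / m_d) ** r
    m_c = 2.0 ** (b - x)
    cc = ((m_c - 1.0) / m_c) ** (2 * r)
    return float(density), float(1.0 - cc), float(cc)


def rules_for_degree(b: int, x: int, mean_degree: float) -> float:
    """Rules needed for a target mean degree at (b, x).

    Inverts mean degree = N * density:
    ``r = 0.5 log(1 - <k> 2^-b) / log(1 - 2^(2(x-b)))``.
    """
    n = 2.0**b
    if not (0 < mean_degree < n):
        raise ValueError("mean_degree must be in (0, 2^b)")
    return float(
        0.5 * np.log1p(-mean_degree / n) / np.log1p(-(2.0 ** (2 * (x - b))))
    )


def rules_for_degree_limit(
    b: int, x: int, mean_degree: float, regime: str
) -> float:
    """Asymptotic rule counts for a target mean degree.

    ``regime="fixed_gap"`` (b - x held constant, large b): r scales as
    <k>/N, i.e. ``r = -0.5 (<k>/N) / log(1 - 2^(2(x-b)))`` — the number of
    rules *shrinks* with system size because each rule's biclique grows as
    N^2.  ``regime="wide_gap"`` (b - x >> 1): ``r = <k> N / 2^(2x+1)``,
    linear in N.
    """
    n = 2.0**b
    if regime == "fixed_gap":
        return float(
            -0.5 * (mean_degree / n) / np.log1p(-(2.0 ** (2 * (x - b))))
        )
    if regime == "wide_gap":
        return float(mean_degree * n / 2.0 ** (2 * x + 1))
    raise ValueError("regime must be 'fixed_gap' or 'wide_gap'")


# ---------------------------------------------------------------------------
# Monte-Carlo estimators


def _component_stats(packed: np.ndarray, n_nodes: int) -> tuple[int, int, int]:
    """(LCC size, #CC, #CC among degree>0 nodes) from packed edge keys."""
    if len(packed) == 0:
        return (1 if n_nodes else 0, n_nodes, 0)
    n = np.int64(n_nodes)
    u = packed // n
    v = packed % n
    touched, idx = np.unique(np.concatenate([u, v]), return_inverse=True)
    m = len(touched)
    iu, iv = idx[: len(u)], idx[len(u) :]
    g = sparse.coo_matrix(
        (np.ones(len(iu), dtype=np.int8), (iu, iv)), shape=(m, m)
    )
    ncc_pos, labels = connected_components(g, directed=False)
    sizes = np.bincount(labels)
    lcc = int(sizes.max())
    return lcc, ncc_pos + (n_nodes - m), ncc_pos


def simulate_density(
    params: RGParams, n_sims: int = 20, seed: int | None = None
) -> np.ndarray:
    """Empirical undirected densities of ``n_sims`` seeded RG draws."""
    rng = _rng(params.seed if seed is None else seed)
    n = params.n
    pairs = n * (n - 1) / 2
    return np.array(
        [
            len(sample_rg_undirected_edges(params, rng)) / pairs
            for _ in range(n_sims)
        ]
    )


def simulate_degree_counts(
    params: RGParams, n_sims: int = 100, seed: int | None = None
) -> np.ndarray:
    """Pooled degree histogram (length N+1) over ``n_sims`` RG draws.

    Degrees are counted on the symmetrized simple loop-free graph;
    isolated nodes contribute to the k = 0 bin.
    """
    rng = _rng(params.seed if seed is None else seed)
    n = params.n
    counts = np.zeros(n + 1, dtype=np.int64)
    for _ in range(n_sims):
        packed = sample_rg_undirected_edges(params, rng)
        deg = np.zeros(n, dtype=np.int64)
        if len(packed):
            u = packed // n
            v = packed % n
            np.add.at(deg, u, 1)
            np.add.at(deg, v, 1)
        counts += np.bincount(deg, minlength=n + 1)
    return counts


def empirical_ccdf(counts: np.ndarray) -> np.ndarray:
    """P(K >= k) from a degree histogram."""
    total = counts.sum()
    return counts[::-1].cumsum()[::-1] / total


def simulate_component_stats(
    params: RGParams, n_sims: int = 20, seed: int | None = None
) -> pd.DataFrame:
    """Component statistics (lcc, ncc, ncc_positive) per RG draw."""
    rng = _rng(params.seed if seed is None else seed)
    rows = []
    for _ in range(n_sims):
        packed = sample_rg_undirected_edges(params, rng)
        lcc, ncc, ncc_pos = _component_stats(packed, params.n)
        rows.append({"lcc": lcc, "ncc": ncc, "ncc_positive": ncc_pos})
    return pd.DataFrame(rows)


@dataclass
class PhaseDiagram:
    """Monte-Carlo component statistics over an (x, r) grid.

    ``table`` is long-format with columns x, r, metric, value where metric
    is one of ``lcc``, ``ncc``, ``ncc_positive`` (replicate means).
    """

    b: int
    replicates: int
    seed: int | None
    table: pd.DataFrame

    def pivot(self, metric: str) -> pd.DataFrame:
        sub = self.table[self.table["metric"] == metric]
        return sub.pivot(index="x", columns="r", values="value")


def phase_scan(
    b: int,
    x_values,
    r_values,
    replicates: int = 20,
    seed: int | None = None,
) -> PhaseDiagram:
    """Mean LCC / #CC / #CC(k>0) over an (x, r) grid of RG simulations."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    ss = np.random.SeedSequence(seed)
    rows = []
    for x in x_values:
        for r in r_values:
            rng = np.random.default_rng(ss.spawn(1)[0])
            stats = simulate_component_stats(
                RGParams(b=b, x=int(x), r=int(r)), n_sims=replicates, seed=rng
            )
            for metric in ("lcc", "ncc", "ncc_positive"):
                rows.append(
                    {
                        "x": int(x),
                        "r": int(r),
                        "metric": metric,
                        "value": float(stats[metric].mean()),
                    }
                )
    return PhaseDiagram(
        b=b, replicates=replicates, seed=seed, table=pd.DataFrame(rows)
    )
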