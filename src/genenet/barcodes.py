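"""Barcode identity spaces, wildcard patterns, and wiring-rule expansion.

Nodes carry a binary *barcode* of ``b`` bits, so an identity space holds
``2**b`` distinct nodes.  A *pattern* is a length-``b`` string over
``{0, 1, X}``: fixed characters ("active" bits) provide specificity, while
``X`` characters ("passive" bits) match either state and provide
multiplicity — a pattern with ``x`` passive bits names a set of ``2**x``
barcodes.  A *wiring rule* ``(S)O(D)`` is an ordered pair of patterns and
expands to the directed biclique: every node matching ``S`` links to every
node matching ``D``, contributing ``2**(x_S + x_D)`` directed edges.

Barcodes are represented as integers ``0 .. 2**b - 1``; the leftmost
character of the string form is bit 1 and maps to the most significant
integer bit, so lexicographic order of the fixed-width strings equals
numeric order.  Pattern matching is a single masked comparison:
``(code & mask) == bits``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MAX_BITS",
    "BarcodeSpace",
    "Pattern",
    "WiringRule",
    "RuleSet",
    "GeneticGraph",
    "parse_pattern",
    "parse_rule",
    "pattern_members",
    "pattern_intersection",
    "expand_rule",
    "build_graph",
    "unique_link_count",
]

#: Enumeration guard: 2**24 nodes is the largest space we will materialize.
MAX_BITS = 24

_PATTERN_CHARS = frozenset("01X")


@dataclass(frozen=True)
class BarcodeSpace:
    """The identity space {0,1}^b of all length-``b`` binary barcodes."""

    b: int

    def __post_init__(self) -> None:
        if not (1 <= self.b <= MAX_BITS):
            raise ValueError(f"b must be in 1..{MAX_BITS}, got {self.b}")

    @property
    def node_count(self) -> int:
        return 1 << self.b

    def barcodes(self) -> np.ndarray:
        """All barcodes as integers, ascending."""
        return np.arange(self.node_count, dtype=np.int64)

    def format(self, code: int) -> str:
        """Fixed-width bit-string form of a barcode (leftmost = bit 1)."""
        return format(int(code), f"0{self.b}b")


@dataclass(frozen=True)
class Pattern:
    """A wildcard pattern over {0,1,X} naming a set of barcodes.

    Attributes
    ----------
    b : int
        Barcode length.
    mask : int
        Bitmask with 1s at active (fixed) positions.
    bits : int
        Required values on the active positions (subset of ``mask``).
    """

    b: int
    mask: int
    bits: int

    def __post_init__(self) -> None:
        full = (1 << self.b) - 1
        if self.mask & ~full:
            raise ValueError("mask has bits outside the barcode width")
        if self.bits & ~self.mask:
            raise ValueError("fixed bits must lie inside the active mask")

    @property
    def text(self) -> str:
        chars = []
        for i in range(self.b):
            bit = 1 << (self.b - 1 - i)
            if self.mask & bit:
                chars.append("1" if self.bits & bit else "0")
            else:
                chars.append("X")
        return "".join(chars)

    @property
    def passive_count(self) -> int:
        """Number of X positions (the pattern's multiplicity exponent x)."""
        return self.b - int(self.mask).bit_count()

    @property
    def member_count(self) -> int:
        return 1 << self.passive_count

    def matches(self, code: int) -> bool:
        return (int(code) & self.mask) == self.bits

    def members(self) -> np.ndarray:
        """All matching barcodes, ascending (== lexicographic on strings)."""
        passive = [
            1 << (self.b - 1 - i)
            for i in range(self.b)
            if not self.mask & (1 << (self.b - 1 - i))
        ]
        x = len(passive)
        out = np.full(1 << x, self.bits, dtype=np.int64)
        idx = np.arange(1 << x)
        for j, bit in enumerate(passive):
            out += ((idx >> j) & 1) * bit
        out.sort()
        return out

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.text


def parse_pattern(text: str, b: int) -> Pattern:
    """Parse a {0,1,X} string of length ``b`` into a :class:`Pattern`.

    Raises
    ------
    ValueError
        If the length is wrong or a character outside {0,1,X} occurs; the
        message names the offending position (1-based, leftmost = bit 1).
    """
    text = text.strip()
    if len(text) != b:
        raise ValueError(
            f"pattern {text!r} has length {len(text)}, expected b={b}"
        )
    mask = 0
    bits = 0
    for i, ch in enumerate(text):
        bit = 1 << (b - 1 - i)
        if ch == "1":
            mask |= bit
            bits |= bit
        elif ch == "0":
            mask |= bit
        elif ch != "X":
            raise ValueError(
                f"pattern {text!r}: invalid character {ch!r} at position {i + 1}"
            )
    return Pattern(b=b, mask=mask, bits=bits)


def pattern_members(p: Pattern) -> np.ndarray:
    """Barcodes matching ``p``, ascending."""
    return p.members()


def pattern_intersection(p: Pattern, q: Pattern) -> Pattern | None:
    """Position-wise meet of two patterns, or ``None`` if they contradict.

    A fixed position survives; a fixed-vs-X position keeps the fixed bit;
    X-vs-X stays X.  Two different fixed bits at the same position make the
    member sets disjoint, returned as ``None``.
    """
    if p.b != q.b:
        raise ValueError(f"patterns have different lengths ({p.b} vs {q.b})")
    common = p.mask & q.mask
    if (p.bits ^ q.bits) & common:
        return None
    return Pattern(b=p.b, mask=p.mask | q.mask, bits=p.bits | q.bits)


@dataclass(frozen=True)
class WiringRule:
    """An ordered pattern pair (S)O(D): the directed biclique S x D."""

    source: Pattern
    destination: Pattern

    def __post_init__(self) -> None:
        if self.source.b != self.destination.b:
            raise ValueError("source and destination must share the same b")

    @property
    def b(self) -> int:
        return self.source.b

    @property
    def link_count(self) -> int:
        """2**(x_S + x_D): edges contributed under the full universe."""
        return self.source.member_count * self.destination.member_count

    @property
    def text(self) -> str:
        return f"{self.source.text} -> {self.destination.text}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"({self.source.text})O({self.destination.text})"


def parse_rule(line: str, b: int) -> WiringRule:
    """Parse ``"SRC -> DST"`` into a :class:`WiringRule`."""
    parts = line.split("->")
    if len(parts) != 2:
        raise ValueError(f"rule line {line!r} is not of the form 'SRC -> DST'")
    return WiringRule(parse_pattern(parts[0], b), parse_pattern(parts[1], b))


@dataclass
class RuleSet:
    """An ordered collection of wiring rules over one barcode space.

    ``universe`` optionally restricts the node set to an explicit subset of
    barcodes (ascending, duplicate-free); by default every rule acts on the
    full 2**b space.
    """

    space: BarcodeSpace
    rules: list[WiringRule] = field(default_factory=list)
    universe: np.ndarray | None = None

    def __post_init__(self) -> None:
        for rule in self.rules:
            if rule.b != self.space.b:
                raise ValueError(
                    f"rule {rule} has b={rule.b}, space has b={self.space.b}"
                )
        if self.universe is not None:
            u = np.unique(np.asarray(self.universe, dtype=np.int64))
            if len(u) != len(self.universe):
                raise ValueError("universe contains duplicate barcodes")
            if len(u) and (u[0] < 0 or u[-1] >= self.space.node_count):
                raise ValueError("universe barcode outside the space")
            self.universe = u

    @property
    def b(self) -> int:
        return self.space.b

    def universe_array(self) -> np.ndarray:
        if self.universe is not None:
            return self.universe
        return self.space.barcodes()


def _restrict(members: np.ndarray, universe: np.ndarray | None) -> np.ndarray:
    if universe is None:
        return members
    return members[np.isin(members, universe)]


def expand_rule(
    rule: WiringRule, universe: np.ndarray | None = None
) -> np.ndarray:
    """Expand one rule to its directed edges, as an (m, 2) integer array.

    The edge set is the Cartesian product of the source and destination
    member sets (each intersected with ``universe`` when given).  Self-loops
    appear whenever the two member sets overlap.
    """
    src = _restrict(rule.source.members(), universe)
    dst = _restrict(rule.destination.members(), universe)
    if len(src) == 0 or len(dst) == 0:
        return np.empty((0, 2), dtype=np.int64)
    u = np.repeat(src, len(dst))
    v = np.tile(dst, len(src))
    return np.column_stack([u, v])


def _pack(src: np.ndarray, dst: np.ndarray, b: int) -> np.ndarray:
    return src * (np.int64(1) << b) + dst


def _unpack(packed: np.ndarray, b: int) -> tuple[np.ndarray, np.ndarray]:
    n = np.int64(1) << b
    return packed // n, packed % n


@dataclass
class GeneticGraph:
    """Directed multigraph produced by a rule set, with per-edge multiplicity.

    Stored as parallel arrays of (source, destination, multiplicity) over
    distinct ordered pairs, sorted by packed key.  Multiplicity counts how
    many rules cover the ordered pair.  Derived views: the *simple* graph
    forgets multiplicity; the *undirected* view symmetrizes and (by default)
    drops self-loops — the convention used by all component / density /
    attack analyses.
    """

    space: BarcodeSpace
    universe: np.ndarray
    src: np.ndarray
    dst: np.ndarray
    mult: np.ndarray

    @property
    def node_count(self) -> int:
        return len(self.universe)

    @property
    def unique_link_count(self) -> int:
        """Distinct ordered pairs covered by at least one rule."""
        return len(self.src)

    @property
    def total_multiplicity(self) -> int:
        """Sum over rules of the links each introduces (with repetition)."""
        return int(self.mult.sum())

    def multiplicity(self, u: int, v: int) -> int:
        key = np.int64(u) * (np.int64(1) << self.space.b) + np.int64(v)
        packed = _pack(self.src, self.dst, self.space.b)
        i = np.searchsorted(packed, key)
        if i < len(packed) and packed[i] == key:
            return int(self.mult[i])
        return 0

    def undirected_edges(self, self_loops: bool = False) -> np.ndarray:
        """Distinct unordered non-loop pairs as an (m, 2) array (u < v).

        With ``self_loops=True``, loops are appended as (u, u) rows.
        """
        lo = np.minimum(self.src, self.dst)
        hi = np.maximum(self.src, self.dst)
        keep = lo < hi if not self_loops else np.ones(len(lo), bool)
        packed = np.unique(_pack(lo[keep], hi[keep], self.space.b))
        u, v = _unpack(packed, self.space.b)
        return np.column_stack([u, v])

    def to_networkx(self, directed: bool = True, self_loops: bool = True):
        """Simple networkx view; edges carry a ``multiplicity`` attribute.

        The undirected view symmetrizes (multiplicities of (u,v) and (v,u)
        are summed) and follows the ``self_loops`` flag.
        """
        import networkx as nx

        g = nx.DiGraph() if directed else nx.Graph()
        g.add_nodes_from(int(u) for u in self.universe)
        for u, v, m in zip(self.src, self.dst, self.mult):
            u, v, m = int(u), int(v), int(m)
            if u == v and not self_loops:
                continue
            if not directed and g.has_edge(u, v):
                g[u][v]["multiplicity"] += m
            else:
                g.add_edge(u, v, multiplicity=m)
        return g

    def undirected_density(self) -> float:
        """Unique undirected non-loop edges over C(N, 2)."""
        n = self.node_count
        if n < 2:
            return 0.0
        m = len(self.undirected_edges())
        return m / (n * (n - 1) / 2)


def build_graph(rs: RuleSet) -> GeneticGraph:
    """Union of all expanded rules; multiplicity = covering-rule count."""
    universe = rs.universe  # None means full space
    parts = []
    for rule in rs.rules:
        edges = expand_rule(rule, universe)
        if len(edges):
            parts.append(_pack(edges[:, 0], edges[:, 1], rs.b))
    if parts:
        packed = np.concatenate(parts)
        keys, counts = np.unique(packed, return_counts=True)
        src, dst = _unpack(keys, rs.b)
    else:
        src = dst = np.empty(0, dtype=np.int64)
        counts = np.empty(0, dtype=np.int64)
    return GeneticGraph(
        space=rs.space,
        universe=rs.universe_array(),
        src=src,
        dst=dst,
        mult=counts,
    )


def _universe_member_count(p: Pattern, universe: np.ndarray | None) -> int:
    if universe is None:
        return p.member_count
    return int(np.isin(universe, p.members()).sum())


def unique_link_count(rs: RuleSet, method: str = "enumeration") -> int:
    """Number of distinct ordered pairs covered by at least one rule.

    ``method="enumeration"`` materializes the union of expansions.
    ``method="inclusion_exclusion"`` sums signed member-count products over
    all non-empty rule subsets, intersecting sources and destinations
    independently — an independent combinatorial route that must agree.
    """
    if method == "enumeration":
        return build_graph(rs).unique_link_count
    if method != "inclusion_exclusion":
        raise ValueError(f"unknown method {method!r}")
    total = 0
    n = len(rs.rules)
    for k in range(1, n + 1):
        sign = 1 if k % 2 == 1 else -1
        for subset in combinations(rs.rules, k):
            s: Pattern | None = subset[0].source
            d: Pattern | None = subset[0].destination
            for rule in subset[1:]:
                if s is None or d is None:
                    break
                s = pattern_intersection(s, rule.source)
                d = None if d is None else pattern_intersection(d, rule.destination)
            if s is None or d is None:
                continue
            total += sign * (
                _universe_member_count(s, rs.universe)
                * _universe_member_count(d, rs.universe)
            )
    return total
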