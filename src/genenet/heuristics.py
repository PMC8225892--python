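"""Deterministic rule-set generators for structured topologies.

Each generator returns a :class:`~genenet.barcodes.RuleSet` that encodes a
known network family with a handful of wildcard wiring rules:

* scale-free graphs (three variants with degree exponents near 1, 2, 3),
* fully-connected feed-forward layer chains,
* rooted complete binary trees,
* hierarchical (clique-of-cliques) modular networks,
* homophily graphs where nodes connect iff their barcodes agree on at
  least ``o`` positions (Hamming distance <= b - o).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np

from .barcodes import (
    BarcodeSpace,
    Pattern,
    RuleSet,
    WiringRule,
    parse_pattern,
)

__all__ = [
    "scale_free_ruleset",
    "ffn_ruleset",
    "binary_tree_ruleset",
    "hierarchical_ruleset",
    "HierarchicalRules",
    "homophily_ruleset",
]


def scale_free_ruleset(b: int, variant: int = 1) -> RuleSet:
    """Scale-free encoder: source sets grow while destination sets shrink.

    Variant 1 emits ``b + 1`` rules; rule ``i`` (i = 0..b) has source
    ``0^(b-i) X^i`` and destination ``X^(b-i) 0^i``, so one node links to
    everything, two nodes to half of everything, and so on down to
    everything linking to one node.  The resulting in/out degree law is the
    exact finite-size form of p(k) = 0.5 k^-1.

    Variant 2 (b even) keeps the variant-1 destinations but widens the
    source by two Xs per step (``b/2 + 1`` rules, in-degree exponent ~2);
    variant 3 (b divisible by 3) widens by three Xs per step
    (``b/3 + 1`` rules, exponent ~3).
    """
    if variant not in (1, 2, 3):
        raise ValueError("variant must be 1, 2, or 3")
    if variant == 2 and b % 2:
        raise ValueError("variant 2 requires b even")
    if variant == 3 and b % 3:
        raise ValueError("variant 3 requires b divisible by 3")
    step = variant
    rules = []
    for t in range(b // step + 1):
        src = parse_pattern("0" * (b - step * t) + "X" * (step * t), b)
        dst = parse_pattern("X" * (b - t) + "0" * t, b)
        rules.append(WiringRule(src, dst))
    return RuleSet(BarcodeSpace(b), rules)


def ffn_ruleset(layer_patterns: list[Pattern] | list[str], b: int | None = None) -> RuleSet:
    """Feed-forward encoder: chain consecutive layers with one rule each.

    ``layer_patterns`` are the per-layer identity patterns (pairwise
    disjoint member sets); L layers produce L - 1 rules, rule i being
    (layer_i)O(layer_{i+1}).  Strings are accepted when ``b`` is given.
    """
    layers = [
        parse_pattern(p, b) if isinstance(p, str) else p for p in layer_patterns
    ]
    if len(layers) < 2:
        raise ValueError("need at least 2 layers")
    bb = layers[0].b
    for i, j in combinations(range(len(layers)), 2):
        common = np.intersect1d(layers[i].members(), layers[j].members())
        if len(common):
            space = BarcodeSpace(bb)
            raise ValueError(
                f"layers {layers[i].text} and {layers[j].text} share barcode "
                f"{space.format(int(common[0]))}"
            )
    rules = [
        WiringRule(layers[i], layers[i + 1]) for i in range(len(layers) - 1)
    ]
    return RuleSet(BarcodeSpace(bb), rules)


def binary_tree_ruleset(b: int) -> RuleSet:
    """Rooted complete binary tree of depth ``b`` on the non-zero barcodes.

    The position of the leftmost '1' sets a node's depth: the root is
    ``0^(b-1) 1``, and the leaves are the barcodes starting with '1'.  A
    FIFO buffer starts with the root; each dequeued barcode emits the rule
    (barcode)O(drop-first-bit + append X), whose two destination barcodes
    are enqueued unless they start with '1' (terminal depth).  This yields
    ``2^(b-1) - 1`` rules over a universe of ``2^b - 1`` nodes (the
    all-zeros barcode encodes no tree position and is excluded).
    """
    if b < 2:
        raise ValueError("binary tree needs b >= 2")
    space = BarcodeSpace(b)
    root = "0" * (b - 1) + "1"
    buffer: deque[str] = deque([root])
    rules = []
    while buffer:
        code = buffer.popleft()
        dest = code[1:] + "X"
        rules.append(WiringRule(parse_pattern(code, b), parse_pattern(dest, b)))
        for child in (code[1:] + "0", code[1:] + "1"):
            if child[0] != "1":
                buffer.append(child)
    universe = np.arange(1, space.node_count, dtype=np.int64)
    return RuleSet(space, rules, universe=universe)


#: Valid 3-bit groups of the hierarchical construction: the group's first
#: bit separates center (0) from periphery (1); a center must have 00 in
#: the remaining bits, a peripheral node may have any.
_HIER_GROUPS = ("000", "100", "101", "110", "111")


@dataclass
class HierarchicalRules:
    """Hierarchical rule set plus its level-structured bookkeeping.

    ``clique_groups`` holds one (periphery-periphery, periphery-center)
    rule pair per bottom-level clique; ``hierarchy_levels[l]`` holds the
    rules that wire the level-l hierarchy (l = 1 .. d-1), each connecting
    the l+1-fold peripheral nodes of a block to its global center.
    """

    d: int
    ruleset: RuleSet
    clique_groups: list[tuple[WiringRule, WiringRule]]
    hierarchy_levels: dict[int, list[WiringRule]] = field(default_factory=dict)


def _valid_prefixes(groups: int) -> list[str]:
    return ["".join(p) for p in product(_HIER_GROUPS, repeat=groups)]


def hierarchical_ruleset(d: int, mode: str = "collapsed") -> HierarchicalRules:
    """Depth-``d`` hierarchical (clique-of-cliques) network at b = 3d.

    The universe is the 5**d barcodes whose ``d`` consecutive 3-bit groups
    each name a valid center/periphery position.  The depth-1 module is a
    5-clique: center 000 plus periphery 1XX, wired by (1XX)O(1XX) and
    (1XX)O(0XX).  Deeper networks replicate this clique wiring under every
    valid prefix (5**(d-1) clique groups) and add, per level l = 1..d-1,
    5**(d-1-l) rules (prefix + (1XX)^(l+1)) O (prefix + (000)^(l+1))
    attaching the l+1-fold peripheral nodes to their block's center.

    ``mode`` may be "collapsed" or "strict"; both name the same
    construction (the distinction exists so topology tests are explicit).
    """
    if d < 1:
        raise ValueError("depth d must be >= 1")
    if mode not in ("collapsed", "strict"):
        raise ValueError("mode must be 'collapsed' or 'strict'")
    b = 3 * d
    space = BarcodeSpace(b)
    clique_groups = []
    rules: list[WiringRule] = []
    for prefix in _valid_prefixes(d - 1):
        pp = WiringRule(
            parse_pattern(prefix + "1XX", b), parse_pattern(prefix + "1XX", b)
        )
        pc = WiringRule(
            parse_pattern(prefix + "1XX", b), parse_pattern(prefix + "0XX", b)
        )
        clique_groups.append((pp, pc))
        rules.extend([pp, pc])
    hierarchy_levels: dict[int, list[WiringRule]] = {}
    for level in range(1, d):
        level_rules = []
        for prefix in _valid_prefixes(d - 1 - level):
            src = parse_pattern(prefix + "1XX" * (level + 1), b)
            dst = parse_pattern(prefix + "000" * (level + 1), b)
            level_rules.append(WiringRule(src, dst))
        hierarchy_levels[level] = level_rules
        rules.extend(level_rules)
    universe = np.sort(
        np.array(
            [int("".join(gs), 2) for gs in product(_HIER_GROUPS, repeat=d)],
            dtype=np.int64,
        )
    )
    rs = RuleSet(space, rules, universe=universe)
    return HierarchicalRules(
        d=d, ruleset=rs, clique_groups=clique_groups,
        hierarchy_levels=hierarchy_levels,
    )


def homophily_ruleset(b: int, o: int) -> RuleSet:
    """Connect all node pairs agreeing on at least ``o`` bit positions.

    Emits the self-paired rule (p)O(p) for every pattern ``p`` with exactly
    ``o`` fixed positions — C(b, o) * 2**o rules.  In the simple undirected
    view, edge(u, v) holds iff Hamming(u, v) <= b - o.  The extremes:
    o = 0 is the complete graph (plus loops), o = b is self-loops only.
    """
    if not (0 <= o <= b):
        raise ValueError(f"overlap o must be in 0..{b}, got {o}")
    space = BarcodeSpace(b)
    rules = []
    for fixed_positions in combinations(range(b), o):
        fixed = set(fixed_positions)
        for values in product("01", repeat=o):
            it = iter(values)
            text = "".join(
                next(it) if i in fixed else "X" for i in range(b)
            )
            p = parse_pattern(text, b)
            rules.append(WiringRule(p, p))
    return RuleSet(space, rules)
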