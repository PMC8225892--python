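"""Plain-text formats: rule files and edge lists.

Rule file format::

    # comment
    b=5
    101XX -> 110XX

The header line ``b=<int>`` fixes the barcode width; each following
non-comment line is one rule ``SOURCE -> DEST``.  Reading and writing
round-trip bit-exactly.

Edge lists are TSV with columns ``source``, ``target``, ``multiplicity``
(barcodes as fixed-width bit strings, leftmost = bit 1); GraphML export of
the simple directed graph carries multiplicity as an edge attribute.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np

from .barcodes import (
    BarcodeSpace,
    GeneticGraph,
    RuleSet,
    parse_rule,
)

__all__ = ["read_rules", "write_rules", "write_edges", "read_edges"]


def read_rules(path) -> RuleSet:
    """Parse a rule file; errors carry the offending line number."""
    lines = Path(path).read_text().splitlines()
    b = None
    rules = []
    space = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if b is None:
            if not line.startswith("b="):
                raise ValueError(
                    f"{path}:{lineno}: expected header 'b=<int>', got {line!r}"
                )
            b = int(line[2:].strip())
            space = BarcodeSpace(b)
            continue
        try:
            rules.append(parse_rule(line, b))
        except ValueError as err:
            raise ValueError(f"{path}:{lineno}: {err}") from err
    if b is None:
        raise ValueError(f"{path}: missing 'b=<int>' header")
    return RuleSet(space, rules)


def write_rules(rs: RuleSet, path) -> None:
    lines = [f"b={rs.b}"]
    lines += [rule.text for rule in rs.rules]
    Path(path).write_text("\n".join(lines) + "\n")


def write_edges(g: GeneticGraph, path, format: str = "tsv") -> None:
    """Write the directed edge list with multiplicities (TSV or GraphML)."""
    if format == "tsv":
        fmt = g.space.format
        lines = ["source\ttarget\tmultiplicity"]
        lines += [
            f"{fmt(u)}\t{fmt(v)}\t{m}"
            for u, v, m in zip(g.src, g.dst, g.mult)
        ]
        Path(path).write_text("\n".join(lines) + "\n")
    elif format == "graphml":
        nxg = nx.DiGraph()
        fmt = g.space.format
        nxg.add_nodes_from(fmt(u) for u in g.universe)
        for u, v, m in zip(g.src, g.dst, g.mult):
            nxg.add_edge(fmt(u), fmt(v), multiplicity=int(m))
        nx.write_graphml(nxg, path)
    else:
        raise ValueError(f"unknown edge format {format!r}")


def read_edges(path, b: int) -> GeneticGraph:
    """Read a TSV edge list back into a :class:`GeneticGraph`."""
    space = BarcodeSpace(b)
    src, dst, mult = [], [], []
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t")[:2] != ["source", "target"]:
        raise ValueError(f"{path}: missing edge-list header")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 columns")
        src.append(int(parts[0], 2))
        dst.append(int(parts[1], 2))
        mult.append(int(parts[2]))
    order = np.argsort(
        np.array(src, dtype=np.int64) * (np.int64(1) << b)
        + np.array(dst, dtype=np.int64)
    )
    return GeneticGraph(
        space=space,
        universe=space.barcodes(),
        src=np.array(src, dtype=np.int64)[order],
        dst=np.array(dst, dtype=np.int64)[order],
        mult=np.array(mult, dtype=np.int64)[order],
    )
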