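"""Wiring rules as threshold linear algebra: B = H(L O L^T).

A pattern (label) becomes a weight row ``W`` over the b bits — +1 where a
bit must be on, -1 where it must be off, 0 where it is passive — plus an
offset ``d`` chosen so that a barcode's score ``W.x + d`` reaches ``b + 1``
exactly when the barcode matches the label (required-on count + d = b + 1;
with binary inputs and weights in {-1, 0, +1} no non-member can reach that
score).  Stacking the indicator f(z) = [z == b+1] over nodes and labels
gives the membership matrix L; a rule set becomes a binary label
interaction matrix O; and the adjacency of the encoded graph is the
entrywise Heaviside (strict: H(0) = 0) of ``L O L^T`` — provably the same
function as direct biclique expansion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .barcodes import Pattern, RuleSet

__all__ = [
    "LabelModel",
    "pattern_to_label_row",
    "label_matrix",
    "ruleset_to_label_model",
    "operator_adjacency",
]


@dataclass
class LabelModel:
    """Labels as threshold rows (W, d) plus their interaction matrix O."""

    b: int
    patterns: list[Pattern]
    W: np.ndarray  # (L, b), entries in {-1, 0, +1}
    d: np.ndarray  # (L,)
    O: np.ndarray  # (L, L), binary

    def __post_init__(self) -> None:
        n_labels = len(self.patterns)
        if self.W.shape != (n_labels, self.b):
            raise ValueError("W shape must be (labels, b)")
        if self.d.shape != (n_labels,):
            raise ValueError("d shape must be (labels,)")
        if self.O.shape != (n_labels, n_labels):
            raise ValueError("O must be labels x labels")


def pattern_to_label_row(p: Pattern) -> tuple[np.ndarray, int]:
    """Weight row and offset of one label.

    W[a] is +1/-1/0 for a required-on / required-off / passive bit a
    (a = 0 is the leftmost bit); d = b + 1 - (number of +1 entries).
    """
    w = np.zeros(p.b, dtype=np.int64)
    for i in range(p.b):
        bit = 1 << (p.b - 1 - i)
        if p.mask & bit:
            w[i] = 1 if p.bits & bit else -1
    d = p.b + 1 - int((w == 1).sum())
    return w, d


def _expression_matrix(b: int, universe: np.ndarray) -> np.ndarray:
    """Bit matrix X: row per node, column per bit (leftmost first)."""
    shifts = b - 1 - np.arange(b)
    return (universe[:, None] >> shifts) & 1


def label_matrix(
    patterns: list[Pattern], universe: np.ndarray | None = None
) -> np.ndarray:
    """Binary membership matrix L (nodes x labels) via the threshold map.

    Entry (u, i) = f(W_i . x_u + d_i) with f(z) = [z == b + 1]; identical
    to direct pattern matching by construction.
    """
    if not patterns:
        n = 0 if universe is None else len(universe)
        return np.zeros((n, 0), dtype=np.int8)
    b = patterns[0].b
    if universe is None:
        universe = np.arange(1 << b, dtype=np.int64)
    rows = [pattern_to_label_row(p) for p in patterns]
    W = np.stack([w for w, _ in rows])
    d = np.array([dd for _, dd in rows])
    scores = _expression_matrix(b, np.asarray(universe, dtype=np.int64)) @ W.T + d
    return (scores == b + 1).astype(np.int8)


def ruleset_to_label_model(rs: RuleSet) -> LabelModel:
    """Deduplicated source/destination patterns + their interaction matrix.

    O[i, j] = 1 for every rule whose source is label i and destination is
    label j (a rule with identical sides sets a diagonal entry).
    """
    patterns: list[Pattern] = []
    index: dict[tuple[int, int], int] = {}
    for rule in rs.rules:
        for p in (rule.source, rule.destination):
            key = (p.mask, p.bits)
            if key not in index:
                index[key] = len(patterns)
                patterns.append(p)
    n_labels = len(patterns)
    O = np.zeros((n_labels, n_labels), dtype=np.int8)
    for rule in rs.rules:
        i = index[(rule.source.mask, rule.source.bits)]
        j = index[(rule.destination.mask, rule.destination.bits)]
        O[i, j] = 1
    rows = [pattern_to_label_row(p) for p in patterns]
    W = (
        np.stack([w for w, _ in rows])
        if rows
        else np.zeros((0, rs.b), dtype=np.int64)
    )
    d = np.array([dd for _, dd in rows], dtype=np.int64)
    return LabelModel(b=rs.b, patterns=patterns, W=W, d=d, O=O)


def operator_adjacency(
    model: LabelModel, universe: np.ndarray | None = None
) -> np.ndarray:
    """Adjacency B = H(L O L^T), entrywise strict Heaviside (H(0) = 0).

    B[u, v] = 1 iff some label pair (i, j) with O[i, j] = 1 has u in label
    i and v in label j — the directed simple graph of the rule set.
    """
    L = label_matrix(model.patterns, universe)
    return (L @ model.O @ L.T > 0).astype(np.int8)
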