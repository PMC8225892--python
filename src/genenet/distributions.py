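"""Discrete degree distributions shared by the analytic modules."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DegreePMF"]


@dataclass
class DegreePMF:
    """A probability mass function over node degree k = 0 .. len(p) - 1.

    Probabilities must be non-negative and sum to 1 (within 1e-9); the
    constructor enforces both.
    """

    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 1:
            raise ValueError("pmf must be one-dimensional")
        if np.any(self.p < -1e-12):
            raise ValueError("pmf has negative mass")
        total = float(self.p.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pmf sums to {total!r}, not 1")

    @property
    def k(self) -> np.ndarray:
        return np.arange(len(self.p))

    def mean(self) -> float:
        return float(np.dot(self.k, self.p))

    def var(self) -> float:
        m = self.mean()
        return float(np.dot((self.k - m) ** 2, self.p))

    def ccdf(self) -> np.ndarray:
        """Complementary CDF: P(K >= k) for each k in the support."""
        return self.p[::-1].cumsum()[::-1]
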