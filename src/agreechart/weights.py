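"""Agreement weight schemes for partial credit on ordinal scales.

A weight ``w_ij in [0, 1]`` says how much credit a (row i, column j) rating
pair earns: 1 on the diagonal, decreasing with category distance
``d = |i - j|``.  The same distance weights reappear as band weights
``w_b`` in the weighted B-statistic, where band ``b`` collects the cells
exactly ``b`` categories off the diagonal.

Schemes
-------
unweighted
    ``w_ij = 1`` iff ``i == j`` — no partial credit.
linear
    ``w_ij = 1 - d/(k-1)`` (Cicchetti-Allison).
quadratic
    ``w_ij = 1 - d^2/(k-1)^2`` (Fleiss-Cohen), the usual choice when
    disagreements far from the diagonal should be penalised more than
    proportionally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["WeightScheme", "SCHEME_NAMES"]

SCHEME_NAMES = ("unweighted", "linear", "quadratic")


@dataclass(frozen=True)
class WeightScheme:
    """A named k x k agreement-weight matrix.

    Build with :meth:`make`; the constructor accepts a precomputed matrix
    for custom schemes (it must satisfy the invariants: symmetric,
    ``w_ii = 1``, dependent only on ``|i - j|``, values in [0, 1]).
    """

    name: str
    k: int
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (self.k, self.k):
            raise ValueError(f"weight matrix shape {m.shape} != ({self.k}, {self.k})")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("diagonal weights must equal 1")
        if not np.allclose(m, m.T):
            raise ValueError("weight matrix must be symmetric")
        if (m < 0).any() or (m > 1).any():
            raise ValueError("weights must lie in [0, 1]")
        for b in range(self.k):
            band = np.diag(m, b)
            if band.size and not np.allclose(band, band[0]):
                raise ValueError("weights must depend only on |i - j|")
        m.setflags(write=False)
        object.__setattr__(self, "matrix", m)

    @classmethod
    def make(cls, name: str, k: int) -> "WeightScheme":
        """Create a standard scheme by name for a k-category scale."""
        if k < 2:
            raise ValueError("need at least 2 categories")
        d = np.abs(np.subtract.outer(np.arange(k), np.arange(k))).astype(float)
        if name == "unweighted":
            m = (d == 0).astype(float)
        elif name == "linear":
            m = 1.0 - d / (k - 1)
        elif name == "quadratic":
            m = 1.0 - d**2 / (k - 1) ** 2
        else:
            raise ValueError(
                f"unknown weight scheme {name!r}; choose from {SCHEME_NAMES}"
            )
        return cls(name, k, m)

    def band_weight(self, b: int) -> float:
        """Weight ``w_b`` at band distance ``b`` (``w_0 = 1``)."""
        if not 0 <= b <= self.k - 1:
            raise IndexError(f"band distance {b} out of range for k={self.k}")
        return float(self.matrix[0, b])
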