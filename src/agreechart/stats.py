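"""Chance-corrected agreement statistics for square contingency tables.

Let ``n_ij`` be the cell counts of a k x k table with row marginals
``n_i.``, column marginals ``n_.j`` and total ``n``.  The statistics here
are the standard pair used for paired ordinal ratings:

Cohen's kappa
    ``kappa = (Po - Pe) / (1 - Pe)`` with observed agreement
    ``Po = sum_i n_ii / n`` and chance-expected agreement
    ``Pe = sum_i n_i. n_.i / n^2``.  The weighted form replaces the
    diagonal sums with weighted sums over all cells,
    ``Po_w = sum_ij w_ij n_ij / n`` and ``Pe_w = sum_ij w_ij n_i. n_.j / n^2``.

Bangdiwala's B-statistic
    ``B = sum_i n_ii^2 / sum_i n_i. n_.i`` — in the agreement chart, the
    area of the dark diagonal squares over the area of the marginal
    rectangles.  The weighted form credits partial agreement through the
    incremental band areas ``A_bi`` of the nested partial-agreement
    rectangles (see :func:`partial_band_areas`):

    ``B_w = sum_i (n_ii^2 + sum_{b>=1} w_b A_bi) / sum_i n_i. n_.i``.

Both statistics equal 1 exactly when every off-diagonal cell is zero, and
both are symmetric in the two raters.

All computational entry points accept either a validated
:class:`~agreechart.tables.ContingencyTable` or a raw non-negative matrix;
the latter lets population-level quantities be evaluated directly on a
joint probability matrix (every statistic is invariant to rescaling all
cells by a positive constant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tables import ContingencyTable
from .weights import WeightScheme

__all__ = [
    "DegenerateTableError",
    "observed_expected",
    "cohen_kappa",
    "b_statistic",
    "partial_band_areas",
    "weighted_b",
    "interpret",
    "AgreementSummary",
    "summarize",
    "DEFAULT_BANDS",
]


class DegenerateTableError(ValueError):
    """Raised when chance agreement Pe = 1 makes kappa undefined.

    Happens only when both raters put all mass in one and the same
    category, so that 1 - Pe = 0.
    """


def _as_matrix(table) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        return table.counts.astype(float)
    m = np.asarray(table, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {m.shape}")
    if (m < 0).any():
        raise ValueError("cells must be non-negative")
    if m.sum() <= 0:
        raise ValueError("matrix total must be positive")
    return m


def _resolve_scheme(scheme, k: int) -> WeightScheme:
    if scheme is None:
        return WeightScheme.make("unweighted", k)
    if isinstance(scheme, str):
        return WeightScheme.make(scheme, k)
    if scheme.k != k:
        raise ValueError(f"weight scheme has k={scheme.k}, table has k={k}")
    return scheme


def observed_expected(table) -> tuple[float, float]:
    """Observed and chance-expected agreement proportions ``(Po, Pe)``."""
    m = _as_matrix(table)
    n = m.sum()
    po = np.trace(m) / n
    pe = float(m.sum(axis=1) @ m.sum(axis=0)) / n**2
    return float(po), float(pe)


def cohen_kappa(table, scheme=None) -> float:
    """Cohen's kappa, optionally weighted.

    Parameters
    ----------
    table : ContingencyTable or array-like
    scheme : WeightScheme, scheme name, or None
        ``None`` / ``"unweighted"`` gives classical kappa; ``"linear"`` or
        ``"quadratic"`` give the weighted statistic.

    Raises
    ------
    DegenerateTableError
        If the (weighted) chance agreement equals 1.
    """
    m = _as_matrix(table)
    n = float(m.sum())
    w = _resolve_scheme(scheme, m.shape[0]).matrix
    po = float((w * m).sum()) / n
    pe = float((w * np.outer(m.sum(axis=1), m.sum(axis=0))).sum()) / n**2
    if pe >= 1.0 - 1e-15:
        raise DegenerateTableError(
            "chance agreement Pe = 1 (all mass in a single category for both "
            "raters); kappa is undefined"
        )
    return float((po - pe) / (1.0 - pe))


def b_statistic(table) -> float:
    """Bangdiwala's B: dark-square area over marginal-rectangle area."""
    m = _as_matrix(table)
    denom = float(m.sum(axis=1) @ m.sum(axis=0))
    if denom <= 0:
        raise DegenerateTableError("all marginal products are zero")
    return float((np.diag(m) ** 2).sum()) / denom


def _band_dims(m: np.ndarray, i: int, b: int) -> tuple[float, float]:
    """Width (column cells) and height (row cells) of the order-b partial
    rectangle inside marginal rectangle ``i``: cells within ``b`` categories
    of the diagonal."""
    k = m.shape[0]
    lo, hi = max(0, i - b), min(k - 1, i + b)
    width = float(m[lo : hi + 1, i].sum())
    height = float(m[i, lo : hi + 1].sum())
    return width, height


def partial_band_areas(table, i: int, b: int) -> float:
    """Incremental partial-agreement band area ``A_bi``.

    ``A_0i = n_ii^2`` is the dark square; for ``b >= 1``,
    ``A_bi = width_b * height_b - width_{b-1} * height_{b-1}`` where the
    order-b rectangle spans the cells at most ``b`` categories off the
    diagonal in row and column ``i``.  Summing over ``b = 0 .. k-1``
    telescopes to the full marginal rectangle area ``n_i. * n_.i``.
    """
    m = _as_matrix(table)
    k = m.shape[0]
    if not 0 <= i <= k - 1:
        raise IndexError(f"category index {i} out of range for k={k}")
    if not 0 <= b <= k - 1:
        raise IndexError(f"band distance {b} out of range for k={k}")
    if b == 0:
        return float(m[i, i] ** 2)
    w1, h1 = _band_dims(m, i, b)
    w0, h0 = _band_dims(m, i, b - 1)
    return w1 * h1 - w0 * h0


def weighted_b(table, scheme="quadratic") -> float:
    """Weighted B-statistic crediting partial agreement by band weights."""
    m = _as_matrix(table)
    k = m.shape[0]
    sch = _resolve_scheme(scheme, k)
    denom = float(m.sum(axis=1) @ m.sum(axis=0))
    if denom <= 0:
        raise DegenerateTableError("all marginal products are zero")
    num = 0.0
    for i in range(k):
        num += float(m[i, i] ** 2)
        prev = float(m[i, i] ** 2)
        for b in range(1, k):
            w, h = _band_dims(m, i, b)
            num += sch.band_weight(b) * (w * h - prev)
            prev = w * h
    return num / denom


# Default qualitative bands (half-open on the left, closed on the right).
# These cutoffs follow the common agreement-strength convention; they are a
# configurable stand-in, not a universal standard.
DEFAULT_BANDS: tuple[tuple[float, str], ...] = (
    (0.0, "poor"),
    (0.2, "slight"),
    (0.4, "fair"),
    (0.6, "moderate"),
    (0.8, "substantial"),
    (1.0, "almost perfect"),
)


def interpret(value: float, bands=DEFAULT_BANDS) -> str:
    """Qualitative label for an agreement statistic.

    ``bands`` is a sequence of ``(upper_bound, label)`` pairs with
    increasing bounds; a value falls in the first band whose upper bound it
    does not exceed, and any value <= the first bound gets the first label.
    """
    if not -1.0 <= value <= 1.0:
        raise ValueError(f"agreement statistic {value} outside [-1, 1]")
    for bound, label in bands:
        if value <= bound:
            return label
    return bands[-1][1]


@dataclass(frozen=True)
class AgreementSummary:
    """Bundle of agreement statistics for one table and weight scheme.

    ``kappa`` and ``kappa_weighted`` are ``None`` when the table is
    degenerate (Pe = 1), in which case ``degenerate`` is set; B remains
    defined (it equals 1 for the point-mass table).
    """

    po: float
    pe: float
    kappa: float | None
    kappa_weighted: float | None
    b: float
    b_weighted: float
    scheme: str
    labels: dict = field(default_factory=dict)
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "po": self.po,
            "pe": self.pe,
            "kappa": self.kappa,
            "kappa_weighted": self.kappa_weighted,
            "b": self.b,
            "b_weighted": self.b_weighted,
            "scheme": self.scheme,
            "labels": dict(self.labels),
            "degenerate": self.degenerate,
        }

    def to_text(self) -> str:
        def fmt(v):
            return "undefined (Pe = 1)" if v is None else f"{v:.4f}"

        rows = [
            ("observed agreement Po", fmt(self.po), None),
            ("chance agreement Pe", fmt(self.pe), None),
            ("kappa", fmt(self.kappa), self.labels.get("kappa")),
            (f"weighted kappa ({self.scheme})", fmt(self.kappa_weighted),
             self.labels.get("kappa_weighted")),
            ("B-statistic", fmt(self.b), self.labels.get("b")),
            (f"weighted B ({self.scheme})", fmt(self.b_weighted),
             self.labels.get("b_weighted")),
        ]
        width = max(len(name) for name, _, _ in rows) + 2
        return "\n".join(
            f"{name:<{width}}{value}" + (f"  [{label}]" if label else "")
            for name, value, label in rows
        )


def summarize(table, scheme="quadratic", bands=DEFAULT_BANDS) -> AgreementSummary:
    """Compute the full set of agreement statistics with qualitative labels."""
    sch = _resolve_scheme(scheme, _as_matrix(table).shape[0])
    po, pe = observed_expected(table)
    b = b_statistic(table)
    bw = weighted_b(table, sch)
    degenerate = False
    try:
        kappa = cohen_kappa(table)
        kappa_w = cohen_kappa(table, sch)
    except DegenerateTableError:
        kappa = kappa_w = None
        degenerate = True
    labels = {"b": interpret(b, bands), "b_weighted": interpret(bw, bands)}
    if kappa is not None:
        labels["kappa"] = interpret(kappa, bands)
        labels["kappa_weighted"] = interpret(kappa_w, bands)
    return AgreementSummary(
        po=po, pe=pe, kappa=kappa, kappa_weighted=kappa_w,
        b=b, b_weighted=bw, scheme=sch.name, labels=labels,
        degenerate=degenerate,
    )
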