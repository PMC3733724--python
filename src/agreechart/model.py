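"""Model/Results interface over the agreement statistics and chart.

:class:`AgreementModel` wraps a validated contingency table; ``fit()``
computes every statistic for a chosen weight scheme and returns an
:class:`AgreementResults` carrying the estimates, qualitative labels, the
chart geometry and plotting/rendering helpers::

    >>> from agreechart import AgreementModel, load_fixture
    >>> res = AgreementModel(load_fixture("lrc_elderly")).fit()
    >>> round(res.kappa, 2), round(res.b, 2)
    (0.57, 0.74)
    >>> print(res.summary())          # doctest: +SKIP

No standard errors or confidence intervals are produced: the package
estimates and visualises agreement, it does not test hypotheses about it.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import chart as _chart
from . import stats as _stats
from .tables import ContingencyTable, from_ratings, read_csv, validate
from .weights import WeightScheme

__all__ = ["AgreementModel", "AgreementResults"]


class AgreementModel:
    """Agreement between two raters on a square ordinal contingency table.

    Parameters
    ----------
    table : ContingencyTable or array-like
        Either a validated table or a raw square count matrix (validated
        on the spot; ``labels`` then names the categories).
    labels : sequence of str, optional
        Category names when ``table`` is a raw matrix.
    """

    def __init__(self, table, labels: Sequence[str] | None = None,
                 row_rater: str = "rater A", col_rater: str = "rater B"):
        if isinstance(table, ContingencyTable):
            self.table = table
        else:
            self.table = validate(table, labels, row_rater, col_rater)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "AgreementModel":
        """Build from a labelled square DataFrame of counts."""
        return cls(df.to_numpy(), labels=[str(c) for c in df.columns], **kwargs)

    @classmethod
    def from_ratings(cls, ratings_a, ratings_b,
                     labels: Sequence[str] | None = None, **kwargs
                     ) -> "AgreementModel":
        """Build by cross-tabulating two aligned per-subject rating vectors."""
        return cls(from_ratings(ratings_a, ratings_b, labels, **kwargs))

    @classmethod
    def from_csv(cls, path, **kwargs) -> "AgreementModel":
        """Build from a CSV table (see :func:`agreechart.tables.read_csv`)."""
        return cls(read_csv(path, **kwargs))

    def fit(self, weights: str | WeightScheme = "quadratic",
            bands=_stats.DEFAULT_BANDS) -> "AgreementResults":
        """Compute all agreement statistics under the given weight scheme."""
        summary = _stats.summarize(self.table, weights, bands)
        return AgreementResults(self, summary)

    def layout(self) -> _chart.ChartLayout:
        """Agreement-chart geometry for this table."""
        return _chart.layout(self.table)


class AgreementResults:
    """Fitted agreement statistics plus chart diagnostics.

    Attributes mirror :class:`agreechart.stats.AgreementSummary`: ``po``,
    ``pe``, ``kappa``, ``kappa_weighted``, ``b``, ``b_weighted``,
    ``scheme``, ``labels``, ``degenerate``.
    """

    def __init__(self, model: AgreementModel, summary: _stats.AgreementSummary):
        self.model = model
        self.table = model.table
        self._summary = summary
        for name in ("po", "pe", "kappa", "kappa_weighted", "b", "b_weighted",
                     "scheme", "labels", "degenerate"):
            setattr(self, name, getattr(summary, name))

    # -- reporting ----------------------------------------------------------

    def to_dict(self) -> dict:
        return self._summary.to_dict()

    def summary(self) -> str:
        """Human-readable report of the table and all statistics."""
        t = self.table
        header = (
            f"Agreement analysis: {t.row_rater} (rows) vs {t.col_rater} (cols)\n"
            f"categories: {', '.join(t.labels)}   items: n = {t.n}\n"
        )
        bias = self.bias()
        biasline = (
            f"\nbias path runs {bias.direction} the no-bias diagonal "
            f"(normalised signed area {bias.area:+.4f})"
        )
        return header + "-" * 58 + "\n" + self._summary.to_text() + biasline

    # -- chart --------------------------------------------------------------

    def layout(self) -> _chart.ChartLayout:
        return self.model.layout()

    def bias(self) -> _chart.BiasDeviation:
        """Signed deviation of the path of rectangles from the diagonal."""
        return _chart.bias_deviation(self.layout())

    def plot(self, ax=None, style: _chart.RenderStyle | None = None):
        """Draw the agreement chart on a matplotlib axes."""
        return _chart.plot(self.layout(), ax=ax, style=style)

    def render(self, path, style: _chart.RenderStyle | None = None):
        """Write the agreement chart to an SVG or PNG file."""
        return _chart.render(self.layout(), style, path)

    def __repr__(self) -> str:
        k = "None" if self.kappa is None else f"{self.kappa:.3f}"
        return (f"<AgreementResults kappa={k} b={self.b:.3f} "
                f"scheme={self.scheme}>")
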