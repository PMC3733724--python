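"""Agreement-chart geometry and rendering.

The chart represents a k x k table inside an n x n square (n = total
count), with the column rater on the x axis and the row rater on the y
axis, origin at the bottom-left and categories increasing up and to the
right:

* one marginal rectangle per category, of width ``n_.i`` (column marginal)
  and height ``n_i.`` (row marginal), stacked corner-to-corner from (0, 0)
  to (n, n);
* inside rectangle ``i``, a dark square of side ``n_ii`` offset by the
  preceding off-diagonal cells — ``sum_{j<i} n_ji`` along x and
  ``sum_{j<i} n_ij`` along y — so its position encodes where the
  disagreements fall;
* nested partial-agreement rectangles for band distances ``b = 1..k-1``,
  drawn with decreasing shading, each spanning the cells at most ``b``
  categories off the diagonal;
* the 45-degree no-bias diagonal and the "path of rectangles" through the
  rectangle corners.  When the two raters use the categories at the same
  rates (marginal homogeneity) the path lies on the diagonal; a rater
  favouring lower categories pulls it off to their side.

The geometry is exact (count units, no rounding), so chart areas and the
B-statistics are two views of the same quantities: the dark-square area
over the rectangle area equals B, and the shade-weighted covered area
equals weighted B.

Perfect agreement makes every rectangle a square identical to its dark
square and both statistics equal to 1.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .tables import ContingencyTable
from .weights import WeightScheme

__all__ = [
    "Rect",
    "BandRect",
    "ChartLayout",
    "RenderStyle",
    "layout",
    "BiasDeviation",
    "bias_deviation",
    "render",
]


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle with lower-left corner (x, y), in count units."""

    x: float
    y: float
    width: float
    height: float

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def upper_right(self) -> tuple[float, float]:
        return (self.x + self.width, self.y + self.height)

    def contains(self, other: "Rect", tol: float = 1e-9) -> bool:
        return (
            self.x - tol <= other.x
            and self.y - tol <= other.y
            and other.x + other.width <= self.x + self.width + tol
            and other.y + other.height <= self.y + self.height + tol
        )


@dataclass(frozen=True)
class BandRect:
    """Order-b partial-agreement rectangle inside marginal rectangle i.

    Spans the cells at most ``b`` categories off the diagonal; band b
    contains band b-1 which contains the dark square (b = 0).
    """

    category: int
    b: int
    rect: Rect


@dataclass(frozen=True)
class ChartLayout:
    """Renderer-agnostic agreement-chart geometry for one table."""

    side: float
    labels: tuple[str, ...]
    rects: tuple[Rect, ...]
    dark_squares: tuple[Rect, ...]
    bands: tuple[tuple[BandRect, ...], ...]
    bias_path: tuple[tuple[float, float], ...]
    diagonal: tuple[tuple[float, float], tuple[float, float]]
    row_rater: str = "rater A"
    col_rater: str = "rater B"
    counts: np.ndarray | None = field(default=None, compare=False)

    @property
    def k(self) -> int:
        return len(self.rects)

    def dark_area_ratio(self) -> float:
        """Total dark-square area over total rectangle area (= B)."""
        return sum(s.area for s in self.dark_squares) / sum(
            r.area for r in self.rects
        )

    def weighted_area_ratio(self, scheme: WeightScheme | str = "quadratic") -> float:
        """Shade-weighted covered area over rectangle area (= weighted B).

        Each incremental band-b annulus counts with the scheme's band
        weight ``w_b``; the dark square counts fully.
        """
        if isinstance(scheme, str):
            scheme = WeightScheme.make(scheme, self.k)
        if scheme.k != self.k:
            raise ValueError(f"scheme k={scheme.k} does not match chart k={self.k}")
        num = 0.0
        for i in range(self.k):
            prev = self.dark_squares[i].area
            num += prev
            for band in self.bands[i]:
                num += scheme.band_weight(band.b) * (band.rect.area - prev)
                prev = band.rect.area
        return num / sum(r.area for r in self.rects)


def layout(table: ContingencyTable) -> ChartLayout:
    """Compute the agreement-chart geometry for a table."""
    m = table.counts.astype(float)
    k = table.k
    n = float(table.n)
    col = table.col_totals.astype(float)
    row = table.row_totals.astype(float)
    x0 = np.concatenate([[0.0], np.cumsum(col)[:-1]])
    y0 = np.concatenate([[0.0], np.cumsum(row)[:-1]])

    rects = tuple(Rect(x0[i], y0[i], col[i], row[i]) for i in range(k))

    dark = []
    for i in range(k):
        off_x = float(m[:i, i].sum())  # column cells from preceding categories
        off_y = float(m[i, :i].sum())  # row cells from preceding categories
        side = float(m[i, i])
        dark.append(Rect(x0[i] + off_x, y0[i] + off_y, side, side))

    bands = []
    for i in range(k):
        per_rect = []
        for b in range(1, k):
            lo = max(0, i - b)
            hi = min(k - 1, i + b)
            bx = x0[i] + float(m[:lo, i].sum())
            by = y0[i] + float(m[i, :lo].sum())
            bw = float(m[lo : hi + 1, i].sum())
            bh = float(m[i, lo : hi + 1].sum())
            per_rect.append(BandRect(i, b, Rect(bx, by, bw, bh)))
        bands.append(tuple(per_rect))

    path = [(0.0, 0.0)]
    path += [(float(np.cumsum(col)[i]), float(np.cumsum(row)[i])) for i in range(k)]

    return ChartLayout(
        side=n,
        labels=table.labels,
        rects=rects,
        dark_squares=tuple(dark),
        bands=tuple(bands),
        bias_path=tuple(path),
        diagonal=((0.0, 0.0), (n, n)),
        row_rater=table.row_rater,
        col_rater=table.col_rater,
        counts=table.counts,
    )


@dataclass(frozen=True)
class BiasDeviation:
    """Signed summary of how the path of rectangles departs from y = x.

    ``area`` is the signed area between the path and the 45-degree
    diagonal, normalised by n^2/2 (the half-square), so it lies in
    [-1, 1].  Positive means the path runs above the diagonal: the row
    rater reaches high cumulative totals sooner, i.e. favours the lower
    categories relative to the column rater.  ``corner_signs`` gives the
    sign of (y - x) at each interior path corner.
    """

    area: float
    corner_signs: tuple[int, ...]

    @property
    def direction(self) -> str:
        if self.area > 0:
            return "above"
        if self.area < 0:
            return "below"
        return "on"


def bias_deviation(layout: ChartLayout) -> BiasDeviation:
    """Signed area between the path of rectangles and the no-bias diagonal."""
    pts = layout.bias_path
    n = layout.side
    area = 0.0
    for (px0, py0), (px1, py1) in zip(pts[:-1], pts[1:]):
        # trapezoid of (y - x) over [px0, px1]
        area += 0.5 * ((py0 - px0) + (py1 - px1)) * (px1 - px0)
    signs = tuple(int(np.sign(y - x)) for x, y in pts[1:-1])
    return BiasDeviation(area=area / (n * n / 2.0), corner_signs=signs)


def _gray(level: float) -> str:
    v = int(round(255 * min(max(level, 0.0), 1.0)))
    return f"#{v:02x}{v:02x}{v:02x}"


@dataclass(frozen=True)
class RenderStyle:
    """Visual parameters for chart rendering.

    The band shade ramp is monotone: band b+1 is strictly lighter than
    band b, and the dark diagonal square is darkest of all.
    """

    size_px: int = 480
    dark_level: float = 0.12
    band_level_near: float = 0.45
    band_level_far: float = 0.92
    outline_color: str = "#333333"
    diagonal_color: str = "#888888"
    bias_path_color: str = "#c0392b"
    stroke_width: float = 0.002  # fraction of chart side
    draw_bias_path: bool = True
    draw_labels: bool = True

    def band_level(self, b: int, k: int) -> float:
        """Gray level for band distance b (1..k-1); larger = lighter."""
        if k <= 2:
            return self.band_level_near
        t = (b - 1) / (k - 2)
        return self.band_level_near + t * (self.band_level_far - self.band_level_near)

    @classmethod
    def from_options(cls, options: dict) -> "RenderStyle":
        """Build a style from string key=value options (CLI / config file)."""
        kwargs = {}
        for key, raw in options.items():
            if key not in cls.__dataclass_fields__:
                raise ValueError(f"unknown style option {key!r}")
            typ = cls.__dataclass_fields__[key].type
            if typ == "int":
                kwargs[key] = int(raw)
            elif typ == "float":
                kwargs[key] = float(raw)
            elif typ == "bool":
                kwargs[key] = str(raw).lower() in ("1", "true", "yes", "on")
            else:
                kwargs[key] = str(raw)
        return cls(**kwargs)


def _render_svg(lay: ChartLayout, style: RenderStyle, path: Path) -> None:
    n = lay.side
    sw = style.stroke_width * n

    def y_flip(y: float, h: float = 0.0) -> float:
        # SVG's y axis points down; the chart's points up.
        return n - y - h

    root = ET.Element(
        "svg",
        {
            "xmlns": "http://www.w3.org/2000/svg",
            "version": "1.1",
            "viewBox": f"0 0 {n} {n}",
            "width": str(style.size_px),
            "height": str(style.size_px),
        },
    )
    ET.SubElement(
        root,
        "rect",
        {
            "class": "outer",
            "x": "0", "y": "0", "width": str(n), "height": str(n),
            "fill": "none", "stroke": style.outline_color,
            "stroke-width": str(sw),
        },
    )
    # bands first (lightest underneath), then dark squares, then outlines
    for i in range(lay.k):
        for band in reversed(lay.bands[i]):
            r = band.rect
            if r.area == 0:
                continue
            ET.SubElement(
                root,
                "rect",
                {
                    "class": "band",
                    "data-category": lay.labels[i],
                    "data-band": str(band.b),
                    "x": str(r.x), "y": str(y_flip(r.y, r.height)),
                    "width": str(r.width), "height": str(r.height),
                    "fill": _gray(style.band_level(band.b, lay.k)),
                    "stroke": "none",
                },
            )
    for i, sq in enumerate(lay.dark_squares):
        if sq.width == 0:
            continue  # zero diagonal count: no square element
        ET.SubElement(
            root,
            "rect",
            {
                "class": "dark",
                "data-category": lay.labels[i],
                "data-count": str(int(sq.width)),
                "x": str(sq.x), "y": str(y_flip(sq.y, sq.height)),
                "width": str(sq.width), "height": str(sq.height),
                "fill": _gray(style.dark_level),
                "stroke": "none",
            },
        )
    for i, r in enumerate(lay.rects):
        ET.SubElement(
            root,
            "rect",
            {
                "class": "marginal",
                "data-category": lay.labels[i],
                "data-row-total": str(int(r.height)),
                "data-col-total": str(int(r.width)),
                "x": str(r.x), "y": str(y_flip(r.y, r.height)),
                "width": str(r.width), "height": str(r.height),
                "fill": "none", "stroke": style.outline_color,
                "stroke-width": str(sw),
            },
        )
    (d0, d1) = lay.diagonal
    ET.SubElement(
        root,
        "line",
        {
            "class": "diagonal",
            "x1": str(d0[0]), "y1": str(y_flip(d0[1])),
            "x2": str(d1[0]), "y2": str(y_flip(d1[1])),
            "stroke": style.diagonal_color, "stroke-width": str(sw),
            "stroke-dasharray": f"{4 * sw} {4 * sw}",
        },
    )
    if style.draw_bias_path:
        pts = " ".join(f"{x},{y_flip(y)}" for x, y in lay.bias_path)
        ET.SubElement(
            root,
            "polyline",
            {
                "class": "bias-path",
                "points": pts,
                "fill": "none",
                "stroke": style.bias_path_color,
                "stroke-width": str(1.5 * sw),
            },
        )
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")


def _render_png(lay: ChartLayout, style: RenderStyle, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(style.size_px / 96, style.size_px / 96))
    plot(lay, ax=ax, style=style)
    fig.savefig(path, dpi=96, bbox_inches="tight")
    plt.close(fig)


def plot(lay: ChartLayout, ax=None, style: RenderStyle | None = None):
    """Draw the chart on a matplotlib axes (created if not given)."""
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    style = style or RenderStyle()
    if ax is None:
        _, ax = plt.subplots()
    n = lay.side
    for i in range(lay.k):
        for band in reversed(lay.bands[i]):
            r = band.rect
            if r.area == 0:
                continue
            ax.add_patch(
                Rectangle((r.x, r.y), r.width, r.height,
                          facecolor=_gray(style.band_level(band.b, lay.k)),
                          edgecolor="none")
            )
    for sq in lay.dark_squares:
        if sq.width:
            ax.add_patch(
                Rectangle((sq.x, sq.y), sq.width, sq.height,
                          facecolor=_gray(style.dark_level), edgecolor="none")
            )
    for r in lay.rects:
        ax.add_patch(
            Rectangle((r.x, r.y), r.width, r.height, fill=False,
                      edgecolor=style.outline_color, linewidth=0.8)
        )
    ax.plot([0, n], [0, n], color=style.diagonal_color, linewidth=0.8,
            linestyle="--")
    if style.draw_bias_path:
        xs, ys = zip(*lay.bias_path)
        ax.plot(xs, ys, color=style.bias_path_color, linewidth=1.2)
    if style.draw_labels:
        for i, r in enumerate(lay.rects):
            ax.text(r.x + r.width / 2, -0.02 * n, lay.labels[i],
                    ha="center", va="top", fontsize=8)
            ax.text(-0.02 * n, r.y + r.height / 2, lay.labels[i],
                    ha="right", va="center", fontsize=8)
        ax.set_xlabel(lay.col_rater)
        ax.set_ylabel(lay.row_rater)
    ax.set_xlim(-0.05 * n, 1.02 * n)
    ax.set_ylim(-0.05 * n, 1.02 * n)
    ax.set_aspect("equal")
    ax.set_xticks([])
    ax.set_yticks([])
    for spine in ax.spines.values():
        spine.set_visible(False)
    return ax


def render(lay: ChartLayout, style: RenderStyle | None = None,
           path: str | Path = "chart.svg") -> Path:
    """Render a layout to SVG (or PNG, inferred from the extension)."""
    style = style or RenderStyle()
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".svg":
        _render_svg(lay, style, path)
    elif ext == ".png":
        _render_png(lay, style, path)
    else:
        raise ValueError(f"unsupported output format {ext!r}; use .svg or .png")
    return path
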