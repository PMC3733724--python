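"""Independent brute-force reference implementation of the agreement
statistics.

Pure Python, loop-based, no numpy and no shared code with the package:
used only to cross-check the vectorized implementations.  Operates on
list-of-lists of counts.
"""

from __future__ import annotations


def _weight(scheme: str, i: int, j: int, k: int) -> float:
    d = abs(i - j)
    if scheme == "unweighted":
        return 1.0 if d == 0 else 0.0
    if scheme == "linear":
        return 1.0 - d / (k - 1)
    if scheme == "quadratic":
        return 1.0 - (d * d) / ((k - 1) * (k - 1))
    raise ValueError(scheme)


def _margins(cells):
    k = len(cells)
    row = [sum(cells[i][j] for j in range(k)) for i in range(k)]
    col = [sum(cells[i][j] for i in range(k)) for j in range(k)]
    n = sum(row)
    return row, col, n


def observed_expected(cells):
    row, col, n = _margins(cells)
    k = len(cells)
    po = sum(cells[i][i] for i in range(k)) / n
    pe = sum(row[i] * col[i] for i in range(k)) / (n * n)
    return po, pe


def kappa(cells, scheme: str = "unweighted") -> float:
    row, col, n = _margins(cells)
    k = len(cells)
    po = 0.0
    pe = 0.0
    for i in range(k):
        for j in range(k):
            w = _weight(scheme, i, j, k)
            po += w * cells[i][j] / n
            pe += w * row[i] * col[j] / (n * n)
    return (po - pe) / (1.0 - pe)


def b_statistic(cells) -> float:
    row, col, n = _margins(cells)
    k = len(cells)
    num = sum(cells[i][i] ** 2 for i in range(k))
    den = sum(row[i] * col[i] for i in range(k))
    return num / den


def weighted_b(cells, scheme: str = "quadratic") -> float:
    row, col, n = _margins(cells)
    k = len(cells)
    num = 0.0
    for i in range(k):
        num += cells[i][i] ** 2
        prev = cells[i][i] ** 2
        for b in range(1, k):
            width = 0.0
            height = 0.0
            for j in range(k):
                if abs(j - i) <= b:
                    width += cells[j][i]
                    height += cells[i][j]
            area = width * height
            num += _weight(scheme, 0, b, k) * (area - prev)
            prev = area
    den = sum(row[i] * col[i] for i in range(k))
    return num / den
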