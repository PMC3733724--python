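from __future__ import annotations

import numpy as np
import pytest

from agreechart import ContingencyTable, list_fixtures, load_fixture


@pytest.fixture(scope="session")
def fixture_tables() -> dict[str, ContingencyTable]:
    """All bundled example tables, loaded once."""
    return {name: load_fixture(name) for name in list_fixtures()}


def random_table(rng: np.random.Generator, k: int | None = None,
                 max_count: int = 30) -> ContingencyTable:
    """A random non-degenerate contingency table (Pe < 1, total > 0)."""
    if k is None:
        k = int(rng.integers(2, 8))
    while True:
        counts = rng.integers(0, max_count + 1, size=(k, k))
        if counts.sum() == 0:
            continue
        row = counts.sum(axis=1)
        col = counts.sum(axis=0)
        pe = float(row @ col) / counts.sum() ** 2
        if pe < 1.0 - 1e-9:
            return ContingencyTable(counts, tuple(str(i + 1) for i in range(k)))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230729)
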