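"""Multinomial simulator for paired ordinal ratings.

A :class:`RatingModel` is a joint probability matrix ``p_ij`` over the
k x k category pairs together with a number of items ``n`` and a seed;
:func:`simulate` draws the n items into the k^2 cells in one multinomial
draw (numpy PCG64 generator, recorded in the model metadata so simulated
tables are reproducible across runs).

Population values of every agreement statistic follow from evaluating the
same formulas on the probability matrix itself — the statistics are
invariant to scaling all cells by a constant, so probabilities work as
pseudo-counts (:func:`population_summary`).  This is what the sample
statistics converge to as n grows.

Helper constructors cover the two cases the tests lean on: rater
independence (``p_ij = p_i q_j``, population kappa exactly 0) and
diagonal inflation (a mixture putting extra mass on exact agreement).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import stats as _stats
from .tables import ContingencyTable
from .weights import WeightScheme

__all__ = [
    "RatingModel",
    "simulate",
    "population_summary",
    "independence_model",
    "diagonal_inflated_model",
]

_GENERATOR = "numpy.random.default_rng (PCG64)"


@dataclass(frozen=True)
class RatingModel:
    """Joint distribution of one item's pair of ratings.

    ``joint[i, j]`` is the probability the row rater says category i and
    the column rater says category j; ``n`` items are rated independently.
    """

    joint: np.ndarray
    n: int
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.joint, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1] or p.shape[0] < 2:
            raise ValueError(f"joint must be square k x k with k >= 2, got {p.shape}")
        if (p < 0).any():
            raise ValueError("joint probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"joint probabilities sum to {p.sum()!r}, not 1")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        p.setflags(write=False)
        object.__setattr__(self, "joint", p)

    @property
    def k(self) -> int:
        return self.joint.shape[0]

    @property
    def metadata(self) -> dict:
        return {"generator": _GENERATOR, "seed": self.seed, "n": self.n}


def simulate(model: RatingModel, labels=None) -> ContingencyTable:
    """Draw a contingency table from the model (deterministic given seed)."""
    rng = np.random.default_rng(model.seed)
    flat = rng.multinomial(model.n, model.joint.ravel())
    counts = flat.reshape(model.joint.shape)
    if labels is None:
        labels = [str(i + 1) for i in range(model.k)]
    return ContingencyTable(counts, tuple(labels),
                            row_rater="simulated A", col_rater="simulated B")


def population_summary(model: RatingModel,
                       scheme: str | WeightScheme = "quadratic"
                       ) -> _stats.AgreementSummary:
    """Exact population statistics implied by the joint distribution.

    Evaluates the agreement formulas directly on ``p_ij`` (closed form, no
    sampling); sample statistics converge to these values as n grows.
    """
    return _stats.summarize(model.joint, scheme)


def independence_model(p_row, p_col=None, n: int = 1000, seed: int = 0
                       ) -> RatingModel:
    """Model with independent raters: ``p_ij = p_i q_j`` (kappa = 0)."""
    p = np.asarray(p_row, dtype=float)
    q = p if p_col is None else np.asarray(p_col, dtype=float)
    p, q = p / p.sum(), q / q.sum()
    return RatingModel(np.outer(p, q), n=n, seed=seed)


def diagonal_inflated_model(p_row, agreement: float, n: int = 1000,
                            seed: int = 0) -> RatingModel:
    """Independence mixed with exact agreement.

    With probability ``agreement`` both raters give the same category
    (drawn from ``p_row``); otherwise the ratings are independent with
    marginal ``p_row`` for both.  ``agreement=0`` is independence,
    ``agreement=1`` a purely diagonal (perfect-agreement) model.
    """
    if not 0.0 <= agreement <= 1.0:
        raise ValueError("agreement must be in [0, 1]")
    p = np.asarray(p_row, dtype=float)
    p = p / p.sum()
    joint = (1 - agreement) * np.outer(p, p) + agreement * np.diag(p)
    return RatingModel(joint, n=n, seed=seed)
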