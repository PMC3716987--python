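"""Scenario parameterization and outcome enumeration.

An evaluation scenario for paired binary data is defined by the number
of pairs ``N``, the two marginal success probabilities ``p1+`` and
``p+1``, and the within-pair odds ratio

    theta = p11 * p22 / (p12 * p21),

which together pin down the joint cell probabilities
``(p11, p12, p21, p22)``.  Solving the theta definition for ``p11``
gives a quadratic whose unique root inside the Frechet bounds
``[max(0, p1+ + p+1 - 1), min(p1+, p+1)]`` is

    p11 = [1 + (theta-1) s - sqrt((1 + (theta-1) s)^2
           - 4 theta (theta-1) p1+ p+1)] / (2 (theta-1)),   s = p1+ + p+1,

with the independence product ``p11 = p1+ p+1`` at theta = 1 and
boundary solutions when a margin is 0 or 1 (where theta is formally
0/0; the boundary solution is the natural limit).

Under the null ``p1+ = p+1`` the discordant cells are equal
(``p12 = p21``), which is exactly what makes the conditional
Binomial(n, 1/2) law of the conditional tests correct.

Only the discordant counts matter to any implemented statistic, so the
outcome space for ``N`` pairs is reduced to the trinomial triplets
``(x12, x21, N - x12 - x21)`` with cell probabilities
``(p12, p21, 1 - p12 - p21)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.special import gammaln


@dataclass(frozen=True)
class CellProbs:
    """Joint outcome probabilities of a paired 2x2 table."""

    p11: float
    p12: float
    p21: float
    p22: float

    def __post_init__(self) -> None:
        probs = (self.p11, self.p12, self.p21, self.p22)
        if any(p < -1e-12 or p > 1 + 1e-12 for p in probs):
            raise ValueError(f"cell probabilities out of [0, 1]: {probs}")
        if abs(sum(probs) - 1.0) > 1e-12:
            raise ValueError(f"cell probabilities must sum to 1: {probs}")

    @property
    def p1plus(self) -> float:
        return self.p11 + self.p12

    @property
    def pplus1(self) -> float:
        return self.p11 + self.p21

    @property
    def p_discordant(self) -> float:
        return self.p12 + self.p21

    def theta(self) -> float:
        """Recompute the odds ratio; nan when formally 0/0."""
        denom = self.p12 * self.p21
        if denom == 0.0:
            return float("nan") if self.p11 * self.p22 == 0.0 else float("inf")
        return self.p11 * self.p22 / denom


@dataclass(frozen=True)
class ScenarioParams:
    """One evaluation scenario: (N, p1+, p+1, theta)."""

    N: int
    p1plus: float
    pplus1: float
    theta: float

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")
        if not 0.0 <= self.p1plus <= 1.0 or not 0.0 <= self.pplus1 <= 1.0:
            raise ValueError("marginal probabilities must lie in [0, 1]")
        if not self.theta > 0:
            raise ValueError(f"theta must be positive, got {self.theta}")

    @property
    def delta(self) -> float:
        """Difference of marginal success probabilities, ``p+1 - p1+``."""
        return self.pplus1 - self.p1plus

    @property
    def is_null(self) -> bool:
        return self.p1plus == self.pplus1

    def cells(self) -> CellProbs:
        return cells_from_margins(self.p1plus, self.pplus1, self.theta)


class Outcome(NamedTuple):
    """One point of the trinomial outcome space with its probability."""

    x12: int
    x21: int
    prob: float


def cells_from_margins(p1plus: float, pplus1: float, theta: float) -> CellProbs:
    """Joint cell probabilities from margins and the odds ratio.

    See the module docstring for the closed-form root.  Degenerate
    margins (0 or 1) short-circuit to the boundary solution for any
    theta.
    """
    if not 0.0 <= p1plus <= 1.0 or not 0.0 <= pplus1 <= 1.0:
        raise ValueError("margins must lie in [0, 1]")
    if not theta > 0:
        raise ValueError(f"theta must be positive, got {theta}")
    if p1plus == 0.0 or pplus1 == 0.0:
        p11 = 0.0
    elif p1plus == 1.0:
        p11 = pplus1
    elif pplus1 == 1.0:
        p11 = p1plus
    elif theta == 1.0:
        p11 = p1plus * pplus1
    else:
        s = p1plus + pplus1
        a = 1.0 + (theta - 1.0) * s
        disc = a * a - 4.0 * theta * (theta - 1.0) * p1plus * pplus1
        p11 = (a - np.sqrt(disc)) / (2.0 * (theta - 1.0))
    lo = max(0.0, p1plus + pplus1 - 1.0)
    hi = min(p1plus, pplus1)
    if not lo - 1e-9 <= p11 <= hi + 1e-9:
        raise RuntimeError(
            f"no admissible p11 root for ({p1plus}, {pplus1}, {theta}); got {p11}"
        )
    p11 = min(max(p11, lo), hi)
    return CellProbs(
        p11=p11,
        p12=p1plus - p11,
        p21=pplus1 - p11,
        p22=1.0 - p1plus - pplus1 + p11,
    )


def outcome_space(N: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical enumeration of the ``(N+1)(N+2)/2`` discordant-count
    pairs ``(x12, x21)`` with ``x12 + x21 <= N``.

    The order is fixed (x12-major) and shared by every cached p-value
    table and mass vector in :mod:`mcnemar.evaluation`.
    """
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    x12, x21 = [], []
    for a in range(N + 1):
        for b in range(N + 1 - a):
            x12.append(a)
            x21.append(b)
    return np.array(x12), np.array(x21)


def outcome_masses(N: int, cells: CellProbs) -> np.ndarray:
    """Trinomial mass of every outcome, aligned with :func:`outcome_space`.

    Computed in log space; zero-probability outcomes (a discordant cell
    probability of exactly zero with a positive count) are retained with
    mass 0.
    """
    x12, x21 = outcome_space(N)
    n = x12 + x21
    log_coef = (
        gammaln(N + 1) - gammaln(x12 + 1) - gammaln(x21 + 1) - gammaln(N - n + 1)
    )
    p12, p21 = cells.p12, cells.p21
    p_conc = 1.0 - p12 - p21
    with np.errstate(divide="ignore", invalid="ignore"):
        lm = (
            log_coef
            + np.where(x12 == 0, 0.0, x12 * np.log(p12))
            + np.where(x21 == 0, 0.0, x21 * np.log(p21))
            + np.where(n == N, 0.0, (N - n) * np.log(max(p_conc, 0.0)))
        )
    return np.exp(lm)


def enumerate_outcomes(N: int, cells: CellProbs) -> list[Outcome]:
    """All outcomes of the trinomial reduction with their probabilities."""
    x12, x21 = outcome_space(N)
    mass = outcome_masses(N, cells)
    return [Outcome(int(a), int(b), float(m)) for a, b, m in zip(x12, x21, mass)]


__all__ = [
    "CellProbs",
    "ScenarioParams",
    "Outcome",
    "cells_from_margins",
    "outcome_space",
    "outcome_masses",
    "enumerate_outcomes",
]
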