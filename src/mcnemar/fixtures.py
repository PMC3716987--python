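"""Built-in example tables, evaluation grids, and random-table generators.

The two named example tables come from published clinical studies of
stem cell transplantation (SCT):

* ``bentur`` — airway hyper-responsiveness before and after SCT in 21
  children (Bentur et al., Bone Marrow Transplant 2009),
* ``cavo`` — complete response before and after consolidation therapy
  in 161 myeloma patients (Cavo et al., Blood 2012).

Both are small enough to exercise every test, and their five reference
p-values (one per method, at 4 decimals) form the regression surface
for the scalar API.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scenarios import ScenarioParams
from .tables import PairedTable

#: Default evaluation-grid axes.
TIER_N_VALUES = tuple(range(10, 101, 5))
TIER_SMALL_N_VALUES = tuple(range(10, 31, 5))
THETA_VALUES = (1.0, 2.0, 3.0, 5.0, 10.0)
POWER_P1_VALUES = (0.1, 0.35, 0.6)
POWER_DELTA_VALUES = (0.10, 0.15, 0.20, 0.25, 0.30, 0.35)


@dataclass(frozen=True)
class NamedFixture:
    """A reference table with its expected p-values at 4 decimals."""

    name: str
    table: PairedTable
    expected: dict[str, float]
    source: str


def builtin_fixtures() -> list[NamedFixture]:
    """The two packaged reference tables with expected p-values."""
    return [
        NamedFixture(
            name="bentur",
            table=PairedTable(1, 1, 7, 12),
            expected={
                "asymptotic": 0.0339,
                "asymptotic_cc": 0.0771,
                "exact_conditional": 0.0703,
                "midp": 0.0391,
                "unconditional": 0.0353,
            },
            source=(
                "Bentur et al. (2009): airway hyper-responsiveness before/after "
                "stem cell transplantation in 21 children"
            ),
        ),
        NamedFixture(
            name="cavo",
            table=PairedTable(59, 6, 16, 80),
            expected={
                "asymptotic": 0.0330,
                "asymptotic_cc": 0.0550,
                "exact_conditional": 0.0525,
                "midp": 0.0347,
                "unconditional": 0.0342,
            },
            source=(
                "Cavo et al. (2012): complete response before/after consolidation "
                "therapy in 161 myeloma patients"
            ),
        ),
    ]


def _marginal_grid() -> list[float]:
    # i/100 avoids accumulating 0.01 floating-point drift over 101 steps
    return [i / 100.0 for i in range(101)]


def builtin_grid(name: str) -> list[ScenarioParams]:
    """Named scenario grids used by the evaluation study.

    * ``tier-9595`` — null grid: N in 10, 15, ..., 100; theta in
      {1, 2, 3, 5, 10}; p1+ = p+1 in 0.00, 0.01, ..., 1.00
      (19 x 5 x 101 = 9595 scenarios).
    * ``tier-small`` — the same restricted to N in {10, ..., 30}
      (2525 scenarios).
    * ``power-grid`` — alternative grid: N = 1..100, the five theta
      values, p1+ in {0.1, 0.35, 0.6}, delta in 0.10, ..., 0.35.
    """
    if name == "tier-9595":
        n_values = TIER_N_VALUES
    elif name == "tier-small":
        n_values = TIER_SMALL_N_VALUES
    elif name == "power-grid":
        return [
            ScenarioParams(N=N, p1plus=p1, pplus1=round(p1 + d, 10), theta=th)
            for N in range(1, 101)
            for th in THETA_VALUES
            for p1 in POWER_P1_VALUES
            for d in POWER_DELTA_VALUES
        ]
    else:
        raise ValueError(
            f"unknown grid {name!r}; expected tier-9595, tier-small, or power-grid"
        )
    return [
        ScenarioParams(N=N, p1plus=p, pplus1=p, theta=th)
        for N in n_values
        for th in THETA_VALUES
        for p in _marginal_grid()
    ]


def random_tables(count: int, Nmax: int = 50, seed: int = 0) -> list[PairedTable]:
    """Reproducible random paired tables for property tests.

    Cell counts are multinomial draws with Dirichlet cell probabilities.
    Every 10th table is forced to be discordant-degenerate
    (``n12 = n21 = 0``) so the convention paths are always exercised.
    """
    if count < 1:
        raise ValueError(f"count must be >= 1, got {count}")
    rng = np.random.default_rng(seed)
    tables = []
    for i in range(count):
        N = int(rng.integers(1, Nmax + 1))
        probs = rng.dirichlet(np.ones(4))
        n11, n12, n21, n22 = rng.multinomial(N, probs)
        if i % 10 == 9:
            n11, n22 = n11 + n12, n22 + n21
            n12 = n21 = 0
        tables.append(PairedTable(int(n11), int(n12), int(n21), int(n22)))
    return tables


__all__ = [
    "NamedFixture",
    "builtin_fixtures",
    "builtin_grid",
    "random_tables",
    "TIER_N_VALUES",
    "TIER_SMALL_N_VALUES",
    "THETA_VALUES",
    "POWER_P1_VALUES",
    "POWER_DELTA_VALUES",
]
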