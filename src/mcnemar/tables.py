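"""Data containers for paired 2x2 tables and test results.

A matched-pairs study records two binary outcomes (events A and B, each
success/failure) on every one of ``N`` pairs.  The data collapse to a 2x2
table of concordant counts (``n11``, ``n22``) and discordant counts
(``n12``, ``n21``); all inference about marginal homogeneity
(``p1+ = p+1``) is driven by the discordant pairs, with the unconditional
test additionally using the total ``N``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np

#: Identifiers of the five implemented tests.
METHODS = (
    "asymptotic",
    "asymptotic_cc",
    "exact_conditional",
    "midp",
    "unconditional",
)

#: Accepted aliases (CLI shorthand) -> canonical method identifier.
METHOD_ALIASES = {
    "asymptotic": "asymptotic",
    "cc": "asymptotic_cc",
    "asymptotic_cc": "asymptotic_cc",
    "exact": "exact_conditional",
    "exact_conditional": "exact_conditional",
    "midp": "midp",
    "mid-p": "midp",
    "unconditional": "unconditional",
}


def canonical_method(name: str) -> str:
    """Resolve a method name or alias to its canonical identifier."""
    try:
        return METHOD_ALIASES[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown method {name!r}; expected one of {sorted(set(METHOD_ALIASES))}"
        ) from None


@dataclass(frozen=True)
class PairedTable:
    """Observed counts of a paired 2x2 table.

    Layout is row-major with rows = event A and columns = event B,
    success before failure: ``n11`` (both successes), ``n12`` (A success,
    B failure), ``n21`` (A failure, B success), ``n22`` (both failures).

    Parameters
    ----------
    n11, n12, n21, n22 : int
        Non-negative cell counts.
    """

    n11: int
    n12: int
    n21: int
    n22: int

    def __post_init__(self) -> None:
        for name in ("n11", "n12", "n21", "n22"):
            value = getattr(self, name)
            if isinstance(value, (bool, float)) and not float(value).is_integer():
                raise ValueError(f"{name} must be an integer, got {value!r}")
            value = int(value)
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")
            object.__setattr__(self, name, value)

    @property
    def N(self) -> int:
        """Total number of pairs."""
        return self.n11 + self.n12 + self.n21 + self.n22

    @property
    def n(self) -> int:
        """Number of discordant pairs, ``n12 + n21``."""
        return self.n12 + self.n21

    def transpose(self) -> "PairedTable":
        """Swap the discordant counts (equivalently, swap events A and B)."""
        return PairedTable(self.n11, self.n21, self.n12, self.n22)

    def counts(self) -> tuple[int, int, int, int]:
        return (self.n11, self.n12, self.n21, self.n22)

    @classmethod
    def from_counts(cls, counts: Iterable[int]) -> "PairedTable":
        values = list(counts)
        if len(values) != 4:
            raise ValueError(f"expected 4 counts (n11 n12 n21 n22), got {len(values)}")
        return cls(*values)


@dataclass(frozen=True)
class TestResult:
    """Outcome of one test applied to one :class:`PairedTable`.

    Attributes
    ----------
    method : str
        Canonical method identifier.
    p_two_sided : float
        Two-sided p-value in (0, 1].
    p_one_sided : float, optional
        One-sided p-value where the test defines one (exact conditional,
        mid-p, unconditional); ``p_two_sided = min(1, 2 * p_one_sided)``.
    statistic : float, optional
        z for the asymptotic tests, z_obs for the unconditional test.
    point_prob : float, optional
        Binomial point probability of the observed ``n12`` given ``n``
        (mid-p diagnostics).
    degenerate : bool
        True when ``n12 = n21 = 0`` and the p-value was set by convention.
    """

    method: str
    p_two_sided: float
    p_one_sided: Optional[float] = None
    statistic: Optional[float] = None
    point_prob: Optional[float] = None
    degenerate: bool = field(default=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.p_two_sided <= 1.0:
            raise ValueError(f"p_two_sided out of (0, 1]: {self.p_two_sided}")


def round_half_up(x: float, decimals: int = 4) -> float:
    """Round half away from zero, matching how p-values are reported."""
    factor = 10.0 ** decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def read_tables(path: Union[str, Path]) -> list[PairedTable]:
    """Read paired tables from a delimited text file.

    One table per line, four integer columns (n11 n12 n21 n22), separated
    by whitespace, commas, or tabs.  Lines starting with ``#`` and blank
    lines are skipped; a single non-numeric header line is tolerated.
    """
    tables: list[PairedTable] = []
    header_seen = False
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = [t for t in line.replace(",", " ").replace("\t", " ").split() if t]
        try:
            counts = [int(t) for t in tokens]
        except ValueError:
            if not header_seen and not tables:
                header_seen = True
                continue
            raise ValueError(f"{path}:{lineno}: non-integer counts in {line!r}")
        tables.append(PairedTable.from_counts(counts))
    return tables
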