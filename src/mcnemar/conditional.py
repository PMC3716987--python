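"""Conditional tests for marginal homogeneity of paired binary data.

All four tests here condition on the number of discordant pairs
``n = n12 + n21``: under the null hypothesis ``p1+ = p+1`` the two
discordant cell probabilities are equal, so conditionally
``n12 ~ Binomial(n, 1/2)``.  Available tests:

* ``asymptotic`` -- the score statistic z = (n12 - n21)/sqrt(n12 + n21)
  referred to the standard normal distribution,
* ``asymptotic_cc`` -- the continuity-corrected version with numerator
  |n12 - n21| - 1,
* ``exact_conditional`` -- the exact binomial tail test (doubled
  one-sided tail),
* ``midp`` -- the quasi-exact mid-p modification, which subtracts the
  point probability of the observed ``n12`` from the exact two-sided
  p-value.

Conventions for degenerate tables: when ``n12 = n21 = 0`` the asymptotic
statistics are undefined and both asymptotic tests return p = 1 (flagged
``degenerate``); the exact conditional test returns 1.0 for any tie
``n12 = n21``, and the mid-p test returns ``1 - f(n12|n)/2`` (0.5 when
n = 0).

Vectorised ``*_pvalues`` functions operate on arrays of discordant
counts and back both the scalar API and the enumeration machinery in
:mod:`mcnemar.evaluation`.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binom, norm

from .tables import METHODS, PairedTable, TestResult, canonical_method


class DegenerateTableError(ValueError):
    """Raised when a statistic is undefined because ``n12 = n21 = 0``."""


def asymptotic_z(table: PairedTable) -> float:
    """Score statistic ``z = (n12 - n21) / sqrt(n12 + n21)``.

    Raises
    ------
    DegenerateTableError
        If there are no discordant pairs (the statistic is undefined;
        :func:`asymptotic_p` applies the p = 1 convention instead).
    """
    if table.n == 0:
        raise DegenerateTableError("z undefined: no discordant pairs (n12 = n21 = 0)")
    return (table.n12 - table.n21) / np.sqrt(table.n)


def binom_point_prob(x12: int, n: int) -> float:
    """Point probability ``C(n, x12) (1/2)^n`` of ``x12`` discordant
    successes among ``n`` discordant pairs under the null.

    Computed in log space (via scipy) so that totals in the hundreds do
    not underflow term by term.
    """
    if not 0 <= x12 <= n:
        raise ValueError(f"require 0 <= x12 <= n, got x12={x12}, n={n}")
    return float(binom.pmf(x12, n, 0.5))


# ---------------------------------------------------------------------------
# vectorised p-value kernels over arrays of discordant counts


def asymptotic_pvalues(x12: np.ndarray, x21: np.ndarray) -> np.ndarray:
    """Two-sided asymptotic p-values, ``2 (1 - Phi(|z|))``; 1 when n = 0."""
    x12 = np.asarray(x12, dtype=float)
    x21 = np.asarray(x21, dtype=float)
    n = x12 + x21
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(x12 - x21) / np.sqrt(n)
    return np.where(n == 0, 1.0, 2.0 * norm.sf(z))


def asymptotic_cc_pvalues(x12: np.ndarray, x21: np.ndarray) -> np.ndarray:
    """Continuity-corrected asymptotic p-values.

    The corrected numerator ``|x12 - x21| - 1`` is clamped at zero so
    that the correction can never increase the apparent evidence; with a
    zero numerator the p-value is exactly 1.
    """
    x12 = np.asarray(x12, dtype=float)
    x21 = np.asarray(x21, dtype=float)
    n = x12 + x21
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.maximum(np.abs(x12 - x21) - 1.0, 0.0) / np.sqrt(n)
    return np.where(n == 0, 1.0, np.minimum(1.0, 2.0 * norm.sf(z)))


def exact_conditional_pvalues(x12: np.ndarray, x21: np.ndarray) -> np.ndarray:
    """Exact conditional two-sided p-values (doubled lower binomial tail).

    Ties ``x12 = x21`` (including n = 0) give exactly 1.0.
    """
    x12 = np.asarray(x12)
    x21 = np.asarray(x21)
    n = x12 + x21
    lower = binom.cdf(np.minimum(x12, x21), n, 0.5)
    return np.where(x12 == x21, 1.0, np.minimum(1.0, 2.0 * lower))


def midp_pvalues(x12: np.ndarray, x21: np.ndarray) -> np.ndarray:
    """Mid-p two-sided p-values.

    General case: exact two-sided p minus the point probability
    ``f(x12|n)``.  Tie case ``x12 = x21``: ``1 - f(x12|n)/2`` (0.5 for
    the empty-discordant table, where f(0|0) = 1).
    """
    x12 = np.asarray(x12)
    x21 = np.asarray(x21)
    n = x12 + x21
    f = binom.pmf(x12, n, 0.5)
    exact = exact_conditional_pvalues(x12, x21)
    return np.where(x12 == x21, 1.0 - 0.5 * f, exact - f)


# ---------------------------------------------------------------------------
# scalar API returning TestResult


def asymptotic_p(table: PairedTable) -> TestResult:
    """Asymptotic McNemar test (no continuity correction)."""
    if table.n == 0:
        return TestResult("asymptotic", 1.0, degenerate=True)
    z = asymptotic_z(table)
    p = float(2.0 * norm.sf(abs(z)))
    return TestResult("asymptotic", p, statistic=float(z))


def asymptotic_cc_p(table: PairedTable) -> TestResult:
    """Asymptotic McNemar test with continuity correction."""
    if table.n == 0:
        return TestResult("asymptotic_cc", 1.0, degenerate=True)
    z_cc = max(abs(table.n12 - table.n21) - 1.0, 0.0) / np.sqrt(table.n)
    p = min(1.0, float(2.0 * norm.sf(z_cc)))
    return TestResult("asymptotic_cc", p, statistic=float(z_cc))


def exact_conditional_p(table: PairedTable) -> TestResult:
    """Exact conditional (binomial) McNemar test."""
    n12, n21, n = table.n12, table.n21, table.n
    one_sided = float(binom.cdf(min(n12, n21), n, 0.5))
    if n12 == n21:
        return TestResult(
            "exact_conditional", 1.0, p_one_sided=one_sided, degenerate=(n == 0)
        )
    return TestResult(
        "exact_conditional", min(1.0, 2.0 * one_sided), p_one_sided=one_sided
    )


def midp_p(table: PairedTable) -> TestResult:
    """Mid-p McNemar test (quasi-exact)."""
    n12, n21, n = table.n12, table.n21, table.n
    f = binom_point_prob(n12, n)
    if n12 == n21:
        p = 1.0 - 0.5 * f
        return TestResult(
            "midp", p, p_one_sided=p / 2.0, point_prob=f, degenerate=(n == 0)
        )
    one_sided = float(binom.cdf(min(n12, n21), n, 0.5)) - 0.5 * f
    p = min(1.0, 2.0 * one_sided)
    return TestResult("midp", p, p_one_sided=one_sided, point_prob=f)


_DISPATCH = {
    "asymptotic": asymptotic_p,
    "asymptotic_cc": asymptotic_cc_p,
    "exact_conditional": exact_conditional_p,
    "midp": midp_p,
}


def run_test(table: PairedTable, method: str, **kwargs) -> TestResult:
    """Run one of the five tests on a paired table.

    Parameters
    ----------
    table : PairedTable
    method : str
        One of ``asymptotic``, ``asymptotic_cc``, ``exact_conditional``,
        ``midp``, ``unconditional`` (aliases ``cc``, ``exact``, ``mid-p``
        accepted).
    **kwargs
        Passed through to :func:`mcnemar.unconditional.unconditional_p`
        (``grid_size``, ``refine_tol``) for the unconditional test.
    """
    method = canonical_method(method)
    if method == "unconditional":
        from .unconditional import unconditional_p

        return unconditional_p(table, **kwargs)
    if kwargs:
        raise TypeError(f"method {method!r} accepts no extra options: {kwargs}")
    return _DISPATCH[method](table)


__all__ = [
    "METHODS",
    "DegenerateTableError",
    "asymptotic_z",
    "binom_point_prob",
    "asymptotic_p",
    "asymptotic_cc_p",
    "exact_conditional_p",
    "midp_p",
    "asymptotic_pvalues",
    "asymptotic_cc_pvalues",
    "exact_conditional_pvalues",
    "midp_pvalues",
    "run_test",
]
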