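"""The exact unconditional test for paired binary data.

Unlike the conditional tests, this test uses all ``N`` pairs.  Writing
``z(x) = (x12 - x21)/sqrt(x12 + x21)`` for the score statistic at an
arbitrary outcome, the one-sided rejection region given an observed
``z_obs >= 0`` collects every outcome at least as extreme,

    C = {(x12, n) : z(x12, n - x12) >= z_obs},

equivalently ``x12 >= h(n)`` with ``h(n) = (z_obs sqrt(n) + n) / 2``.
Under the null the triplet ``(x12, x21, N - n)`` is trinomial with
probabilities ``(p/2, p/2, 1 - p)``, where ``p`` — the probability that
a pair is discordant — is a nuisance parameter.  The attained level

    P(p) = sum_{n} C(N, n) p^n (1 - p)^(N - n) * c_n,

where ``c_n`` is the Binomial(n, 1/2) mass of the region at discordant
total n, is maximised over 0 < p < 1; the supremum is the one-sided
p-value and the two-sided p-value is twice that (capped at 1).

Region membership is decided by the direct inequality
``z(x) >= z_obs - 1e-12`` (inclusive at the boundary, with a small guard
against floating-point ties).  An alternative coefficient construction
via the integer index ``i_n = int(h(n))`` and the cumulative binomial
``F_n`` is provided for cross-checking; the two agree except possibly
where ``h(n)`` is an exact integer, in which case the inclusive reading
is used.

``P(p)`` is a polynomial in ``p`` and can be multimodal, so the
supremum is located by a dense uniform grid followed by bounded scalar
refinement of the best local maxima.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import binom

from .tables import PairedTable, TestResult

#: Floating-point guard for inclusive region membership at the boundary.
BOUNDARY_EPS = 1e-12

#: Defaults for the supremum search.
DEFAULT_GRID_SIZE = 2000
DEFAULT_REFINE_TOL = 1e-8


def z_stat(x12: int, x21: int) -> float:
    """Score statistic ``z = (x12 - x21)/sqrt(x12 + x21)``.

    Defined as 0 for the empty-discordant outcome ``x12 = x21 = 0``,
    which carries no evidence in either direction.
    """
    n = x12 + x21
    if n == 0:
        return 0.0
    return (x12 - x21) / np.sqrt(n)


@dataclass
class UnconditionalContext:
    """Rejection region and supremum-search state for one observed table.

    Attributes
    ----------
    N : int
        Total number of pairs.
    z_obs : float
        Observed statistic (non-negative; callers reflect first).
    k : int
        Smallest discordant total with a non-empty region,
        ``int(z_obs**2 + 1)`` for ``z_obs > 0``.
    region_coeffs : ndarray, shape (N + 1,)
        ``c_n`` = Binomial(n, 1/2) probability of the one-sided region
        at discordant total n.
    p_grid : ndarray
        Interior grid used for the supremum search.
    sup_location : float, optional
        Nuisance-parameter value where the supremum was attained.
    p_one_sided : float, optional
        The supremum (one-sided p-value), filled by the search.
    """

    N: int
    z_obs: float
    k: int
    region_coeffs: np.ndarray
    p_grid: np.ndarray
    sup_location: Optional[float] = None
    p_one_sided: Optional[float] = None
    _log_binom_coef: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        ns = np.arange(self.N + 1)
        self._log_binom_coef = (
            gammaln(self.N + 1) - gammaln(ns + 1) - gammaln(self.N - ns + 1)
        )


def region_thresholds(N: int, z_obs: float) -> np.ndarray:
    """Smallest ``x12`` inside the one-sided region, per discordant total n.

    Entry n is the least integer ``x12`` with
    ``z(x12, n - x12) >= z_obs - BOUNDARY_EPS``; values above n mean the
    region is empty at that n.
    """
    ns = np.arange(N + 1)
    with np.errstate(invalid="ignore"):
        h = ((z_obs - BOUNDARY_EPS) * np.sqrt(ns) + ns) / 2.0
    t = np.ceil(h).astype(int)
    t = np.maximum(t, 0)
    # n = 0: z(0, 0) = 0 is in the region only when z_obs <= 0 (+eps)
    t[0] = 0 if 0.0 >= z_obs - BOUNDARY_EPS else 1
    return t


def build_region(
    N: int, z_obs: float, grid_size: int = DEFAULT_GRID_SIZE
) -> UnconditionalContext:
    """Construct the one-sided rejection region for ``z_obs >= 0``."""
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    if z_obs < 0:
        raise ValueError("z_obs must be non-negative; reflect the table first")
    t = region_thresholds(N, z_obs)
    ns = np.arange(N + 1)
    coeffs = np.where(t <= ns, binom.sf(t - 1, np.maximum(ns, 1), 0.5), 0.0)
    # binom.sf with n=0 is degenerate; handle the empty-discordant cell directly
    coeffs[0] = 1.0 if t[0] == 0 else 0.0
    k = int(z_obs**2 + 1) if z_obs > 0 else 0
    p_grid = np.arange(1, grid_size + 1) / (grid_size + 1)
    return UnconditionalContext(
        N=N, z_obs=float(z_obs), k=k, region_coeffs=coeffs, p_grid=p_grid
    )


def region_coeffs_from_index(N: int, z_obs: float) -> np.ndarray:
    """Region coefficients via the cumulative-binomial indexing.

    Uses ``c_n = F_n(n - i_n - 1)`` with ``i_n = int(h(n))`` and ``F_n``
    the Binomial(n, 1/2) distribution function, and ``c_n = 0`` for
    ``n < k = int(z_obs**2 + 1)``.  Internal cross-check only: at
    integer ``h(n)`` this excludes the boundary outcome that the direct
    inequality includes.
    """
    ns = np.arange(N + 1)
    h = (z_obs * np.sqrt(ns) + ns) / 2.0
    i_n = np.floor(h).astype(int)
    coeffs = binom.cdf(ns - i_n - 1, np.maximum(ns, 1), 0.5)
    coeffs[ns < int(z_obs**2 + 1)] = 0.0
    coeffs[0] = 1.0 if z_obs <= 0 else 0.0
    return coeffs


def attained_level(ctx: UnconditionalContext, p: float) -> float:
    """Attained significance level ``P(p)`` at nuisance parameter ``p``.

    Evaluates the binomial regrouping of the trinomial sum,
    ``sum_n C(N, n) p^n (1 - p)^(N - n) c_n``, in log space.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0, 1), got {p}")
    ns = np.arange(ctx.N + 1)
    log_w = ctx._log_binom_coef + ns * np.log(p) + (ctx.N - ns) * np.log1p(-p)
    return float(np.exp(log_w) @ ctx.region_coeffs)


def _attained_level_grid(ctx: UnconditionalContext, p_grid: np.ndarray) -> np.ndarray:
    """Vectorised ``P(p)`` over a grid of nuisance-parameter values."""
    ns = np.arange(ctx.N + 1)
    log_w = (
        ctx._log_binom_coef[None, :]
        + ns[None, :] * np.log(p_grid[:, None])
        + (ctx.N - ns)[None, :] * np.log1p(-p_grid[:, None])
    )
    return np.exp(log_w) @ ctx.region_coeffs


def supremum_search(
    ctx: UnconditionalContext,
    refine_tol: float = DEFAULT_REFINE_TOL,
    n_refine: int = 5,
    grid_values: Optional[np.ndarray] = None,
) -> UnconditionalContext:
    """Maximise ``P(p)`` over the nuisance parameter.

    Dense-grid scan followed by bounded scalar refinement around the
    ``n_refine`` largest grid values; fills ``p_one_sided`` and
    ``sup_location`` on the context and returns it.

    ``P`` extends continuously to the closed interval with limits
    ``c_0`` at p = 0 and ``c_N`` at p = 1, and the supremum over the
    open interval equals the maximum over the closure, so the two
    boundary limits enter the comparison exactly.  (For small
    ``|z_obs|`` the attained level increases all the way to p = 1; for
    a tie, the empty-discordant point mass at p = 0 puts the supremum
    there with value 1.)
    """
    ps = ctx.p_grid
    vals = _attained_level_grid(ctx, ps) if grid_values is None else grid_values
    best_idx = int(np.argmax(vals))
    best_val = float(vals[best_idx])
    best_p = float(ps[best_idx])
    for i in np.argsort(vals)[-n_refine:]:
        lo = ps[max(i - 1, 0)]
        hi = ps[min(i + 1, len(ps) - 1)]
        if hi <= lo:
            continue
        res = minimize_scalar(
            lambda p: -attained_level(ctx, p),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": refine_tol},
        )
        if -res.fun > best_val:
            best_val = float(-res.fun)
            best_p = float(res.x)
    for p_limit, limit_val in ((0.0, ctx.region_coeffs[0]), (1.0, ctx.region_coeffs[-1])):
        if limit_val > best_val:
            best_val = float(limit_val)
            best_p = p_limit
    ctx.p_one_sided = best_val
    ctx.sup_location = best_p
    return ctx


def unconditional_one_sided(
    N: int,
    z_obs: float,
    grid_size: int = DEFAULT_GRID_SIZE,
    refine_tol: float = DEFAULT_REFINE_TOL,
) -> UnconditionalContext:
    """One-sided supremum p-value for a non-negative observed statistic."""
    ctx = build_region(N, z_obs, grid_size=grid_size)
    return supremum_search(ctx, refine_tol=refine_tol)


def unconditional_p(
    table: PairedTable,
    grid_size: int = DEFAULT_GRID_SIZE,
    refine_tol: float = DEFAULT_REFINE_TOL,
) -> TestResult:
    """Exact unconditional test; two-sided p-value by doubling.

    A negative observed statistic is handled by reflection (swapping
    ``n12`` and ``n21``), equivalent to reversing the region inequality.
    Ties ``n12 = n21`` give ``z_obs = 0``; the one-sided supremum is then
    at least 1/2 and the two-sided p-value is 1.
    """
    if grid_size < 100:
        raise ValueError(f"grid_size must be >= 100, got {grid_size}")
    if table.N < 1:
        raise ValueError("unconditional test requires at least one pair")
    reflected = table if table.n12 >= table.n21 else table.transpose()
    z_obs = z_stat(reflected.n12, reflected.n21)
    ctx = unconditional_one_sided(
        table.N, z_obs, grid_size=grid_size, refine_tol=refine_tol
    )
    return TestResult(
        "unconditional",
        p_two_sided=min(1.0, 2.0 * ctx.p_one_sided),
        p_one_sided=ctx.p_one_sided,
        statistic=float(z_stat(table.n12, table.n21)),
        degenerate=(table.n == 0),
    )


# ---------------------------------------------------------------------------
# brute-force oracle (small N)


def trinomial_attained_level(N: int, z_obs: float, p: float) -> float:
    """Direct trinomial evaluation of ``P(p)``; small-N oracle.

    Enumerates every outcome triplet ``(x12, x21, N - x12 - x21)``,
    includes those with ``z(x) >= z_obs - BOUNDARY_EPS``, and sums
    trinomial probabilities with cell probabilities (p/2, p/2, 1 - p).
    """
    total = 0.0
    logfacN = gammaln(N + 1)
    for x12 in range(N + 1):
        for x21 in range(N + 1 - x12):
            if z_stat(x12, x21) < z_obs - BOUNDARY_EPS:
                continue
            n = x12 + x21
            log_coef = (
                logfacN - gammaln(x12 + 1) - gammaln(x21 + 1) - gammaln(N - n + 1)
            )
            log_prob = log_coef + n * np.log(p / 2.0) + (N - n) * np.log1p(-p)
            total += np.exp(log_prob)
    return float(total)


def brute_force_unconditional_p(table: PairedTable, p_grid: np.ndarray) -> float:
    """One-sided unconditional p-value by full outcome enumeration.

    Independent of the regrouped fast path: enumerates every outcome
    triplet, keeps those with ``z(x) >= z_obs`` (after reflecting a
    negative observed statistic), and maximises the direct trinomial sum
    over the supplied nuisance-parameter grid.  Restricted to ``N <= 30``
    (oracle scale).
    """
    N = table.N
    if N > 30:
        raise ValueError(f"brute-force oracle limited to N <= 30, got N={N}")
    reflected = table if table.n12 >= table.n21 else table.transpose()
    z_obs = z_stat(reflected.n12, reflected.n21)
    log_coef, n = [], []
    logfacN = gammaln(N + 1)
    for x12 in range(N + 1):
        for x21 in range(N + 1 - x12):
            if z_stat(x12, x21) < z_obs - BOUNDARY_EPS:
                continue
            n.append(x12 + x21)
            log_coef.append(
                logfacN - gammaln(x12 + 1) - gammaln(x21 + 1) - gammaln(N - x12 - x21 + 1)
            )
    log_coef = np.array(log_coef)
    n = np.array(n)
    p = np.asarray(p_grid, dtype=float)[:, None]
    log_prob = log_coef[None, :] + n[None, :] * np.log(p / 2.0) + (N - n)[None, :] * np.log1p(-p)
    return float(np.exp(log_prob).sum(axis=1).max())


__all__ = [
    "BOUNDARY_EPS",
    "DEFAULT_GRID_SIZE",
    "DEFAULT_REFINE_TOL",
    "UnconditionalContext",
    "z_stat",
    "build_region",
    "region_thresholds",
    "region_coeffs_from_index",
    "attained_level",
    "supremum_search",
    "unconditional_one_sided",
    "unconditional_p",
    "trinomial_attained_level",
    "brute_force_unconditional_p",
]
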