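"""The four conditional tests: reference values, conventions, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom, chi2
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from mcnemar import (
    DegenerateTableError,
    PairedTable,
    asymptotic_cc_p,
    asymptotic_p,
    asymptotic_z,
    binom_point_prob,
    exact_conditional_p,
    midp_p,
    random_tables,
    round_half_up,
    run_test,
)

CONDITIONAL_METHODS = ["asymptotic", "asymptotic_cc", "exact_conditional", "midp"]

counts = st.integers(min_value=0, max_value=60)
tables = st.builds(PairedTable, counts, counts, counts, counts)


# ---------------------------------------------------------------------------
# statistic and point probability


def test_asymptotic_z_values():
    assert asymptotic_z(PairedTable(1, 1, 7, 12)) == pytest.approx(-6 / np.sqrt(8))
    assert asymptotic_z(PairedTable(0, 5, 5, 0)) == 0.0
    assert asymptotic_z(PairedTable(0, 16, 6, 0)) == pytest.approx(10 / np.sqrt(22))


def test_asymptotic_z_undefined_without_discordant_pairs():
    with pytest.raises(DegenerateTableError):
        asymptotic_z(PairedTable(4, 0, 0, 6))


@pytest.mark.parametrize(
    "x12, n, expected",
    [(1, 8, 8 / 256), (0, 0, 1.0), (6, 22, 74613 / 4194304)],
)
def test_binom_point_prob(x12, n, expected):
    assert binom_point_prob(x12, n) == pytest.approx(expected, abs=1e-15)


def test_binom_point_prob_domain_error():
    with pytest.raises(ValueError):
        binom_point_prob(5, 4)


def test_binom_point_prob_stable_at_large_n():
    # C(200, 100) / 2^200: far below naive 2^-200 underflow if terms
    # were multiplied one by one
    assert binom_point_prob(100, 200) == pytest.approx(0.0563484, rel=1e-5)


# ---------------------------------------------------------------------------
# reference p-values for the two published studies


@pytest.mark.parametrize(
    "method, p_bentur, p_cavo",
    [
        ("asymptotic", 0.0339, 0.0330),
        ("asymptotic_cc", 0.0771, 0.0550),
        ("exact_conditional", 0.0703, 0.0525),
        ("midp", 0.0391, 0.0347),
    ],
)
def test_reference_pvalues(bentur, cavo, method, p_bentur, p_cavo):
    assert round_half_up(run_test(bentur, method).p_two_sided, 4) == p_bentur
    assert round_half_up(run_test(cavo, method).p_two_sided, 4) == p_cavo


# ---------------------------------------------------------------------------
# degenerate and tie conventions


def test_degenerate_table_conventions():
    table = PairedTable(4, 0, 0, 6)
    asym = asymptotic_p(table)
    cc = asymptotic_cc_p(table)
    assert asym.p_two_sided == 1.0 and asym.degenerate
    assert cc.p_two_sided == 1.0 and cc.degenerate
    assert exact_conditional_p(table).p_two_sided == 1.0
    assert midp_p(table).p_two_sided == 0.5


def test_tie_conventions():
    table = PairedTable(0, 3, 3, 0)
    assert asymptotic_cc_p(table).p_two_sided == 1.0
    assert exact_conditional_p(PairedTable(0, 4, 4, 0)).p_two_sided == 1.0
    # mid-p at a tie: 1 - f(n12|n)/2
    f = binom_point_prob(3, 6)
    assert midp_p(table).p_two_sided == pytest.approx(1.0 - f / 2)


def test_chi_squared_form_is_equivalent():
    # the normal two-sided p equals the upper chi2(1) tail of z^2
    for table in random_tables(30, Nmax=60, seed=7):
        if table.n == 0:
            continue
        z = asymptotic_z(table)
        assert asymptotic_p(table).p_two_sided == pytest.approx(
            chi2.sf(z**2, df=1), abs=1e-12
        )


# ---------------------------------------------------------------------------
# independent oracles


def test_exact_one_sided_matches_brute_force_tail_sum():
    # lower-tail sum of binomial point probabilities, all n <= 25
    for n12 in range(26):
        for n21 in range(26 - n12):
            table = PairedTable(0, n12, n21, 0)
            expected = sum(
                binom_point_prob(x, n12 + n21) for x in range(min(n12, n21) + 1)
            )
            res = exact_conditional_p(table)
            assert res.p_one_sided == pytest.approx(expected, abs=1e-12)


def test_against_statsmodels():
    for table in random_tables(40, Nmax=80, seed=11):
        if table.n == 0:
            continue  # statsmodels returns nan for the degenerate table
        sm = [[table.n11, table.n12], [table.n21, table.n22]]
        assert asymptotic_p(table).p_two_sided == pytest.approx(
            sm_mcnemar(sm, exact=False, correction=False).pvalue, abs=1e-12
        )
        if table.n12 != table.n21:
            # at a tie statsmodels squares the corrected numerator (-1)
            # instead of clamping it at zero, manufacturing evidence
            # from a perfectly balanced table; conventions agree
            # everywhere else
            assert asymptotic_cc_p(table).p_two_sided == pytest.approx(
                sm_mcnemar(sm, exact=False, correction=True).pvalue, abs=1e-12
            )
        assert exact_conditional_p(table).p_two_sided == pytest.approx(
            sm_mcnemar(sm, exact=True).pvalue, abs=1e-12
        )


# ---------------------------------------------------------------------------
# structural properties


@settings(max_examples=200, deadline=None)
@given(tables)
def test_pvalue_contracts(table):
    results = {m: run_test(table, m) for m in CONDITIONAL_METHODS}
    for res in results.values():
        assert 0.0 < res.p_two_sided <= 1.0
        if res.p_one_sided is not None:
            assert res.p_two_sided == pytest.approx(
                min(1.0, 2.0 * res.p_one_sided), abs=1e-12
            )
    # continuity correction can only increase the p-value
    assert (
        results["asymptotic_cc"].p_two_sided
        >= results["asymptotic"].p_two_sided - 1e-12
    )
    # mid-p is smaller than exact conditional, by exactly the point
    # probability when there is no tie
    exact = results["exact_conditional"].p_two_sided
    midp = results["midp"].p_two_sided
    assert midp < exact
    if table.n12 != table.n21:
        f = binom_point_prob(table.n12, table.n)
        assert exact - midp == pytest.approx(f, abs=1e-12)


@settings(max_examples=100, deadline=None)
@given(tables)
def test_symmetry_and_concordant_invariance(table):
    swapped = table.transpose()
    shifted = PairedTable(table.n11 + 3, table.n12, table.n21, table.n22 + 5)
    for m in CONDITIONAL_METHODS:
        p = run_test(table, m).p_two_sided
        assert run_test(swapped, m).p_two_sided == pytest.approx(p, abs=1e-12)
        assert run_test(shifted, m).p_two_sided == pytest.approx(p, abs=1e-12)


def test_run_test_rejects_unknown_method(bentur):
    with pytest.raises(ValueError, match="unknown method"):
        run_test(bentur, "fisher")


def test_invalid_table_counts():
    with pytest.raises(ValueError):
        PairedTable(1, -2, 3, 4)
    with pytest.raises(ValueError):
        PairedTable.from_counts([1, 2, 3])
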