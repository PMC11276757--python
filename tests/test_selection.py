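"""pN/pS summaries, the shared-ratio LRT, and the exact tests."""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pytest
from scipy.stats import binom, chi2_contingency, mannwhitneyu

from pnpskit.selection import (
    exact_binomial_test,
    exact_rank_sum_test,
    pnps_lrt,
    pnps_summary,
)


def test_pnps_summary_fields_and_edge_cases():
    s = pnps_summary(10, 40, 3000.0, 1000.0)
    assert s.freq_nonsyn == pytest.approx(10 / 3000)
    assert s.freq_syn == pytest.approx(40 / 1000)
    assert s.freq_overall == pytest.approx(50 / 4000)
    assert s.pnps == pytest.approx((10 / 3000) / (40 / 1000))
    zero_nonsyn = pnps_summary(0, 10, 1000.0, 1000.0)
    assert zero_nonsyn.pnps == 0.0 and zero_nonsyn.freq_nonsyn == 0.0
    assert pnps_summary(5, 0, 1000.0, 1000.0).pnps is None  # missing, not inf
    with pytest.raises(ValueError):
        pnps_summary(1, 1, 0.0, 10.0)


def test_pnps_scaling_invariances():
    s = pnps_summary(7, 21, 500.0, 300.0)
    scaled = pnps_summary(7, 21, 500.0 * 3.7, 300.0 * 3.7)
    assert scaled.pnps == pytest.approx(s.pnps)
    nonsyn_scaled = pnps_summary(7, 21, 500.0 * 2.0, 300.0)
    assert nonsyn_scaled.pnps == pytest.approx(s.pnps / 2.0)


# -- likelihood-ratio test ---------------------------------------------------


def _grid_oracle_chi2(a, b):
    """Independent oracle: dense grid search over the shared log-ratio."""

    def ll(r, c):
        n_nonsyn, n_syn, s_n, s_s = c
        pi = r * s_n / (r * s_n + s_s)
        return float(binom.logpmf(n_nonsyn, n_nonsyn + n_syn, pi))

    r_a = (a[0] / a[2]) / (a[1] / a[3])
    r_b = (b[0] / b[2]) / (b[1] / b[3])
    alt = ll(r_a, a) + ll(r_b, b)
    grid = np.exp(np.linspace(np.log(min(r_a, r_b)) - 2, np.log(max(r_a, r_b)) + 2, 200001))
    null = max(ll(r, a) + ll(r, b) for r in grid)
    return 2 * (alt - null)


def test_lrt_toy_example_matches_grid_oracle():
    a, b = (5, 5, 1000.0, 1000.0), (1, 9, 1000.0, 1000.0)
    res = pnps_lrt(a, b)
    assert res.chi2 == pytest.approx(4.070, abs=1e-3)
    assert res.chi2 == pytest.approx(_grid_oracle_chi2(a, b), abs=1e-6)
    assert res.df == 1 and 0 < res.p_value < 0.05


def test_lrt_identical_counts_give_zero():
    c = (30, 90, 5000.0, 2000.0)
    res = pnps_lrt(c, c)
    assert res.chi2 == pytest.approx(0.0, abs=1e-8)
    assert res.p_value == pytest.approx(1.0, abs=1e-4)
    assert res.ratio_shared_mle == pytest.approx(res.ratio_a_mle, rel=1e-6)


def test_lrt_invariant_under_joint_site_rescaling():
    a, b = (12, 17, 1000.0, 400.0), (40, 120, 900.0, 300.0)
    res = pnps_lrt(a, b)
    scaled = pnps_lrt((12, 17, 5000.0, 2000.0), b)
    assert scaled.chi2 == pytest.approx(res.chi2, abs=1e-8)


def test_lrt_equals_g_test_when_site_ratios_match():
    """With equal S_N/S_S across classes the LRT is the 2x2 G-test."""
    rng = np.random.default_rng(17)
    for _ in range(10):
        table = rng.integers(5, 200, size=(2, 2))
        a = (int(table[0, 0]), int(table[0, 1]), 3.0, 1.0)
        b = (int(table[1, 0]), int(table[1, 1]), 3.0, 1.0)
        res = pnps_lrt(a, b)
        g, _, _, _ = chi2_contingency(table, correction=False, lambda_="log-likelihood")
        assert res.chi2 == pytest.approx(g, abs=1e-6)


def test_lrt_input_validation():
    good = (5, 5, 100.0, 100.0)
    with pytest.raises(ValueError):
        pnps_lrt(good, (5, 0, 100.0, 100.0))  # no synonymous SNPs
    with pytest.raises(ValueError):
        pnps_lrt(good, (0, 0, 100.0, 100.0))
    with pytest.raises(ValueError):
        pnps_lrt(good, (5, 5, 0.0, 100.0))


# -- exact tests ---------------------------------------------------------------


def _binomial_oracle(k, n):
    pmf = [math.comb(n, x) * 0.5**n for x in range(n + 1)]
    return sum(p for p in pmf if p <= pmf[k] * (1 + 1e-7))


def test_exact_binomial_values():
    assert exact_binomial_test(5, 5).p_value == pytest.approx(1.0)
    assert exact_binomial_test(170, 0).p_value == pytest.approx(2 * 0.5**170, rel=1e-9)
    for k, n in [(7, 11), (3, 10), (0, 6)]:
        assert exact_binomial_test(k, n - k).p_value == pytest.approx(
            _binomial_oracle(k, n), rel=1e-9
        )


def test_exact_binomial_symmetry_and_validation():
    for k1, k2 in [(7, 4), (0, 9), (12, 12)]:
        assert exact_binomial_test(k1, k2).p_value == pytest.approx(
            exact_binomial_test(k2, k1).p_value
        )
    with pytest.raises(ValueError):
        exact_binomial_test(1, 1, p0=1.5)
    with pytest.raises(ValueError):
        exact_binomial_test(0, 0)


def _rank_sum_oracle(a, b):
    """Independent enumeration of 2*min tail probabilities of U."""
    n_a = len(a)
    combined = sorted(a + b)
    ranks_a = [combined.index(v) + 1 for v in a]
    u = sum(ranks_a) - n_a * (n_a + 1) / 2
    dist = [
        sum(s) - n_a * (n_a + 1) / 2
        for s in combinations(range(1, len(combined) + 1), n_a)
    ]
    p_le = sum(x <= u for x in dist) / len(dist)
    p_ge = sum(x >= u for x in dist) / len(dist)
    return min(1.0, 2 * min(p_le, p_ge))


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ([1, 2], [3, 4], 1 / 3),
        ([1, 3], [2, 4], 2 / 3),
    ],
)
def test_rank_sum_small_enumerations(a, b, expected):
    res = exact_rank_sum_test(a, b)
    assert res.p_value == pytest.approx(expected)
    assert res.p_value == pytest.approx(_rank_sum_oracle(a, b))


def test_rank_sum_agrees_with_scipy_exact():
    rng = np.random.default_rng(5)
    for _ in range(20):
        a = list(rng.normal(size=int(rng.integers(2, 6))))
        b = list(rng.normal(size=int(rng.integers(2, 6))))
        mine = exact_rank_sum_test(a, b).p_value
        ref = mannwhitneyu(a, b, method="exact").pvalue
        assert mine == pytest.approx(ref, rel=1e-9)


def test_rank_sum_monotone_transform_invariance_and_ties():
    a, b = [0.1, 0.4, 0.9], [0.2, 0.3, 0.8]
    base = exact_rank_sum_test(a, b).p_value
    assert exact_rank_sum_test(
        [math.exp(5 * x) for x in a], [math.exp(5 * x) for x in b]
    ).p_value == pytest.approx(base)
    with pytest.raises(ValueError, match="tie"):
        exact_rank_sum_test([1.0, 2.0], [2.0, 3.0])


# -- hypothesis property checks ------------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    n_nonsyn=st.integers(0, 500),
    n_syn=st.integers(1, 500),
    sites=st.tuples(
        st.floats(1.0, 1e7, allow_nan=False), st.floats(1.0, 1e7, allow_nan=False)
    ),
    scale=st.floats(1e-3, 1e3, allow_nan=False),
)
def test_pnps_invariant_under_joint_site_scaling(n_nonsyn, n_syn, sites, scale):
    s_n, s_s = sites
    base = pnps_summary(n_nonsyn, n_syn, s_n, s_s)
    scaled = pnps_summary(n_nonsyn, n_syn, s_n * scale, s_s * scale)
    assert scaled.pnps == pytest.approx(base.pnps, rel=1e-9)
    assert scaled.freq_nonsyn == pytest.approx(base.freq_nonsyn / scale, rel=1e-9)
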