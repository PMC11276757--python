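"""The statistical core: pN/pS summaries and hypothesis tests.

pN/pS is the nonsynonymous SNP rate (SNPs per covered nonsynonymous site)
divided by the synonymous rate; values well below 1 indicate purifying
selection, and the contrast of interest is whether pN/pS differs between SNP
classes (e.g. recent mutations in a clonal lineage vs. low-frequency variants
in a sexual one).

The class contrast is a likelihood-ratio test under a conditional binomial
model: within each class, given the total SNP count n = nN + nS, the
nonsynonymous count is Binomial(n, pi(r)) with

    pi(r) = r * S_N / (r * S_N + S_S),

where S_N and S_S are the covered-site totals acting as exposures and
r = pN/pS.  This is the conditional form of a two-Poisson exposure model with
the synonymous rate profiled out; the alternative fits one r per class
(closed form r_hat = (nN/S_N)/(nS/S_S)), the null a shared r (1-D numeric
maximisation on the log scale), and 2*(delta log-likelihood) is referred to
chi-square with 1 df.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import binom, binomtest, chi2


@dataclass
class PnPsSummary:
    """SNP counts, covered-site denominators and the derived rates."""

    n_nonsyn: int
    n_syn: int
    sites_nonsyn: float
    sites_syn: float

    @property
    def freq_nonsyn(self) -> float:
        return self.n_nonsyn / self.sites_nonsyn

    @property
    def freq_syn(self) -> float:
        return self.n_syn / self.sites_syn

    @property
    def freq_overall(self) -> float:
        return (self.n_nonsyn + self.n_syn) / (self.sites_nonsyn + self.sites_syn)

    @property
    def pnps(self) -> float | None:
        """pN/pS; None (missing) when no synonymous SNPs were observed."""
        if self.n_syn == 0:
            return None
        return self.freq_nonsyn / self.freq_syn


@dataclass
class LrtResult:
    ratio_shared_mle: float
    ratio_a_mle: float
    ratio_b_mle: float
    loglik_null: float
    loglik_alt: float
    chi2: float
    df: int
    p_value: float


@dataclass
class ExactTestResult:
    statistic: float
    p_value: float
    method: str


def pnps_summary(
    n_nonsyn: int, n_syn: int, sites_nonsyn: float, sites_syn: float
) -> PnPsSummary:
    if sites_nonsyn <= 0 or sites_syn <= 0:
        raise ValueError("covered-site totals must be positive")
    if n_nonsyn < 0 or n_syn < 0:
        raise ValueError("SNP counts must be non-negative")
    return PnPsSummary(n_nonsyn, n_syn, sites_nonsyn, sites_syn)


Counts = tuple[int, int, float, float]  # (nN, nS, S_N, S_S)


def _loglik(r: float, counts: Counts) -> float:
    n_nonsyn, n_syn, s_n, s_s = counts
    n = n_nonsyn + n_syn
    pi = r * s_n / (r * s_n + s_s)
    return float(binom.logpmf(n_nonsyn, n, pi))


def pnps_lrt(counts_a: Counts, counts_b: Counts) -> LrtResult:
    """LRT of a shared vs separate pN/pS ratio between two SNP classes."""
    for c in (counts_a, counts_b):
        n_nonsyn, n_syn, s_n, s_s = c
        if s_n <= 0 or s_s <= 0:
            raise ValueError("site totals must be positive")
        if n_nonsyn < 0 or n_syn < 0 or n_nonsyn + n_syn == 0:
            raise ValueError("each class needs at least one SNP")
        if n_syn == 0:
            raise ValueError("no synonymous SNPs: ratio unidentifiable")
    r_a = (counts_a[0] / counts_a[2]) / (counts_a[1] / counts_a[3])
    r_b = (counts_b[0] / counts_b[2]) / (counts_b[1] / counts_b[3])
    loglik_alt = _loglik(r_a, counts_a) + _loglik(r_b, counts_b) if r_a > 0 and r_b > 0 else (
        _loglik(max(r_a, 1e-300), counts_a) + _loglik(max(r_b, 1e-300), counts_b)
    )
    # shared-ratio MLE: 1-D bounded search on log r, bracketing both per-class MLEs
    lo = math.log(max(min(r_a, r_b), 1e-12)) - 5.0
    hi = math.log(max(r_a, r_b, 1e-12)) + 5.0
    res = minimize_scalar(
        lambda lr: -(_loglik(math.exp(lr), counts_a) + _loglik(math.exp(lr), counts_b)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-12},
    )
    r_shared = math.exp(res.x)
    loglik_null = -float(res.fun)
    stat = max(0.0, 2.0 * (loglik_alt - loglik_null))
    return LrtResult(
        ratio_shared_mle=r_shared,
        ratio_a_mle=r_a,
        ratio_b_mle=r_b,
        loglik_null=loglik_null,
        loglik_alt=loglik_alt,
        chi2=stat,
        df=1,
        p_value=float(chi2.sf(stat, 1)),
    )


def exact_binomial_test(k_female: int, k_male: int, p0: float = 0.5) -> ExactTestResult:
    """Two-sided exact binomial test of a count pair against proportion p0.

    Two-sided p sums P(X = x) over outcomes no more likely than the observed
    one (minimum-likelihood rule).
    """
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    n = k_female + k_male
    if n < 1:
        raise ValueError("need at least one observation")
    p = binomtest(k_female, n, p0).pvalue
    return ExactTestResult(statistic=float(k_female), p_value=float(p), method="exact binomial")


def exact_rank_sum_test(
    values_a: Sequence[float], values_b: Sequence[float], max_enumeration: int = 2_000_000
) -> ExactTestResult:
    """Exact two-sample Mann-Whitney test by full enumeration.

    The null distribution of U is built over all C(nA+nB, nA) group
    assignments of the observed ranks; two-sided p = 2*min(P(U <= u),
    P(U >= u)), capped at 1.  Tied values across the two groups are an error
    (the exact distribution assumes distinct ranks; large-sample tie handling
    is out of scope).
    """
    a = list(values_a)
    b = list(values_b)
    if not a or not b:
        raise ValueError("both groups need at least one value")
    combined = a + b
    if len(set(combined)) != len(combined):
        raise ValueError(
            "tied values: the exact enumeration requires distinct values "
            "(a large-sample tie-corrected test is out of scope)"
        )
    n_a, n = len(a), len(combined)
    if math.comb(n, n_a) > max_enumeration:
        raise ValueError("sample too large for exact enumeration")
    order = sorted(range(n), key=combined.__getitem__)
    ranks = [0] * n
    for rank, idx in enumerate(order, start=1):
        ranks[idx] = rank
    u_obs = sum(ranks[:n_a]) - n_a * (n_a + 1) // 2
    u_null = [
        sum(subset) - n_a * (n_a + 1) // 2
        for subset in combinations(range(1, n + 1), n_a)
    ]
    total = len(u_null)
    p_le = sum(u <= u_obs for u in u_null) / total
    p_ge = sum(u >= u_obs for u in u_null) / total
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return ExactTestResult(statistic=float(u_obs), p_value=p, method="exact Mann-Whitney U")
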