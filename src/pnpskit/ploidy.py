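"""Allele-balance profiles and diploid/triploid inference.

At a heterozygous SNP the fraction of reads carrying the reference allele has
expectation 1/2 in a diploid but 1/3 or 2/3 in a triploid (one or two of three
copies).  Ploidy is called by comparing the total log-likelihood of the read
counts under Binomial(n, 1/2) against a symmetric two-component mixture
(1/2)·Binomial(n, 1/3) + (1/2)·Binomial(n, 2/3), a deterministic stand-in for
inspecting the allele-balance histogram's peak structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import binom

from .io import SampleRecord, VariantRecord

logger = logging.getLogger(__name__)


@dataclass
class AlleleBalanceProfile:
    sample_id: str
    balances: list[float]
    bin_edges: np.ndarray
    bin_counts: np.ndarray
    loglik_diploid: float
    loglik_triploid: float
    inferred_ploidy: str  # "diploid" | "triploid" | "undetermined"


def het_allele_balances(
    variants: Iterable[VariantRecord], sample: SampleRecord | str
) -> list[float]:
    """Reference-read fractions at the sample's biallelic heterozygous sites."""
    fractions = []
    for r, a in het_read_counts(variants, sample):
        fractions.append(r / (r + a))
    return fractions


def het_read_counts(
    variants: Iterable[VariantRecord], sample: SampleRecord | str
) -> list[tuple[int, int]]:
    """(ref reads, alt reads) at biallelic heterozygous sites of one sample."""
    sid = sample.sample_id if isinstance(sample, SampleRecord) else sample
    out = []
    for v in variants:
        if not v.is_biallelic or v.involves_allele_above(1):
            continue
        call = v.calls.get(sid)
        if call is None or not call.is_het():
            continue
        ref, alt = call.allele_depths[0], call.allele_depths[1]
        if ref + alt == 0:
            logger.warning(
                "zero allele-depth sum for %s at %s:%d; site skipped",
                sid, v.transcript_id, v.position,
            )
            continue
        out.append((ref, alt))
    return out


def balance_histogram(
    balances: Sequence[float], bin_width: float = 0.02
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of balances on fixed [0, 1] bins, right-open except the last."""
    edges = np.linspace(0.0, 1.0, int(round(1.0 / bin_width)) + 1)
    counts, _ = np.histogram(balances, bins=edges)
    return edges, counts


def ploidy_loglikelihoods(read_counts: Sequence[tuple[int, int]]) -> tuple[float, float]:
    """(diploid, triploid) log-likelihoods of het-site reference read counts."""
    if not read_counts:
        return 0.0, 0.0
    r = np.array([c[0] for c in read_counts])
    n = np.array([c[0] + c[1] for c in read_counts])
    ll2 = float(binom.logpmf(r, n, 0.5).sum())
    ll3 = float(
        np.logaddexp(
            np.log(0.5) + binom.logpmf(r, n, 1.0 / 3.0),
            np.log(0.5) + binom.logpmf(r, n, 2.0 / 3.0),
        ).sum()
    )
    return ll2, ll3


def infer_ploidy(
    variants: Iterable[VariantRecord],
    sample: SampleRecord | str,
    min_sites: int = 100,
    bin_width: float = 0.02,
) -> AlleleBalanceProfile:
    """Call diploid vs triploid from allele balance at heterozygous SNPs.

    Returns ``undetermined`` (not an error) below ``min_sites`` heterozygous
    sites.
    """
    sid = sample.sample_id if isinstance(sample, SampleRecord) else sample
    counts = het_read_counts(variants, sample)
    balances = [r / (r + a) for r, a in counts]
    edges, hist = balance_histogram(balances, bin_width)
    ll2, ll3 = ploidy_loglikelihoods(counts)
    if len(counts) < min_sites:
        call = "undetermined"
    else:
        call = "triploid" if ll3 > ll2 else "diploid"
    return AlleleBalanceProfile(sid, balances, edges, hist, ll2, ll3, call)
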