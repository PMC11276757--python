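"""Pairwise dN/dS by Nei-Gojobori (1986) counting with Jukes-Cantor correction.

A deliberately simple, exactly verifiable codon-counting estimator of
between-species divergence: NG86 fractional site counts averaged over the two
sequences, per-codon substitution paths enumerated and averaged for
multi-difference codons (paths through stop codons are allowed, with any step
touching a stop counted nonsynonymous), and the proportions corrected with
d = -(3/4) ln(1 - 4p/3).  It makes none of the rate-matrix or codon-frequency
refinements of maximum-likelihood codon models and is intended for
simulator-scale analyses, not for publication-grade divergence estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

from .codon import GENETIC_CODE, STOP, ng86_codon_sites

_BASES = frozenset("ACGT")


@dataclass
class DnDsResult:
    syn_sites_mean: float
    nonsyn_sites_mean: float
    syn_diffs: float
    nonsyn_diffs: float

    @property
    def ps_prop(self) -> float:
        return self.syn_diffs / self.syn_sites_mean

    @property
    def pn_prop(self) -> float:
        return self.nonsyn_diffs / self.nonsyn_sites_mean

    @property
    def ds(self) -> float | None:
        return jukes_cantor(self.ps_prop)

    @property
    def dn(self) -> float | None:
        return jukes_cantor(self.pn_prop)

    @property
    def dnds(self) -> float | None:
        ds, dn = self.ds, self.dn
        if ds is None or dn is None or ds == 0:
            return None
        return dn / ds


def jukes_cantor(p: float) -> float | None:
    """JC69 distance; None when p >= 3/4 (correction undefined)."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0) + 0.0  # +0.0 avoids -0.0


def _step_is_synonymous(c_from: str, c_to: str) -> bool:
    aa0, aa1 = GENETIC_CODE[c_from], GENETIC_CODE[c_to]
    if aa0 == STOP or aa1 == STOP:
        return False  # stop-touching steps count as nonsynonymous
    return aa0 == aa1


def codon_path_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(syn, nonsyn) differences between two codons, averaged over all
    substitution orderings."""
    diff_pos = [k for k in range(3) if codon_a[k] != codon_b[k]]
    if not diff_pos:
        return 0.0, 0.0
    syn_total = 0.0
    paths = 0
    for order in permutations(diff_pos):
        cur = codon_a
        syn = 0
        for k in order:
            nxt = cur[:k] + codon_b[k] + cur[k + 1 :]
            if _step_is_synonymous(cur, nxt):
                syn += 1
            cur = nxt
        syn_total += syn
        paths += 1
    syn_mean = syn_total / paths
    return syn_mean, len(diff_pos) - syn_mean


def pairwise_dnds(seq_a: str, seq_b: str) -> DnDsResult:
    """NG86 pairwise dN/dS of two aligned, gap-free coding sequences."""
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    if len(seq_a) % 3:
        raise ValueError("length must be a multiple of 3")
    if (set(seq_a) | set(seq_b)) - _BASES:
        raise ValueError("sequences must be gap-free unambiguous nucleotides")
    syn_sites = [0.0, 0.0]
    nonsyn_sites = [0.0, 0.0]
    syn_diffs = 0.0
    nonsyn_diffs = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        for j, c in enumerate((ca, cb)):
            s, n = ng86_codon_sites(c)
            syn_sites[j] += s
            nonsyn_sites[j] += n
        s, n = codon_path_diffs(ca, cb)
        syn_diffs += s
        nonsyn_diffs += n
    return DnDsResult(
        syn_sites_mean=sum(syn_sites) / 2.0,
        nonsyn_sites_mean=sum(nonsyn_sites) / 2.0,
        syn_diffs=syn_diffs,
        nonsyn_diffs=nonsyn_diffs,
    )
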