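"""Genetic-code machinery and Nei-Gojobori (1986) site accounting.

The NG86 scheme assigns each codon position a fractional synonymous-site
weight equal to the fraction of its three possible single-base changes that
preserve the encoded amino acid; the remainder is nonsynonymous.  Summed over
a codon the weights total 3, and over the 61 sense codons of the standard
code they total 183.  Changes that create or destroy a stop codon are counted
as nonsynonymous, both in SNP classification and in site counting.

Covered-site totals — the pN/pS denominators — apply these per-position
weights only at CDS positions whose sequencing depth passes a threshold in
the required sample set, mirroring how SNP numerators are restricted to
confidently genotyped sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import product
from typing import Sequence

import numpy as np
from Bio.Data import CodonTable

from .io import CodingRegion, DepthTable, SampleRecord

_BASES = "ACGT"
STOP = "*"

# standard genetic code, all 64 codons, stops as "*"
_table = CodonTable.unambiguous_dna_by_id[1]
GENETIC_CODE: dict[str, str] = {
    "".join(c): _table.forward_table.get("".join(c), STOP) for c in product(_BASES, repeat=3)
}
SENSE_CODONS: tuple[str, ...] = tuple(c for c, aa in GENETIC_CODE.items() if aa != STOP)
assert len(GENETIC_CODE) == 64 and len(SENSE_CODONS) == 61


class EffectClass(str, Enum):
    synonymous = "synonymous"
    nonsynonymous = "nonsynonymous"
    non_coding = "non_coding"


@dataclass(frozen=True)
class SiteCountResult:
    """NG86 covered-site totals (fractional sites)."""

    covered_nonsyn_sites: float
    covered_syn_sites: float

    @property
    def total(self) -> float:
        return self.covered_nonsyn_sites + self.covered_syn_sites


def translate_codon(codon: str) -> str:
    """Standard-code translation; stop codons return ``"*"``."""
    codon = codon.upper()
    if len(codon) != 3 or set(codon) - set(_BASES):
        raise ValueError(f"not an unambiguous codon: {codon!r}")
    return GENETIC_CODE[codon]


def _position_syn_fraction(codon: str, offset: int) -> float:
    """Fraction of the 3 single-base changes at ``offset`` that are synonymous.

    Changes producing a stop are nonsynonymous by convention.
    """
    aa = GENETIC_CODE[codon]
    syn = 0
    for b in _BASES:
        if b == codon[offset]:
            continue
        mutant = codon[:offset] + b + codon[offset + 1 :]
        if GENETIC_CODE[mutant] == aa and GENETIC_CODE[mutant] != STOP:
            syn += 1
    return syn / 3.0


def ng86_codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous sites, nonsynonymous sites) of a sense codon; totals 3."""
    codon = codon.upper()
    if translate_codon(codon) == STOP:
        raise ValueError(f"stop codon {codon} has no NG86 site decomposition")
    syn = sum(_position_syn_fraction(codon, k) for k in range(3))
    return syn, 3.0 - syn


def classify_substitution(region: CodingRegion, position: int, ref: str, alt: str) -> EffectClass:
    """Effect of a single-base substitution judged against the reference codon."""
    ref, alt = ref.upper(), alt.upper()
    if position < 1 or position > len(region.sequence):
        raise ValueError(f"position {position} outside transcript {region.transcript_id}")
    if region.sequence[position - 1] != ref:
        raise ValueError(
            f"{region.transcript_id}:{position}: reference allele {ref} does not match "
            f"sequence base {region.sequence[position - 1]}"
        )
    if not region.in_cds(position):
        return EffectClass.non_coding
    codon, off = region.codon_at(position)
    mutant = codon[:off] + alt + codon[off + 1 :]
    aa0, aa1 = GENETIC_CODE[codon], GENETIC_CODE[mutant]
    if aa0 == aa1 and aa0 != STOP:
        return EffectClass.synonymous
    if aa0 == aa1 == STOP:
        # both stops: no amino-acid change, but stop-involved => nonsynonymous convention
        return EffectClass.nonsynonymous
    return EffectClass.synonymous if aa0 == aa1 else EffectClass.nonsynonymous


# per-codon, per-position synonymous weights, indexed by codon integer code,
# used to vectorise covered-site totals (stop codons get NaN and are rejected)
_codon_index = {c: 16 * _BASES.index(c[0]) + 4 * _BASES.index(c[1]) + _BASES.index(c[2])
                for c in GENETIC_CODE}
_POS_SYN_W = np.full((64, 3), np.nan)
for _c in SENSE_CODONS:
    for _k in range(3):
        _POS_SYN_W[_codon_index[_c], _k] = _position_syn_fraction(_c, _k)


def position_weights(cds: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-CDS-position (syn, nonsyn) NG86 weights as arrays of length len(cds)."""
    arr = np.frombuffer(cds.encode(), dtype=np.uint8)
    code = np.zeros(len(cds) // 3, dtype=np.int64)
    lut = np.zeros(256, dtype=np.int64)
    for i, b in enumerate(_BASES):
        lut[ord(b)] = i
    idx = lut[arr]
    code = 16 * idx[0::3] + 4 * idx[1::3] + idx[2::3]
    w = _POS_SYN_W[code]  # (n_codons, 3)
    if np.isnan(w).any():
        raise ValueError("CDS contains internal stop codons")
    syn = w.reshape(-1)
    return syn, 1.0 - syn


def covered_site_totals(
    regions: Sequence[CodingRegion],
    depths: DepthTable,
    samples: Sequence[SampleRecord | str],
    mode: str = "per_individual",
    min_depth: int = 20,
) -> SiteCountResult:
    """NG86 site totals over CDS positions passing the depth threshold.

    ``mode="per_individual"`` requires exactly one sample and counts positions
    with depth >= ``min_depth`` in that sample; ``mode="all_individuals"``
    requires the threshold in every listed sample.  Positions absent from the
    depth table count as depth 0.
    """
    ids = [s.sample_id if isinstance(s, SampleRecord) else s for s in samples]
    if mode == "per_individual":
        if len(ids) != 1:
            raise ValueError("per_individual mode requires exactly one sample")
    elif mode != "all_individuals":
        raise ValueError(f"unknown mode {mode!r}")
    syn_total = 0.0
    nonsyn_total = 0.0
    for region in regions:
        syn_w, nonsyn_w = position_weights(region.cds)
        mat = depths.matrix(region.transcript_id, ids, len(region.sequence))
        cds_depths = mat[region.cds_start - 1 : region.cds_end]
        mask = (cds_depths >= min_depth).all(axis=1)
        syn_total += float(syn_w[mask].sum())
        nonsyn_total += float(nonsyn_w[mask].sum())
    return SiteCountResult(covered_nonsyn_sites=nonsyn_total, covered_syn_sites=syn_total)
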