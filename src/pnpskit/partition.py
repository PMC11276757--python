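"""Partition SNPs into the analysis classes used for the selection contrasts.

For a set of triploid clonal adults:

* *candidate novel* — some adults homozygous reference (0/0/0) and the others
  carrying a single derived copy (0/0/1), no other genotype present: the
  pattern a heterozygous mutation arising in one lineage after the origin of
  the clone produces.
* *ancestral identical* — every adult exactly 0/0/1: heterozygosity inherited
  from the hybrid founding of the clone.

For a diploid outcrossing sample set, *low frequency* sites carry exactly one
alternate allele among the 2N sampled alleles (one 0/1 carrier, the rest 0/0).

Pattern matching is strict: any third genotype (e.g. 0/1/1), or a missing
call, disqualifies the site, which keeps genotyping noise out of the novel
class.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .clonality import biallelic_subset
from .io import Role, SampleRecord, VariantRecord

_HOM_REF3 = (0, 0, 0)
_HET3 = (0, 0, 1)
_HOM_REF2 = (0, 0)
_HET2 = (0, 1)


def per_individual_het(
    variants: Iterable[VariantRecord], sample: SampleRecord | str
) -> list[VariantRecord]:
    """Biallelic SNPs at which the sample carries both allele 0 and allele 1."""
    sid = sample.sample_id if isinstance(sample, SampleRecord) else sample
    out = []
    for v in biallelic_subset(variants):
        call = v.calls.get(sid)
        if call is not None and call.is_het():
            out.append(v)
    return out


def _check(samples: Sequence[SampleRecord], ploidy: int, adults_only: bool) -> list[str]:
    for s in samples:
        if s.ploidy != ploidy:
            raise ValueError(f"sample {s.sample_id} has ploidy {s.ploidy}, need {ploidy}")
        if adults_only and s.role != Role.adult:
            raise ValueError(f"sample {s.sample_id} is not an adult")
    return [s.sample_id for s in samples]


def candidate_novel(
    variants: Iterable[VariantRecord], adults: Sequence[SampleRecord]
) -> list[VariantRecord]:
    """Sites with >=1 adult 0/0/0, >=1 adult 0/0/1 and no other genotype."""
    ids = _check(adults, ploidy=3, adults_only=True)
    out = []
    for v in biallelic_subset(variants):
        calls = [v.calls.get(sid) for sid in ids]
        if any(c is None or c.missing for c in calls):
            continue
        gts = [c.allele_indices for c in calls]
        if any(g not in (_HOM_REF3, _HET3) for g in gts):
            continue
        if _HOM_REF3 in gts and _HET3 in gts:
            out.append(v)
    return out


def ancestral_identical(
    variants: Iterable[VariantRecord], adults: Sequence[SampleRecord]
) -> list[VariantRecord]:
    """Sites where every adult is exactly 0/0/1."""
    ids = _check(adults, ploidy=3, adults_only=True)
    out = []
    for v in biallelic_subset(variants):
        calls = [v.calls.get(sid) for sid in ids]
        if any(c is None or c.missing for c in calls):
            continue
        if all(c.allele_indices == _HET3 for c in calls):
            out.append(v)
    return out


def low_frequency(
    variants: Iterable[VariantRecord], samples: Sequence[SampleRecord]
) -> list[VariantRecord]:
    """Sites with a singleton alternate allele: one 0/1 sample, the rest 0/0."""
    ids = _check(samples, ploidy=2, adults_only=False)
    out = []
    for v in biallelic_subset(variants):
        calls = [v.calls.get(sid) for sid in ids]
        if any(c is None or c.missing for c in calls):
            continue
        gts = [c.allele_indices for c in calls]
        if any(g not in (_HOM_REF2, _HET2) for g in gts):
            continue
        if gts.count(_HET2) == 1:
            out.append(v)
    return out
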