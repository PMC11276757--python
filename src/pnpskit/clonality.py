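"""Genotype-identity (clonality) metrics across samples.

In a clonal lineage every individual inherits its mother's genotype, so the
fraction of biallelic SNPs at which a set of individuals share identical
genotypes approaches 1, eroded only by post-divergence mutation and
genotyping error; in an outcrossing population it is far lower.  "Identical"
means equal sorted allele multisets, so a diploid 0/1 and a triploid 0/0/1
are never identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import SampleRecord, VariantRecord


@dataclass
class ClonalitySummary:
    n_biallelic: int
    n_identical: int
    sample_set: tuple[str, ...]
    subset_label: str = "all SNPs"

    @property
    def fraction(self) -> float | None:
        if self.n_biallelic == 0:
            return None
        return self.n_identical / self.n_biallelic

    @property
    def percent(self) -> float | None:
        f = self.fraction
        return None if f is None else round(100.0 * f, 1)


def biallelic_subset(variants: Iterable[VariantRecord]) -> list[VariantRecord]:
    """SNPs with exactly one alternate allele and no call referencing allele >1."""
    return [v for v in variants if v.is_biallelic and not v.involves_allele_above(1)]


def subset_by_markers(
    variants: Iterable[VariantRecord], transcript_ids: Iterable[str]
) -> list[VariantRecord]:
    keep = set(transcript_ids)
    return [v for v in variants if v.transcript_id in keep]


def identity_fraction(
    variants: Iterable[VariantRecord],
    samples: Sequence[SampleRecord | str],
    subset_label: str = "all SNPs",
) -> ClonalitySummary:
    """Fraction of biallelic SNPs at which all listed samples are identical.

    Records with a missing call in any listed sample are dropped from both
    numerator and denominator.
    """
    ids = tuple(s.sample_id if isinstance(s, SampleRecord) else s for s in samples)
    if len(ids) < 2:
        raise ValueError("identity requires at least two samples")
    n_total = 0
    n_identical = 0
    for v in variants:
        calls = [v.calls.get(sid) for sid in ids]
        if any(c is None or c.missing for c in calls):
            continue
        n_total += 1
        first = calls[0].allele_indices
        if all(c.allele_indices == first for c in calls[1:]):
            n_identical += 1
    return ClonalitySummary(n_total, n_identical, ids, subset_label)


def pairwise_identity(
    variants: Iterable[VariantRecord],
    sample_a: SampleRecord | str,
    sample_b: SampleRecord | str,
    subset_label: str = "all SNPs",
) -> ClonalitySummary:
    return identity_fraction(variants, [sample_a, sample_b], subset_label)
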