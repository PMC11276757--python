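"""Reading and writing the pipeline's file formats.

All coordinates are 1-based, inclusive, on the transcript (the reference is a
transcriptome, so no genome-level coordinates exist).  Only single-base SNP
records are accepted from VCF input; indels and MNPs are skipped with a
warning.  Genotypes are stored as sorted allele-index multisets, so the
triploid strings ``0/0/1`` and ``0/1/0`` parse to the same call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


class Role(str, Enum):
    adult = "adult"
    offspring_pool = "offspring_pool"


class Sex(str, Enum):
    female = "female"
    male = "male"
    unknown = "unknown"


@dataclass(frozen=True)
class SampleRecord:
    """One sequenced sample: id, species, ploidy (2 or 3), role and sex."""

    sample_id: str
    species_id: str
    ploidy: int
    role: Role = Role.adult
    sex: Sex = Sex.unknown

    def __post_init__(self) -> None:
        if self.ploidy not in (2, 3):
            raise ValueError(f"ploidy must be 2 or 3, got {self.ploidy} for {self.sample_id}")
        object.__setattr__(self, "role", Role(self.role))
        object.__setattr__(self, "sex", Sex(self.sex))


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's genotype at one site.

    ``allele_indices`` is the sorted multiset of allele indices (0 = reference);
    its length equals the sample's ploidy unless the call is missing, in which
    case it is empty.  ``allele_depths`` is read counts per allele, reference
    first (VCF AD, Number=R).
    """

    allele_indices: tuple[int, ...]
    depth: int = 0
    allele_depths: tuple[int, ...] = ()
    genotype_quality: float = 0.0
    missing: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "allele_indices", tuple(sorted(self.allele_indices)))
        object.__setattr__(self, "allele_depths", tuple(int(x) for x in self.allele_depths))
        if sum(self.allele_depths) > self.depth:
            raise ValueError("sum(AD) exceeds DP")

    @classmethod
    def missing_call(cls, n_alleles: int) -> "GenotypeCall":
        return cls((), 0, (0,) * n_alleles, 0.0, missing=True)

    def is_het(self) -> bool:
        """True when the call carries both the reference and allele 1."""
        return (not self.missing) and 0 in self.allele_indices and 1 in self.allele_indices

    def count(self, allele_index: int) -> int:
        return self.allele_indices.count(allele_index)


@dataclass
class VariantRecord:
    """One SNP site with per-sample genotype calls."""

    transcript_id: str
    position: int  # 1-based on the transcript
    ref_allele: str
    alt_alleles: tuple[str, ...]
    site_quality: float
    calls: dict[str, GenotypeCall]

    def __post_init__(self) -> None:
        self.alt_alleles = tuple(self.alt_alleles)
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if not self.alt_alleles:
            raise ValueError("alt_alleles must be non-empty")
        if self.ref_allele in self.alt_alleles:
            raise ValueError("alt alleles must differ from the reference allele")

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref_allele,) + self.alt_alleles

    @property
    def is_biallelic(self) -> bool:
        return len(self.alt_alleles) == 1

    def involves_allele_above(self, max_index: int) -> bool:
        return any(
            i > max_index for c in self.calls.values() for i in c.allele_indices
        )


@dataclass
class CodingRegion:
    """A transcript with its CDS interval (1-based, inclusive, in frame)."""

    transcript_id: str
    sequence: str
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        n = self.cds_end - self.cds_start + 1
        if n <= 0 or n % 3:
            raise ValueError(
                f"{self.transcript_id}: CDS length {n} is not a positive multiple of 3"
            )
        if self.cds_start < 1 or self.cds_end > len(self.sequence):
            raise ValueError(f"{self.transcript_id}: CDS exceeds sequence bounds")
        if set(self.cds) - _BASES:
            raise ValueError(f"{self.transcript_id}: ambiguity codes inside the CDS")

    @property
    def cds(self) -> str:
        return self.sequence[self.cds_start - 1 : self.cds_end]

    @property
    def n_codons(self) -> int:
        return len(self.cds) // 3

    def in_cds(self, position: int) -> bool:
        return self.cds_start <= position <= self.cds_end

    def codon_at(self, position: int) -> tuple[str, int]:
        """Reference codon containing ``position`` and the 0-based offset within it."""
        if not self.in_cds(position):
            raise ValueError(f"position {position} outside CDS of {self.transcript_id}")
        off = (position - self.cds_start) % 3
        start = position - off
        return self.sequence[start - 1 : start + 2], off


class DepthTable:
    """Per-base sequencing depth, (transcript, position) x sample.

    Backed by a DataFrame with columns ``transcript_id``, ``position`` and one
    integer column per sample.  Positions absent from the table are depth 0.
    """

    def __init__(self, df: pd.DataFrame):
        if not {"transcript_id", "position"} <= set(df.columns):
            raise ValueError("depth table needs transcript_id and position columns")
        self.df = df
        self._by_transcript: dict[str, pd.DataFrame] | None = None

    @property
    def samples(self) -> list[str]:
        return [c for c in self.df.columns if c not in ("transcript_id", "position")]

    @classmethod
    def read(cls, path: str | Path) -> "DepthTable":
        return cls(pd.read_csv(path, sep="\t"))

    def write(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    def _groups(self) -> dict[str, pd.DataFrame]:
        if self._by_transcript is None:
            self._by_transcript = {k: g for k, g in self.df.groupby("transcript_id", sort=False)}
        return self._by_transcript

    def depth(self, transcript_id: str, position: int, sample_id: str) -> int:
        g = self._groups().get(transcript_id)
        if g is None:
            return 0
        hit = g.loc[g["position"] == position, sample_id]
        return int(hit.iloc[0]) if len(hit) else 0

    def matrix(self, transcript_id: str, sample_ids: Sequence[str], length: int) -> np.ndarray:
        """Depths for positions 1..length (rows) x sample_ids (cols); absent = 0."""
        out = np.zeros((length, len(sample_ids)), dtype=np.int64)
        g = self._groups().get(transcript_id)
        if g is None:
            return out
        pos = g["position"].to_numpy()
        ok = (pos >= 1) & (pos <= length)
        idx = pos[ok] - 1
        for j, s in enumerate(sample_ids):
            out[idx, j] = g[s].to_numpy()[ok]
        return out


# ---------------------------------------------------------------------------
# sample sheet


def read_sample_sheet(path: str | Path) -> list[SampleRecord]:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "species_id", "ploidy", "role", "sex"}
    if not required <= set(df.columns):
        raise ValueError(f"sample sheet missing columns: {sorted(required - set(df.columns))}")
    records = [
        SampleRecord(str(r.sample_id), str(r.species_id), int(r.ploidy), str(r.role), str(r.sex))
        for r in df.itertuples()
    ]
    ids = [r.sample_id for r in records]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate sample_id in sample sheet")
    return records


def write_sample_sheet(samples: Sequence[SampleRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "species_id": s.species_id,
                "ploidy": s.ploidy,
                "role": s.role.value,
                "sex": s.sex.value,
            }
            for s in samples
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: str | Path, samples: Sequence[SampleRecord]) -> list[VariantRecord]:
    """Parse a VCF into VariantRecords, enforcing per-sample ploidy.

    Only single-base SNP records are kept (indels/MNPs are skipped with a
    warning).  A genotype whose arity differs from the sample sheet's declared
    ploidy is a hard error; ``./.``-style genotypes (any arity) are missing.
    """
    by_id = {s.sample_id: s for s in samples}
    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        vcf_samples = list(vf.header.samples)
        unknown = set(vcf_samples) - set(by_id)
        if unknown:
            raise ValueError(f"VCF contains samples absent from the sample sheet: {sorted(unknown)}")
        for rec in vf:
            alts = tuple(rec.alts or ())
            if len(rec.ref) != 1 or rec.ref not in _BASES or not alts or any(
                len(a) != 1 or a not in _BASES for a in alts
            ):
                logger.warning("skipping non-SNP record at %s:%s", rec.contig, rec.pos)
                continue
            calls: dict[str, GenotypeCall] = {}
            n_alleles = 1 + len(alts)
            for sid in vcf_samples:
                sm = rec.samples[sid]
                gt = sm.get("GT")
                if gt is None or all(a is None for a in gt):
                    calls[sid] = GenotypeCall.missing_call(n_alleles)
                    continue
                if any(a is None for a in gt):
                    calls[sid] = GenotypeCall.missing_call(n_alleles)
                    continue
                ploidy = by_id[sid].ploidy
                if len(gt) != ploidy:
                    raise ValueError(
                        f"sample {sid} at {rec.contig}:{rec.pos}: genotype arity "
                        f"{len(gt)} != declared ploidy {ploidy}"
                    )
                ad = sm.get("AD")
                ad = tuple(int(x) for x in ad) if ad is not None else (0,) * n_alleles
                dp = int(sm.get("DP") or 0)
                gq = float(sm.get("GQ") or 0)
                calls[sid] = GenotypeCall(tuple(gt), dp, ad, gq)
            out.append(
                VariantRecord(
                    transcript_id=rec.contig,
                    position=rec.pos,
                    ref_allele=rec.ref,
                    alt_alleles=alts,
                    site_quality=float(rec.qual) if rec.qual is not None else 0.0,
                    calls=calls,
                )
            )
    return out


def write_vcf(
    variants: Iterable[VariantRecord],
    samples: Sequence[SampleRecord],
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write records as uncompressed VCF 4.2 with GT:DP:AD:GQ.

    Genotypes are rendered in sorted canonical form; records are ordered by
    (transcript_id, position).
    """
    variants = sorted(variants, key=lambda v: (v.transcript_id, v.position))
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele read depths">')
    header.add_line('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">')
    contigs: dict[str, int] = dict(contig_lengths or {})
    for v in variants:
        contigs[v.transcript_id] = max(contigs.get(v.transcript_id, 0), v.position)
    for name in sorted(contigs):
        header.add_line(f"##contig=<ID={name},length={contigs[name]}>")
    for s in samples:
        header.add_sample(s.sample_id)
    by_id = {s.sample_id: s for s in samples}
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for v in variants:
            rec = vf.new_record(
                contig=v.transcript_id,
                start=v.position - 1,
                stop=v.position,
                alleles=v.alleles,
                qual=v.site_quality,
            )
            for s in samples:
                call = v.calls.get(s.sample_id)
                sm = rec.samples[s.sample_id]
                if call is None or call.missing:
                    sm["GT"] = (None,) * by_id[s.sample_id].ploidy
                else:
                    sm["GT"] = call.allele_indices
                    sm["DP"] = call.depth
                    sm["AD"] = call.allele_depths
                    sm["GQ"] = int(round(call.genotype_quality))
            vf.write(rec)


# ---------------------------------------------------------------------------
# CDS FASTA + coordinate table


def read_cds(fasta: str | Path, cds_table: str | Path) -> list[CodingRegion]:
    """Join a transcript FASTA with a 3-column CDS coordinate TSV.

    Transcripts present in the FASTA but absent from the table are skipped with
    a warning; a table row whose transcript is missing from the FASTA is an
    error, as are out-of-frame or out-of-bounds coordinates.
    """
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")}
    tab = pd.read_csv(cds_table, sep="\t", header=None, dtype=str, comment="#")
    if tab.shape[1] < 3:
        raise ValueError("CDS table must have 3 columns: transcript_id, cds_start, cds_end")
    # header row is optional: drop it if the coordinate columns are not numeric
    first = tab.iloc[0]
    if not (str(first[1]).isdigit() and str(first[2]).isdigit()):
        tab = tab.iloc[1:]
    regions = []
    listed = set()
    for row in tab.itertuples(index=False):
        tid, start, end = str(row[0]), int(row[1]), int(row[2])
        listed.add(tid)
        if tid not in seqs:
            raise ValueError(f"CDS table transcript {tid} not in FASTA")
        regions.append(CodingRegion(tid, seqs[tid], start, end))
    for tid in seqs.keys() - listed:
        logger.warning("transcript %s has no CDS table entry; skipped", tid)
    return regions


def write_cds(regions: Sequence[CodingRegion], fasta: str | Path, cds_table: str | Path) -> None:
    with open(fasta, "w") as fh:
        for r in regions:
            fh.write(f">{r.transcript_id}\n{r.sequence}\n")
    with open(cds_table, "w") as fh:
        fh.write("transcript_id\tcds_start\tcds_end\n")
        for r in regions:
            fh.write(f"{r.transcript_id}\t{r.cds_start}\t{r.cds_end}\n")


# ---------------------------------------------------------------------------
# genotype-level quality filters


def apply_quality_filters(
    variants: Iterable[VariantRecord],
    sample_ids: Sequence[str] | None = None,
    min_depth: int = 20,
    min_gq: float = 30.0,
    min_site_qual: float = 30.0,
) -> list[VariantRecord]:
    """Retain sites genotyped confidently in every listed sample.

    A record passes iff its site quality is >= ``min_site_qual`` and every
    listed sample's call is present with DP >= ``min_depth`` and
    GQ >= ``min_gq`` (thresholds inclusive; missing calls fail).  The input is
    not modified.
    """
    out = []
    for v in variants:
        if v.site_quality < min_site_qual:
            continue
        ids = sample_ids if sample_ids is not None else list(v.calls)
        ok = True
        for sid in ids:
            c = v.calls.get(sid)
            if c is None or c.missing or c.depth < min_depth or c.genotype_quality < min_gq:
                ok = False
                break
        if ok:
            out.append(v)
    return out
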