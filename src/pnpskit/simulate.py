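"""Synthetic study generator with truth labels.

Emulates the statistical structure of the dataset the analysis assumes:

* an *asexual* species — a triploid apomictic clone set with an AAB hybrid
  karyotype: two progenitor haplotypes A and B diverged at per-site
  probability ``d``, so every individual shares the same dense set of
  ancestral heterozygous sites, plus rare per-individual novel mutations
  (each a single-copy heterozygous change in one adult), with an optional
  pooled-offspring sample that copies its mother's genotypes exactly
  (apomixis);
* a *sexual* species — a diploid outcrossing population with segregating
  SNPs whose alternate-allele counts follow a configurable spectrum and
  whose genotypes are drawn by sampling allele slots without replacement.

Selection is modelled as a retention filter: a proposed nonsynonymous change
survives with probability ``f`` (novel mutations), ``f_ancestral``
(progenitor divergence) or ``f_sexual`` (segregating sites), while synonymous
proposals always survive.  Because proposals are uniform single-base changes,
the expected pN/pS of a class equals its retention probability under NG86
site counting, which is what the recovery tests exploit.

Read support is simulated per call: DP ~ NegativeBinomial(mean_depth,
dispersion) and the reference allele depth ~ Binomial(DP, reference copy
number / ploidy), so triploid heterozygous sites show reference-read
fractions near 1/3 or 2/3 and diploid ones near 1/2.  The transcriptome
"reference" allele at each ancestral site is chosen from the two progenitor
haplotypes with equal probability, mimicking an assembler's arbitrary choice
(so both allele-balance peaks appear), without the asymmetric
reference-choice bias real assemblers show.  GQ is a constant stand-in: the
generator tests filter plumbing, not a caller's error model.

Every emitted byte is a deterministic function of the seed.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .codon import GENETIC_CODE, STOP, SENSE_CODONS, classify_substitution, EffectClass
from .io import (
    CodingRegion,
    DepthTable,
    GenotypeCall,
    Role,
    SampleRecord,
    Sex,
    VariantRecord,
    write_cds,
    write_sample_sheet,
    write_vcf,
)

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")


@dataclass
class SimulationConfig:
    """Study conditions for the generator (defaults are the tested conditions)."""

    seed: int = 0
    n_transcripts: int = 2000
    cds_length_codons: int = 150
    progenitor_divergence: float = 0.005  # d: per-site A/B substitution probability
    novel_mut_rate: float = 2e-5  # mu: per haploid CDS site per individual
    nonsyn_retention: float = 0.2  # f: novel nonsynonymous proposals kept
    ancestral_retention: float = 0.1  # f_ancestral
    sexual_retention: float = 0.1  # f_sexual
    sexual_snp_density: float = 0.001  # segregating-site proposals per CDS site
    sexual_alt_freq_spec: tuple[float, ...] | None = None  # probs over alt counts 1..2N-1
    n_adults_asexual: int = 4
    include_offspring_pool: bool = True
    n_samples_sexual: int = 4
    mean_depth: float = 60.0
    depth_dispersion: float = 30.0  # negative-binomial size; inf => Poisson
    gq_constant: float = 60.0
    site_qual: float = 60.0
    asexual_species: str = "triclone"
    sexual_species: str = "dipsex"

    def __post_init__(self) -> None:
        for name in (
            "progenitor_divergence",
            "novel_mut_rate",
            "nonsyn_retention",
            "ancestral_retention",
            "sexual_retention",
            "sexual_snp_density",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class SpeciesData:
    species_id: str
    samples: list[SampleRecord]
    regions: list[CodingRegion]
    variants: list[VariantRecord]
    depth: DepthTable


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    asexual: SpeciesData
    sexual: SpeciesData
    truth: pd.DataFrame

    @property
    def samples(self) -> list[SampleRecord]:
        return self.asexual.samples + self.sexual.samples


# ---------------------------------------------------------------------------
# reference sequences


def generate_reference_cds(
    n_transcripts: int,
    cds_length_codons: int,
    rng: np.random.Generator,
    prefix: str = "t",
) -> list[CodingRegion]:
    """Random in-frame transcripts: ATG + sense codons + a terminal stop.

    The terminal stop sits outside the CDS interval so every counted codon is
    a sense codon.
    """
    non_atg = [c for c in SENSE_CODONS if c != "ATG"]
    regions = []
    for i in range(n_transcripts):
        body = rng.choice(len(non_atg), size=cds_length_codons - 1)
        seq = "ATG" + "".join(non_atg[j] for j in body) + _STOPS[int(rng.integers(3))]
        regions.append(
            CodingRegion(f"{prefix}{i + 1:05d}", seq, 1, 3 * cds_length_codons)
        )
    return regions


def _propose_base(rng: np.random.Generator, current: str) -> str:
    others = [b for b in _BASES if b != current]
    return others[int(rng.integers(3))]


def _effect_vs(seq: str, cds_start: int, local_pos: int, alt: str) -> EffectClass:
    """Effect of ref->alt at 1-based CDS-local position against ``seq``."""
    off = (local_pos - 1) % 3
    start = local_pos - off
    codon = seq[start - 1 : start + 2]
    mutant = codon[:off] + alt + codon[off + 1 :]
    aa0, aa1 = GENETIC_CODE[codon], GENETIC_CODE[mutant]
    if aa0 == aa1 and aa0 != STOP:
        return EffectClass.synonymous
    return EffectClass.nonsynonymous


# ---------------------------------------------------------------------------
# asexual (triploid clone) species


def make_triploid_clone(
    config: SimulationConfig,
    regions: Sequence[CodingRegion],
    rng: np.random.Generator,
) -> tuple[list[CodingRegion], list[dict]]:
    """Derive the AAB clone's ancestral heterozygous sites.

    Haplotype B differs from A at Bernoulli(d) CDS sites; nonsynonymous
    proposals are retained with probability ``ancestral_retention``
    (purifying selection already acted in the sexual progenitors).  Each
    retained difference is an ancestral heterozygous site shared by all
    asexual individuals.  The emitted reference base is drawn from {A allele,
    B allele} with equal probability per site, so the clone's genotype at a
    site is 0/0/1 when the reference is the doubled A allele and 0/1/1 when
    it is the single B allele.
    """
    if config.progenitor_divergence > 0.1:
        raise ValueError("progenitor divergence above 0.1 is outside the modelled regime")
    out_regions: list[CodingRegion] = []
    sites: list[dict] = []
    for region in regions:
        seq_a = region.cds
        n = len(seq_a)
        hits = np.flatnonzero(rng.random(n) < config.progenitor_divergence)
        ref_seq = list(region.sequence)
        region_sites = []
        for idx in hits:
            pos = int(idx) + 1  # CDS starts at 1
            a_base = seq_a[idx]
            b_base = _propose_base(rng, a_base)
            effect = _effect_vs(region.sequence, region.cds_start, pos, b_base)
            if effect is EffectClass.nonsynonymous and rng.random() >= config.ancestral_retention:
                continue
            flip = rng.random() < 0.5  # assembler picks the B allele as reference
            if flip:
                # an ORF-predicted reference never contains internal stops, so
                # a flip that would create one is rejected (A stays reference)
                off = (pos - 1) % 3
                start = pos - off
                codon = "".join(ref_seq[start - 1 : start + 2])
                mutant = codon[:off] + b_base + codon[off + 1 :]
                if GENETIC_CODE[mutant] == STOP:
                    flip = False
            if flip:
                ref_seq[pos - 1] = b_base
                region_sites.append((pos, b_base, a_base, 1))
            else:
                region_sites.append((pos, a_base, b_base, 2))
        new_seq = "".join(ref_seq)
        out_regions.append(
            CodingRegion(region.transcript_id, new_seq, region.cds_start, region.cds_end)
        )
        for pos, ref, alt, ref_copies in region_sites:
            # truth effect re-judged against the final (mosaic) reference codon,
            # which is the context the pipeline classifies against
            effect = _effect_vs(new_seq, 1, pos, alt)
            sites.append(
                dict(
                    transcript_id=region.transcript_id,
                    position=pos,
                    ref=ref,
                    alt=alt,
                    ref_copies=ref_copies,
                    true_class="ancestral_hybrid",
                    true_effect=effect.value,
                )
            )
    return out_regions, sites


def add_novel_mutations(
    config: SimulationConfig,
    regions: Sequence[CodingRegion],
    occupied: set[tuple[str, int]],
    adult_ids: Sequence[str],
    rng: np.random.Generator,
) -> list[dict]:
    """Per-adult heterozygous novel mutations (single derived copy, 0/0/1).

    Each haploid CDS site of each adult mutates with probability ``mu``;
    nonsynonymous proposals are retained with probability
    ``nonsyn_retention``.  Proposals colliding with an occupied site are
    skipped.
    """
    lengths = [len(r.cds) for r in regions]
    total = sum(lengths)
    offsets = np.cumsum([0] + lengths)
    sites: list[dict] = []
    taken = set(occupied)
    for sid in adult_ids:
        n_prop = rng.binomial(3 * total, config.novel_mut_rate)
        for g in rng.integers(0, total, size=n_prop):
            ridx = int(np.searchsorted(offsets, g, side="right")) - 1
            region = regions[ridx]
            pos = int(g - offsets[ridx]) + 1
            key = (region.transcript_id, pos)
            if key in taken:
                continue
            ref = region.sequence[pos - 1]
            alt = _propose_base(rng, ref)
            effect = _effect_vs(region.sequence, 1, pos, alt)
            if effect is EffectClass.nonsynonymous and rng.random() >= config.nonsyn_retention:
                continue
            taken.add(key)
            sites.append(
                dict(
                    transcript_id=region.transcript_id,
                    position=pos,
                    ref=ref,
                    alt=alt,
                    ref_copies=2,
                    true_class="novel",
                    true_effect=effect.value,
                    carrier=sid,
                )
            )
    return sites


# ---------------------------------------------------------------------------
# sexual (diploid outcrossing) species


def make_sexual_population(
    config: SimulationConfig,
    regions: Sequence[CodingRegion],
    sample_ids: Sequence[str],
    rng: np.random.Generator,
) -> list[dict]:
    """Segregating diploid SNPs with a configurable alt-allele-count spectrum."""
    n = len(sample_ids)
    n_alleles = 2 * n
    spec = config.sexual_alt_freq_spec
    if spec is None:
        spec = tuple([1.0 / (n_alleles - 1)] * (n_alleles - 1))
    if len(spec) != n_alleles - 1 or not math.isclose(sum(spec), 1.0, rel_tol=1e-9):
        raise ValueError("sexual_alt_freq_spec must give probabilities for alt counts 1..2N-1")
    sites: list[dict] = []
    for region in regions:
        hits = np.flatnonzero(rng.random(len(region.cds)) < config.sexual_snp_density)
        for idx in hits:
            pos = int(idx) + 1
            ref = region.sequence[pos - 1]
            alt = _propose_base(rng, ref)
            effect = _effect_vs(region.sequence, 1, pos, alt)
            if effect is EffectClass.nonsynonymous and rng.random() >= config.sexual_retention:
                continue
            k = int(rng.choice(np.arange(1, n_alleles), p=np.asarray(spec)))
            # allele slots 0..2N-1; sample i owns slots 2i and 2i+1
            slots = rng.permutation(n_alleles)[:k]
            alt_copies = [int(np.isin(slots, [2 * i, 2 * i + 1]).sum()) for i in range(n)]
            sites.append(
                dict(
                    transcript_id=region.transcript_id,
                    position=pos,
                    ref=ref,
                    alt=alt,
                    alt_copies=tuple(alt_copies),
                    true_class="sexual_segregating",
                    true_effect=effect.value,
                )
            )
    return sites


# ---------------------------------------------------------------------------
# read-count simulation and assembly into records


def _draw_depths(
    config: SimulationConfig, shape: tuple[int, int], rng: np.random.Generator
) -> np.ndarray:
    if math.isinf(config.depth_dispersion):
        return rng.poisson(config.mean_depth, size=shape)
    k = config.depth_dispersion
    p = k / (k + config.mean_depth)
    return rng.negative_binomial(k, p, size=shape)


def _depth_frame(
    regions: Sequence[CodingRegion], sample_ids: Sequence[str], mat: np.ndarray
) -> DepthTable:
    tids = np.concatenate(
        [np.full(len(r.cds), r.transcript_id, dtype=object) for r in regions]
    )
    pos = np.concatenate([np.arange(1, len(r.cds) + 1) for r in regions])
    df = pd.DataFrame({"transcript_id": tids, "position": pos})
    for j, sid in enumerate(sample_ids):
        df[sid] = mat[:, j]
    return DepthTable(df)


def _position_index(regions: Sequence[CodingRegion]) -> dict[tuple[str, int], int]:
    idx = {}
    g = 0
    for r in regions:
        for p in range(1, len(r.cds) + 1):
            idx[(r.transcript_id, p)] = g
            g += 1
    return idx


def _make_variant(
    config: SimulationConfig,
    transcript_id: str,
    position: int,
    ref: str,
    alt: str,
    genotypes: dict[str, tuple[int, ...]],
    depths: dict[str, int],
    ploidy: int,
    rng: np.random.Generator,
) -> VariantRecord:
    calls = {}
    for sid, gt in genotypes.items():
        dp = depths[sid]
        ref_copies = gt.count(0)
        ad_ref = int(rng.binomial(dp, ref_copies / ploidy)) if dp > 0 else 0
        calls[sid] = GenotypeCall(gt, dp, (ad_ref, dp - ad_ref), config.gq_constant)
    return VariantRecord(transcript_id, position, ref, (alt,), config.site_qual, calls)


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate the full two-species study in memory."""
    rng = np.random.default_rng(config.seed)

    # --- asexual species -------------------------------------------------
    adult_ids = [f"TPU_A{i + 1}" for i in range(config.n_adults_asexual)]
    asex_samples = [
        SampleRecord(sid, config.asexual_species, 3, Role.adult, Sex.female)
        for sid in adult_ids
    ]
    pool_id = None
    if config.include_offspring_pool:
        pool_id = "TPU_pool"
        asex_samples.append(
            SampleRecord(pool_id, config.asexual_species, 3, Role.offspring_pool, Sex.unknown)
        )
    base_regions = generate_reference_cds(
        config.n_transcripts, config.cds_length_codons, rng, prefix="TPU_t"
    )
    asex_regions, anc_sites = make_triploid_clone(config, base_regions, rng)
    occupied = {(s["transcript_id"], s["position"]) for s in anc_sites}
    novel_sites = add_novel_mutations(config, asex_regions, occupied, adult_ids, rng)

    asex_ids = [s.sample_id for s in asex_samples]
    depth_mat_a = _draw_depths(config, (sum(len(r.cds) for r in asex_regions), len(asex_ids)), rng)
    pos_index_a = _position_index(asex_regions)
    asex_variants = []
    truth_rows = []
    mother = adult_ids[0]
    for s in anc_sites:
        het = (0, 0, 1) if s["ref_copies"] == 2 else (0, 1, 1)
        genotypes = {sid: het for sid in adult_ids}
        if pool_id:
            genotypes[pool_id] = genotypes[mother]
        g = pos_index_a[(s["transcript_id"], s["position"])]
        depths = {sid: int(depth_mat_a[g, j]) for j, sid in enumerate(asex_ids)}
        asex_variants.append(
            _make_variant(config, s["transcript_id"], s["position"], s["ref"], s["alt"],
                          genotypes, depths, 3, rng)
        )
        truth_rows.append(
            dict(species_id=config.asexual_species, transcript_id=s["transcript_id"],
                 position=s["position"], true_class="ancestral_hybrid",
                 true_effect=s["true_effect"], carriers=",".join(asex_ids))
        )
    for s in novel_sites:
        genotypes = {sid: ((0, 0, 1) if sid == s["carrier"] else (0, 0, 0)) for sid in adult_ids}
        if pool_id:
            genotypes[pool_id] = genotypes[mother]
        carriers = [s["carrier"]] + ([pool_id] if pool_id and s["carrier"] == mother else [])
        g = pos_index_a[(s["transcript_id"], s["position"])]
        depths = {sid: int(depth_mat_a[g, j]) for j, sid in enumerate(asex_ids)}
        asex_variants.append(
            _make_variant(config, s["transcript_id"], s["position"], s["ref"], s["alt"],
                          genotypes, depths, 3, rng)
        )
        truth_rows.append(
            dict(species_id=config.asexual_species, transcript_id=s["transcript_id"],
                 position=s["position"], true_class="novel",
                 true_effect=s["true_effect"], carriers=",".join(carriers))
        )
    asex_variants.sort(key=lambda v: (v.transcript_id, v.position))
    asexual = SpeciesData(
        config.asexual_species,
        asex_samples,
        asex_regions,
        asex_variants,
        _depth_frame(asex_regions, asex_ids, depth_mat_a),
    )

    # --- sexual species --------------------------------------------------
    sex_ids = [f"HRI_S{i + 1}" for i in range(config.n_samples_sexual)]
    sexes = [Sex.female if i % 2 == 0 else Sex.male for i in range(config.n_samples_sexual)]
    sex_samples = [
        SampleRecord(sid, config.sexual_species, 2, Role.adult, sx)
        for sid, sx in zip(sex_ids, sexes)
    ]
    sex_regions = generate_reference_cds(
        config.n_transcripts, config.cds_length_codons, rng, prefix="HRI_t"
    )
    seg_sites = make_sexual_population(config, sex_regions, sex_ids, rng)
    depth_mat_s = _draw_depths(config, (sum(len(r.cds) for r in sex_regions), len(sex_ids)), rng)
    pos_index_s = _position_index(sex_regions)
    sex_variants = []
    for s in seg_sites:
        genotypes = {
            sid: tuple(sorted([1] * k + [0] * (2 - k)))
            for sid, k in zip(sex_ids, s["alt_copies"])
        }
        carriers = [sid for sid, k in zip(sex_ids, s["alt_copies"]) if k > 0]
        g = pos_index_s[(s["transcript_id"], s["position"])]
        depths = {sid: int(depth_mat_s[g, j]) for j, sid in enumerate(sex_ids)}
        sex_variants.append(
            _make_variant(config, s["transcript_id"], s["position"], s["ref"], s["alt"],
                          genotypes, depths, 2, rng)
        )
        truth_rows.append(
            dict(species_id=config.sexual_species, transcript_id=s["transcript_id"],
                 position=s["position"], true_class="sexual_segregating",
                 true_effect=s["true_effect"], carriers=",".join(carriers))
        )
    sex_variants.sort(key=lambda v: (v.transcript_id, v.position))
    sexual = SpeciesData(
        config.sexual_species,
        sex_samples,
        sex_regions,
        sex_variants,
        _depth_frame(sex_regions, sex_ids, depth_mat_s),
    )

    truth = pd.DataFrame(
        truth_rows,
        columns=["species_id", "transcript_id", "position", "true_class", "true_effect", "carriers"],
    ).sort_values(["species_id", "transcript_id", "position"], kind="mergesort").reset_index(drop=True)
    return SimulatedStudy(config, asexual, sexual, truth)


def emit_study(study: SimulatedStudy, outdir: str | Path) -> dict[str, Path]:
    """Write the study to disk in the pipeline's input formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for sp in (study.asexual, study.sexual):
        vcf = outdir / f"{sp.species_id}.vcf"
        fasta = outdir / f"{sp.species_id}_cds.fasta"
        table = outdir / f"{sp.species_id}_cds.tsv"
        depth = outdir / f"{sp.species_id}_depth.tsv"
        write_vcf(sp.variants, sp.samples, vcf,
                  contig_lengths={r.transcript_id: len(r.sequence) for r in sp.regions})
        write_cds(sp.regions, fasta, table)
        sp.depth.write(depth)
        paths.update({
            f"{sp.species_id}_vcf": vcf,
            f"{sp.species_id}_fasta": fasta,
            f"{sp.species_id}_cds_table": table,
            f"{sp.species_id}_depth": depth,
        })
    sheet = outdir / "samples.tsv"
    write_sample_sheet(study.samples, sheet)
    truth_path = outdir / "truth.tsv"
    study.truth.to_csv(truth_path, sep="\t", index=False)
    cfg_path = outdir / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(asdict(study.config), fh, sort_keys=True)
    paths.update(sample_sheet=sheet, truth=truth_path, config=cfg_path)
    return paths
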