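"""Orchestration: run the full SNP-class analysis and write report tables.

The report bundle mirrors the analysis structure: a sex-ratio table with an
exact binomial test, a clonality (genotype-identity) table, a per-individual
heterozygous-SNP table with pN/pS, a SNP-class table (candidate novel /
ancestral identical / low frequency / all) with the shared-vs-separate pN/pS
likelihood-ratio tests, allele-balance histograms with ploidy calls, and an
optional pairwise dN/dS table when aligned ortholog pairs are supplied.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from . import clonality as clonality_mod
from . import partition as partition_mod
from .codon import EffectClass, classify_substitution, covered_site_totals
from .dnds import pairwise_dnds
from .io import (
    CodingRegion,
    DepthTable,
    Role,
    SampleRecord,
    Sex,
    VariantRecord,
    apply_quality_filters,
    read_cds,
    read_sample_sheet,
    read_vcf,
)
from .ploidy import infer_ploidy
from .selection import (
    PnPsSummary,
    exact_binomial_test,
    exact_rank_sum_test,
    pnps_lrt,
    pnps_summary,
)

logger = logging.getLogger(__name__)


@dataclass
class DatasetPaths:
    vcf: Path
    fasta: Path
    cds_table: Path
    depth_tsv: Path


@dataclass
class PipelineConfig:
    sample_sheet: Path
    datasets: dict[str, DatasetPaths]  # keyed by species_id
    outdir: Path
    min_depth: int = 20
    min_gq: float = 30.0
    min_site_qual: float = 30.0
    marker_transcripts: Path | None = None
    ortholog_pairs: Path | None = None
    pool_mother: dict[str, str] = field(default_factory=dict)  # species -> mother sample_id
    adult_pair: dict[str, tuple[str, str]] = field(default_factory=dict)
    seed: int | None = None
    histogram_bin_width: float = 0.02


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


# ---------------------------------------------------------------------------
# building blocks reused by the report and by callers


def effect_counts(
    variants: Iterable[VariantRecord], regions_by_id: Mapping[str, CodingRegion]
) -> tuple[int, int]:
    """(nonsynonymous, synonymous) counts of biallelic SNPs inside CDS."""
    n_nonsyn = n_syn = 0
    for v in variants:
        region = regions_by_id.get(v.transcript_id)
        if region is None:
            continue
        eff = classify_substitution(region, v.position, v.ref_allele, v.alt_alleles[0])
        if eff is EffectClass.nonsynonymous:
            n_nonsyn += 1
        elif eff is EffectClass.synonymous:
            n_syn += 1
    return n_nonsyn, n_syn


def per_individual_pnps(
    variants: Sequence[VariantRecord],
    regions: Sequence[CodingRegion],
    depth: DepthTable,
    sample: SampleRecord,
    min_depth: int = 20,
) -> PnPsSummary:
    """Heterozygous-SNP pN/pS for one sample, per-individual covered sites."""
    regions_by_id = {r.transcript_id: r for r in regions}
    het = partition_mod.per_individual_het(variants, sample)
    n_nonsyn, n_syn = effect_counts(het, regions_by_id)
    sites = covered_site_totals(regions, depth, [sample], "per_individual", min_depth)
    return pnps_summary(n_nonsyn, n_syn, sites.covered_nonsyn_sites, sites.covered_syn_sites)


def class_pnps(
    class_variants: Sequence[VariantRecord],
    regions: Sequence[CodingRegion],
    depth: DepthTable,
    mask_samples: Sequence[SampleRecord],
    min_depth: int = 20,
) -> PnPsSummary:
    """pN/pS of a SNP class against all-individuals covered-site denominators."""
    regions_by_id = {r.transcript_id: r for r in regions}
    n_nonsyn, n_syn = effect_counts(class_variants, regions_by_id)
    sites = covered_site_totals(regions, depth, mask_samples, "all_individuals", min_depth)
    return pnps_summary(n_nonsyn, n_syn, sites.covered_nonsyn_sites, sites.covered_syn_sites)


def _pnps_row(label: str, s: PnPsSummary) -> dict:
    return {
        "dataset": label,
        "covered_nonsyn_sites": round(s.sites_nonsyn, 2),
        "covered_syn_sites": round(s.sites_syn, 2),
        "nonsyn_snps": s.n_nonsyn,
        "syn_snps": s.n_syn,
        "overall_snp_freq": float(f"{s.freq_overall:.3g}"),
        "nonsyn_snp_freq": float(f"{s.freq_nonsyn:.3g}"),
        "syn_snp_freq": float(f"{s.freq_syn:.3g}"),
        "pnps": None if s.pnps is None else round(s.pnps, 4),
    }


@dataclass
class SpeciesInputs:
    species_id: str
    samples: list[SampleRecord]
    regions: list[CodingRegion]
    variants_raw: list[VariantRecord]
    variants: list[VariantRecord]  # quality-filtered
    depth: DepthTable

    @property
    def adults(self) -> list[SampleRecord]:
        return [s for s in self.samples if s.role is Role.adult]

    @property
    def pools(self) -> list[SampleRecord]:
        return [s for s in self.samples if s.role is Role.offspring_pool]


def load_species(config: PipelineConfig, species_id: str) -> SpeciesInputs:
    paths = config.datasets[species_id]
    all_samples = read_sample_sheet(config.sample_sheet)
    samples = [s for s in all_samples if s.species_id == species_id]
    if not samples:
        raise ValueError(f"no samples for species {species_id} in the sample sheet")
    regions = read_cds(paths.fasta, paths.cds_table)
    variants_raw = read_vcf(paths.vcf, samples)
    variants = apply_quality_filters(
        variants_raw,
        [s.sample_id for s in samples],
        config.min_depth,
        config.min_gq,
        config.min_site_qual,
    )
    depth = DepthTable.read(paths.depth_tsv)
    return SpeciesInputs(species_id, samples, regions, variants_raw, variants, depth)


# ---------------------------------------------------------------------------
# the full report


def run_report(config: PipelineConfig) -> dict[str, object]:
    """Run every stage and write the report bundle into ``config.outdir``.

    Returns the in-memory tables.  On any stage failure the partially written
    outputs are removed and a StageError is raised.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log_lines: list[str] = []

    def emit(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", index=False)
        written.append(path)

    try:
        stage = "load"
        species_inputs = {sp: load_species(config, sp) for sp in sorted(config.datasets)}
        for sp, si in species_inputs.items():
            log_lines.append(
                f"{sp}: {len(si.variants_raw)} SNP records read, "
                f"{len(si.variants)} after quality filters "
                f"(DP>={config.min_depth}, GQ>={config.min_gq}, QUAL>={config.min_site_qual})"
            )

        stage = "sex_ratio"
        rows = []
        for sp, si in species_inputs.items():
            n_f = sum(1 for s in si.adults if s.sex is Sex.female)
            n_m = sum(1 for s in si.adults if s.sex is Sex.male)
            res = exact_binomial_test(n_f, n_m) if n_f + n_m >= 1 else None
            rows.append(
                {"species_id": sp, "female": n_f, "male": n_m, "total": n_f + n_m,
                 "binomial_p": None if res is None else float(f"{res.p_value:.3g}")}
            )
        table1 = pd.DataFrame(rows)
        emit("table1_sex_ratio.tsv", table1)

        stage = "clonality"
        import random as _random

        rows = []
        for sp, si in species_inputs.items():
            bi = clonality_mod.biallelic_subset(si.variants)
            log_lines.append(f"{sp}: {len(bi)} biallelic quality-filtered SNPs")
            subsets = {"all SNPs": bi}
            if config.marker_transcripts is not None:
                markers = [
                    ln.strip() for ln in Path(config.marker_transcripts).read_text().splitlines()
                    if ln.strip()
                ]
                subsets["marker subset"] = clonality_mod.subset_by_markers(bi, markers)
            for label, sub in subsets.items():
                adults = si.adults
                if len(adults) >= 2:
                    s = clonality_mod.identity_fraction(sub, adults, label)
                    rows.append({"species_id": sp, "subset": label, "comparison": "all adults",
                                 "n_biallelic": s.n_biallelic, "n_identical": s.n_identical,
                                 "percent_identical": s.percent})
                mother = config.pool_mother.get(sp)
                if mother and si.pools:
                    s = clonality_mod.pairwise_identity(sub, mother, si.pools[0].sample_id, label)
                    rows.append({"species_id": sp, "subset": label,
                                 "comparison": "mother vs offspring pool",
                                 "n_biallelic": s.n_biallelic, "n_identical": s.n_identical,
                                 "percent_identical": s.percent})
                if len(adults) >= 2:
                    pair = config.adult_pair.get(sp)
                    if pair is None:
                        rng = _random.Random(config.seed if config.seed is not None else 0)
                        pair = tuple(rng.sample([a.sample_id for a in adults], 2))
                    s = clonality_mod.pairwise_identity(sub, pair[0], pair[1], label)
                    rows.append({"species_id": sp, "subset": label,
                                 "comparison": f"pair {pair[0]}/{pair[1]}",
                                 "n_biallelic": s.n_biallelic, "n_identical": s.n_identical,
                                 "percent_identical": s.percent})
        emit("table3_clonality.tsv", pd.DataFrame(rows))

        stage = "ploidy"
        rows = []
        for sp, si in species_inputs.items():
            for s in si.samples:
                prof = infer_ploidy(si.variants, s, bin_width=config.histogram_bin_width)
                rows.append({"sample_id": s.sample_id, "species_id": sp,
                             "n_het_sites": len(prof.balances),
                             "loglik_diploid": round(prof.loglik_diploid, 3),
                             "loglik_triploid": round(prof.loglik_triploid, 3),
                             "call": prof.inferred_ploidy})
                hist = pd.DataFrame({
                    "bin_start": prof.bin_edges[:-1],
                    "bin_end": prof.bin_edges[1:],
                    "count": prof.bin_counts,
                })
                (outdir / "fig1_histograms").mkdir(exist_ok=True)
                path = outdir / "fig1_histograms" / f"{s.sample_id}.tsv"
                hist.to_csv(path, sep="\t", index=False)
                written.append(path)
        emit("ploidy_calls.tsv", pd.DataFrame(rows))

        stage = "per_individual_pnps"
        rows = []
        per_sample_pnps: dict[str, PnPsSummary] = {}
        for sp, si in species_inputs.items():
            for s in si.samples:
                summ = per_individual_pnps(si.variants, si.regions, si.depth, s, config.min_depth)
                per_sample_pnps[s.sample_id] = summ
                rows.append({"sample_id": s.sample_id, "species_id": sp, **_pnps_row(s.sample_id, summ)})
        table4 = pd.DataFrame(rows).drop(columns=["dataset"])
        emit("table4_per_individual.tsv", table4)

        stage = "snp_classes"
        rows = []
        class_counts: dict[str, PnPsSummary] = {}
        for sp, si in species_inputs.items():
            adults = si.adults
            ploidies = {s.ploidy for s in si.samples}
            if ploidies == {3}:
                novel = partition_mod.candidate_novel(si.variants, adults)
                ident = partition_mod.ancestral_identical(si.variants, adults)
                for label, cls in [("candidate novel SNPs", novel), ("identical SNPs", ident)]:
                    summ = class_pnps(cls, si.regions, si.depth, adults, config.min_depth)
                    class_counts[f"{sp}:{label}"] = summ
                    rows.append({"species_id": sp, **_pnps_row(label, summ)})
                log_lines.append(f"{sp}: {len(novel)} candidate novel, {len(ident)} identical SNPs")
            elif ploidies == {2}:
                bi = clonality_mod.biallelic_subset(si.variants)
                lowf = partition_mod.low_frequency(si.variants, si.samples)
                for label, cls in [("all SNPs", bi), ("low-frequency SNPs", lowf)]:
                    summ = class_pnps(cls, si.regions, si.depth, si.samples, config.min_depth)
                    class_counts[f"{sp}:{label}"] = summ
                    rows.append({"species_id": sp, **_pnps_row(label, summ)})
                log_lines.append(f"{sp}: {len(lowf)} low-frequency SNPs")
        emit("table5_classes.tsv", pd.DataFrame(rows))

        stage = "lrt"
        tests: dict[str, dict] = {}

        def counts(key: str):
            s = class_counts[key]
            return (s.n_nonsyn, s.n_syn, s.sites_nonsyn, s.sites_syn)

        novel_keys = [k for k in class_counts if k.endswith("candidate novel SNPs")]
        ident_keys = [k for k in class_counts if k.endswith("identical SNPs") and "candidate" not in k]
        lowf_keys = [k for k in class_counts if k.endswith("low-frequency SNPs")]
        pairs = []
        if novel_keys and ident_keys:
            pairs.append(("novel_vs_identical", novel_keys[0], ident_keys[0]))
        if novel_keys and lowf_keys:
            pairs.append(("novel_vs_low_frequency", novel_keys[0], lowf_keys[0]))
        for name, ka, kb in pairs:
            try:
                res = pnps_lrt(counts(ka), counts(kb))
            except ValueError as e:
                tests[name] = {"error": str(e)}
                continue
            tests[name] = {
                "classes": [ka, kb],
                "ratio_a": round(res.ratio_a_mle, 4),
                "ratio_b": round(res.ratio_b_mle, 4),
                "ratio_shared": round(res.ratio_shared_mle, 4),
                "chi2": round(res.chi2, 1),
                "df": res.df,
                "p": float(f"{res.p_value:.3g}"),
                "method": "conditional binomial LRT, site-total offsets",
            }

        stage = "rank_sum"
        asex = [sp for sp, si in species_inputs.items() if {s.ploidy for s in si.samples} == {3}]
        sex = [sp for sp, si in species_inputs.items() if {s.ploidy for s in si.samples} == {2}]
        if asex and sex:
            a_vals = [per_sample_pnps[s.sample_id].pnps
                      for s in species_inputs[asex[0]].adults
                      if per_sample_pnps[s.sample_id].pnps is not None]
            b_vals = [per_sample_pnps[s.sample_id].pnps
                      for s in species_inputs[sex[0]].adults
                      if per_sample_pnps[s.sample_id].pnps is not None]
            if a_vals and b_vals:
                try:
                    res = exact_rank_sum_test(a_vals, b_vals)
                    tests["per_individual_pnps_rank_sum"] = {
                        "groups": [asex[0], sex[0]],
                        "U": res.statistic,
                        "p": float(f"{res.p_value:.2g}"),
                        "method": res.method,
                    }
                except ValueError as e:
                    tests["per_individual_pnps_rank_sum"] = {"error": str(e)}
        path = outdir / "tests.json"
        path.write_text(json.dumps(tests, indent=2) + "\n")
        written.append(path)

        stage = "dnds"
        if config.ortholog_pairs is not None:
            recs = list(SeqIO.parse(str(config.ortholog_pairs), "fasta"))
            if len(recs) % 2:
                raise ValueError("ortholog pair FASTA must contain an even number of records")
            rows = []
            for i in range(0, len(recs), 2):
                a, b = recs[i], recs[i + 1]
                res = pairwise_dnds(str(a.seq), str(b.seq))
                rows.append({"ortholog_id": a.id,
                             "dN": None if res.dn is None else round(res.dn, 4),
                             "dS": None if res.ds is None else round(res.ds, 4),
                             "dnds": None if res.dnds is None else round(res.dnds, 4)})
            emit("dnds_pairs.tsv", pd.DataFrame(rows))

        stage = "log"
        log_path = outdir / "report_log.txt"
        from ._version import __version__

        log_path.write_text(
            "\n".join([f"pnpskit {__version__}", f"seed: {config.seed}"] + log_lines) + "\n"
        )
        written.append(log_path)
    except Exception as e:  # remove partial outputs, then surface the stage
        for p in written:
            p.unlink(missing_ok=True)
        raise StageError(stage, e) from e

    return {
        "table1": table1,
        "table4": table4,
        "tests": tests,
        "class_counts": class_counts,
        "per_sample_pnps": per_sample_pnps,
    }
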