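"""The synthetic study generator: determinism, truth labels, expectations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pnpskit.codon import position_weights
from pnpskit.io import Role, read_cds, read_vcf, DepthTable
from pnpskit.simulate import SimulationConfig, emit_study, simulate_study


def _cfg(**kw):
    base = dict(seed=7, n_transcripts=40, cds_length_codons=60)
    base.update(kw)
    return SimulationConfig(**base)


def test_reference_cds_shape():
    study = simulate_study(_cfg())
    for sp in (study.asexual, study.sexual):
        assert len(sp.regions) == 40
        for r in sp.regions:
            assert r.cds.startswith("ATG")
            assert len(r.cds) == 180
            position_weights(r.cds)  # raises on internal stops
            assert r.sequence[r.cds_end:] in ("TAA", "TAG", "TGA")


def test_same_seed_reproduces_identical_bytes(tmp_path):
    a = emit_study(simulate_study(_cfg()), tmp_path / "a")
    b = emit_study(simulate_study(_cfg()), tmp_path / "b")
    for key in a:
        assert a[key].read_bytes() == b[key].read_bytes(), key
    c = emit_study(simulate_study(_cfg(seed=8)), tmp_path / "c")
    assert a["truth"].read_bytes() != c["truth"].read_bytes()


def test_emitted_files_round_trip(tmp_path):
    study = simulate_study(_cfg())
    paths = emit_study(study, tmp_path)
    sp = study.asexual
    assert read_vcf(paths[f"{sp.species_id}_vcf"], sp.samples) == sp.variants
    regions = read_cds(paths[f"{sp.species_id}_fasta"], paths[f"{sp.species_id}_cds_table"])
    assert [r.sequence for r in regions] == [r.sequence for r in sp.regions]
    depth = DepthTable.read(paths[f"{sp.species_id}_depth"])
    pd.testing.assert_frame_equal(depth.df, sp.depth.df)


def test_truth_rows_one_per_variant():
    study = simulate_study(_cfg())
    for sp in (study.asexual, study.sexual):
        truth = study.truth[study.truth.species_id == sp.species_id]
        keys = {(v.transcript_id, v.position) for v in sp.variants}
        assert set(zip(truth.transcript_id, truth.position)) == keys
        assert len(truth) == len(sp.variants)


def test_zero_divergence_and_zero_mutation_rates():
    study = simulate_study(_cfg(progenitor_divergence=0.0, novel_mut_rate=0.0))
    assert study.asexual.variants == []
    quiet = simulate_study(_cfg(novel_mut_rate=0.0))
    truth = quiet.truth
    assert (truth.true_class == "novel").sum() == 0
    # with no novel mutations every asexual sample is genotype-identical
    gts = [
        {sid: c.allele_indices for sid, c in v.calls.items()}
        for v in quiet.asexual.variants
    ]
    for g in gts:
        assert len(set(g.values())) == 1
    zero_density = simulate_study(_cfg(sexual_snp_density=0.0))
    assert zero_density.sexual.variants == []


def test_offspring_pool_copies_mother_everywhere():
    study = simulate_study(_cfg(novel_mut_rate=3e-4))
    mother = "TPU_A1"
    for v in study.asexual.variants:
        assert v.calls["TPU_pool"].allele_indices == v.calls[mother].allele_indices


def test_ancestral_het_density_matches_binomial_expectation():
    cfg = _cfg(n_transcripts=150, progenitor_divergence=0.006, novel_mut_rate=0.0)
    study = simulate_study(cfg)
    n_sites = sum(len(r.cds) for r in study.asexual.regions)
    # retention probability: synonymous proposals always kept, nonsynonymous
    # with probability f_ancestral; the synonymous fraction of uniform
    # proposals equals the NG86 synonymous site fraction of the sequence
    syn_w = np.concatenate([position_weights(r.cds)[0] for r in study.asexual.regions])
    q_syn = syn_w.mean()
    keep = q_syn + (1 - q_syn) * cfg.ancestral_retention
    expected = n_sites * cfg.progenitor_divergence * keep
    sd = np.sqrt(n_sites * cfg.progenitor_divergence * keep * (1 - cfg.progenitor_divergence * keep))
    assert abs(len(study.asexual.variants) - expected) < 3 * sd


def test_full_retention_keeps_all_proposals():
    cfg = _cfg(n_transcripts=150, ancestral_retention=1.0, novel_mut_rate=0.0,
               progenitor_divergence=0.006)
    study = simulate_study(cfg)
    n_sites = sum(len(r.cds) for r in study.asexual.regions)
    expected = n_sites * cfg.progenitor_divergence
    sd = np.sqrt(expected)
    assert abs(len(study.asexual.variants) - expected) < 3.5 * sd


def test_triploid_read_fractions_near_expectation():
    study = simulate_study(_cfg(n_transcripts=250, progenitor_divergence=0.01,
                                novel_mut_rate=0.0))
    fracs = []
    for v in study.asexual.variants:
        c = v.calls["TPU_A1"]
        if c.allele_indices == (0, 0, 1) and c.depth > 0:
            fracs.append(c.allele_depths[0] / c.depth)
    assert len(fracs) > 30
    assert np.mean(fracs) == pytest.approx(2 / 3, abs=0.02)


def test_alt_count_spectrum_controls_low_frequency_sites():
    from pnpskit.partition import low_frequency

    singleton = SimulationConfig(
        seed=5, n_transcripts=60, cds_length_codons=60, sexual_snp_density=0.005,
        sexual_alt_freq_spec=(1.0, 0, 0, 0, 0, 0, 0),
    )
    study = simulate_study(singleton)
    hits = low_frequency(study.sexual.variants, study.sexual.samples)
    assert len(hits) == len(study.sexual.variants) > 0
    mid = SimulationConfig(
        seed=5, n_transcripts=60, cds_length_codons=60, sexual_snp_density=0.005,
        sexual_alt_freq_spec=(0, 0, 0, 1.0, 0, 0, 0),
    )
    study = simulate_study(mid)
    assert low_frequency(study.sexual.variants, study.sexual.samples) == []


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(nonsyn_retention=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(progenitor_divergence=-0.1)
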