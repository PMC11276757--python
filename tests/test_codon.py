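"""Genetic-code machinery: translation, NG86 sites, effect classes, coverage."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from pnpskit.codon import (
    EffectClass,
    SENSE_CODONS,
    classify_substitution,
    covered_site_totals,
    ng86_codon_sites,
    translate_codon,
)
from pnpskit.io import CodingRegion, DepthTable

BASES = "ACGT"


def oracle_ng86(codon: str) -> tuple[float, float]:
    """Independent brute force: Biopython translation over all 9 mutants."""
    aa = str(Seq(codon).translate())
    syn = 0
    for k in range(3):
        for b in BASES:
            if b == codon[k]:
                continue
            mut = str(Seq(codon[:k] + b + codon[k + 1 :]).translate())
            if mut == aa and mut != "*":
                syn += 1
    return syn / 3, 3 - syn / 3


def test_translation_standard_code():
    assert translate_codon("ATG") == "M"
    assert translate_codon("TAA") == "*"
    assert translate_codon("GGA") == "G"
    with pytest.raises(ValueError):
        translate_codon("ANG")


def test_ng86_matches_bruteforce_for_all_sense_codons():
    for codon in SENSE_CODONS:
        assert ng86_codon_sites(codon) == pytest.approx(oracle_ng86(codon), abs=1e-12)


def test_ng86_totals():
    total = sum(sum(ng86_codon_sites(c)) for c in SENSE_CODONS)
    assert total == pytest.approx(183.0)
    for c in SENSE_CODONS:
        assert sum(ng86_codon_sites(c)) == pytest.approx(3.0)
    with pytest.raises(ValueError):
        ng86_codon_sites("TAA")


def _region(cds="GGAAAACAA", pre="", post=""):
    seq = pre + cds + post
    return CodingRegion("t1", seq, len(pre) + 1, len(pre) + len(cds))


@pytest.mark.parametrize(
    "pos,ref,alt,expected",
    [
        (3, "A", "G", EffectClass.synonymous),      # GGA->GGG, 4-fold site
        (5, "A", "G", EffectClass.nonsynonymous),   # AAA->AGA, Lys->Arg
        (7, "C", "T", EffectClass.nonsynonymous),   # CAA->TAA, stop gain
    ],
)
def test_effect_classification(pos, ref, alt, expected):
    assert classify_substitution(_region(), pos, ref, alt) is expected


def test_positions_outside_cds_are_non_coding():
    region = _region(pre="TT", post="TGA")
    assert classify_substitution(region, 1, "T", "A") is EffectClass.non_coding
    assert classify_substitution(region, 12, "T", "A") is EffectClass.non_coding


def test_reference_mismatch_is_an_error():
    with pytest.raises(ValueError, match="does not match"):
        classify_substitution(_region(), 3, "C", "G")


def test_synonymy_symmetric_under_allele_swap():
    rng = np.random.default_rng(7)
    for _ in range(200):
        codon = SENSE_CODONS[rng.integers(len(SENSE_CODONS))]
        k = int(rng.integers(3))
        alt = BASES[rng.integers(4)]
        if alt == codon[k]:
            continue
        mutant = codon[:k] + alt + codon[k + 1 :]
        fwd = classify_substitution(CodingRegion("t", codon, 1, 3), k + 1, codon[k], alt)
        if str(Seq(mutant).translate()) == "*":
            continue  # reverse region would carry an internal stop
        rev = classify_substitution(CodingRegion("t", mutant, 1, 3), k + 1, alt, codon[k])
        assert fwd is rev


def _depth_table(depths_by_sample, positions, tid="t1"):
    df = pd.DataFrame({"transcript_id": tid, "position": positions})
    for sid, d in depths_by_sample.items():
        df[sid] = d
    return DepthTable(df)


def test_covered_sites_single_codon_full_depth():
    region = CodingRegion("t1", "TTT", 1, 3)
    depths = _depth_table({"a": [25, 25, 25]}, [1, 2, 3])
    res = covered_site_totals([region], depths, ["a"], "per_individual")
    assert res.covered_syn_sites == pytest.approx(1 / 3)
    assert res.covered_nonsyn_sites == pytest.approx(8 / 3)


def test_covered_sites_per_position_exclusion():
    region = CodingRegion("t1", "TTT", 1, 3)
    depths = _depth_table({"a": [25, 19, 25]}, [1, 2, 3])
    res = covered_site_totals([region], depths, ["a"], "per_individual")
    # position 2 of TTT is wholly nonsynonymous: syn weight unchanged
    assert res.covered_syn_sites == pytest.approx(1 / 3)
    assert res.covered_nonsyn_sites == pytest.approx(5 / 3)


def test_covered_sites_all_individuals_requires_every_sample():
    region = CodingRegion("t1", "TTT", 1, 3)
    depths = _depth_table({"a": [25, 25, 25], "b": [5, 5, 5]}, [1, 2, 3])
    res = covered_site_totals([region], depths, ["a", "b"], "all_individuals")
    assert res.total == 0.0
    with pytest.raises(ValueError):
        covered_site_totals([region], depths, ["a", "b"], "per_individual")


def test_covered_sites_monotone_in_threshold_and_samples():
    rng = np.random.default_rng(42)
    cds = "".join(SENSE_CODONS[i] for i in rng.integers(0, 61, size=40))
    region = CodingRegion("t1", cds, 1, len(cds))
    positions = list(range(1, len(cds) + 1))
    depths = _depth_table(
        {s: rng.integers(0, 60, size=len(cds)) for s in "abc"}, positions
    )
    totals = [
        covered_site_totals([region], depths, ["a"], "per_individual", min_depth=d).total
        for d in (0, 10, 20, 40, 61)
    ]
    assert totals == sorted(totals, reverse=True)
    assert totals[0] == pytest.approx(len(cds))
    by_samples = [
        covered_site_totals([region], depths, list("abc")[:k], "all_individuals").total
        for k in (1, 2, 3)
    ]
    assert by_samples == sorted(by_samples, reverse=True)


def test_positions_absent_from_depth_table_count_as_zero():
    region = CodingRegion("t1", "GGG", 1, 3)
    depths = _depth_table({"a": [30]}, [2])
    res = covered_site_totals([region], depths, ["a"], "per_individual")
    assert res.total == pytest.approx(1.0)  # only position 2 covered
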