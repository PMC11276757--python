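"""Shared fixtures: small synthetic studies and hand-built variant records."""

from __future__ import annotations

import pytest

from pnpskit.io import GenotypeCall, SampleRecord, VariantRecord
from pnpskit.simulate import SimulationConfig, simulate_study


def make_call(gt, dp=60, ad=None, gq=60.0):
    if ad is None:
        n_alt = sum(1 for a in gt if a == 1)
        ad_alt = (dp * n_alt) // len(gt)
        ad = (dp - ad_alt, ad_alt)
    return GenotypeCall(tuple(gt), dp, tuple(ad), gq)


def make_variant(tid="t1", pos=1, ref="A", alts=("G",), qual=60.0, calls=None):
    return VariantRecord(tid, pos, ref, tuple(alts), qual, calls or {})


@pytest.fixture(scope="session")
def small_study():
    """A compact clone + outcrosser study with plenty of SNPs of every class."""
    cfg = SimulationConfig(
        seed=20240101,
        n_transcripts=120,
        cds_length_codons=80,
        progenitor_divergence=0.01,
        novel_mut_rate=3e-4,
        sexual_snp_density=0.003,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def triploid_adults():
    return [
        SampleRecord(f"A{i}", "clone", 3, "adult", "female") for i in range(1, 5)
    ]


@pytest.fixture(scope="session")
def diploid_samples():
    return [
        SampleRecord(f"S{i}", "outcross", 2, "adult", "female" if i % 2 else "male")
        for i in range(1, 5)
    ]
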