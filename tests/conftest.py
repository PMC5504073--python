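"""Shared fixtures: one default synthetic bundle per session plus small helpers."""

from __future__ import annotations

import numpy as np
import pytest

from ctcf_landscape import motifs as M
from ctcf_landscape import peaks as P
from ctcf_landscape import synthetic_data as S

# One fixed seed for the default study-condition bundle used across the suite.
BUNDLE_SEED = 7


@pytest.fixture(scope="session")
def default_cfg() -> S.GeneratorConfig:
    return S.GeneratorConfig(seed=BUNDLE_SEED)


@pytest.fixture(scope="session")
def bundle(default_cfg) -> S.SimulatedBundle:
    return S.simulate_bundle(default_cfg)


@pytest.fixture(scope="session")
def embryo_consensus(bundle) -> P.ConsensusPeakSet:
    runs = bundle.peak_calls["embryo"]
    return P.consensus_peaks(runs["rep1"], runs["rep2"], runs["merged"], "embryo")


@pytest.fixture(scope="session")
def two_part(bundle, embryo_consensus) -> M.TwoPartResult:
    return M.two_part_pipeline(embryo_consensus, bundle.genome, M.TwoPartConfig(seed=1))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)


def make_peak(chrom="chr1", start=100, end=400, name="p", fe=10.0, summit=150, score=0):
    from ctcf_landscape.formats import PeakRecord

    return PeakRecord(
        chrom=chrom, start=start, end=end, name=name, score=score, strand=".",
        fold_enrichment=fe, summit_offset=summit - start,
    )
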