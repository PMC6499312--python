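"""Shared fixtures: a compact synthetic genome, background catalogs and a
planted chain, generated once per session."""

import numpy as np
import pytest

import crisischain as cc


@pytest.fixture(scope="session")
def genome():
    return cc.default_genome()


@pytest.fixture(scope="session")
def background_catalogs(genome):
    return cc.simulate_background_breaks(genome, 8, seed=11)


@pytest.fixture(scope="session")
def rates(genome, background_catalogs):
    return cc.estimate_break_rate(background_catalogs, genome)


@pytest.fixture(scope="session")
def planted_chain(genome):
    records, labels = cc.plant_chain(genome, cc.ChainSpec(), seed=7)
    return records, labels


@pytest.fixture(scope="session")
def detected_chain(planted_chain, rates):
    records, _ = planted_chain
    chains = cc.detect_chains(records, rates, cc.ChainConfig(t=1e-3, b_min=6))
    assert len(chains) == 1
    return chains[0]


@pytest.fixture(scope="session")
def contig_reference():
    return cc.random_reference({"refA": 40_000, "refB": 40_000}, seed=13)


@pytest.fixture(scope="session")
def synthetic_contig(contig_reference):
    return cc.make_contig(contig_reference, cc.ContigSpec(n_fragments=14), seed=17)
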