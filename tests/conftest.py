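"""Shared fixtures: the standard synthetic cross used across the suite.

The standard conditions mirror the study design: a 1 Mb genome pair at 1%
core divergence; clones carry a marker-covering fragment (log-uniform
10–500 kb) plus a Poisson(1.5) number of extra fragments in the marker
neighbourhood; clones are sequenced at 10x and pools of 50 clones at
100x aggregate, read length 150, substitution error 1e-3.
"""
from __future__ import annotations

import numpy as np
import pytest

from hfrmap.classify import classify_builtin
from hfrmap.distributions import FragmentLengthDistribution
from hfrmap.synthetic import (
    GenomePairConfig,
    build_pool,
    generate_genome_pair,
    simulate_reads,
    simulate_recombinant,
)

GENOME_LENGTH = 1_000_000
DIVERGENCE = 0.01
MARKER = 500_000
READ_LENGTH = 150
ERROR_RATE = 1e-3

MARKER_DIST = FragmentLengthDistribution("log_uniform", low=10_000, high=500_000)
EXTRA_DIST = FragmentLengthDistribution("log_uniform", low=1_000, high=100_000)
# clone fixture uses a 5 kb floor so every truth fragment spans >= 10
# polymorphic sites at 1% divergence (recovery is then exactly countable)
EXTRA_DIST_CLONES = FragmentLengthDistribution("log_uniform", low=5_000, high=100_000)


@pytest.fixture(scope="session")
def standard_pair():
    return generate_genome_pair(
        GenomePairConfig(genome_length=GENOME_LENGTH, divergence=DIVERGENCE, seed=1)
    )


@pytest.fixture(scope="session")
def small_pair():
    """100 kb pair with accessory segments on both sides, for unit tests."""
    return generate_genome_pair(
        GenomePairConfig(
            genome_length=100_000,
            divergence=0.01,
            accessory_segments=(("donor", 3_000, 1), ("recipient", 2_000, 1)),
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def standard_clones(standard_pair):
    """10 clones at 10x with truth and classified reads."""
    out = []
    for i in range(10):
        clone = simulate_recombinant(
            standard_pair,
            marker_position=MARKER,
            marker_dist=MARKER_DIST,
            extra_count=("poisson", 1.5),
            extra_dist=EXTRA_DIST_CLONES,
            seed=1_000 + i,
            clone_id=f"clone{i:02d}",
        )
        reads = simulate_reads(
            clone, depth=10.0, read_length=READ_LENGTH, error_rate=ERROR_RATE, seed=2_000 + i
        )
        out.append((clone, classify_builtin(reads, standard_pair)))
    return out


def _make_pool(pair, seed, n_clones=50, total_depth=100.0, counter_selected=None,
               placement="window", extra_count=("poisson", 1.5), extra_dist=EXTRA_DIST):
    rng_seeds = seed + np.arange(n_clones)
    clones = [
        simulate_recombinant(
            pair,
            marker_position=MARKER,
            marker_dist=MARKER_DIST,
            extra_count=extra_count,
            extra_dist=extra_dist,
            placement=placement,
            counter_selected=counter_selected,
            seed=int(s),
            clone_id=f"p{j:02d}",
        )
        for j, s in enumerate(rng_seeds)
    ]
    reads, manifest = build_pool(
        clones,
        weights=np.ones(n_clones),
        total_depth=total_depth,
        read_length=READ_LENGTH,
        error_rate=ERROR_RATE,
        seed=seed + 999,
    )
    classified = classify_builtin(reads, pair)
    truths = [c.truth for c in clones]  # drop the 1 Mb sequences, keep truth
    return truths, classified, manifest


@pytest.fixture(scope="session")
def standard_pool(standard_pair):
    """50-clone selected pool at 100x aggregate coverage."""
    return _make_pool(standard_pair, seed=40_000)


@pytest.fixture(scope="session")
def counter_selected_pool(standard_pair):
    """Pool with a counter-selected 3-kb cassette donor DNA never replaces.

    Pooled selections contain hundreds of recombinants; the pool size
    (250 clones) matters here because bins abutting the cassette are only
    reachable by fragments starting or ending within a few kb of it, and
    enough clones are needed for those bins to stay covered while the
    cassette itself is donor-free.
    """
    cassette = (800_000, 803_000)
    clones, classified, manifest = _make_pool(
        standard_pair,
        seed=50_000,
        n_clones=250,
        total_depth=60.0,
        counter_selected=cassette,
        placement="genome",
        extra_count=("poisson", 8.0),
        extra_dist=FragmentLengthDistribution("log_uniform", low=2_000, high=150_000),
    )
    return clones, classified, manifest, cassette
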