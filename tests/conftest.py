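"""Shared fixtures: the standard seeded synthetic community.

The standard community holds three genomes separated both in GC (0.35 /
0.50 / 0.65) and fold-coverage (5x / 20x / 80x), cut into contigs of at
least 5 kb with recorded provenance.  Heavier artifacts (the shotgun read
set) are session-scoped so they are simulated once.
"""

from __future__ import annotations

import pytest

from maglake import synthetic_community as sc
from maglake.marker_completeness import MarkerSet

COMMUNITY_SPECS = [
    # (id, gc, coverage, implanted markers out of the 35-gene set)
    ("gA", 0.35, 5.0, 34),
    ("gB", 0.50, 20.0, 35),
    ("gC", 0.65, 80.0, 30),
]
GENOME_LEN = 100_000
READ_LEN = 100
ERROR_RATE = 0.02


@pytest.fixture(scope="session")
def marker_set35() -> MarkerSet:
    return MarkerSet.bundled("set35")


@pytest.fixture(scope="session")
def community_genomes(marker_set35):
    return [
        sc.generate_genome(
            GENOME_LEN,
            gc,
            seed=i,
            genome_id=gid,
            markers=marker_set35.markers[:n_markers],
        )
        for i, (gid, gc, _cov, n_markers) in enumerate(COMMUNITY_SPECS)
    ]


@pytest.fixture(scope="session")
def community_contigs(community_genomes):
    contigs = []
    for i, (genome, (_gid, _gc, cov, _nm)) in enumerate(
        zip(community_genomes, COMMUNITY_SPECS)
    ):
        contigs.extend(
            sc.fragment_genome(
                genome, n_contigs=15, min_len=5000, seed=100 + i,
                coverage={"sample1": cov},
            )
        )
    return contigs


@pytest.fixture(scope="session")
def community_reads(community_genomes):
    coverages = {gid: cov for gid, _gc, cov, _nm in COMMUNITY_SPECS}
    return sc.simulate_reads(
        community_genomes, coverages, read_len=READ_LEN,
        error_rate=ERROR_RATE, seed=7,
    )
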