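"""Shared fixtures: a small simulated world reused across the unit tests."""
from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from abclip.simulate import SimConfig, generate_reads, make_genome, plant_sites

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A scaled-down 3-plex used by most unit tests (fast to simulate)."""
    return SimConfig(
        chrom_lengths=(120_000, 120_000),
        n_transcripts=16,
        sites_per_rbp=2,
        n_shared_sites=1,
        reads_per_rbp=4_000,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    """(genome, models, sites, truth reads) for the small 3-plex."""
    genome, models = make_genome(small_config)
    sites = plant_sites(models, small_config)
    truth = generate_reads(models, sites, small_config)
    return genome, models, sites, truth
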