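from __future__ import annotations

import pytest

from riboproteo.footprints import build_track
from riboproteo.models import TranscriptIndex
from riboproteo.synthetic_data import (
    SimConfig,
    simulate_footprints,
    simulate_genome,
    simulate_psm_table,
)


@pytest.fixture(scope="session")
def clean_config() -> SimConfig:
    """Noise- and jitter-free study conditions with strong LTM signal."""
    return SimConfig(
        seed=101,
        n_genes=20,
        ltm_jitter=0.0,
        noise_fraction=0.0,
        ltm_reads_per_tis=200.0,
        decoy_fraction=0.0,
    )


@pytest.fixture(scope="session")
def clean_sim(clean_config):
    genome, models, truth = simulate_genome(clean_config)
    return genome, models, truth


@pytest.fixture(scope="session")
def clean_tracks(clean_config, clean_sim):
    genome, models, truth = clean_sim
    ltm_reads, chx_reads = simulate_footprints(genome, models, truth, clean_config)
    index = TranscriptIndex(models)
    ltm = build_track(ltm_reads, "LTM", index)
    chx = build_track(chx_reads, "CHX", index)
    return ltm, chx, ltm_reads, chx_reads


@pytest.fixture(scope="session")
def clean_psms(clean_config, clean_sim):
    _, _, truth = clean_sim
    return simulate_psm_table(truth, clean_config)
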