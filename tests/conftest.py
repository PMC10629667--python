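"""Shared fixtures: small deterministic libraries and annotation bundles.

Expensive fixtures (the full 20k-read libraries used by the end-to-end
checks) are session-scoped so they are simulated once per run.
"""

from __future__ import annotations

import pytest

from slurptassel.simulate import (
    SimConfig,
    make_annotation,
    simulate_library,
)


@pytest.fixture(scope="session")
def default_spike_library():
    """20k-read direct-cDNA library from the spike-in ladder, seed 42."""
    config = SimConfig(seed=42, n_reads=20_000)
    reads, truth, bundle = simulate_library(config, which="spikeins")
    return config, reads, truth, bundle


@pytest.fixture(scope="session")
def small_spike_library():
    """2k-read library for cheaper module-level checks."""
    config = SimConfig(seed=7, n_reads=2_000)
    reads, truth, bundle = simulate_library(config, which="spikeins")
    return config, reads, truth, bundle


@pytest.fixture(scope="session")
def clean_spike_library():
    """Error-free, artifact-free, full-length library (orientation truth only)."""
    config = SimConfig(
        seed=11, n_reads=500, sub_rate=0.0, ins_rate=0.0, del_rate=0.0,
        artifact_rate=0.0, full_length_prob=1.0,
    )
    reads, truth, bundle = simulate_library(config, which="spikeins")
    return config, reads, truth, bundle


@pytest.fixture(scope="session")
def genome_bundle():
    """Small truth genome/annotation for merge and comparison fixtures."""
    config = SimConfig(seed=5, genome_size=800_000, n_genes=80)
    return config, make_annotation(config)
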