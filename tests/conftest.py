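"""Shared fixtures: small, fast simulation scenarios."""

from __future__ import annotations

import pytest

from uidseq.simulate import SimConfig, SpikedMutation, simulate_reads


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A small but non-trivial library: 2k fragments, 20k reads."""
    return SimConfig(
        reference_length=12_000,
        panel_regions=((1_000, 11_000),),
        n_fragments=2_000,
        pcr_cycles=10,
        carrying_capacity=100_000,
        reads_sequenced=20_000,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_run(small_config):
    """(reads, truth, fragments) for the small library."""
    return simulate_reads(small_config)


@pytest.fixture(scope="session")
def clean_config() -> SimConfig:
    """Error-free small library (all error rates zero)."""
    return SimConfig(
        reference_length=12_000,
        panel_regions=((1_000, 11_000),),
        n_fragments=500,
        pcr_cycles=8,
        carrying_capacity=20_000,
        polymerase_error_rate=0.0,
        seq_error_rate=0.0,
        uid_error_rate=0.0,
        reads_sequenced=6_000,
        read_length=None,
        seed=11,
    )


@pytest.fixture(scope="session")
def clean_run(clean_config):
    return simulate_reads(clean_config)
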