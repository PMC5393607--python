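import dataclasses

import pytest

from bivalscreen import PipelineConfig, SimConfig, run_screen, run_simulate


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    """The packaged osteoclast scenario at its documented defaults (seed 42)."""
    return SimConfig()


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A desk-sized scenario for fast unit tests (same model, smaller genome)."""
    return SimConfig(
        n_genes=120,
        n_chroms=2,
        chrom_length=2_000_000,
        n_switch=10,
        n_tf_bound=6,
        seed=7,
    )


@pytest.fixture(scope="session")
def osteoclast_run(tmp_path_factory, default_config):
    """One full default simulate + screen run, shared across the session.

    Returns (sim_result, screen_summary, sim_config).
    """
    out = tmp_path_factory.mktemp("osteoclast")
    sim = run_simulate(default_config, out / "sim")
    summary = run_screen(sim["screen_config"])
    return sim, summary, default_config


@pytest.fixture(scope="session")
def small_run(tmp_path_factory, small_config):
    out = tmp_path_factory.mktemp("small")
    sim = run_simulate(small_config, out / "sim")
    summary = run_screen(sim["screen_config"])
    return sim, summary, small_config
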