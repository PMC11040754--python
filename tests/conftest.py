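"""Shared fixtures: small synthetic quartets computed once per session."""

import pytest

from pantropon.io import PipelineConfig, fate_stage, origin_stage
from pantropon.simulate import SimulationConfig, simulate_quartet


def small_config(seed: int = 3) -> SimulationConfig:
    """Reduced-scale quartet: every planted feature class present, fast."""
    return SimulationConfig(
        seed=seed, ancestor_length_bp=2_000_000, n_chromosomes=2, n_genes=100,
        n_ltr_per_family=20, n_nascent_per_genome=10, nascent_len_range=(8000, 16000),
        n_lost_per_subgenome=10, lost_len_range=(8000, 16000), n_accessions=30,
        n_lost_both=5, n_reverted_per_subgenome=8, n_gained=6, n_favorable=5)


@pytest.fixture(scope="session")
def small_cfg():
    return small_config()


@pytest.fixture(scope="session")
def small_quartet(small_cfg):
    return simulate_quartet(small_cfg)


@pytest.fixture(scope="session")
def default_quartet():
    """Full default scale (200 planted LTR elements), for estimator recovery."""
    return simulate_quartet(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_origin_report(small_quartet):
    quartet, truth = small_quartet
    return origin_stage(quartet, PipelineConfig(), truth)


@pytest.fixture(scope="session")
def small_fate_report(small_quartet):
    quartet, truth = small_quartet
    return fate_stage(quartet, PipelineConfig(), truth)
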