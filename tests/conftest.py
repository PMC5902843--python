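import numpy as np
import pytest

from splicemark.simulate import (
    SimConfig,
    simulate_annotation,
    simulate_coverage,
    simulate_junction_counts,
)


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(n_genes=60, n_celltypes=4, seed=11)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    return simulate_annotation(small_cfg)


@pytest.fixture(scope="session")
def small_tracks(small_cfg, small_sim):
    annotation, events, truth = small_sim
    tracks, truth_peaks = simulate_coverage(events, annotation, truth, small_cfg)
    return tracks, truth_peaks


@pytest.fixture(scope="session")
def small_counts(small_cfg, small_sim):
    annotation, events, truth = small_sim
    return simulate_junction_counts(events, truth, small_cfg)


@pytest.fixture(scope="session")
def default_cfg():
    """The desk-scale study conditions every calibration test runs at."""
    return SimConfig(seed=2024)


@pytest.fixture(scope="session")
def default_sim(default_cfg):
    return simulate_annotation(default_cfg)
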