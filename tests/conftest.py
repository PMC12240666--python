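"""Shared fixtures: small synthetic configurations and generated subjects."""

import numpy as np
import pytest

from gstopo.synthetic import SimulationConfig, generate_parcellation, generate_subject


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Desk-scale config small enough for per-test image work."""
    return SimulationConfig(
        n_sites=2, subjects_per_site_per_group=2, grid_shape=(14, 14, 10),
        n_rois=12, n_timepoints=80, n_discard=3, seed=11,
        effect_rois=(1, 2), clinical_link_rois=(5, 6),
    )


@pytest.fixture(scope="session")
def small_parcellation(small_config):
    return generate_parcellation(small_config)


@pytest.fixture(scope="session")
def small_subject(small_config, small_parcellation):
    """One generated subject (BOLD, masks, motion, GMV, truth)."""
    return generate_subject(small_config, site=0, group="MDD_anx", index=0,
                            parcellation=small_parcellation)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
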