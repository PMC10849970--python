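"""Shared fixtures: small synthetic recordings generated at test time."""

import numpy as np
import pytest

from respdyn import synthetic


@pytest.fixture(scope="session")
def eupnea_small():
    """60-s default (saddle) eupnea recording with 30 units."""
    cfg = synthetic.GroundTruthConfig(duration=60.0, n_units=30, seed=11)
    return synthetic.generate_dataset(cfg)


@pytest.fixture(scope="session")
def node_small():
    """90-s spiral/node recording with 40 units (representable switching)."""
    cfg = synthetic.spiral_node_config(seed=21, duration=90.0, n_units=40)
    return synthetic.generate_dataset(cfg)


@pytest.fixture(scope="session")
def archetypes():
    """Three-archetype tuning family with nominal coherence bounds."""
    return synthetic.make_archetype_tunings(seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
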