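import numpy as np
import pandas as pd
import pytest

from cpmflow import Atlas, generate_atlas


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def small_atlas():
    """Deterministic 12-node atlas with both hemispheres and all networks."""
    return generate_atlas(12, seed=7)


@pytest.fixture
def tiny_atlas_2l2r():
    """Four nodes, two per hemisphere, for exhaustive edge classification."""
    return Atlas(pd.DataFrame({
        "node_id": [1, 2, 3, 4],
        "hemisphere": ["L", "L", "R", "R"],
        "network": ["MF", "FP", "DMN", "Mot"],
        "region": ["prefrontal", "prefrontal", "parietal", "motor"],
        "x": [-40.0, -20.0, 40.0, 20.0],
        "y": [10.0, -60.0, 10.0, -60.0],
        "z": [0.0, 20.0, 0.0, 20.0],
    }))
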