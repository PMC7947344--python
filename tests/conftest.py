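import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracles.py

import ryrclust as rc


@pytest.fixture(scope="session")
def small_sim_config() -> rc.SimulationConfig:
    """A 4 x 4 µm field: ~69 clusters, fast to build and analyze."""
    return rc.SimulationConfig(field_size=(4000.0, 4000.0), seed=11)


@pytest.fixture(scope="session")
def small_scene(small_sim_config) -> rc.GroundTruthScene:
    return rc.build_scene(small_sim_config)


@pytest.fixture(scope="session")
def recovery_runs():
    """Three full simulate→analyze runs at full labelling, shared across tests."""
    runs = []
    for seed in (21, 22, 23):
        sim = rc.SimulationConfig(field_size=(6000.0, 6000.0), seed=seed,
                                  labeling_efficiency=1.0)
        scene = rc.build_scene(sim)
        events = rc.simulate_events(scene, sim)
        actinin = rc.simulate_actinin_widefield(scene)
        result = rc.analyze_image(events=events, actinin=actinin,
                                  config=rc.PipelineConfig())
        runs.append((scene, result))
    return runs


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
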