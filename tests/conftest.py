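import numpy as np
import pytest
from hypothesis import settings

import flashschool as fs

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def short_scene():
    """A small rendered scene with ground truth, shared across tests."""
    cfg = fs.SceneConfig(seed=7)
    stack, truth = fs.make_flash_scene(cfg, n_frames=120)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def default_run():
    """One medium school run at defaults, shared by dynamics tests."""
    cfg = fs.SimConfig(n_fish=80, seed=5)
    return cfg, fs.run_simulation(cfg, 600)


def make_agent(position, velocity=(0, 0, 0), flashing=True, **kw):
    return fs.AgentState(
        position=np.asarray(position, dtype=float),
        velocity=np.asarray(velocity, dtype=float),
        is_flashing=flashing,
        **kw,
    )
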