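import numpy as np
import pytest

from feedscope import GeneratorConfig, generate_session
from feedscope.datatypes import Arena, PoseTrack


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    return GeneratorConfig(n_cells=20, duration=300.0)


@pytest.fixture(scope="session")
def small_session(small_config):
    return generate_session(small_config, seed=101)


@pytest.fixture(scope="session")
def medium_session():
    cfg = GeneratorConfig(n_cells=30, duration=600.0)
    return generate_session(cfg, seed=202)


def make_pose(
    head: np.ndarray,
    rate: float = 30.0,
    target: np.ndarray | None = None,
    arena: Arena | None = None,
) -> PoseTrack:
    """Pose track whose ear midpoint equals the given head trajectory."""
    head = np.asarray(head, dtype=float)
    n = head.shape[0]
    time = np.arange(n) / rate
    offset = np.array([0.0, 1.0])
    parts = {
        "nose": head + np.array([1.5, 0.0]),
        "ear_left": head + offset,
        "ear_right": head - offset,
        "tailbase": head - np.array([3.0, 0.0]),
    }
    if target is not None:
        target = np.broadcast_to(np.asarray(target, float), (n, 2)).copy()
    return PoseTrack(time=time, parts=parts, target=target, arena=arena)
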