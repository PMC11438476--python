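import numpy as np
import pytest

from ssgpos import PlayerInfo, TrajectorySet
from ssgpos.synthetic import SimulationParams, simulate_bout


@pytest.fixture
def rng():
    return np.random.default_rng(20240909)


@pytest.fixture
def four_player_traj():
    """Two teams of four outfield players on a 20-frame uniform grid."""
    rng = np.random.default_rng(7)
    players = [PlayerInfo(f"{t}{i}", t) for t in "AB" for i in range(1, 5)]
    t = np.arange(20) / 10.0
    xy = rng.uniform([0, 0], [42, 29], size=(20, 8, 2))
    return TrajectorySet(players=players, t=t, xy=xy, fs=10.0)


@pytest.fixture
def short_bout():
    """A 30 s simulated bout with default (free-play-like) parameters."""
    traj, gt = simulate_bout(SimulationParams(duration_s=30.0, seed=42))
    return traj, gt
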