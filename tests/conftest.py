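import numpy as np
import pytest

from mazeplan.planners import MazeModel
from mazeplan.synthetic_data import fixture_mazes, generate_maze


@pytest.fixture(scope="session")
def fixtures():
    return fixture_mazes()


@pytest.fixture(scope="session")
def fixture_models(fixtures):
    return {name: MazeModel(m, maze_id=name) for name, m in fixtures.items()}


@pytest.fixture(scope="session")
def small_maze_battery():
    """Ten small generated mazes shared across tests (expensive to build)."""
    rng = np.random.default_rng(2024)
    return {
        f"m{i:02d}": generate_maze(rng, n_rooms=int(rng.integers(2, 6)))
        for i in range(10)
    }


@pytest.fixture(scope="session")
def battery_models(small_maze_battery):
    return {n: MazeModel(m, maze_id=n) for n, m in small_maze_battery.items()}


@pytest.fixture(scope="session")
def deep_battery_models():
    """Deeper mazes (5-7 rooms) where look-ahead and discounting matter."""
    rng = np.random.default_rng(99)
    return {
        f"d{i:02d}": MazeModel(
            generate_maze(rng, n_rooms=int(rng.integers(5, 8))), maze_id=f"d{i:02d}"
        )
        for i in range(12)
    }


@pytest.fixture()
def simple_two_room(fixtures):
    return fixtures["corridor"]
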