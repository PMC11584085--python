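"""Synthetic mazes and cohorts with known generating parameters.

Three pieces: a rejection-sampling random maze generator (rooms hang off a
corridor trunk via bent branches, so every room is hidden until its doorway
and then fully visible); hand-coded fixture mazes whose decision structure
discriminates between model families (property-checked at load); and a
cohort generator that simulates softmax agents over a maze battery and
attaches decision times linear in the generating parameters plus noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .decision_tree import build_tree
from .errors import FixtureError, GenerationError
from .maze_world import GridMaze, make_maze, validate_maze
from .planners import (
    MazeModel,
    ModelParams,
    cost_du,
    cost_eu,
    heuristic_cost,
    simulate_agent,
)
from .records import DecisionRecord


# -- random maze generation --------------------------------------------------


def _paint_branch(
    grid: dict, trunk_row: int, col: int, up: bool, side: int,
    up_len: int, side_len: int, room_len: int, letter: str,
    width: int, height: int,
) -> bool:
    """Paint one branch: vertical stub, sideways stub, then a 1-wide room
    extending away from the trunk, entered end-on from the branch tip.
    Returns False on overlap, bounds violation, or missing wall margin."""
    tiles: list[tuple[int, int, str]] = []
    dr = -1 if up else 1
    r = trunk_row
    for _ in range(up_len):
        r += dr
        tiles.append((col, r, "."))
    c = col
    for _ in range(side_len):
        c += side
        tiles.append((c, r, "."))
    for k in range(1, room_len + 1):
        tiles.append((c, r + dr * k, letter))
    occupied = {(t[0], t[1]) for t in tiles}
    for cc, rr, _ch in tiles:
        if not (1 <= cc < width - 1 and 1 <= rr < height - 1):
            return False
        if (cc, rr) in grid:
            return False
        for dc in (-1, 0, 1):
            for drr in (-1, 0, 1):
                nb = (cc + dc, rr + drr)
                if nb in grid and nb not in occupied and nb[1] != trunk_row:
                    return False
    for cc, rr, ch in tiles:
        grid[(cc, rr)] = ch
    return True


def generate_maze(
    rng: np.random.Generator,
    n_rooms: int = 4,
    room_size_range: tuple[int, int] = (2, 6),
    max_attempts: int = 400,
    node_cap: int = 200_000,
) -> GridMaze:
    """Rejection-sample a validated maze with exactly ``n_rooms`` rooms.

    The result passes :func:`validate_maze` with no partial-visibility
    warnings, builds a decision tree under ``node_cap``, and offers at least
    two root choices. The exit is uniform over room tiles.
    """
    lo, hi = room_size_range
    lengths = [n for n in range(max(2, lo), min(6, hi) + 1)]
    if not lengths or n_rooms < 1:
        raise GenerationError(
            f"infeasible parameters: {n_rooms} rooms of size {room_size_range}"
        )

    for _ in range(max_attempts):
        n_blocks = (n_rooms + 1) // 2
        block_w = 7
        width = 4 + block_w * n_blocks
        height = 19
        trunk_row = 9
        grid: dict[tuple[int, int], str] = {}
        for c in range(2, width - 2):
            grid[(c, trunk_row)] = "."
        ok = True
        for i in range(n_rooms):
            block, up = i // 2, i % 2 == 0
            col = 4 + block * block_w + int(rng.integers(0, 2))
            side = int(rng.choice([-1, 1]))
            up_len = int(rng.integers(2, 4))
            side_len = int(rng.integers(2, 4))
            room_len = lengths[int(rng.integers(len(lengths)))]
            if not _paint_branch(
                grid, trunk_row, col, up, side, up_len, side_len, room_len,
                chr(ord("a") + i), width, height,
            ):
                ok = False
                break
        if not ok:
            continue
        start_col = int(rng.integers(2, width - 2))
        if grid.get((start_col, trunk_row)) != ".":
            continue
        lines = [
            "".join(grid.get((c, r), "#") for c in range(width))
            for r in range(height)
        ]
        row = list(lines[trunk_row])
        row[start_col] = "S"
        lines[trunk_row] = "".join(row)
        room_tiles = sorted(t for t, ch in grid.items() if ch.islower())
        exit_tile = room_tiles[int(rng.integers(len(room_tiles)))]
        try:
            maze = make_maze("\n".join(lines), exit=exit_tile, name="generated")
        except Exception:
            continue
        if len(maze.rooms) != n_rooms:
            continue
        report = validate_maze(maze)
        if not report.ok or report.warnings:
            continue
        try:
            root = build_tree(maze, node_cap=node_cap)
        except Exception:
            continue
        if len(root.children) < min(2, n_rooms):
            continue
        return maze
    raise GenerationError(
        f"could not generate a valid {n_rooms}-room maze in {max_attempts} attempts"
    )


# -- fixture mazes -----------------------------------------------------------

# Two equidistant (s=5) six-tile rooms: a 1x6 line room (mean exit distance
# 3.5, worst case 6) vs a 2x3 block over a widened doorway (mean 2.5, worst
# 4). EU, PW and all heuristics tie at the root; DU(gamma<1) strictly
# prefers the compact block.
_LONG_COMPACT = """
################
######a#########
######a#########
######a#########
######a#####bb##
######a#####bb##
######a#####bb##
######..###...##
#######.###.####
#######..S..####
################
"""

# Near small room (4 tiles, 2 steps) vs far big room (8 tiles, 4 steps),
# with the vantage-to-vantage distance making the EU costs tie exactly,
# while DU and Steps prefer near and Cells prefers far.
_NEAR_FAR = """
#################
#############b###
#############b###
#############b###
#############b###
#######a#####b###
#######a#####b###
#######a#####b###
#######a#####b###
#######..S....###
#################
"""

# Both root options cost 2 steps and reveal 6 cells (all heuristics tied);
# a third room hides behind the right one, so planners are not indifferent.
_TIED_HEURISTICS = """
#################
######a###b######
######a###b######
######a###b######
######a###b##c###
######a###b##c###
######a###b##c###
######..S.....###
#################
"""

# Four rooms behind four two-step arms: four root children.
_FOUR_ROOMS = """
##############
##############
##########d###
#####ccc.#d###
########.#d###
######..S..###
######a#.#####
######a#.bbb##
######a#######
##############
"""

# Ring corridor: one room observable from both ends of the loop at
# different distances, plus a second room off a bent stub — more than two
# root children for a two-room maze.
_LOOPED = """
#########
#########
##.....##
##.###a##
##S###a##
##.###a##
##.###a##
##.###.##
##.....##
####.####
####.b###
#########
"""

# Minimal two-room corridor maze for oracle unit tests.
_CORRIDOR = """
#########
######b##
##a###b##
##a###b##
##..S..##
#########
"""

_FIXTURE_SPECS: dict[str, tuple[str, tuple[int, int]]] = {
    "long_compact": (_LONG_COMPACT, (6, 3)),
    "near_far": (_NEAR_FAR, (13, 5)),
    "tied_heuristics": (_TIED_HEURISTICS, (6, 3)),
    "four_rooms": (_FOUR_ROOMS, (6, 7)),
    "looped": (_LOOPED, (6, 5)),
    "corridor": (_CORRIDOR, (6, 2)),
}


def fixture_mazes(verify: bool = True) -> dict[str, GridMaze]:
    """Hand-coded discriminating mazes, property-checked at load."""
    out = {
        name: make_maze(grid, exit=exit_tile, name=name)
        for name, (grid, exit_tile) in _FIXTURE_SPECS.items()
    }
    if verify:
        _verify_fixtures(out)
    return out


def _verify_fixtures(mazes: dict[str, GridMaze]) -> None:
    for name, maze in mazes.items():
        report = validate_maze(maze)
        if not report.ok:
            raise FixtureError(f"{name}: {report.failures}")
        if report.warnings:
            raise FixtureError(f"{name}: partial visibility: {report.warnings}")

    root = build_tree(mazes["long_compact"])
    kids = root.children
    if len(kids) != 2:
        raise FixtureError("long_compact: expected 2 root children")
    if not (kids[0].s == kids[1].s == 5 and kids[0].cells == kids[1].cells == 6):
        raise FixtureError("long_compact: root children must be (s=5, cells=6)")
    if abs(kids[0].p - kids[1].p) > 1e-12 or abs(kids[0].e - kids[1].e) < 1e-9:
        raise FixtureError("long_compact: need equal p, different e")
    if abs(cost_eu(kids[0]) - cost_eu(kids[1])) > 1e-9:
        raise FixtureError("long_compact: EU must tie at the root")
    du = [cost_du(k, 0.8) for k in kids]
    compact = min(range(2), key=lambda i: kids[i].e)
    if not du[compact] < du[1 - compact] - 1e-9:
        raise FixtureError("long_compact: DU(0.8) must prefer the compact room")

    root = build_tree(mazes["near_far"])
    kids = sorted(root.children, key=lambda k: k.s)
    if len(kids) != 2 or (kids[0].s, kids[0].cells) != (2, 4) or (
        kids[1].s, kids[1].cells
    ) != (4, 8):
        raise FixtureError("near_far: need (s=2, 4 tiles) vs (s=4, 8 tiles) rooms")
    if abs(cost_eu(kids[0]) - cost_eu(kids[1])) > 1e-9:
        raise FixtureError("near_far: EU must tie at the root")
    if not cost_du(kids[0], 0.8) < cost_du(kids[1], 0.8) - 1e-9:
        raise FixtureError("near_far: DU must prefer the near room")

    root = build_tree(mazes["tied_heuristics"])
    kids = root.children
    if len(kids) != 2 or {(k.s, k.cells) for k in kids} != {(2, 6)}:
        raise FixtureError("tied_heuristics: root children must both be (s=2, cells=6)")
    for h in ("Steps", "Cells", "Steps-Cells"):
        c = [heuristic_cost(k, h) for k in kids]
        if abs(c[0] - c[1]) > 1e-12:
            raise FixtureError(f"tied_heuristics: heuristic {h} must tie")
    if abs(cost_eu(kids[0]) - cost_eu(kids[1])) < 1e-9:
        raise FixtureError("tied_heuristics: EU must not tie")

    root = build_tree(mazes["four_rooms"])
    if len(root.children) != 4:
        raise FixtureError("four_rooms: expected 4 root children")

    root = build_tree(mazes["looped"])
    if len(mazes["looped"].rooms) != 2 or len(root.children) <= 2:
        raise FixtureError("looped: two-room maze must have >2 root children")


# -- cohorts -----------------------------------------------------------------


@dataclass(frozen=True)
class TimeModel:
    """Linear decision-time generator: time = const + Σ coef·param + noise."""

    initial: dict[str, float] = field(
        default_factory=lambda: {"const": 3200.0, "tau": -250.0, "gamma": 500.0}
    )
    subsequent: dict[str, float] = field(
        default_factory=lambda: {"const": 900.0, "tau": 60.0, "gamma": -130.0}
    )
    noise_sd: float = 400.0
    floor_ms: float = 100.0


@dataclass(frozen=True)
class CohortConfig:
    n_participants: int
    mixture: dict[str, float]  # model_id -> proportion
    param_values: dict[str, dict[str, list]]  # model -> param -> choices
    time_model: TimeModel = field(default_factory=TimeModel)
    master_seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture proportions sum to {total}, expected 1")
        if self.time_model.noise_sd < 0:
            raise ValueError("noise SD must be nonnegative")


def _draw_params(
    model_id: str, spec: dict[str, list], rng: np.random.Generator
) -> ModelParams:
    kwargs = {}
    for name, choices in spec.items():
        value = choices[int(rng.integers(len(choices)))]
        kwargs[name] = value
    return ModelParams(model_id=model_id, **kwargs)


def _time_value(coefs: dict[str, float], params: ModelParams) -> float:
    value = coefs.get("const", 0.0)
    value += coefs.get("tau", 0.0) * params.tau
    value += coefs.get("gamma", 0.0) * params.gamma
    value += coefs.get("B", 0.0) * params.B
    value += coefs.get("b", 0.0) * abs(params.beta - 1.0)
    return value


def generate_cohort(
    config: CohortConfig,
    maze_models: dict[str, MazeModel],
) -> tuple[list[DecisionRecord], pd.DataFrame]:
    """Simulate a cohort over the maze battery.

    Per participant a generating model and parameters are drawn from the
    config, every maze is played by softmax simulation, and decision times
    follow the linear time model with Gaussian noise (floored). All
    randomness derives from per-participant seeds spawned from the master
    seed, so identical configs reproduce identical cohorts.
    """
    model_ids = sorted(config.mixture)
    probs = np.array([config.mixture[m] for m in model_ids])
    records: list[DecisionRecord] = []
    truth_rows = []
    for i in range(config.n_participants):
        rng = np.random.default_rng(np.random.SeedSequence([config.master_seed, i]))
        pid = f"p{i:04d}"
        model_id = model_ids[int(rng.choice(len(model_ids), p=probs))]
        params = _draw_params(model_id, config.param_values.get(model_id, {}), rng)
        truth_rows.append(
            {
                "participant_id": pid,
                "model_id": model_id,
                "tau": params.tau,
                "gamma": params.gamma,
                "beta": params.beta,
                "B": params.B,
                "k_weight": params.k_weight,
            }
        )
        tm = config.time_model
        for maze_id in sorted(maze_models):
            mm = maze_models[maze_id]
            _, recs = simulate_agent(mm.maze, params, rng, model=mm, participant_id=pid)
            for r in recs:
                coefs = tm.initial if r.is_initial else tm.subsequent
                t = _time_value(coefs, params) + rng.normal(0.0, tm.noise_sd)
                records.append(replace(r, decision_time_ms=max(tm.floor_ms, t)))
    return records, pd.DataFrame(truth_rows)
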