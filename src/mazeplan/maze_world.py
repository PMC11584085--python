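"""Grid-maze geometry: tiles, line-of-sight, shortest paths, and room revelation.

A maze is a rectangular grid of unit-square tiles. Each tile is a wall, a
corridor, or part of a *room* — a cluster of initially hidden tiles that is
revealed all at once when any of its tiles enters the agent's line of sight.
Coordinates are ``(col, row)``, 0-based, origin at the top-left. Movement is
4-connected over non-wall tiles.

Visibility uses a corner-discretized isovist: a target tile is visible from
the observer's tile iff each of the target's four corners is joined to at
least one of the observer's four corners by a segment that does not pass
through (or graze along) any wall square. This realises the rule that the
target's entire area must be seeable from somewhere within the observer's
cell, and makes visibility symmetric and deterministic.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import yaml

from .errors import (
    InvalidLocationError,
    InvalidMoveError,
    MazeValidationError,
    NoPathError,
)

Tile = tuple[int, int]

WALL = 0
CORRIDOR = 1
ROOM = 2

_KIND_NAMES = {WALL: "wall", CORRIDOR: "corridor", ROOM: "room"}


@dataclass
class GridMaze:
    """Static maze geometry.

    Attributes
    ----------
    width, height:
        Tile counts along columns and rows.
    kind:
        ``(height, width)`` int array of tile kinds (WALL/CORRIDOR/ROOM).
    room_id:
        ``(height, width)`` int array; room identifier per tile, -1 elsewhere.
    rooms:
        Mapping room id -> frozenset of its tiles.
    start:
        Agent start tile (a corridor tile).
    exit:
        Exit tile (lies inside exactly one room).
    """

    width: int
    height: int
    kind: np.ndarray
    room_id: np.ndarray
    rooms: dict[int, frozenset[Tile]]
    start: Tile
    exit: Tile
    name: str = ""
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    # -- basic queries ----------------------------------------------------

    def in_bounds(self, t: Tile) -> bool:
        c, r = t
        return 0 <= c < self.width and 0 <= r < self.height

    def tile_kind(self, t: Tile) -> int:
        if not self.in_bounds(t):
            raise InvalidLocationError(f"tile {t} out of bounds")
        return int(self.kind[t[1], t[0]])

    def is_wall(self, t: Tile) -> bool:
        return self.tile_kind(t) == WALL

    def is_walkable(self, t: Tile) -> bool:
        return self.in_bounds(t) and self.kind[t[1], t[0]] != WALL

    def room_at(self, t: Tile) -> int | None:
        rid = int(self.room_id[t[1], t[0]])
        return rid if rid >= 0 else None

    def walkable_tiles(self) -> Iterator[Tile]:
        for r in range(self.height):
            for c in range(self.width):
                if self.kind[r, c] != WALL:
                    yield (c, r)

    def neighbors4(self, t: Tile) -> Iterator[Tile]:
        c, r = t
        for dc, dr in ((0, -1), (-1, 0), (1, 0), (0, 1)):
            u = (c + dc, r + dr)
            if self.is_walkable(u):
                yield u

    @property
    def total_room_tiles(self) -> int:
        return sum(len(ts) for ts in self.rooms.values())

    @property
    def exit_room(self) -> int:
        rid = self.room_at(self.exit)
        if rid is None:
            raise MazeValidationError(f"exit {self.exit} is not on a room tile")
        return rid

    # -- debug rendering --------------------------------------------------

    def to_ascii(self, letters: dict[int, str] | None = None) -> str:
        if letters is None:
            letters = {rid: chr(ord("a") + i) for i, rid in enumerate(sorted(self.rooms))}
        rows = []
        for r in range(self.height):
            row = []
            for c in range(self.width):
                t = (c, r)
                k = self.kind[r, c]
                if t == self.start:
                    row.append("S")
                elif t == self.exit:
                    row.append("!")
                elif k == WALL:
                    row.append("#")
                elif k == CORRIDOR:
                    row.append(".")
                else:
                    row.append(letters[int(self.room_id[r, c])])
            rows.append("".join(row))
        return "\n".join(rows)

    def __hash__(self) -> int:  # identity hash; mazes are treated as immutable
        return id(self)


@dataclass(frozen=True)
class BeliefState:
    """What the agent knows: its position and which rooms it has seen."""

    agent: Tile
    revealed_rooms: frozenset[int]
    exit_seen: bool


# -- segment-vs-wall geometry ---------------------------------------------

_EPS = 1e-9


def _wall_origins(maze: GridMaze) -> tuple[np.ndarray, np.ndarray]:
    cached = maze._cache.get("wall_origins")
    if cached is None:
        rs, cs = np.nonzero(maze.kind == WALL)
        cached = (cs.astype(float), rs.astype(float))
        maze._cache["wall_origins"] = cached
    return cached


def _slab_interval(p: float, d: float, lo: np.ndarray, hi: np.ndarray):
    """Parameter interval where the line p + t*d lies inside [lo, hi]."""
    if d == 0.0:
        inside = (lo <= p) & (p <= hi)
        t0 = np.where(inside, -np.inf, np.inf)
        t1 = np.where(inside, np.inf, -np.inf)
        return t0, t1
    ta = (lo - p) / d
    tb = (hi - p) / d
    return np.minimum(ta, tb), np.maximum(ta, tb)


def segment_clear(maze: GridMaze, a: tuple[float, float], b: tuple[float, float]) -> bool:
    """True iff the segment a-b touches no closed wall square except at its
    own endpoints. Grazing along a wall edge or passing through a wall corner
    counts as blocked."""
    if a == b:
        return True
    wx, wy = _wall_origins(maze)
    if wx.size == 0:
        return True
    x0, y0 = a
    x1, y1 = b
    tx0, tx1 = _slab_interval(x0, x1 - x0, wx, wx + 1.0)
    ty0, ty1 = _slab_interval(y0, y1 - y0, wy, wy + 1.0)
    t0 = np.maximum(np.maximum(tx0, ty0), 0.0)
    t1 = np.minimum(np.minimum(tx1, ty1), 1.0)
    hit = t0 <= t1 + _EPS
    interior = (t1 - t0 > _EPS) | ((t0 > _EPS) & (t0 < 1.0 - _EPS))
    return not bool(np.any(hit & interior))


def _corners(t: Tile) -> tuple[tuple[float, float], ...]:
    c, r = t
    return (
        (float(c), float(r)),
        (float(c + 1), float(r)),
        (float(c), float(r + 1)),
        (float(c + 1), float(r + 1)),
    )


def _corner_visible(maze: GridMaze, pa: tuple[float, float], pb: tuple[float, float]) -> bool:
    cache = maze._cache.setdefault("corner_vis", {})
    key = (pa, pb) if pa <= pb else (pb, pa)
    hit = cache.get(key)
    if hit is None:
        hit = segment_clear(maze, pa, pb)
        cache[key] = hit
    return hit


def _covers(maze: GridMaze, obs_corners, tgt_corners) -> bool:
    return all(
        any(_corner_visible(maze, oc, tc) for oc in obs_corners)
        for tc in tgt_corners
    )


def tile_visible(maze: GridMaze, observer: Tile, target: Tile) -> bool:
    """Corner-discretized full-area visibility between two tiles.

    Each corner of either tile must be joined by a wall-free segment to at
    least one corner of the other. Requiring both directions makes the
    relation symmetric (the one-directional corner rule is not: a corner of
    A may see no corner of B while every corner of B sees some corner of A)
    and therefore independent of evaluation order.
    """
    if observer == target:
        return True
    cache = maze._cache.setdefault("tile_vis", {})
    key = (observer, target) if observer <= target else (target, observer)
    res = cache.get(key)
    if res is not None:
        return res
    a, b = _corners(observer), _corners(target)
    res = _covers(maze, a, b) and _covers(maze, b, a)
    cache[key] = res
    return res


def compute_isovist(maze: GridMaze, observer: Tile) -> frozenset[Tile]:
    """Set of non-wall tiles fully visible from ``observer``, itself included."""
    if not maze.in_bounds(observer) or maze.is_wall(observer):
        raise InvalidLocationError(f"observer tile {observer} is not a free tile")
    cache = maze._cache.setdefault("isovist", {})
    iso = cache.get(observer)
    if iso is None:
        iso = frozenset(t for t in maze.walkable_tiles() if tile_visible(maze, observer, t))
        cache[observer] = iso
    return iso


def visible_rooms(maze: GridMaze, observer: Tile) -> frozenset[int]:
    """Rooms with at least one tile in the observer's isovist."""
    cache = maze._cache.setdefault("visible_rooms", {})
    out = cache.get(observer)
    if out is None:
        out = frozenset(
            rid for t in compute_isovist(maze, observer)
            if (rid := maze.room_at(t)) is not None
        )
        cache[observer] = out
    return out


# -- shortest paths --------------------------------------------------------


def distance_field(maze: GridMaze, source: Tile) -> dict[Tile, int]:
    """BFS distances from ``source`` over non-wall tiles (cached per source)."""
    if not maze.is_walkable(source):
        raise InvalidLocationError(f"source tile {source} is not walkable")
    cache = maze._cache.setdefault("dist", {})
    dist = cache.get(source)
    if dist is None:
        dist = {source: 0}
        q = deque([source])
        while q:
            t = q.popleft()
            d = dist[t]
            for u in maze.neighbors4(t):
                if u not in dist:
                    dist[u] = d + 1
                    q.append(u)
        cache[source] = dist
    return dist


def shortest_path_steps(maze: GridMaze, a: Tile, b: Tile) -> int:
    """Length of the shortest 4-connected path between two free tiles."""
    if not maze.is_walkable(a):
        raise InvalidLocationError(f"tile {a} is not walkable")
    if not maze.is_walkable(b):
        raise InvalidLocationError(f"tile {b} is not walkable")
    d = distance_field(maze, a).get(b)
    if d is None:
        raise NoPathError(f"no path between {a} and {b}")
    return d


def shortest_path(maze: GridMaze, a: Tile, b: Tile) -> list[Tile]:
    """One shortest path a..b inclusive (ties broken by neighbor order)."""
    dist = distance_field(maze, b)
    if a not in dist:
        raise NoPathError(f"no path between {a} and {b}")
    path = [a]
    t = a
    while t != b:
        t = min((u for u in maze.neighbors4(t) if u in dist), key=lambda u: dist[u])
        path.append(t)
    return path


# -- revelation mechanics ---------------------------------------------------


def reveal(maze: GridMaze, state: BeliefState, new_position: Tile) -> BeliefState:
    """Move to an adjacent tile (or stay) and reveal rooms entering the isovist.

    Any room with at least one tile visible from ``new_position`` is revealed
    in full. Monotone and idempotent in ``revealed_rooms``.
    """
    if not maze.in_bounds(new_position) or maze.is_wall(new_position):
        raise InvalidMoveError(f"cannot move into {new_position}")
    dc = abs(new_position[0] - state.agent[0])
    dr = abs(new_position[1] - state.agent[1])
    if dc + dr > 1:
        raise InvalidMoveError(
            f"move {state.agent} -> {new_position} is not a single step"
        )
    revealed = frozenset(state.revealed_rooms | visible_rooms(maze, new_position))
    exit_seen = state.exit_seen or maze.exit_room in revealed
    return BeliefState(agent=new_position, revealed_rooms=revealed, exit_seen=exit_seen)


def initial_state(maze: GridMaze) -> BeliefState:
    """Belief at trial start: standing on ``start`` with its isovist applied."""
    blank = BeliefState(agent=maze.start, revealed_rooms=frozenset(), exit_seen=False)
    return reveal(maze, blank, maze.start)


# -- validation --------------------------------------------------------------


@dataclass
class ValidationReport:
    failures: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


def _connected(tiles: frozenset[Tile]) -> bool:
    if not tiles:
        return False
    seen = set()
    q = deque([next(iter(tiles))])
    seen.add(next(iter(tiles)))
    while q:
        c, r = q.popleft()
        for dc, dr in ((0, -1), (-1, 0), (1, 0), (0, 1)):
            u = (c + dc, r + dr)
            if u in tiles and u not in seen:
                seen.add(u)
                q.append(u)
    return len(seen) == len(tiles)


def validate_maze(maze: GridMaze) -> ValidationReport:
    """Check all structural invariants; never raises — reports failures.

    Also warns about the partial-visibility hazard: a room whose entry tiles
    (tiles seeing part of the room while some neighbor on the approach does
    not see it at all) do not see the room in full. Under the all-at-once
    revelation convention such rooms reveal tiles that are not in view.
    """
    rep = ValidationReport()

    if not maze.in_bounds(maze.start):
        rep.failures.append(f"start {maze.start} out of bounds")
        return rep
    if maze.tile_kind(maze.start) != CORRIDOR:
        rep.failures.append(f"start {maze.start} is not a corridor tile")

    # rooms partition the room tiles
    seen: dict[Tile, int] = {}
    for rid, tiles in maze.rooms.items():
        if not tiles:
            rep.failures.append(f"room {rid} is empty")
            continue
        for t in tiles:
            if t in seen:
                rep.failures.append(f"tile {t} in rooms {seen[t]} and {rid}")
            seen[t] = rid
            if not maze.in_bounds(t) or maze.kind[t[1], t[0]] != ROOM:
                rep.failures.append(f"room {rid} tile {t} is not a room tile")
            elif maze.room_at(t) != rid:
                rep.failures.append(f"tile {t} labelled room {maze.room_at(t)}, listed in {rid}")
        if not _connected(tiles):
            rep.failures.append(f"room {rid} is not 4-connected")
    grid_rooms = {
        (c, r) for r in range(maze.height) for c in range(maze.width)
        if maze.kind[r, c] == ROOM
    }
    uncovered = grid_rooms - set(seen)
    if uncovered:
        rep.failures.append(f"room tiles not assigned to any room: {sorted(uncovered)}")

    # exit inside exactly one room
    exit_owner = [rid for rid, tiles in maze.rooms.items() if maze.exit in tiles]
    if len(exit_owner) != 1:
        rep.failures.append(f"exit {maze.exit} lies in {len(exit_owner)} rooms (need exactly 1)")

    # global connectivity
    if maze.is_walkable(maze.start):
        reach = set(distance_field(maze, maze.start))
        free = set(maze.walkable_tiles())
        if reach != free:
            rep.failures.append(
                f"{len(free - reach)} free tiles unreachable from start"
            )

    if rep.failures:
        return rep

    # partial-visibility hazard (warning only)
    for rid, tiles in maze.rooms.items():
        for t in maze.walkable_tiles():
            vis = compute_isovist(maze, t)
            n_vis = sum(1 for rt in tiles if rt in vis)
            if n_vis == 0:
                continue
            is_entry = t == maze.start or any(
                rid not in visible_rooms(maze, u) for u in maze.neighbors4(t)
            )
            if is_entry and n_vis < len(tiles):
                rep.warnings.append(
                    f"room {rid}: entry tile {t} sees {n_vis}/{len(tiles)} tiles"
                )
                break
    return rep


# -- construction and file formats ------------------------------------------


def make_maze(
    ascii_grid: str,
    exit: Tile | None = None,
    name: str = "",
) -> GridMaze:
    """Build a GridMaze from an ASCII sketch.

    ``#`` wall, ``.`` corridor, ``S`` start (corridor), lowercase letter a
    room tile of that letter's room, ``!`` the exit (room inferred from the
    unique adjacent room letter unless ``exit`` names the tile directly).
    """
    lines = [ln for ln in ascii_grid.strip("\n").splitlines()]
    height = len(lines)
    width = max(len(ln) for ln in lines)
    kind = np.zeros((height, width), dtype=np.int8)
    room_id = np.full((height, width), -1, dtype=np.int16)
    letters: dict[str, list[Tile]] = {}
    start = None
    exit_tile = exit
    bang = None
    for r, ln in enumerate(lines):
        for c, ch in enumerate(ln.ljust(width, "#")):
            t = (c, r)
            if ch == "#":
                continue
            if ch == "S":
                kind[r, c] = CORRIDOR
                start = t
            elif ch == ".":
                kind[r, c] = CORRIDOR
            elif ch == "!":
                kind[r, c] = ROOM
                bang = t
            elif ch.islower():
                kind[r, c] = ROOM
                letters.setdefault(ch, []).append(t)
            else:
                raise MazeValidationError(f"unknown maze character {ch!r} at {t}")
    if start is None:
        raise MazeValidationError("maze has no start tile 'S'")
    if bang is not None:
        if exit_tile is not None and exit_tile != bang:
            raise MazeValidationError("explicit exit disagrees with '!' marker")
        exit_tile = bang
        # attach the '!' tile to the unique adjacent room letter
        adj = {
            ch for ch, ts in letters.items()
            for t in ts
            if abs(t[0] - bang[0]) + abs(t[1] - bang[1]) == 1
        }
        if len(adj) != 1:
            raise MazeValidationError(
                f"exit marker at {bang} adjacent to {len(adj)} rooms; cannot infer room"
            )
        letters[adj.pop()].append(bang)
    if exit_tile is None:
        raise MazeValidationError("maze has no exit")
    rooms: dict[int, frozenset[Tile]] = {}
    for i, ch in enumerate(sorted(letters)):
        tiles = frozenset(letters[ch])
        rooms[i] = tiles
        for c, r in tiles:
            room_id[r, c] = i
    return GridMaze(
        width=width, height=height, kind=kind, room_id=room_id,
        rooms=rooms, start=start, exit=exit_tile, name=name,
    )


def with_exit(maze: GridMaze, exit: Tile) -> GridMaze:
    """Copy of the maze with the exit moved to another room tile."""
    if maze.room_at(exit) is None:
        raise MazeValidationError(f"exit {exit} must lie on a room tile")
    return GridMaze(
        width=maze.width, height=maze.height, kind=maze.kind,
        room_id=maze.room_id, rooms=maze.rooms, start=maze.start,
        exit=exit, name=maze.name,
    )


def with_random_exit(maze: GridMaze, rng: np.random.Generator) -> GridMaze:
    """Re-randomize the exit uniformly over all room tiles."""
    tiles = sorted(t for ts in maze.rooms.values() for t in ts)
    return with_exit(maze, tiles[int(rng.integers(len(tiles)))])


def _room_letters(maze: GridMaze) -> dict[int, str]:
    return {rid: chr(ord("a") + i) for i, rid in enumerate(sorted(maze.rooms))}


def dump_ascii(maze: GridMaze) -> tuple[str, str]:
    """Serialize to (grid text, YAML sidecar text). Round-trips bit-exactly."""
    letters = _room_letters(maze)
    grid = maze.to_ascii(letters)
    sidecar = {
        "width": maze.width,
        "height": maze.height,
        "name": maze.name,
        "rooms": {letters[rid]: rid for rid in sorted(maze.rooms)},
        "exit": [maze.exit[0], maze.exit[1]],
        "exit_room": letters[maze.exit_room],
    }
    return grid + "\n", yaml.safe_dump(sidecar, sort_keys=True)


def load_ascii(grid_text: str, sidecar_text: str) -> GridMaze:
    """Parse the ASCII grid + YAML sidecar pair written by :func:`dump_ascii`."""
    side = yaml.safe_load(sidecar_text)
    lines = grid_text.strip("\n").splitlines()
    height = len(lines)
    width = max(len(ln) for ln in lines)
    if width != side["width"] or height != side["height"]:
        raise MazeValidationError(
            f"grid is {width}x{height}, sidecar says {side['width']}x{side['height']}"
        )
    kind = np.zeros((height, width), dtype=np.int8)
    room_id = np.full((height, width), -1, dtype=np.int16)
    letter_to_id = dict(side["rooms"])
    tiles_by_id: dict[int, list[Tile]] = {rid: [] for rid in letter_to_id.values()}
    start = None
    exit_tile = (side["exit"][0], side["exit"][1])
    for r, ln in enumerate(lines):
        for c, ch in enumerate(ln.ljust(width, "#")):
            t = (c, r)
            if ch == "#":
                continue
            if ch == "S":
                kind[r, c] = CORRIDOR
                start = t
            elif ch == ".":
                kind[r, c] = CORRIDOR
            elif ch == "!":
                if t != exit_tile:
                    raise MazeValidationError(f"'!' at {t} but sidecar exit is {exit_tile}")
                rid = letter_to_id[side["exit_room"]]
                kind[r, c] = ROOM
                room_id[r, c] = rid
                tiles_by_id[rid].append(t)
            elif ch in letter_to_id:
                rid = letter_to_id[ch]
                kind[r, c] = ROOM
                room_id[r, c] = rid
                tiles_by_id[rid].append(t)
            else:
                raise MazeValidationError(f"unknown maze character {ch!r} at {t}")
    if start is None:
        raise MazeValidationError("maze has no start tile 'S'")
    rooms = {rid: frozenset(ts) for rid, ts in tiles_by_id.items()}
    return GridMaze(
        width=width, height=height, kind=kind, room_id=room_id,
        rooms=rooms, start=start, exit=exit_tile, name=side.get("name", ""),
    )


def dump_structured(maze: GridMaze) -> str:
    """Single-file YAML representation with explicit tile lists."""
    doc = {
        "format": "mazeplan-maze/1",
        "name": maze.name,
        "width": maze.width,
        "height": maze.height,
        "start": [maze.start[0], maze.start[1]],
        "exit": [maze.exit[0], maze.exit[1]],
        "corridors": sorted(
            [c, r] for (c, r) in maze.walkable_tiles() if maze.kind[r, c] == CORRIDOR
        ),
        "rooms": {
            int(rid): sorted([c, r] for (c, r) in tiles)
            for rid, tiles in sorted(maze.rooms.items())
        },
    }
    return yaml.safe_dump(doc, sort_keys=True)


def load_structured(text: str) -> GridMaze:
    doc = yaml.safe_load(text)
    if doc.get("format") != "mazeplan-maze/1":
        raise MazeValidationError(f"unknown maze format {doc.get('format')!r}")
    width, height = doc["width"], doc["height"]
    kind = np.zeros((height, width), dtype=np.int8)
    room_id = np.full((height, width), -1, dtype=np.int16)
    for c, r in doc["corridors"]:
        kind[r, c] = CORRIDOR
    rooms: dict[int, frozenset[Tile]] = {}
    for rid, tiles in doc["rooms"].items():
        rid = int(rid)
        rooms[rid] = frozenset((c, r) for c, r in tiles)
        for c, r in tiles:
            kind[r, c] = ROOM
            room_id[r, c] = rid
    return GridMaze(
        width=width, height=height, kind=kind, room_id=room_id, rooms=rooms,
        start=tuple(doc["start"]), exit=tuple(doc["exit"]),
        name=doc.get("name", ""),
    )
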