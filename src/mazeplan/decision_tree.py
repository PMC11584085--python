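"""Observation-order decision trees over a grid maze.

Each node is one observation event: a vantage tile plus the set of rooms
observed so far. Children of a node are the distinct next observations —
(vantage, co-revealed room set) pairs found by walking outward from the
node's vantage until an unrevealed room enters the line of sight.

Per-node statistics:

``s``      steps from the parent's vantage to this vantage,
``e``      mean steps from the vantage to each newly revealed tile
           (the expected distance to the exit if it is found here),
``p``      newly revealed tiles / tiles still unobserved before this node,
``cells``  number of newly revealed tiles.

Subtrees below a node depend only on (vantage, observed rooms), so equal
subproblems are shared: the structure is a DAG and leaf/path counts are
computed by path enumeration. With every room holding a single vantage and
all orders feasible this still yields n! root-to-leaf paths for n rooms.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Iterator

from .errors import TreeSizeError, UnobservableRoomError
from .maze_world import (
    GridMaze,
    Tile,
    distance_field,
    visible_rooms,
)

DEFAULT_NODE_CAP = 200_000


@dataclass(eq=False)
class TreeNode:
    node_id: int
    vantage: Tile
    observed_rooms: frozenset[int]
    new_rooms: frozenset[int]
    s: float
    e: float
    p: float
    cells: float
    remaining_before: float
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # compact, for debugging dumps
        return (
            f"TreeNode({self.node_id}, v={self.vantage}, new={sorted(self.new_rooms)}, "
            f"s={self.s}, e={self.e:.3f}, p={self.p:.3f}, cells={self.cells})"
        )


@dataclass(frozen=True)
class ObservationEvent:
    """A next-observation candidate: where to stand, how far, what it reveals."""

    vantage: Tile
    steps: int
    co_revealed: frozenset[int]


def enumerate_observation_events(
    maze: GridMaze, origin: Tile, revealed: frozenset[int]
) -> list[ObservationEvent]:
    """All next observation events reachable from ``origin``.

    Walks a BFS outward from ``origin``; a tile from which any unrevealed
    room has a visible tile is an *event* and is not walked through (the
    revelation would trigger there). Events are deduplicated by
    ``(steps, co_revealed)`` keeping the row-major-first vantage.
    """
    unrevealed = set(maze.rooms) - set(revealed)
    if not unrevealed:
        return []

    def trigger(t: Tile) -> frozenset[int]:
        return frozenset(visible_rooms(maze, t) & unrevealed)

    dist = {origin: 0}
    q = deque([origin])
    events: dict[tuple[int, frozenset[int]], Tile] = {}
    while q:
        t = q.popleft()
        d = dist[t]
        # expand in row-major neighbor order so first-found vantages are
        # row-major-minimal among equal (steps, co_revealed) keys
        for u in sorted(maze.neighbors4(t), key=lambda x: (x[1], x[0])):
            if u in dist:
                continue
            dist[u] = d + 1
            trig = trigger(u)
            if trig:
                key = (d + 1, trig)
                prev = events.get(key)
                if prev is None or (u[1], u[0]) < (prev[1], prev[0]):
                    events[key] = u
            else:
                q.append(u)
    return [
        ObservationEvent(vantage=v, steps=k[0], co_revealed=k[1])
        for k, v in sorted(events.items(), key=lambda kv: (kv[0][0], sorted(kv[0][1]), kv[1][1], kv[1][0]))
    ]


def enumerate_vantages(
    maze: GridMaze, origin: Tile, revealed: frozenset[int], room: int
) -> list[tuple[Tile, int]]:
    """Candidate observation points for one specific unrevealed room."""
    if room in revealed:
        raise ValueError(f"room {room} is already revealed")
    out = [
        (ev.vantage, ev.steps)
        for ev in enumerate_observation_events(maze, origin, revealed)
        if room in ev.co_revealed
    ]
    if not out:
        raise UnobservableRoomError(
            f"room {room} cannot be observed from {origin} given revealed={sorted(revealed)}"
        )
    return out


def node_statistics(
    maze: GridMaze,
    vantage: Tile,
    new_rooms: frozenset[int],
    revealed_before: frozenset[int],
    steps: int,
) -> tuple[int, float, float, int]:
    """(s, e, p, cells) for observing ``new_rooms`` from ``vantage``."""
    new_tiles = sorted(t for rid in new_rooms for t in maze.rooms[rid])
    cells = len(new_tiles)
    seen_before = sum(len(maze.rooms[rid]) for rid in revealed_before)
    remaining = maze.total_room_tiles - seen_before
    dist = distance_field(maze, vantage)
    e = sum(dist[t] for t in new_tiles) / cells
    p = cells / remaining
    return steps, e, p, cells


def build_tree(maze: GridMaze, node_cap: int = DEFAULT_NODE_CAP) -> TreeNode:
    """Fully expanded decision tree (as a subproblem-sharing DAG).

    The root is degenerate: vantage = start, observed = rooms visible from
    the start, s = e = 0 and p = the share of room tiles initially visible.
    Raises :class:`TreeSizeError` beyond ``node_cap`` distinct nodes and
    :class:`UnobservableRoomError` if some room can never be observed.
    """
    counter = iter(range(10**9))
    n_nodes = 0
    total = maze.total_room_tiles
    # children shared by the (vantage, observed) subproblem
    memo: dict[tuple[Tile, frozenset[int]], list[TreeNode]] = {}

    def expand(vantage: Tile, observed: frozenset[int]) -> list[TreeNode]:
        nonlocal n_nodes
        key = (vantage, observed)
        if key in memo:
            return memo[key]
        memo[key] = []  # placeholder; subproblems never recurse into themselves
        children: list[TreeNode] = []
        unobserved = set(maze.rooms) - set(observed)
        if unobserved:
            events = enumerate_observation_events(maze, vantage, observed)
            if not events:
                raise UnobservableRoomError(
                    f"rooms {sorted(unobserved)} unobservable from {vantage}"
                )
            for ev in events:
                n_nodes += 1
                if n_nodes > node_cap:
                    raise TreeSizeError(f"decision tree exceeds node cap {node_cap}")
                s, e, p, cells = node_statistics(
                    maze, ev.vantage, ev.co_revealed, observed, ev.steps
                )
                child = TreeNode(
                    node_id=next(counter),
                    vantage=ev.vantage,
                    observed_rooms=observed | ev.co_revealed,
                    new_rooms=ev.co_revealed,
                    s=s,
                    e=e,
                    p=p,
                    cells=cells,
                    remaining_before=total - sum(
                        len(maze.rooms[rid]) for rid in observed
                    ),
                )
                child.children = expand(child.vantage, child.observed_rooms)
                children.append(child)
        memo[key] = children
        return children

    init_rooms = visible_rooms(maze, maze.start)
    init_cells = sum(len(maze.rooms[rid]) for rid in init_rooms)
    root = TreeNode(
        node_id=next(counter),
        vantage=maze.start,
        observed_rooms=frozenset(init_rooms),
        new_rooms=frozenset(init_rooms),
        s=0,
        e=0.0,
        p=init_cells / total if total else 0.0,
        cells=init_cells,
        remaining_before=total,
    )
    root.children = expand(maze.start, root.observed_rooms)
    # renumber in a deterministic DFS pre-order over distinct nodes
    seen: set[int] = set()
    counter2 = iter(range(10**9))

    def renumber(node: TreeNode) -> None:
        if id(node) in seen:
            return
        seen.add(id(node))
        node.node_id = next(counter2)
        for ch in node.children:
            renumber(ch)

    renumber(root)
    return root


def iter_nodes(root: TreeNode) -> Iterator[TreeNode]:
    """Distinct nodes in DFS pre-order (each shared node yielded once)."""
    seen: set[int] = set()
    stack = [root]
    while stack:
        node = stack.pop()
        if id(node) in seen:
            continue
        seen.add(id(node))
        yield node
        stack.extend(reversed(node.children))


def count_leaves(root: TreeNode) -> int:
    """Number of root-to-leaf paths (complete observation orders)."""
    memo: dict[int, int] = {}

    def walk(node: TreeNode) -> int:
        got = memo.get(id(node))
        if got is None:
            got = 1 if node.is_leaf else sum(walk(ch) for ch in node.children)
            memo[id(node)] = got
        return got

    return walk(root)


def iter_leaf_paths(root: TreeNode, cap: int = 1_000_000) -> Iterator[list[TreeNode]]:
    """All root-to-leaf node sequences (explicit path enumeration)."""
    n = 0

    def walk(node: TreeNode, prefix: list[TreeNode]) -> Iterator[list[TreeNode]]:
        nonlocal n
        path = prefix + [node]
        if node.is_leaf:
            n += 1
            if n > cap:
                raise TreeSizeError(f"leaf-path enumeration exceeds cap {cap}")
            yield path
        for ch in node.children:
            yield from walk(ch, path)

    yield from walk(root, [])


def path_probability_sums(root: TreeNode) -> list[float]:
    """Unconditional find-probability sum for each root-to-leaf path.

    Along a path, the probability the exit is found at node i is
    p_i * prod_{j<i} (1 - p_j); for an exhaustive observation order these
    sums must equal 1.
    """
    sums: list[float] = []

    def walk(node: TreeNode, acc: float, survive: float) -> None:
        acc = acc + survive * node.p
        survive = survive * (1.0 - node.p)
        if node.is_leaf:
            sums.append(acc)
        for ch in node.children:
            walk(ch, acc, survive)

    walk(root, 0.0, 1.0)
    return sums


def map_tree(root: TreeNode, fn: Callable[[TreeNode], TreeNode]) -> TreeNode:
    """Structure-preserving map over the DAG (sharing kept intact).

    ``fn`` receives a shallow copy of each node (children not yet set) and
    may alter its statistics; it must return the node.
    """
    memo: dict[int, TreeNode] = {}

    def walk(node: TreeNode) -> TreeNode:
        got = memo.get(id(node))
        if got is None:
            clone = TreeNode(
                node_id=node.node_id,
                vantage=node.vantage,
                observed_rooms=node.observed_rooms,
                new_rooms=node.new_rooms,
                s=node.s,
                e=node.e,
                p=node.p,
                cells=node.cells,
                remaining_before=node.remaining_before,
            )
            got = fn(clone)
            memo[id(node)] = got
            got.children = [walk(ch) for ch in node.children]
        return got

    return walk(root)


def export_tree(root: TreeNode) -> str:
    """Tab-separated dump of the DAG: one row per (parent, child) edge plus
    the root row. Shared nodes keep their node_id across rows."""
    lines = ["node_id\tparent_id\tvantage_col\tvantage_row\ts\te\tp\tcells\tnew_rooms"]

    def row(node: TreeNode, parent: int | None) -> str:
        pid = "" if parent is None else str(parent)
        rooms = ",".join(str(r) for r in sorted(node.new_rooms))
        return (
            f"{node.node_id}\t{pid}\t{node.vantage[0]}\t{node.vantage[1]}\t"
            f"{node.s:g}\t{node.e:.10g}\t{node.p:.10g}\t{node.cells:g}\t{rooms}"
        )

    emitted: set[tuple[int | None, int]] = set()

    def walk(node: TreeNode, parent: int | None) -> None:
        key = (parent, node.node_id)
        if key in emitted:
            return
        emitted.add(key)
        lines.append(row(node, parent))
        for ch in node.children:
            walk(ch, node.node_id)

    walk(root, None)
    return "\n".join(lines) + "\n"
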