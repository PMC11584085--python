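"""Cost models over the decision tree and the softmax choice rule.

Planning models score a child node by a recursion over its subtree:

* ``EU``     C(N) = s + p·e + (1−p)·min_child C              (full look-ahead)
* ``DU``     C(N) = s + p·e + γ·(1−p)·min_child C            (discounted)
* ``PW``     C(N) = s + π(p)·e + π(1−p)·min_child C          (weighted probs)
* ``PW-DU``  C(N) = s + π(p)·e + γ·π(1−p)·min_child C

with π(p) = exp(−|ln p|^β). Myopic heuristics score the child alone:
``Steps`` → s, ``Cells`` → −cells, ``Steps-Cells`` → k·s − (1−k)·cells,
``Random`` → 1. ``-Num`` variants pass counts through a bit-limited
numerosity channel first. ``Sampling`` estimates EU child costs by Monte
Carlo tree search under an iteration budget.

Costs map to choice probabilities through a temperature-τ softmax over the
negated costs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .decision_tree import TreeNode, build_tree, iter_nodes, map_tree
from .errors import ParameterError
from .maze_world import GridMaze, distance_field, shortest_path_steps
from .numerosity import N_MAX, NumerosityChannel, build_channel
from .records import DecisionRecord, OptionStats

PLANNER_MODELS = ("EU", "DU", "PW", "PW-DU", "EU-Num", "DU-Num", "Sampling")
HEURISTIC_MODELS = (
    "Steps",
    "Cells",
    "Steps-Cells",
    "Steps-Num",
    "Cells-Num",
    "Steps-Cells-Num",
    "Random",
)
ALL_MODELS = PLANNER_MODELS + HEURISTIC_MODELS

_NUM_MODELS = {"EU-Num", "DU-Num", "Steps-Num", "Cells-Num", "Steps-Cells-Num"}


@dataclass(frozen=True)
class ModelParams:
    """Parameter bundle; only fields relevant to ``model_id`` are read."""

    model_id: str
    tau: float = 1.0
    gamma: float = 1.0
    beta: float = 1.0
    B: float = 10.0
    k_weight: float = 0.5
    mcts_budget: int = 200
    mcts_exploration: float = 1.0

    def __post_init__(self) -> None:
        if self.model_id not in ALL_MODELS:
            raise ParameterError(f"unknown model {self.model_id!r}")
        if not (self.tau > 0):
            raise ParameterError(f"tau must be positive, got {self.tau}")
        if not (0.0 <= self.gamma <= 1.0):
            raise ParameterError(f"gamma must be in [0, 1], got {self.gamma}")
        if self.beta < 0:
            raise ParameterError(f"beta must be nonnegative, got {self.beta}")
        if not (0.0 <= self.k_weight <= 1.0):
            raise ParameterError(f"k_weight must be in [0, 1], got {self.k_weight}")
        if self.mcts_budget < 1:
            raise ParameterError(f"mcts_budget must be >= 1, got {self.mcts_budget}")
        if self.mcts_exploration < 0:
            raise ParameterError(
                f"mcts_exploration must be >= 0, got {self.mcts_exploration}"
            )

    @property
    def uses_numerosity(self) -> bool:
        return self.model_id in _NUM_MODELS

    @property
    def is_heuristic(self) -> bool:
        return self.model_id in HEURISTIC_MODELS

    def cost_key(self) -> tuple:
        """Hashable key identifying the cost function (τ excluded)."""
        m = self.model_id
        if m in ("EU", "Random", "Steps", "Cells"):
            return (m,)
        if m == "DU":
            return (m, self.gamma)
        if m == "PW":
            return (m, self.beta)
        if m == "PW-DU":
            return (m, self.gamma, self.beta)
        if m == "EU-Num":
            return (m, self.B)
        if m == "DU-Num":
            return (m, self.gamma, self.B)
        if m == "Steps-Num":
            return (m, self.B)
        if m == "Cells-Num":
            return (m, self.B)
        if m == "Steps-Cells":
            return (m, self.k_weight)
        if m == "Steps-Cells-Num":
            return (m, self.k_weight, self.B)
        if m == "Sampling":
            return (m, self.mcts_budget, self.mcts_exploration)
        raise ParameterError(m)


# -- softmax choice ----------------------------------------------------------


def choice_probabilities(costs, tau: float) -> np.ndarray:
    """Softmax over negated costs: lower cost, higher probability."""
    costs = np.asarray(costs, dtype=float)
    if costs.size == 0:
        raise ParameterError("no options to choose among")
    if not (tau > 0):
        raise ParameterError(f"tau must be positive, got {tau}")
    z = -(costs - costs.min()) / tau
    w = np.exp(z)
    return w / w.sum()


# -- probability weighting ---------------------------------------------------


def weight_probability(p: float, beta: float) -> float:
    """π(p) = exp(−|ln p|^β); π(0)=0 and π(1)=1 at every β by continuity in p."""
    if beta < 0:
        raise ParameterError(f"beta must be nonnegative, got {beta}")
    if p <= 0.0:
        return 0.0
    if p >= 1.0:
        return 1.0
    return math.exp(-abs(math.log(p)) ** beta)


# -- recursive planner costs -------------------------------------------------


def _recursive_cost(
    node: TreeNode,
    gamma: float,
    beta: float,
    memo: dict[int, float],
) -> float:
    got = memo.get(id(node))
    if got is not None:
        return got
    if beta == 1.0:
        wp, wq = node.p, 1.0 - node.p
    else:
        wp = weight_probability(node.p, beta)
        wq = weight_probability(1.0 - node.p, beta)
    cost = node.s + wp * node.e
    if node.children:
        best = min(
            (_recursive_cost(ch, gamma, beta, memo), ch.node_id)
            for ch in node.children
        )[0]
        cost += gamma * wq * best
    memo[id(node)] = cost
    return cost


def cost_eu(node: TreeNode) -> float:
    """Expected steps to the exit under optimal continuation."""
    return _recursive_cost(node, 1.0, 1.0, {})

def cost_du(node: TreeNode, gamma: float) -> float:
    if not (0.0 <= gamma <= 1.0):
        raise ParameterError(f"gamma must be in [0, 1], got {gamma}")
    return _recursive_cost(node, gamma, 1.0, {})

def cost_pw(node: TreeNode, beta: float) -> float:
    return _recursive_cost(node, 1.0, beta, {})

def cost_pw_du(node: TreeNode, gamma: float, beta: float) -> float:
    if not (0.0 <= gamma <= 1.0):
        raise ParameterError(f"gamma must be in [0, 1], got {gamma}")
    return _recursive_cost(node, gamma, beta, {})


# -- numerosity distortion ---------------------------------------------------


def _q_count(channel: NumerosityChannel, n: float) -> float:
    """q(n) with q(0) = 0 and counts above the domain clamped."""
    if n <= 0:
        return 0.0
    return float(channel.q[min(int(round(n)), N_MAX) - 1])


def apply_numerosity(
    root: TreeNode, channel: NumerosityChannel, maze: GridMaze
) -> TreeNode:
    """Tree with s, cells, remaining and e passed through the channel.

    ``e`` is recomputed as the mean of q(distance) over the newly revealed
    tiles; ``p`` as q(cells)/q(remaining). Sharing in the DAG is preserved.
    """

    def distort(node: TreeNode) -> TreeNode:
        node.s = _q_count(channel, node.s)
        node.cells = _q_count(channel, node.cells)
        node.remaining_before = _q_count(channel, node.remaining_before)
        if node.new_rooms:
            dist = distance_field(maze, node.vantage)
            tiles = [t for rid in node.new_rooms for t in maze.rooms[rid]]
            node.e = sum(_q_count(channel, dist[t]) for t in tiles) / len(tiles)
        if node.remaining_before > 0 and node.cells > 0:
            node.p = node.cells / node.remaining_before
        return node

    return map_tree(root, distort)


# -- Monte Carlo tree search -------------------------------------------------


@dataclass
class _MCTSStats:
    visits: int = 0
    total: float = 0.0

    @property
    def mean(self) -> float:
        return self.total / self.visits if self.visits else math.inf


def _rollout(node: TreeNode, rng: np.random.Generator) -> float:
    """Cost of a uniform-random observation order from ``node`` onward."""
    cost = 0.0
    survive = 1.0
    while True:
        cost += survive * (node.s + node.p * node.e)
        survive *= 1.0 - node.p
        if not node.children:
            return cost
        node = node.children[int(rng.integers(len(node.children)))]


def mcts_plan(
    root: TreeNode,
    budget: int,
    exploration: float,
    rng: np.random.Generator,
    return_costs: bool = False,
):
    """MCTS approximation of the EU choice at ``root``.

    Each iteration: UCB1 selection down the in-memory tree (unvisited
    children first, in random order), expansion of one child, a
    uniform-random rollout to a leaf, and mean-cost backup. Returns the
    root-child visit proportions; with ``return_costs`` also each root
    child's mean sampled cost (unvisited children inherit the worst visited
    mean plus one step).
    """
    if budget < 1:
        raise ParameterError(f"budget must be >= 1, got {budget}")
    if not root.children:
        raise ParameterError("root has no children to plan over")
    stats: dict[int, _MCTSStats] = {}

    def stat(node: TreeNode) -> _MCTSStats:
        st = stats.get(id(node))
        if st is None:
            st = _MCTSStats()
            stats[id(node)] = st
        return st

    for _ in range(budget):
        path = [root]
        node = root
        # selection
        while node.children:
            unvisited = [ch for ch in node.children if stat(ch).visits == 0]
            if unvisited:
                node = unvisited[int(rng.integers(len(unvisited)))]
                path.append(node)
                break
            n_parent = sum(stat(ch).visits for ch in node.children)
            log_n = math.log(max(n_parent, 1))
            node = min(
                node.children,
                key=lambda ch: (
                    stat(ch).mean
                    - exploration * math.sqrt(2.0 * log_n / stat(ch).visits),
                    ch.node_id,
                ),
            )
            path.append(node)
        # rollout the continuation below the newly reached node
        if node.children:
            below = node.children[int(rng.integers(len(node.children)))]
            tail = _rollout(below, rng)
        else:
            tail = 0.0
        # backup: reconstruct conditional costs bottom-up along the path
        for node in reversed(path[1:]):
            cost = node.s + node.p * node.e + (1.0 - node.p) * tail
            st = stat(node)
            st.visits += 1
            st.total += cost
            tail = cost

    visits = np.array([stat(ch).visits for ch in root.children], dtype=float)
    proportions = visits / visits.sum()
    if not return_costs:
        return proportions
    means = [stat(ch).mean for ch in root.children]
    worst = max((m for m in means if math.isfinite(m)), default=0.0)
    costs = np.array([m if math.isfinite(m) else worst + 1.0 for m in means])
    return proportions, costs


# -- unified evaluation ------------------------------------------------------


class MazeModel:
    """Cost/choice evaluator for one maze: caches the decision tree, its
    numerosity-distorted variants, and per-parameter cost tables."""

    def __init__(self, maze: GridMaze, maze_id: str = "", root: TreeNode | None = None):
        self.maze = maze
        self.maze_id = maze_id or maze.name or "maze"
        self.root = root if root is not None else build_tree(maze)
        self._distorted: dict[float, TreeNode] = {}
        self._index: dict[float | None, dict[int, TreeNode]] = {}
        self._cost_memo: dict[tuple, dict[int, float]] = {}

    def _tree_for(self, params: ModelParams) -> TreeNode:
        if not params.uses_numerosity:
            return self.root
        key = round(params.B, 10)
        tree = self._distorted.get(key)
        if tree is None:
            tree = apply_numerosity(self.root, build_channel(params.B), self.maze)
            self._distorted[key] = tree
        return tree

    def node_index(self, params: ModelParams | None = None) -> dict[int, TreeNode]:
        key = None
        tree = self.root
        if params is not None and params.uses_numerosity:
            key = round(params.B, 10)
            tree = self._tree_for(params)
        idx = self._index.get(key)
        if idx is None:
            idx = {n.node_id: n for n in iter_nodes(tree)}
            self._index[key] = idx
        return idx

    def child_costs(
        self,
        node_id: int,
        params: ModelParams,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Cost per child of the decision node, in child order."""
        node = self.node_index(params)[node_id]
        m = params.model_id
        if m == "Random":
            return np.ones(len(node.children))
        if m in ("Steps", "Steps-Num"):
            return np.array([ch.s for ch in node.children], dtype=float)
        if m in ("Cells", "Cells-Num"):
            return np.array([-ch.cells for ch in node.children], dtype=float)
        if m in ("Steps-Cells", "Steps-Cells-Num"):
            k = params.k_weight
            return np.array(
                [k * ch.s - (1.0 - k) * ch.cells for ch in node.children], dtype=float
            )
        if m == "Sampling":
            if rng is None:
                rng = np.random.default_rng(
                    abs(hash((node_id, params.mcts_budget, params.mcts_exploration)))
                    % 2**32
                )
            _, costs = mcts_plan(
                node, params.mcts_budget, params.mcts_exploration, rng, return_costs=True
            )
            return costs
        # recursive planners (possibly on the distorted tree)
        gamma = params.gamma if m in ("DU", "PW-DU", "DU-Num") else 1.0
        beta = params.beta if m in ("PW", "PW-DU") else 1.0
        memo = self._cost_memo.setdefault(params.cost_key(), {})
        return np.array(
            [_recursive_cost(ch, gamma, beta, memo) for ch in node.children]
        )

    def choice_probs(
        self,
        node_id: int,
        params: ModelParams,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        return choice_probabilities(self.child_costs(node_id, params, rng), params.tau)


def heuristic_cost(node: TreeNode, model_id: str, k_weight: float = 0.5) -> float:
    """Myopic cost of one node (Num variants expect a pre-distorted node)."""
    if model_id in ("Steps", "Steps-Num"):
        return float(node.s)
    if model_id in ("Cells", "Cells-Num"):
        return float(-node.cells)
    if model_id in ("Steps-Cells", "Steps-Cells-Num"):
        return float(k_weight * node.s - (1.0 - k_weight) * node.cells)
    if model_id == "Random":
        return 1.0
    raise ParameterError(f"{model_id!r} is not a myopic heuristic")


# -- generative simulation ---------------------------------------------------


@dataclass
class Trajectory:
    maze_id: str
    steps: int
    node_ids: list[int] = field(default_factory=list)
    found_at_node: int | None = None


def simulate_agent(
    maze: GridMaze,
    params: ModelParams,
    rng: np.random.Generator,
    model: MazeModel | None = None,
    participant_id: str = "sim",
) -> tuple[Trajectory, list[DecisionRecord]]:
    """Walk one trial: sample children by softmax over model costs until the
    exit's room is revealed, then walk to the exit.

    Emits one :class:`DecisionRecord` per multi-child node visited; the
    record at the tree root is flagged as the initial decision. Decision
    times are left at 0 (the synthetic cohort generator attaches them).
    """
    if model is None:
        model = MazeModel(maze)
    node = model.root
    steps = 0
    traj = Trajectory(maze_id=model.maze_id, steps=0, node_ids=[node.node_id])
    records: list[DecisionRecord] = []
    exit_room = maze.exit_room
    if exit_room in node.new_rooms:
        steps += shortest_path_steps(maze, node.vantage, maze.exit)
        traj.steps = steps
        traj.found_at_node = node.node_id
        return traj, records
    while node.children:
        if len(node.children) >= 2:
            probs = model.choice_probs(node.node_id, params, rng)
            idx = int(rng.choice(len(probs), p=probs))
            records.append(
                DecisionRecord(
                    participant_id=participant_id,
                    maze_id=model.maze_id,
                    node_id=node.node_id,
                    options=tuple(
                        OptionStats(ch.node_id, ch.s, ch.e, ch.p, ch.cells)
                        for ch in node.children
                    ),
                    chosen_id=node.children[idx].node_id,
                    decision_time_ms=0.0,
                    is_initial=node is model.root,
                )
            )
        else:
            idx = 0
        node = node.children[idx]
        steps += int(node.s)
        traj.node_ids.append(node.node_id)
        if exit_room in node.new_rooms:
            steps += shortest_path_steps(maze, node.vantage, maze.exit)
            traj.found_at_node = node.node_id
            break
    traj.steps = steps
    return traj, records
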