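"""Individual-level model fitting and comparison.

Each participant's decisions are treated as independent choices among the
child nodes of a decision node. A model is fitted by grid search over its
parameters, maximizing the train log-posterior: the softmax log-likelihood
plus an improper 1/τ prior on the temperature (uniform priors elsewhere).
Out-of-sample performance is the total test log-likelihood across five
seeded cross-validation folds; Monte-Carlo splits are available as an
option. Model families are compared per individual by the best planner
versus the best heuristic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, InsufficientDataError, MazeplanError
from .planners import (
    ALL_MODELS,
    HEURISTIC_MODELS,
    PLANNER_MODELS,
    MazeModel,
    ModelParams,
)
from .records import DecisionRecord


@dataclass(frozen=True)
class ParamGrids:
    """Search grids per parameter; models read only the ones they use."""

    tau: tuple[float, ...]
    gamma: tuple[float, ...]
    beta: tuple[float, ...]
    B: tuple[float, ...]
    k_weight: tuple[float, ...]
    mcts_budget: tuple[int, ...]
    mcts_exploration: tuple[float, ...]

    def __post_init__(self) -> None:
        for name in ("tau", "gamma", "beta", "B", "k_weight", "mcts_budget", "mcts_exploration"):
            if len(getattr(self, name)) == 0:
                raise ConfigError(f"empty grid for {name}")


def default_grids(reduced: bool = False) -> ParamGrids:
    """Default search grids; ``reduced`` coarsens them for large recovery runs."""
    if reduced:
        return ParamGrids(
            tau=tuple(np.round(np.logspace(-1.3, 1, 13), 6)),
            gamma=tuple(np.round(np.arange(0.0, 1.0001, 0.1), 2)),
            beta=tuple(np.round(np.arange(0.2, 2.01, 0.2), 2)),
            B=(0.1, 0.5, 2.0, 10.0),
            k_weight=tuple(np.round(np.arange(0.0, 1.0001, 0.25), 2)),
            mcts_budget=(50, 200),
            mcts_exploration=(1.0,),
        )
    return ParamGrids(
        tau=tuple(np.round(np.logspace(-2, 1, 31), 6)),
        gamma=tuple(np.round(np.arange(0.0, 1.0001, 0.05), 2)),
        beta=tuple(np.round(np.arange(0.1, 2.01, 0.1), 2)) + (2.5, 3.0),
        B=(0.1, 0.25, 0.5, 1.0, 2.0, 4.0, 7.0, 10.0),
        k_weight=tuple(np.round(np.arange(0.0, 1.0001, 0.1), 2)),
        mcts_budget=(10, 50, 200),
        mcts_exploration=(0.3, 1.0, 3.0),
    )


_MODEL_GRID_FIELDS: dict[str, tuple[str, ...]] = {
    "EU": (),
    "DU": ("gamma",),
    "PW": ("beta",),
    "PW-DU": ("gamma", "beta"),
    "EU-Num": ("B",),
    "DU-Num": ("gamma", "B"),
    "Sampling": ("mcts_budget", "mcts_exploration"),
    "Steps": (),
    "Cells": (),
    "Steps-Cells": ("k_weight",),
    "Steps-Num": ("B",),
    "Cells-Num": ("B",),
    "Steps-Cells-Num": ("k_weight", "B"),
    "Random": (),
}


def parameter_combos(model_id: str, grids: ParamGrids) -> list[ModelParams]:
    """All non-τ parameter settings for a model (τ fixed at a placeholder)."""
    fields_ = _MODEL_GRID_FIELDS[model_id]
    out = []
    for values in itertools.product(*(getattr(grids, f) for f in fields_)):
        kw = dict(zip(fields_, values))
        out.append(ModelParams(model_id=model_id, tau=1.0, **kw))
    return out


@dataclass
class FitResult:
    participant_id: str
    model_id: str
    best_params: ModelParams
    fold_test_ll: list[float]
    total_test_ll: float
    train_ll: float
    n_decisions: int


# -- likelihood machinery ----------------------------------------------------


def _option_costs(
    maze_models: dict[str, MazeModel], record: DecisionRecord, params: ModelParams
) -> np.ndarray:
    """Cost vector aligned with the record's option order."""
    model = maze_models[record.maze_id]
    node = model.node_index(params)[record.node_id]
    costs = model.child_costs(record.node_id, params)
    by_id = {ch.node_id: costs[i] for i, ch in enumerate(node.children)}
    return np.array([by_id[o.node_id] for o in record.options], dtype=float)


def _loglik_matrix(
    records: list[DecisionRecord],
    params: ModelParams,
    maze_models: dict[str, MazeModel],
    taus: np.ndarray,
) -> np.ndarray:
    """(n_tau, n_decisions) chosen-option log-likelihoods under one combo."""
    out = np.empty((len(taus), len(records)))
    for j, rec in enumerate(records):
        c = _option_costs(maze_models, rec, params)
        z = -(c[None, :] - c.min()) / taus[:, None]
        # max-shifted log-softmax
        zmax = z.max(axis=1, keepdims=True)
        logZ = zmax[:, 0] + np.log(np.exp(z - zmax).sum(axis=1))
        out[:, j] = z[:, rec.chosen_index] - logZ
    return out


def make_folds(n: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random near-equal partition of range(n) into ``n_folds`` index arrays."""
    idx = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(idx, n_folds)]


def monte_carlo_splits(
    n: int, n_splits: int, test_frac: float, rng: np.random.Generator
) -> list[np.ndarray]:
    """Repeated random test subsets (Monte-Carlo cross-validation)."""
    n_test = max(1, int(round(test_frac * n)))
    return [np.sort(rng.permutation(n)[:n_test]) for _ in range(n_splits)]


def fit_individual(
    records: list[DecisionRecord],
    model_id: str,
    maze_models: dict[str, MazeModel],
    grids: ParamGrids | None = None,
    rng: np.random.Generator | None = None,
    n_folds: int = 5,
    folds: list[np.ndarray] | None = None,
) -> FitResult:
    """Cross-validated MAP grid search for one participant and model.

    Per fold the train log-posterior (log-likelihood − ln τ) is maximized
    over the model's grid; the fold's test log-likelihood is evaluated at
    that MAP. ``best_params`` maximizes the posterior on all decisions.
    """
    if model_id not in ALL_MODELS:
        raise ConfigError(f"unknown model {model_id!r}")
    records = [r for r in records if r.n_options >= 2]
    if len(records) < n_folds:
        raise InsufficientDataError(
            f"need at least {n_folds} multi-option decisions, got {len(records)}"
        )
    grids = grids or default_grids()
    if folds is None:
        if rng is None:
            rng = np.random.default_rng(0)
        folds = make_folds(len(records), n_folds, rng)

    taus = np.asarray(grids.tau, dtype=float)
    log_prior = -np.log(taus)  # improper 1/τ prior; uniform elsewhere
    combos = parameter_combos(model_id, grids)
    # chosen-option log-likelihood per (combo, tau, decision)
    ll = np.stack(
        [_loglik_matrix(records, combo, maze_models, taus) for combo in combos]
    )  # (n_combos, n_tau, n_decisions)

    pid = records[0].participant_id
    all_idx = np.arange(len(records))
    fold_test = []
    for test_idx in folds:
        train_idx = np.setdiff1d(all_idx, test_idx)
        posterior = ll[:, :, train_idx].sum(axis=2) + log_prior[None, :]
        ci, ti = np.unravel_index(int(np.argmax(posterior)), posterior.shape)
        fold_test.append(float(ll[ci, ti, test_idx].sum()))

    posterior_all = ll.sum(axis=2) + log_prior[None, :]
    ci, ti = np.unravel_index(int(np.argmax(posterior_all)), posterior_all.shape)
    from dataclasses import replace as _replace

    best = _replace(combos[ci], tau=float(taus[ti]))
    return FitResult(
        participant_id=pid,
        model_id=model_id,
        best_params=best,
        fold_test_ll=fold_test,
        total_test_ll=float(sum(fold_test)),
        train_ll=float(ll[ci, ti, :].sum()),
        n_decisions=len(records),
    )


def fit_cohort(
    records: list[DecisionRecord],
    model_ids: list[str],
    maze_models: dict[str, MazeModel],
    grids: ParamGrids | None = None,
    master_seed: int = 0,
    n_folds: int = 5,
) -> dict[str, dict[str, FitResult]]:
    """Fit every model to every participant. Fold assignment is seeded per
    participant from the master seed and shared across models (so test-LL
    differences compare like with like)."""
    grids = grids or default_grids()
    by_pid: dict[str, list[DecisionRecord]] = {}
    for r in records:
        if r.n_options >= 2:
            by_pid.setdefault(r.participant_id, []).append(r)
    out: dict[str, dict[str, FitResult]] = {m: {} for m in model_ids}
    for k, (pid, recs) in enumerate(sorted(by_pid.items())):
        rng = np.random.default_rng(np.random.SeedSequence([master_seed, k]))
        folds = make_folds(len(recs), n_folds, rng)
        for m in model_ids:
            out[m][pid] = fit_individual(
                recs, m, maze_models, grids=grids, folds=folds, n_folds=n_folds
            )
    return out


# -- model comparison --------------------------------------------------------


@dataclass
class ModelComparison:
    ranking: pd.DataFrame  # model_id, total_test_ll, delta_ll (vs best)
    individual: pd.DataFrame  # participant, best planner/heuristic, family winner

    @property
    def best_model(self) -> str:
        return str(self.ranking.iloc[0]["model_id"])


def compare_models(fits: dict[str, dict[str, FitResult]]) -> ModelComparison:
    """Rank models by total test LL and label each individual's best family."""
    model_ids = sorted(fits)
    pids = sorted(fits[model_ids[0]])
    for m in model_ids:
        if sorted(fits[m]) != pids:
            raise MazeplanError(f"model {m} fitted to a different participant set")
        for pid in pids:
            if fits[m][pid].n_decisions != fits[model_ids[0]][pid].n_decisions:
                raise MazeplanError(
                    f"model {m} fitted on a different decision set for {pid}"
                )

    totals = {
        m: sum(fits[m][pid].total_test_ll for pid in pids) for m in model_ids
    }
    best_total = max(totals.values())
    ranking = pd.DataFrame(
        {
            "model_id": sorted(model_ids, key=lambda m: -totals[m]),
        }
    )
    ranking["total_test_ll"] = [totals[m] for m in ranking["model_id"]]
    ranking["delta_ll"] = best_total - ranking["total_test_ll"]

    rows = []
    planners = [m for m in model_ids if m in PLANNER_MODELS]
    heuristics = [m for m in model_ids if m in HEURISTIC_MODELS]
    for pid in pids:
        row: dict = {"participant_id": pid}
        if planners:
            bp = max(planners, key=lambda m: fits[m][pid].total_test_ll)
            row["best_planner"] = bp
            row["best_planner_ll"] = fits[bp][pid].total_test_ll
        if heuristics:
            bh = max(heuristics, key=lambda m: fits[m][pid].total_test_ll)
            row["best_heuristic"] = bh
            row["best_heuristic_ll"] = fits[bh][pid].total_test_ll
        if planners and heuristics:
            row["family"] = (
                "planner"
                if row["best_planner_ll"] >= row["best_heuristic_ll"]
                else "heuristic"
            )
        rows.append(row)
    return ModelComparison(ranking=ranking, individual=pd.DataFrame(rows))


def random_model_ll(records: list[DecisionRecord]) -> float:
    """Closed-form total LL of the Random model: Σ ln(1/m_d)."""
    return float(sum(np.log(1.0 / r.n_options) for r in records if r.n_options >= 2))


# -- aggregate first-choice analysis ----------------------------------------


def aggregate_first_choices(
    records: list[DecisionRecord],
    initial_only: bool = True,
    min_visit_frac: float = 0.2,
) -> pd.DataFrame:
    """Empirical per-option choice frequencies aggregated across participants.

    With ``initial_only`` the analysis is restricted to each maze's root
    decision (shared by all participants). Otherwise all decision nodes are
    used, dropping nodes visited by fewer than ``min_visit_frac`` of
    participants.
    """
    rows = []
    pool = [r for r in records if (r.is_initial or not initial_only)]
    n_participants = len({r.participant_id for r in records}) or 1
    by_node: dict[tuple[str, int], list[DecisionRecord]] = {}
    for r in pool:
        by_node.setdefault((r.maze_id, r.node_id), []).append(r)
    for (maze_id, node_id), recs in sorted(by_node.items()):
        if not initial_only:
            visitors = len({r.participant_id for r in recs})
            if visitors / n_participants < min_visit_frac:
                continue
        counts: dict[int, int] = {o.node_id: 0 for o in recs[0].options}
        for r in recs:
            counts[r.chosen_id] = counts.get(r.chosen_id, 0) + 1
        total = sum(counts.values())
        for opt_id in sorted(counts):
            rows.append(
                {
                    "maze_id": maze_id,
                    "node_id": node_id,
                    "option_id": opt_id,
                    "count": counts[opt_id],
                    "prob": counts[opt_id] / total,
                }
            )
    return pd.DataFrame(rows)


def predicted_choice_probs(
    maze_models: dict[str, MazeModel], params: ModelParams, initial_only: bool = True
) -> dict[tuple[str, int, int], float]:
    """Model choice probabilities keyed by (maze_id, node_id, option_id)."""
    out: dict[tuple[str, int, int], float] = {}
    for maze_id, model in sorted(maze_models.items()):
        nodes = [model.root] if initial_only else list(model.node_index().values())
        for node in nodes:
            if len(node.children) < 2:
                continue
            probs = model.choice_probs(node.node_id, params)
            for ch, pr in zip(node.children, probs):
                out[(maze_id, node.node_id, ch.node_id)] = float(pr)
    return out


def _empirical_vector(
    freq: pd.DataFrame, predicted: dict[tuple[str, int, int], float]
) -> tuple[np.ndarray, np.ndarray]:
    emp, pred = [], []
    for row in freq.itertuples():
        key = (row.maze_id, row.node_id, row.option_id)
        if key in predicted:
            emp.append(row.prob)
            pred.append(predicted[key])
    return np.array(emp), np.array(pred)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 3:
        raise MazeplanError("need at least 3 aligned options for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise MazeplanError("undefined correlation: zero-variance vector")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class BootstrapCorrelation:
    r: float
    ci_low: float
    ci_high: float
    n_boot: int
    samples: np.ndarray = field(repr=False, default=None)


def bootstrap_model_correlation(
    records: list[DecisionRecord],
    predicted: dict[tuple[str, int, int], float],
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    initial_only: bool = True,
) -> BootstrapCorrelation:
    """Pearson correlation between aggregated choice frequencies and model
    predictions, with a participant-level bootstrap 95% CI."""
    rng = rng or np.random.default_rng(0)
    freq = aggregate_first_choices(records, initial_only=initial_only)
    emp, pred = _empirical_vector(freq, predicted)
    r = _pearson(emp, pred)
    pids = sorted({rec.participant_id for rec in records})
    by_pid = {pid: [rec for rec in records if rec.participant_id == pid] for pid in pids}
    samples = np.empty(n_boot)
    for b in range(n_boot):
        draw = rng.choice(len(pids), size=len(pids), replace=True)
        resampled = [rec for i in draw for rec in by_pid[pids[i]]]
        f = aggregate_first_choices(resampled, initial_only=initial_only)
        e, p = _empirical_vector(f, predicted)
        try:
            samples[b] = _pearson(e, p)
        except MazeplanError:
            samples[b] = np.nan
    lo, hi = np.nanpercentile(samples, [2.5, 97.5])
    return BootstrapCorrelation(
        r=r, ci_low=float(lo), ci_high=float(hi), n_boot=n_boot, samples=samples
    )


def bootstrap_correlation_difference(
    records: list[DecisionRecord],
    predicted_a: dict[tuple[str, int, int], float],
    predicted_b: dict[tuple[str, int, int], float],
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> BootstrapCorrelation:
    """Bootstrap CI for r(model A) − r(model B) on the same decisions."""
    rng = rng or np.random.default_rng(0)
    freq = aggregate_first_choices(records)
    ea, pa = _empirical_vector(freq, predicted_a)
    eb, pb = _empirical_vector(freq, predicted_b)
    diff = _pearson(ea, pa) - _pearson(eb, pb)
    pids = sorted({rec.participant_id for rec in records})
    by_pid = {pid: [rec for rec in records if rec.participant_id == pid] for pid in pids}
    samples = np.empty(n_boot)
    for b in range(n_boot):
        draw = rng.choice(len(pids), size=len(pids), replace=True)
        resampled = [rec for i in draw for rec in by_pid[pids[i]]]
        f = aggregate_first_choices(resampled)
        try:
            ea, pa = _empirical_vector(f, predicted_a)
            eb, pb = _empirical_vector(f, predicted_b)
            samples[b] = _pearson(ea, pa) - _pearson(eb, pb)
        except MazeplanError:
            samples[b] = np.nan
    lo, hi = np.nanpercentile(samples, [2.5, 97.5])
    return BootstrapCorrelation(
        r=diff, ci_low=float(lo), ci_high=float(hi), n_boot=n_boot, samples=samples
    )


def fit_results_frame(fits: dict[str, dict[str, FitResult]]) -> pd.DataFrame:
    """Flat table of fit results for export."""
    rows = []
    for model_id, per_pid in sorted(fits.items()):
        for pid, fr in sorted(per_pid.items()):
            p = fr.best_params
            rows.append(
                {
                    "participant_id": pid,
                    "model_id": model_id,
                    "tau": p.tau,
                    "gamma": p.gamma,
                    "beta": p.beta,
                    "B": p.B,
                    "k_weight": p.k_weight,
                    "mcts_budget": p.mcts_budget,
                    "mcts_exploration": p.mcts_exploration,
                    "total_test_ll": fr.total_test_ll,
                    "train_ll": fr.train_ll,
                    "n_decisions": fr.n_decisions,
                }
            )
    return pd.DataFrame(rows)
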