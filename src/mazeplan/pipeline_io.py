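"""Pipeline orchestration: configs, manifests, seed fan-out, and the
simulate → fit → compare → correlate → regress → recover stages.

Every stage is a plain function over in-memory objects plus a thin
file-writing wrapper used by the CLI. One master seed fans out to labeled
child seeds so each stage is independently reproducible; outputs are
delimited text plus a YAML manifest carrying the config snapshot, seeds and
content digests.
"""

from __future__ import annotations

import hashlib
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .decision_times import decision_time_tables
from .errors import ConfigError
from .fitting import (
    FitResult,
    ParamGrids,
    bootstrap_model_correlation,
    default_grids,
    fit_cohort,
    fit_results_frame,
    predicted_choice_probs,
)
from .maze_world import GridMaze, dump_ascii, dump_structured, load_ascii, load_structured
from .planners import ALL_MODELS, MazeModel, ModelParams
from .records import DecisionRecord, write_decision_log
from .synthetic_data import CohortConfig, TimeModel, fixture_mazes, generate_cohort, generate_maze


def labeled_seed(master: int, label: str) -> np.random.SeedSequence:
    """Deterministic child seed for a named pipeline component."""
    return np.random.SeedSequence([int(master), zlib.crc32(label.encode())])


# -- config ------------------------------------------------------------------

_SIM_KEYS = {"n_participants", "mazes", "mixture", "params", "time", "master_seed"}
_MAZE_KEYS = {"kind", "n", "n_rooms", "room_size"}
_TIME_KEYS = {"initial", "subsequent", "noise_sd", "floor_ms"}


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    return cfg


def parse_simulate_config(cfg: dict) -> dict:
    unknown = set(cfg) - _SIM_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    mz = cfg.get("mazes", {"kind": "fixtures"})
    if set(mz) - _MAZE_KEYS:
        raise ConfigError(f"unknown maze config keys: {sorted(set(mz) - _MAZE_KEYS)}")
    tm = cfg.get("time", {})
    if set(tm) - _TIME_KEYS:
        raise ConfigError(f"unknown time config keys: {sorted(set(tm) - _TIME_KEYS)}")
    for m in cfg.get("mixture", {}):
        if m not in ALL_MODELS:
            raise ConfigError(f"unknown model in mixture: {m!r}")
    return cfg


def build_mazes_from_config(mz_cfg: dict, seed: int) -> dict[str, GridMaze]:
    kind = mz_cfg.get("kind", "fixtures")
    if kind == "fixtures":
        return fixture_mazes()
    if kind == "generated":
        rng = np.random.default_rng(labeled_seed(seed, "maze-generation"))
        n = int(mz_cfg.get("n", 10))
        lo, hi = mz_cfg.get("n_rooms", [4, 6])
        size = tuple(mz_cfg.get("room_size", [2, 6]))
        out = {}
        for i in range(n):
            rooms = int(rng.integers(lo, hi + 1))
            maze = generate_maze(rng, n_rooms=rooms, room_size_range=size)
            out[f"m{i:03d}"] = maze
        return out
    raise ConfigError(f"unknown maze kind {kind!r}")


def cohort_config_from_dict(cfg: dict, seed: int) -> CohortConfig:
    tm_cfg = cfg.get("time", {})
    tm_kwargs = {}
    if "initial" in tm_cfg:
        tm_kwargs["initial"] = dict(tm_cfg["initial"])
    if "subsequent" in tm_cfg:
        tm_kwargs["subsequent"] = dict(tm_cfg["subsequent"])
    if "noise_sd" in tm_cfg:
        tm_kwargs["noise_sd"] = float(tm_cfg["noise_sd"])
    if "floor_ms" in tm_cfg:
        tm_kwargs["floor_ms"] = float(tm_cfg["floor_ms"])
    return CohortConfig(
        n_participants=int(cfg.get("n_participants", 20)),
        mixture={k: float(v) for k, v in cfg.get("mixture", {"EU": 1.0}).items()},
        param_values=cfg.get("params", {}),
        time_model=TimeModel(**tm_kwargs),
        master_seed=int(cfg.get("master_seed", seed)),
    )


# -- manifests ---------------------------------------------------------------


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_manifest(out_dir: Path, command: str, seed: int, config: dict) -> Path:
    files = sorted(
        p for p in out_dir.rglob("*") if p.is_file() and p.name != "manifest.yaml"
    )
    doc = {
        "command": command,
        "version": __version__,
        "master_seed": int(seed),
        "config": config,
        "digests": {str(p.relative_to(out_dir)): _digest(p) for p in files},
    }
    path = out_dir / "manifest.yaml"
    path.write_text(yaml.safe_dump(doc, sort_keys=True))
    return path


# -- maze I/O helpers --------------------------------------------------------


def resolve_maze(spec: str) -> GridMaze:
    """Load a maze from a fixture name, a structured .yaml file, or an
    ASCII grid file with a ``.sidecar.yaml`` companion."""
    fixtures = fixture_mazes(verify=False)
    if spec in fixtures:
        return fixtures[spec]
    path = Path(spec)
    if not path.exists():
        raise ConfigError(f"unknown maze {spec!r} (not a fixture or file)")
    if path.suffix in (".yaml", ".yml"):
        return load_structured(path.read_text())
    sidecar = path.with_suffix(path.suffix + ".sidecar.yaml")
    if not sidecar.exists():
        raise ConfigError(f"missing sidecar {sidecar}")
    return load_ascii(path.read_text(), sidecar.read_text())


def write_maze_files(maze: GridMaze, out_dir: Path, name: str) -> None:
    grid, sidecar = dump_ascii(maze)
    (out_dir / f"{name}.txt").write_text(grid)
    (out_dir / f"{name}.txt.sidecar.yaml").write_text(sidecar)
    (out_dir / f"{name}.yaml").write_text(dump_structured(maze))


# -- pipeline stages ---------------------------------------------------------


def stage_simulate(cfg: dict, seed: int, out_dir: Path) -> dict[str, Path]:
    cfg = parse_simulate_config(cfg)
    out_dir.mkdir(parents=True, exist_ok=True)
    mazes = build_mazes_from_config(cfg.get("mazes", {"kind": "fixtures"}), seed)
    maze_dir = out_dir / "mazes"
    maze_dir.mkdir(exist_ok=True)
    for name, maze in sorted(mazes.items()):
        write_maze_files(maze, maze_dir, name)
    models = {name: MazeModel(maze, maze_id=name) for name, maze in mazes.items()}
    cc = cohort_config_from_dict(cfg, seed)
    records, truth = generate_cohort(cc, models)
    write_decision_log(records, out_dir / "decisions.tsv")
    truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    write_manifest(out_dir, "simulate", seed, cfg)
    return {"decisions": out_dir / "decisions.tsv", "truth": out_dir / "truth.tsv"}


def load_maze_models(maze_dir: Path) -> dict[str, MazeModel]:
    out = {}
    for path in sorted(maze_dir.glob("*.yaml")):
        if path.name.endswith(".sidecar.yaml"):
            continue
        maze = load_structured(path.read_text())
        out[path.stem] = MazeModel(maze, maze_id=path.stem)
    if not out:
        raise ConfigError(f"no structured maze files in {maze_dir}")
    return out


def stage_fit(
    records: list[DecisionRecord],
    maze_models: dict[str, MazeModel],
    model_ids: list[str],
    seed: int,
    grids: ParamGrids | None = None,
) -> dict[str, dict[str, FitResult]]:
    return fit_cohort(
        records, model_ids, maze_models, grids=grids or default_grids(), master_seed=seed
    )


def stage_correlate(
    records: list[DecisionRecord],
    maze_models: dict[str, MazeModel],
    fits: dict[str, dict[str, FitResult]],
    seed: int,
    n_boot: int = 1000,
) -> pd.DataFrame:
    """First-choice correlation per model at the cohort-mean parameters."""
    rows = []
    rng = np.random.default_rng(labeled_seed(seed, "bootstrap"))
    for model_id, per_pid in sorted(fits.items()):
        frame = fit_results_frame({model_id: per_pid})
        mean_params = ModelParams(
            model_id=model_id,
            tau=float(frame["tau"].mean()),
            gamma=float(frame["gamma"].mean()),
            beta=float(frame["beta"].mean()),
            B=float(np.clip(frame["B"].mean(), 0.1, 10.0)),
            k_weight=float(frame["k_weight"].mean()),
        )
        predicted = predicted_choice_probs(maze_models, mean_params)
        bc = bootstrap_model_correlation(records, predicted, n_boot=n_boot, rng=rng)
        rows.append(
            {
                "model_id": model_id,
                "r": bc.r,
                "ci_low": bc.ci_low,
                "ci_high": bc.ci_high,
                "n_boot": bc.n_boot,
            }
        )
    return pd.DataFrame(rows)


def stage_recover(
    seed: int,
    out_dir: Path,
    n_participants: int = 30,
    n_mazes: int = 12,
    gammas: tuple[float, ...] = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
) -> dict:
    """End-to-end parameter-recovery study: simulate DU agents with known
    discount rates, refit, and report the truth-vs-fit correlation."""
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(labeled_seed(seed, "maze-generation"))
    mazes = {
        f"m{i:03d}": generate_maze(rng, n_rooms=int(rng.integers(4, 7)))
        for i in range(n_mazes)
    }
    models = {n: MazeModel(m, maze_id=n) for n, m in mazes.items()}
    cc = CohortConfig(
        n_participants=n_participants,
        mixture={"DU": 1.0},
        param_values={"DU": {"tau": [0.5], "gamma": list(gammas)}},
        master_seed=seed,
    )
    records, truth = generate_cohort(cc, models)
    fits = fit_cohort(records, ["DU"], models, grids=default_grids(reduced=True), master_seed=seed)
    frame = fit_results_frame(fits).merge(
        truth, on="participant_id", suffixes=("_fit", "_true")
    )
    r = float(np.corrcoef(frame["gamma_true"], frame["gamma_fit"])[0, 1])
    frame.to_csv(out_dir / "recovery.tsv", sep="\t", index=False)
    report = {
        "n_participants": n_participants,
        "n_mazes": n_mazes,
        "gamma_correlation": r,
    }
    (out_dir / "recovery_report.yaml").write_text(yaml.safe_dump(report))
    write_manifest(out_dir, "recover", seed, report)
    return report


def stage_regress(
    records: list[DecisionRecord],
    fits: dict[str, dict[str, FitResult]],
    out_dir: Path,
) -> dict[str, pd.DataFrame]:
    tables = decision_time_tables(records, fits)
    out_dir.mkdir(parents=True, exist_ok=True)
    for model_id, table in tables.items():
        table.to_csv(out_dir / f"times_{model_id}.tsv", sep="\t", index=False)
    return tables
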