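"""Decision records and the delimited decision-log format.

One record is one room-choice: the decision node, its available child
options with their (s, e, p, cells) statistics, the chosen child, and the
decision time. Logs round-trip through a tab-separated text format with the
options packed as ``id:s:e:p:cells`` groups joined by ``;``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class OptionStats:
    node_id: int
    s: float
    e: float
    p: float
    cells: float


@dataclass(frozen=True)
class DecisionRecord:
    participant_id: str
    maze_id: str
    node_id: int
    options: tuple[OptionStats, ...]
    chosen_id: int
    decision_time_ms: float
    is_initial: bool

    def __post_init__(self) -> None:
        if all(o.node_id != self.chosen_id for o in self.options):
            raise ValueError(
                f"chosen option {self.chosen_id} not among "
                f"{[o.node_id for o in self.options]}"
            )

    @property
    def n_options(self) -> int:
        return len(self.options)

    @property
    def chosen_index(self) -> int:
        for i, o in enumerate(self.options):
            if o.node_id == self.chosen_id:
                return i
        raise ValueError("chosen option missing")  # unreachable after init


def _pack_options(options: tuple[OptionStats, ...]) -> str:
    return ";".join(
        f"{o.node_id}:{o.s:g}:{o.e:.10g}:{o.p:.10g}:{o.cells:g}" for o in options
    )


def _unpack_options(text: str) -> tuple[OptionStats, ...]:
    out = []
    for group in text.split(";"):
        nid, s, e, p, cells = group.split(":")
        out.append(
            OptionStats(
                node_id=int(nid), s=float(s), e=float(e), p=float(p), cells=float(cells)
            )
        )
    return tuple(out)


def records_to_frame(records: list[DecisionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "maze_id": [r.maze_id for r in records],
            "node_id": [r.node_id for r in records],
            "options": [_pack_options(r.options) for r in records],
            "chosen_id": [r.chosen_id for r in records],
            "decision_time_ms": [r.decision_time_ms for r in records],
            "is_initial": [int(r.is_initial) for r in records],
        }
    )


def frame_to_records(frame: pd.DataFrame) -> list[DecisionRecord]:
    return [
        DecisionRecord(
            participant_id=str(row.participant_id),
            maze_id=str(row.maze_id),
            node_id=int(row.node_id),
            options=_unpack_options(row.options),
            chosen_id=int(row.chosen_id),
            decision_time_ms=float(row.decision_time_ms),
            is_initial=bool(row.is_initial),
        )
        for row in frame.itertuples()
    ]


def write_decision_log(records: list[DecisionRecord], path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_decision_log(path) -> list[DecisionRecord]:
    return frame_to_records(pd.read_csv(path, sep="\t"))
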