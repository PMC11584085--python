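"""Linear regressions of decision times on fitted model parameters.

Initial decision times (first move of a trial, taken at the tree root) and
subsequent decision times (interior nodes) are regressed separately on the
parameters fitted to each participant. The predictor set depends on the
fitted model: τ alone; τ and γ; τ, γ and B; or τ, γ and b = |β − 1| (the
distance of the weighting exponent from its optimal value). The observation
unit is the individual decision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConfigError, MazeplanError
from .fitting import FitResult
from .records import DecisionRecord

MODEL_PREDICTORS: dict[str, tuple[str, ...]] = {
    "EU": ("tau",),
    "DU": ("tau", "gamma"),
    "DU-Num": ("tau", "gamma", "B"),
    "PW-DU": ("tau", "gamma", "b"),
}


def beta_distance(beta: float) -> float:
    """b = |β − 1|: distance of the weighting exponent from optimal."""
    return abs(beta - 1.0)


def split_decision_times(
    records: list[DecisionRecord],
) -> tuple[list[DecisionRecord], list[DecisionRecord]]:
    """Partition records into (initial, subsequent) by the is_initial flag."""
    initial = [r for r in records if r.is_initial]
    subsequent = [r for r in records if not r.is_initial]
    return initial, subsequent


@dataclass
class RegressionSpec:
    """One fitted regression in the layout of the decision-time tables."""

    response: str  # "initial" | "subsequent"
    model_id: str
    predictors: tuple[str, ...]
    coefficients: dict[str, float]  # includes "intercept"
    p_values: dict[str, float]
    f_statistic: float
    f_pvalue: float
    df_model: int
    df_resid: int
    n_obs: int

    def to_row(self) -> dict:
        row = {
            "times": self.response,
            "p": self.f_pvalue,
            "F": self.f_statistic,
            "df1": self.df_model,
            "df2": self.df_resid,
            "alpha0": self.coefficients["intercept"],
        }
        for i, name in enumerate(self.predictors, start=1):
            row[f"alpha{i} ({name})"] = self.coefficients[name]
            row[f"p (alpha{i})"] = self.p_values[name]
        return row


def _predictor_value(fr: FitResult, name: str) -> float:
    p = fr.best_params
    if name == "tau":
        return p.tau
    if name == "gamma":
        return p.gamma
    if name == "B":
        return p.B
    if name == "b":
        return beta_distance(p.beta)
    raise ConfigError(f"unknown predictor {name!r}")


def regress_times(
    records: list[DecisionRecord],
    fits: dict[str, FitResult],
    model_id: str,
    response: str,
    log_time: bool = False,
) -> RegressionSpec:
    """OLS of decision times on the participant-level fitted parameters.

    ``fits`` maps participant id to that participant's fit of ``model_id``;
    every time observation joins its participant's parameters. Raises on a
    rank-deficient design (e.g. a single participant).
    """
    predictors = MODEL_PREDICTORS.get(model_id)
    if predictors is None:
        raise ConfigError(
            f"no regression layout for model {model_id!r}; "
            f"choose one of {sorted(MODEL_PREDICTORS)}"
        )
    rows = []
    for r in records:
        fr = fits.get(r.participant_id)
        if fr is None:
            raise MazeplanError(f"no fitted parameters for {r.participant_id}")
        row = {name: _predictor_value(fr, name) for name in predictors}
        row["time"] = np.log(r.decision_time_ms) if log_time else r.decision_time_ms
        rows.append(row)
    frame = pd.DataFrame(rows)
    X = sm.add_constant(frame[list(predictors)].to_numpy(), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise MazeplanError("rank-deficient design matrix")
    res = sm.OLS(frame["time"].to_numpy(), X).fit()
    names = ("intercept",) + predictors
    return RegressionSpec(
        response=response,
        model_id=model_id,
        predictors=predictors,
        coefficients={n: float(res.params[i]) for i, n in enumerate(names)},
        p_values={n: float(res.pvalues[i]) for i, n in enumerate(names)},
        f_statistic=float(res.fvalue),
        f_pvalue=float(res.f_pvalue),
        df_model=int(res.df_model),
        df_resid=int(res.df_resid),
        n_obs=int(res.nobs),
    )


def decision_time_tables(
    records: list[DecisionRecord],
    fits_by_model: dict[str, dict[str, FitResult]],
    model_ids: tuple[str, ...] = ("EU", "DU", "DU-Num", "PW-DU"),
    log_time: bool = False,
) -> dict[str, pd.DataFrame]:
    """Initial and subsequent regressions for each requested model."""
    initial, subsequent = split_decision_times(records)
    tables: dict[str, pd.DataFrame] = {}
    for m in model_ids:
        if m not in fits_by_model:
            continue
        rows = [
            regress_times(initial, fits_by_model[m], m, "initial", log_time).to_row(),
            regress_times(
                subsequent, fits_by_model[m], m, "subsequent", log_time
            ).to_row(),
        ]
        tables[m] = pd.DataFrame(rows)
    return tables
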