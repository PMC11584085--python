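import numpy as np
import pytest

from mazeplan.errors import ConfigError, InsufficientDataError, MazeplanError
from mazeplan.fitting import (
    ParamGrids,
    aggregate_first_choices,
    bootstrap_correlation_difference,
    bootstrap_model_correlation,
    compare_models,
    default_grids,
    fit_cohort,
    fit_individual,
    fit_results_frame,
    make_folds,
    monte_carlo_splits,
    parameter_combos,
    predicted_choice_probs,
    random_model_ll,
    _loglik_matrix,
)
from mazeplan.planners import ModelParams
from mazeplan.records import DecisionRecord, OptionStats
from mazeplan.synthetic_data import CohortConfig, generate_cohort


def du_cohort(battery_models, n=8, gammas=(0.2, 0.5, 0.8), seed=0, tau=0.5):
    cc = CohortConfig(
        n_participants=n,
        mixture={"DU": 1.0},
        param_values={"DU": {"tau": [tau], "gamma": list(gammas)}},
        master_seed=seed,
    )
    return generate_cohort(cc, battery_models)


class TestFitIndividual:
    def test_random_model_closed_form(self, battery_models):
        records, _ = du_cohort(battery_models, n=1)
        fr = fit_individual(
            records, "Random", battery_models, grids=default_grids(reduced=True),
            rng=np.random.default_rng(0),
        )
        assert fr.total_test_ll == pytest.approx(random_model_ll(records), abs=1e-9)

    def test_insufficient_data(self, battery_models):
        records, _ = du_cohort(battery_models, n=1)
        with pytest.raises(InsufficientDataError):
            fit_individual(records[:3], "EU", battery_models)

    def test_empty_grid_rejected(self):
        with pytest.raises(ConfigError):
            ParamGrids(
                tau=(), gamma=(1.0,), beta=(1.0,), B=(10.0,), k_weight=(0.5,),
                mcts_budget=(10,), mcts_exploration=(1.0,),
            )

    def test_nesting_du_train_at_least_eu(self, battery_models):
        records, _ = du_cohort(battery_models, n=2)
        pid = records[0].participant_id
        recs = [r for r in records if r.participant_id == pid]
        grids = default_grids(reduced=True)
        folds = make_folds(len(recs), 5, np.random.default_rng(0))
        du = fit_individual(recs, "DU", battery_models, grids=grids, folds=folds)
        eu = fit_individual(recs, "EU", battery_models, grids=grids, folds=folds)
        assert du.train_ll >= eu.train_ll - 1e-9  # EU nested in DU's grid

    def test_gamma_recovery(self, battery_models):
        """Fitted discount rates track the generating ones."""
        records, truth = du_cohort(
            battery_models, n=12, gammas=(0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
            seed=5,
        )
        fits = fit_cohort(
            records, ["DU"], battery_models, grids=default_grids(reduced=True),
            master_seed=1,
        )
        frame = fit_results_frame(fits).merge(
            truth, on="participant_id", suffixes=("_fit", "_true")
        )
        err = np.abs(frame["gamma_fit"] - frame["gamma_true"])
        assert err.mean() <= 0.15

    def test_tau_upper_bound_approaches_random(self, battery_models):
        """As the tau grid collapses to its upper bound the fit flattens to
        the Random likelihood; the approach is monotone."""
        records, _ = du_cohort(battery_models, n=1)
        target = random_model_ll(records)
        taus = [1.0, 10.0, 100.0, 1000.0]
        params = ModelParams(model_id="DU", tau=1.0, gamma=0.5)
        lls = [
            float(_loglik_matrix(records, params, battery_models, np.array([t])).sum())
            for t in taus
        ]
        gaps = [abs(ll - target) for ll in lls]
        assert gaps == sorted(gaps, reverse=True)
        assert gaps[-1] < 0.05


class TestCompareModels:
    def test_identical_fits_zero_delta(self, battery_models):
        records, _ = du_cohort(battery_models, n=3)
        fits = fit_cohort(
            records, ["EU"], battery_models, grids=default_grids(reduced=True),
            master_seed=0,
        )
        fits2 = {"EU": fits["EU"], "DU": fits["EU"]}  # same numbers, two labels
        cmp = compare_models(fits2)
        assert cmp.ranking["delta_ll"].iloc[1] == pytest.approx(0.0)

    def test_mismatched_participants_error(self, battery_models):
        records, _ = du_cohort(battery_models, n=3)
        fits = fit_cohort(
            records, ["EU", "Steps"], battery_models,
            grids=default_grids(reduced=True), master_seed=0,
        )
        fits["Steps"] = {
            k: v for i, (k, v) in enumerate(sorted(fits["Steps"].items())) if i > 0
        }
        with pytest.raises(MazeplanError):
            compare_models(fits)

    def test_family_labels(self, battery_models):
        records, _ = du_cohort(battery_models, n=4)
        fits = fit_cohort(
            records, ["EU", "DU", "Steps", "Random"], battery_models,
            grids=default_grids(reduced=True), master_seed=0,
        )
        cmp = compare_models(fits)
        assert set(cmp.individual["family"]) <= {"planner", "heuristic"}
        assert set(cmp.individual["best_planner"]) <= {"EU", "DU"}


class TestAggregateChoices:
    def _mk(self, pid, maze, chosen, options=(1, 2), t=500.0, initial=True):
        return DecisionRecord(
            participant_id=pid, maze_id=maze, node_id=0,
            options=tuple(OptionStats(o, 1, 1, 0.5, 3) for o in options),
            chosen_id=chosen, decision_time_ms=t, is_initial=initial,
        )

    def test_unanimous(self):
        recs = [self._mk(f"p{i}", "m", 1) for i in range(5)]
        freq = aggregate_first_choices(recs)
        assert freq.loc[freq.option_id == 1, "prob"].iloc[0] == 1.0
        assert freq.loc[freq.option_id == 2, "prob"].iloc[0] == 0.0

    def test_even_split(self):
        recs = [self._mk(f"p{i}", "m", 1 if i < 58 else 2) for i in range(116)]
        freq = aggregate_first_choices(recs)
        assert set(freq["prob"]) == {0.5}

    def test_visitation_threshold(self):
        recs = [self._mk(f"p{i}", "m", 1) for i in range(10)]
        rare = [self._mk("p0", "m2", 1, initial=False)]
        freq = aggregate_first_choices(recs + rare, initial_only=False)
        assert "m2" not in set(freq["maze_id"])  # visited by 10% < 20%

    def test_generative_consistency(self, battery_models):
        """Simulated cohort frequencies match the model's own predictions."""
        cc = CohortConfig(
            n_participants=60, mixture={"DU": 1.0},
            param_values={"DU": {"tau": [0.5], "gamma": [0.6]}}, master_seed=9,
        )
        records, _ = generate_cohort(cc, battery_models)
        params = ModelParams(model_id="DU", tau=0.5, gamma=0.6)
        predicted = predicted_choice_probs(battery_models, params)
        freq = aggregate_first_choices(records)
        checked = 0
        for row in freq.itertuples():
            key = (row.maze_id, row.node_id, row.option_id)
            if key not in predicted:
                continue
            n = 60
            p = predicted[key]
            sigma = np.sqrt(max(p * (1 - p), 0.01) / n)
            assert abs(row.prob - p) < 5 * sigma
            checked += 1
        assert checked >= 10


class TestBootstrapCorrelation:
    def test_perfect_correlation(self, battery_models):
        cc = CohortConfig(
            n_participants=40, mixture={"EU": 1.0},
            param_values={"EU": {"tau": [0.5]}}, master_seed=2,
        )
        records, _ = generate_cohort(cc, battery_models)
        freq = aggregate_first_choices(records)
        predicted = {
            (r.maze_id, r.node_id, r.option_id): r.prob for r in freq.itertuples()
        }
        bc = bootstrap_model_correlation(
            records, predicted, n_boot=50, rng=np.random.default_rng(0)
        )
        assert bc.r == pytest.approx(1.0)
        # resampling perturbs the empirical frequencies, so the CI hugs 1
        # from below rather than containing it exactly
        assert bc.ci_low > 0.9 and bc.ci_high <= 1.0 + 1e-9

    def test_anti_correlation(self, battery_models):
        cc = CohortConfig(
            n_participants=40, mixture={"EU": 1.0},
            param_values={"EU": {"tau": [0.5]}}, master_seed=2,
        )
        records, _ = generate_cohort(cc, battery_models)
        freq = aggregate_first_choices(records)
        predicted = {
            (r.maze_id, r.node_id, r.option_id): 1.0 - r.prob
            for r in freq.itertuples()
        }
        bc = bootstrap_model_correlation(
            records, predicted, n_boot=20, rng=np.random.default_rng(0)
        )
        assert bc.r == pytest.approx(-1.0)

    def test_matched_model_beats_mismatched(self, battery_models):
        cc = CohortConfig(
            n_participants=80, mixture={"DU": 1.0},
            param_values={"DU": {"tau": [0.3], "gamma": [0.3]}}, master_seed=4,
        )
        records, _ = generate_cohort(cc, battery_models)
        good = predicted_choice_probs(
            battery_models, ModelParams(model_id="DU", tau=0.3, gamma=0.3)
        )
        bad = predicted_choice_probs(
            battery_models, ModelParams(model_id="Cells", tau=0.3)
        )
        r_good = bootstrap_model_correlation(
            records, good, n_boot=10, rng=np.random.default_rng(0)
        ).r
        r_bad = bootstrap_model_correlation(
            records, bad, n_boot=10, rng=np.random.default_rng(0)
        ).r
        assert r_good > r_bad
        diff = bootstrap_correlation_difference(
            records, good, bad, n_boot=100, rng=np.random.default_rng(1)
        )
        assert diff.r > 0

    def test_zero_variance_error(self):
        recs = [
            DecisionRecord(
                participant_id=f"p{i}", maze_id="m", node_id=0,
                options=(OptionStats(1, 1, 1, 0.5, 3), OptionStats(2, 1, 1, 0.5, 3)),
                chosen_id=1, decision_time_ms=1.0, is_initial=True,
            )
            for i in range(4)
        ]
        predicted = {("m", 0, 1): 0.5, ("m", 0, 2): 0.5}
        with pytest.raises(MazeplanError):
            bootstrap_model_correlation(
                recs, predicted, n_boot=5, rng=np.random.default_rng(0)
            )


class TestFolds:
    def test_partition(self):
        folds = make_folds(23, 5, np.random.default_rng(0))
        allidx = np.concatenate(folds)
        assert sorted(allidx) == list(range(23))
        assert len(folds) == 5

    def test_order_invariance_of_total_ll(self, battery_models):
        records, _ = du_cohort(battery_models, n=1)
        params = ModelParams(model_id="DU", tau=0.5, gamma=0.5)
        taus = np.array([0.5])
        fwd = _loglik_matrix(records, params, battery_models, taus).sum()
        rev = _loglik_matrix(records[::-1], params, battery_models, taus).sum()
        assert fwd == pytest.approx(rev, abs=1e-12)

    def test_monte_carlo_splits(self):
        splits = monte_carlo_splits(30, 7, 0.2, np.random.default_rng(0))
        assert len(splits) == 7
        assert all(len(s) == 6 for s in splits)


def test_parameter_combos_counts():
    grids = default_grids(reduced=True)
    assert len(parameter_combos("EU", grids)) == 1
    assert len(parameter_combos("DU", grids)) == len(grids.gamma)
    assert len(parameter_combos("PW-DU", grids)) == len(grids.gamma) * len(grids.beta)
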