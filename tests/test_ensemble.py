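"""Splitting, learning curves, the custom loss, tuning, selection, and the
negative-only averaging rule."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.dummy import DummyRegressor
from sklearn.linear_model import LinearRegression
from sklearn.neighbors import KNeighborsRegressor

from dapsol.ensemble import (
    EnsembleModel,
    LearningCurve,
    ModelSpec,
    RandomSampler,
    TPESampler,
    TunedModel,
    auc_of_curve,
    custom_loss,
    default_registry,
    ensemble_predict,
    evaluate,
    learning_curve,
    select_ensemble,
    split_data,
    tune,
)


def _table(n_solvents=5, rows_per_solvent=20, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_solvents):
        for i in range(rows_per_solvent):
            rows.append({"solvent_id": f"s{s}", "solvent_fraction": 1.0,
                         "T": 290.0 + i, "d1": rng.normal(), "log10x": -3.0 + 0.1 * s})
    return pd.DataFrame(rows)


class TestSplitData:
    def test_counts_match_fractions(self):
        train, test, val = split_data(_table(), (0.6, 0.2, 0.2), seed=1)
        assert (len(train), len(test), len(val)) == (60, 20, 20)

    def test_partition_is_disjoint_exhaustive_and_stratified(self):
        table = _table()
        train, test, val = split_data(table, (0.7, 0.15, 0.15), seed=3)
        idx = sorted([*train.index, *test.index, *val.index])
        assert idx == sorted(table.index)
        for part in (train, test, val):
            assert set(part["solvent_id"]) == set(table["solvent_id"])

    def test_same_seed_reproduces_partition(self):
        t = _table()
        a = split_data(t, seed=9)
        b = split_data(t, seed=9)
        for x, y in zip(a, b):
            assert x.index.equals(y.index)

    def test_degenerate_fractions_rejected(self):
        with pytest.raises(ValueError):
            split_data(_table(), (1.0, 0.0, 0.0))


def _xy(n=60, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 3))
    y = X @ np.array([1.0, -2.0, 0.5]) + noise * rng.normal(size=n)
    return X, y


class TestLearningCurve:
    def test_two_point_mode_yields_two_points(self):
        X, y = _xy()
        curve = learning_curve(LinearRegression(), X, y, (0.5, 1.0), seed=1)
        assert curve.fractions == (0.5, 1.0)
        assert len(curve.val_metric) == 2

    def test_memorizer_improves_with_more_data(self):
        # 1-NN on noiseless smooth data: validation error decreases with f
        rng = np.random.default_rng(2)
        X = rng.uniform(-1, 1, size=(300, 1))
        y = np.sin(3 * X[:, 0])
        curve = learning_curve(KNeighborsRegressor(1), X, y,
                               (0.5, 0.75, 1.0), seed=4)
        assert curve.val_metric[-1] < curve.val_metric[0]

    def test_constant_model_is_flat_at_analytic_mae(self):
        y = np.array([-4.0, -2.0] * 30)
        X = np.zeros((60, 1))
        curve = learning_curve(DummyRegressor(strategy="mean"), X, y,
                               (0.5, 1.0), seed=0)
        # MAE of predicting the mean of a symmetric two-level target is 1.0
        assert curve.val_metric == pytest.approx((1.0, 1.0), abs=0.05)
        assert curve.train_metric == pytest.approx((1.0, 1.0), abs=0.05)

    def test_subsample_smaller_than_folds_rejected(self):
        X, y = _xy(n=8)
        with pytest.raises(ValueError, match="smaller"):
            learning_curve(LinearRegression(), X, y, (0.5, 1.0), cv_folds=5)


class TestAucOfCurve:
    def _curve(self, fr, tr, va):
        return LearningCurve(tuple(fr), tuple(tr), tuple(va), "MAE", 5)

    def test_flat_curve_auc_is_its_value(self):
        c = self._curve((0.5, 1.0), (0.3, 0.3), (0.3, 0.3))
        assert auc_of_curve(c, "val") == pytest.approx(0.3)

    def test_linear_curve_trapezoid(self):
        c = self._curve((0.5, 1.0), (0.1, 0.1), (0.4, 0.2))
        assert auc_of_curve(c, "val") == pytest.approx(0.3)

    def test_collinear_interior_points_do_not_change_auc(self):
        c2 = self._curve((0.5, 1.0), (0.1, 0.1), (0.4, 0.2))
        c3 = self._curve((0.5, 0.75, 1.0), (0.1, 0.1, 0.1), (0.4, 0.3, 0.2))
        assert auc_of_curve(c3, "val") == pytest.approx(auc_of_curve(c2, "val"))


class TestCustomLoss:
    def _curve(self, tr, va, fr=(0.5, 1.0)):
        return LearningCurve(tuple(fr), tuple(tr), tuple(va), "MAE", 5)

    def test_no_gap_reduces_to_validation_mae(self):
        c = self._curve((0.4, 0.3), (0.4, 0.3))
        assert custom_loss(c) == pytest.approx(0.3)

    def test_constant_gap_adds_alpha_times_gap(self):
        c = self._curve((0.2, 0.3), (0.4, 0.5))
        assert custom_loss(c, alpha=1.0) == pytest.approx(0.7)

    def test_alpha_zero_is_plain_validation_mae(self):
        c = self._curve((0.1, 0.1), (0.9, 0.6))
        assert custom_loss(c, alpha=0.0) == pytest.approx(0.6)

    def test_negative_gap_is_not_rewarded(self):
        c = self._curve((0.9, 0.8), (0.4, 0.3))
        assert custom_loss(c) == pytest.approx(0.3)  # hinge clips to zero

    def test_loss_bounded_below_by_full_val_mae(self):
        c = self._curve((0.1, 0.2), (0.5, 0.4))
        assert custom_loss(c) >= 0.4

    def test_missing_full_data_point_rejected(self):
        c = LearningCurve((0.5, 0.9), (0.1, 0.1), (0.2, 0.2), "MAE", 5)
        with pytest.raises(ValueError, match="full-data"):
            custom_loss(c)


class TestSamplers:
    SPACE = {
        "a": ("logfloat", 1e-3, 1e2),
        "b": ("int", 1, 10),
        "c": ("cat", ("x", "y")),
        "d": ("float", 0.0, 1.0),
    }

    def _in_bounds(self, p):
        assert 1e-3 <= p["a"] <= 1e2
        assert 1 <= p["b"] <= 10 and isinstance(p["b"], int)
        assert p["c"] in ("x", "y")
        assert 0.0 <= p["d"] <= 1.0

    def test_random_sampler_stays_in_bounds_and_is_seeded(self):
        s1, s2 = RandomSampler(5), RandomSampler(5)
        for _ in range(20):
            p1, p2 = s1.suggest(self.SPACE, []), s2.suggest(self.SPACE, [])
            assert p1 == p2
            self._in_bounds(p1)

    def test_tpe_sampler_exploits_good_region(self):
        # loss = |log10(a)|: the TPE proposals should concentrate near a=1
        rng = np.random.default_rng(0)
        smp = TPESampler(seed=0, n_startup=10)
        history = []
        for _ in range(80):
            p = smp.suggest(self.SPACE, history)
            self._in_bounds(p)
            history.append((p, abs(math.log10(p["a"]))))
        late = [abs(math.log10(p["a"])) for p, _ in history[60:]]
        early = [abs(math.log10(p["a"])) for p, _ in history[:10]]
        assert np.mean(late) < np.mean(early)


class TestTune:
    def test_degenerate_space_returns_single_configuration(self):
        X, y = _xy()
        spec = ModelSpec("knn1",
                         lambda p, s: KNeighborsRegressor(n_neighbors=p["k"]),
                         {"k": ("int", 3, 3)})
        tuned = tune(spec, X, y, n_trials=1, seed=0)
        assert tuned.hyperparameters == {"k": 3}
        assert math.isfinite(tuned.custom_loss)

    def test_random_sampler_rerun_is_identical(self):
        X, y = _xy(noise=0.1)
        spec = next(s for s in default_registry() if s.algorithm_id == "ridge")
        t1 = tune(spec, X, y, n_trials=25, sampler="random", seed=11)
        t2 = tune(spec, X, y, n_trials=25, sampler="random", seed=11)
        assert t1.hyperparameters == t2.hyperparameters
        assert t1.custom_loss == t2.custom_loss

    def test_ridge_recovers_near_ols_on_linear_data(self):
        X, y = _xy(n=80, noise=0.05, seed=3)
        spec = next(s for s in default_registry() if s.algorithm_id == "ridge")
        tuned = tune(spec, X, y, n_trials=60, seed=2)
        ols_curve = learning_curve(LinearRegression(), X, y, (0.5, 1.0), seed=2)
        ols_loss = custom_loss(ols_curve)
        assert tuned.custom_loss <= ols_loss * 1.05


def _planted_candidate(name, auc, fitted=None):
    curve = LearningCurve((0.5, 1.0), (auc, auc), (auc, auc), "RMS", 5)
    spec = ModelSpec(name, lambda p, s: None, {})
    return TunedModel(name, {}, auc, curve, spec, 0, dense_lca=curve, fitted=fitted)


class TestSelectEnsemble:
    def test_planted_low_auc_cluster_is_selected_exactly(self):
        low = [_planted_candidate(f"low{i}", 0.1 + 0.001 * i) for i in range(9)]
        high = [_planted_candidate(f"high{i}", 1.0 + 0.01 * i) for i in range(27)]
        ens = select_ensemble(low + high, k=9)
        assert sorted(m.algorithm_id for m in ens.members) == sorted(
            c.algorithm_id for c in low
        )

    def test_dominating_candidate_ranks_first(self):
        cands = [_planted_candidate("best", 0.05)] + [
            _planted_candidate(f"c{i}", 0.5 + 0.1 * i) for i in range(9)
        ]
        ens = select_ensemble(cands, k=3)
        assert ens.members[0].algorithm_id == "best"

    def test_identical_candidates_any_k_selected(self):
        cands = [_planted_candidate(f"c{i}", 0.2) for i in range(12)]
        ens = select_ensemble(cands, k=9)
        assert len(ens.members) == 9

    def test_too_few_candidates_rejected(self):
        with pytest.raises(ValueError, match="need >="):
            select_ensemble([_planted_candidate("a", 0.1)], k=9)


class _Const:
    def __init__(self, v):
        self.v = v

    def predict(self, X):
        return np.full(len(X), self.v)


def _const_ensemble(values):
    members = [_planted_candidate(f"m{i}", 0.1, fitted=_Const(v))
               for i, v in enumerate(values)]
    return EnsembleModel(members, {}, {})


class TestEnsemblePredict:
    def test_negative_only_averaging(self):
        out = ensemble_predict(_const_ensemble([-3.0, -2.0, 0.5]), np.zeros((4, 1)))
        assert np.allclose(out["log10x_pred"], -2.5)
        assert (out["n_members_used"] == 2).all()
        assert not out["failed"].any()

    def test_unanimous_members_pass_through(self):
        out = ensemble_predict(_const_ensemble([-4.2, -4.2, -4.2]), np.zeros((2, 1)))
        assert np.allclose(out["log10x_pred"], -4.2)

    def test_all_nonnegative_rows_are_flagged_failed(self):
        out = ensemble_predict(_const_ensemble([0.1, 0.2]), np.zeros((3, 1)))
        assert out["failed"].all()
        assert out["log10x_pred"].isna().all()

    def test_prediction_within_member_range(self):
        out = ensemble_predict(_const_ensemble([-5.0, -1.0, -3.0]), np.zeros((1, 1)))
        assert -5.0 <= out["log10x_pred"].iloc[0] <= -1.0


class TestEvaluate:
    def test_perfect_prediction(self):
        m = evaluate([-1.0, -2.0, -3.0], [-1.0, -2.0, -3.0])
        assert m["MAE"] == 0 and m["RMSE"] == 0 and m["R2"] == 1

    def test_constant_offset(self):
        obs = np.array([-1.0, -2.0, -3.0, -4.0])
        m = evaluate(obs + 0.1, obs)
        assert m["MAE"] == pytest.approx(0.1)
        assert m["RMSE"] == pytest.approx(0.1)

    def test_matches_hand_computation_on_four_points(self):
        obs = np.array([-2.0, -3.0, -4.0, -5.0])
        pred = np.array([-2.1, -2.8, -4.3, -5.0])
        m = evaluate(pred, obs)
        errs = pred - obs
        assert m["MAE"] == pytest.approx(np.abs(errs).mean())
        assert m["RMSE"] == pytest.approx(np.sqrt((errs**2).mean()))
        ss_res = (errs**2).sum()
        ss_tot = ((obs - obs.mean()) ** 2).sum()
        assert m["R2"] == pytest.approx(1 - ss_res / ss_tot)
        assert m["MAPE_log10"] == pytest.approx(
            100 * np.mean(np.abs(errs / obs))
        )


class TestEndToEndRecovery:
    def test_tuned_ensemble_recovers_planted_signal(self):
        # 300 rows, three informative descriptors at planted link R^2 = 0.9:
        # the tuned ensemble must reach test R^2 >= 0.8
        from dapsol.ensemble import train_ensemble
        from dapsol.synthetic import (
            SyntheticTruth, gen_descriptor_table, gen_solubility_profiles,
            gen_solvent_space, gen_truth,
        )
        solvents = gen_solvent_space(10, (-1.0, 0.0, 1.0), seed=6)
        truth = gen_truth(solvents, seed=6)
        truth.descriptor_links = {
            "d1": (1.0, 0.0, 0.9), "d2": (-1.5, 2.0, 0.9), "d3": (0.7, -1.0, 0.9)
        }
        recs = gen_solubility_profiles(
            solvents, tuple(288.15 + 4 * i for i in range(10)), truth, seed=7
        )
        table = gen_descriptor_table(recs, truth, seed=8)
        assert len(table) == 300
        ensemble, report = train_ensemble(table, n_trials=8, seed=0, dense_points=5)
        assert len(ensemble.members) == 9
        assert report["test"]["R2"] >= 0.8
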