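"""Split plans, metrics, residual diagnostics, cross-dataset floor."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pathdsp import (
    compute_metrics,
    laplace_residual_test,
    make_splits,
    theoretical_floor,
)
from pathdsp.evaluation import run_experiment
from pathdsp.features import FeatureMatrix


def _pairs(n_drugs=5, n_cells=8):
    return [(f"d{i}", f"c{j}") for i in range(n_drugs) for j in range(n_cells)]


class TestMakeSplits:
    def test_kfold_10x5_yields_50_partitioning_folds(self):
        pairs = _pairs(10, 10)
        plan = make_splits(pairs, mode="kfold", k=10, repeats=5, rng_seed=0)
        assert len(plan) == 50
        for r in range(5):
            test_union = np.concatenate(
                [te for (_, te) in plan.folds[r * 10:(r + 1) * 10]])
            assert sorted(test_union) == list(range(len(pairs)))

    def test_kfold_sizes_within_one(self):
        plan = make_splits(_pairs(3, 11), mode="kfold", k=10, rng_seed=1)
        sizes = [len(te) for _, te in plan.folds]
        assert max(sizes) - min(sizes) <= 1

    def test_kfold_deterministic_given_seed(self):
        pairs = _pairs()
        a = make_splits(pairs, k=5, rng_seed=3)
        b = make_splits(pairs, k=5, rng_seed=3)
        assert all((x[1] == y[1]).all() for x, y in zip(a.folds, b.folds))

    def test_kfold_singleton_folds(self):
        plan = make_splits(_pairs(2, 5), mode="kfold", k=10, rng_seed=0)
        assert all(len(te) == 1 for _, te in plan.folds)

    def test_k_exceeding_rows_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            make_splits(_pairs(1, 5), k=10)

    @pytest.mark.parametrize("mode,key", [("lodo", 0), ("loco", 1)])
    def test_held_out_entity_absent_from_training(self, mode, key):
        pairs = _pairs()
        plan = make_splits(pairs, mode=mode)
        entities = sorted({p[key] for p in pairs})
        assert plan.labels == entities
        for (tr, te), label in zip(plan.folds, plan.labels):
            assert all(pairs[i][key] == label for i in te)
            assert all(pairs[i][key] != label for i in tr)
            assert len(tr) + len(te) == len(pairs)

    def test_every_fold_is_leak_free(self):
        pairs = _pairs()
        for mode in ("kfold", "lodo", "loco"):
            plan = make_splits(pairs, mode=mode, k=5, rng_seed=0)
            for tr, te in plan.folds:
                assert not set(tr) & set(te)


class TestComputeMetrics:
    def test_perfect_prediction(self):
        m = compute_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (m["MAE"], m["RMSE"], m["R2"], m["PCC"]) == (0.0, 0.0, 1.0, 1.0)

    def test_closed_form_errors_three_and_four(self):
        m = compute_metrics([0.0, 0.0], [3.0, 4.0])
        assert m["MAE"] == pytest.approx(3.5)
        assert m["RMSE"] == pytest.approx(3.5355, abs=1e-4)

    def test_constant_prediction_gives_nan_pcc(self):
        with pytest.warns(UserWarning, match="PCC"):
            m = compute_metrics([1.0, 2.0], [5.0, 5.0])
        assert np.isnan(m["PCC"])

    # magnitudes bounded away from the underflow regime so e**2 stays finite
    _value = st.one_of(st.just(0.0), st.floats(1e-6, 1e6), st.floats(-1e6, -1e-6))

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.tuples(_value, _value), min_size=2, max_size=50))
    def test_rmse_dominates_mae(self, pairs):
        y_true = [a for a, _ in pairs]
        y_pred = [b for _, b in pairs]
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = compute_metrics(y_true, y_pred)
        assert m["RMSE"] >= m["MAE"] >= 0

    def test_rmse_equals_mae_iff_equal_magnitudes(self):
        m = compute_metrics([0.0, 0.0], [2.0, -2.0])
        assert m["RMSE"] == pytest.approx(m["MAE"])


class TestLaplaceResidualTest:
    def test_accepts_laplace_samples(self):
        accepted = sum(
            laplace_residual_test(
                np.random.default_rng(s).laplace(0, 1, size=1000)
            )["p_value"] > 0.05
            for s in range(5)
        )
        assert accepted >= 4

    def test_rejects_uniform_samples(self):
        rejected = sum(
            laplace_residual_test(
                np.random.default_rng(s).uniform(-1, 1, size=1000)
            )["p_value"] < 0.01
            for s in range(5)
        )
        assert rejected >= 4

    def test_too_few_residuals_raises(self):
        with pytest.raises(ValueError, match="30"):
            laplace_residual_test(np.zeros(10))

    def test_fit_is_median_and_mad(self):
        res = np.array([-2.0, -1.0, 0.0, 1.0, 10.0] * 10)
        out = laplace_residual_test(res)
        assert out["loc"] == np.median(res)
        assert out["scale"] == pytest.approx(np.mean(np.abs(res - np.median(res))))


class TestTheoreticalFloor:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["drug", "cell", "response"])

    def test_identical_tables_floor_zero(self):
        t = self._table([("d", "c", 1.0), ("d2", "c", -0.5)])
        assert theoretical_floor(t, t) == (0.0, 0.0)

    def test_single_shared_pair(self):
        a = self._table([("d", "c", 1.0)])
        b = self._table([("d", "c", 3.0)])
        assert theoretical_floor(a, b) == (2.0, 2.0)

    def test_restricted_to_shared_pairs(self):
        a = self._table([("d", "c", 1.0), ("dX", "cX", 99.0)])
        b = self._table([("d", "c", 2.0), ("dY", "cY", -99.0)])
        assert theoretical_floor(a, b) == (1.0, 1.0)

    def test_disjoint_tables_raise(self):
        a = self._table([("d1", "c1", 1.0)])
        b = self._table([("d2", "c2", 1.0)])
        with pytest.raises(ValueError, match="share no"):
            theoretical_floor(a, b)


class TestRunExperiment:
    def test_cv_driver_produces_per_fold_and_pooled_metrics(self, rng):
        n, d = 60, 5
        cols = pd.MultiIndex.from_tuples([("EXP", f"P{i}") for i in range(d)])
        idx = pd.MultiIndex.from_tuples(
            [(f"d{i % 3}", f"c{i}") for i in range(n)])
        X = pd.DataFrame(rng.normal(size=(n, d)), index=idx, columns=cols)
        y = pd.Series(X.to_numpy() @ np.arange(1.0, d + 1), index=idx)
        fm = FeatureMatrix(X=X, y=y)
        plan = make_splits(list(idx), mode="kfold", k=3, rng_seed=0)
        res = run_experiment(fm, plan,
                             fnn_params=dict(hidden_layer_sizes=(16,),
                                             max_epochs=60, patience=60,
                                             learning_rate=3e-3),
                             rng_seed=0)
        assert len(res.fold_metrics) == 3
        assert len(res.predictions) == n
        pooled = res.pooled_metrics()
        assert pooled["RMSE"] >= pooled["MAE"]
        # the model must beat the mean predictor on this linear signal
        assert pooled["RMSE"] < y.std()
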