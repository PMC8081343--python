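import numpy as np
import pandas as pd
import pytest

import kernelstack as ks
from kernelstack.forest import ForestParams
from kernelstack.stacking import (
    StackedKernelConfig,
    binarize_regression_errors,
    derive_seed,
    load_model,
    save_model,
    select_relevant_forests,
    write_importance_tables,
)


def _cfg(**kw):
    base = dict(
        forest=ForestParams(n_trees=50),
        n_lambda_candidates=10,
        seed=0,
    )
    base.update(kw)
    return StackedKernelConfig(**base)


@pytest.fixture(scope="module")
def trained():
    ds, coll, truth = ks.generate(
        n_samples=50, n_sets=6, set_size_range=(5, 8), n_causal=4, seed=17
    )
    model = ks.train(ds, coll, _cfg(seed=2))
    return ds, coll, truth, model


class TestBinarizeRegressionErrors:
    def test_quantile_flags_exact_count_with_distinct_errors(self):
        rng = np.random.default_rng(0)
        preds = rng.standard_normal((8, 100))
        y = np.zeros(8)
        flags = binarize_regression_errors(preds, y, q=0.05)
        # type-7 quantile with distinct errors: 5% of 100 sets + interpolation
        counts = flags.sum(axis=1)
        assert ((counts >= 5) & (counts <= 6)).all()
        # brute-force check per sample
        errs = np.abs(preds - y[:, None])
        for i in range(8):
            thr = np.quantile(errs[i], 0.05)
            assert np.array_equal(flags[i], errs[i] <= thr)

    def test_flag_count_monotone_in_q_and_full_in_the_limit(self):
        preds = np.arange(12.0).reshape(3, 4)
        y = np.zeros(3)
        counts = [
            binarize_regression_errors(preds, y, q).sum()
            for q in (0.05, 0.5, 0.9, 0.999999)
        ]
        assert counts == sorted(counts)
        # as q -> 1 the threshold approaches the max error: all but at most
        # the single maximal-error set per sample are flagged
        assert counts[-1] >= preds.size - preds.shape[0]

    def test_minimum_error_set_always_flagged(self):
        rng = np.random.default_rng(1)
        preds = rng.standard_normal((10, 30))
        y = rng.standard_normal(10)
        flags = binarize_regression_errors(preds, y, q=0.05)
        best = np.abs(preds - y[:, None]).argmin(axis=1)
        assert flags[np.arange(10), best].all()


class TestSelection:
    def test_single_always_correct_forest(self, trained):
        ds, coll, _, model = trained
        from kernelstack.datasets import map_feature_set
        from kernelstack.forest import fit_forest

        af = map_feature_set("planted_set", coll.sets["planted_set"], ds)
        f = fit_forest(af, ds, ForestParams(n_trees=80, seed=0))
        # force perfect OOB predictions: selection must return just this forest
        f.oob_prediction = ds.labels.to_numpy().copy()
        f.tau = 1.0
        sel = select_relevant_forests([f], ds.labels.to_numpy(), G=1, q=0.05,
                                      task=ds.task)
        assert [s.set_name for s in sel] == ["planted_set"]

    def test_tau_ties_break_by_set_name(self, trained):
        ds, *_ = trained
        from kernelstack.datasets import map_feature_set
        from kernelstack.forest import fit_forest

        y = ds.labels.to_numpy()
        forests = []
        for name in ("zzz", "aaa", "mmm"):
            af = map_feature_set(name, ["GENE00000"], ds)
            f = fit_forest(af, ds, ForestParams(n_trees=40, seed=1))
            f.oob_prediction = y.copy()
            f.tau = 0.75
            forests.append(f)
        sel = select_relevant_forests(forests, y, G=2, q=0.05, task=ds.task)
        assert [s.set_name for s in sel] == ["aaa", "mmm"]

    def test_no_correct_forest_raises(self, trained):
        ds, *_ = trained
        from kernelstack.datasets import map_feature_set
        from kernelstack.forest import fit_forest

        y = ds.labels.to_numpy()
        af = map_feature_set("s", ["GENE00000"], ds)
        f = fit_forest(af, ds, ForestParams(n_trees=40, seed=1))
        f.oob_prediction = 1 - y  # always wrong
        with pytest.raises(ValueError, match="no forest"):
            select_relevant_forests([f], y, G=3, q=0.05, task=ds.task)


class TestTrainPredict:
    def test_model_structure(self, trained):
        ds, coll, truth, model = trained
        w = model.feature_set_weights
        assert w.sum() == pytest.approx(1.0)
        assert (w >= 0).all()
        assert set(model.selected_set_names) == set(w.index)
        fw = model.feature_weights
        assert fw.sum() == pytest.approx(1.0)
        selected_feats = {
            f for forest in model.selected_forests for f in forest.feature_names
        }
        assert set(fw[fw > 0].index) <= selected_feats
        assert model.datatype_weights.sum() == pytest.approx(1.0)

    def test_same_seed_same_weights(self):
        ds, coll, _ = ks.generate(
            n_samples=45, n_sets=5, set_size_range=(5, 7), n_causal=4, seed=23
        )
        m1 = ks.train(ds, coll, _cfg(seed=9))
        m2 = ks.train(ds, coll, _cfg(seed=9))
        pd.testing.assert_series_equal(m1.feature_set_weights, m2.feature_set_weights)
        pd.testing.assert_series_equal(m1.feature_weights, m2.feature_weights)

    def test_predict_training_reproduces_fitted_scores(self, trained):
        ds, _, _, model = trained
        from kernelstack.mkl import mkl_predict
        from kernelstack.kernels import rf_kernel_full

        fulls = [rf_kernel_full(f) for f in model.selected_forests]
        fitted = mkl_predict(model.meta, fulls)["score"]
        pred = ks.predict(model, ds)
        assert np.allclose(pred["score"].to_numpy(), fitted, atol=1e-8)

    def test_duplicated_new_sample_identical_predictions(self, trained):
        ds, _, _, model = trained
        X2 = ds.X.iloc[[3, 3]]
        pred = ks.predict(model, X2)
        assert pred.iloc[0]["score"] == pred.iloc[1]["score"]

    def test_missing_features_error(self, trained):
        ds, _, _, model = trained
        with pytest.raises(ValueError, match="missing required features"):
            ks.predict(model, ds.X.iloc[:, :3])

    def test_worker_count_does_not_change_results(self):
        ds, coll, _ = ks.generate(
            n_samples=40, n_sets=4, set_size_range=(5, 6), n_causal=4, seed=29
        )
        m1 = ks.train(ds, coll, _cfg(seed=5, n_jobs=1))
        m2 = ks.train(ds, coll, _cfg(seed=5, n_jobs=2))
        pd.testing.assert_series_equal(m1.feature_set_weights, m2.feature_set_weights)


class TestRegressionTask:
    def test_pipeline_runs_and_beats_constant_predictor(self):
        ds, coll, _ = ks.generate(
            n_samples=60, n_sets=5, set_size_range=(5, 8), n_causal=4,
            task="regression", effect_size=1.5, seed=31,
        )
        model = ks.train(ds, coll, _cfg(seed=1))
        fresh, _, _ = ks.generate(
            n_samples=60, n_sets=5, set_size_range=(5, 8), n_causal=4,
            task="regression", effect_size=1.5, seed=31, data_seed=999,
        )
        pred = ks.predict(model, fresh)["score"].to_numpy()
        y = fresh.labels.to_numpy()
        rmse = np.sqrt(np.mean((pred - y) ** 2))
        const = np.sqrt(np.mean((y - y.mean()) ** 2))
        assert rmse < const

    def test_meta_loss_is_squared(self):
        ds, coll, _ = ks.generate(
            n_samples=40, n_sets=4, set_size_range=(5, 6), n_causal=4,
            task="regression", seed=37,
        )
        model = ks.train(ds, coll, _cfg(seed=1))
        assert model.meta.loss == "squared"
        pred = ks.predict(model, ds)
        assert list(pred.columns) == ["score"]


class TestSerialization:
    def test_roundtrip_bit_identical_predictions(self, trained, tmp_path):
        ds, _, _, model = trained
        p = tmp_path / "model.pkl"
        save_model(model, p)
        back = load_model(p)
        a = ks.predict(model, ds)["score"].to_numpy()
        b = ks.predict(back, ds)["score"].to_numpy()
        assert np.array_equal(a, b)

    def test_importance_tables_written(self, trained, tmp_path):
        _, _, _, model = trained
        write_importance_tables(model, tmp_path)
        fs = pd.read_csv(tmp_path / "feature_set_importance.tsv", sep="\t")
        assert list(fs.columns) == ["rank", "feature_set", "weight"]
        assert fs["weight"].sum() == pytest.approx(1.0)
        fw = pd.read_csv(tmp_path / "feature_importance.tsv", sep="\t")
        assert set(fw["data_type"]) <= {"expr", "cnv", "global"}


class TestImportanceAggregation:
    def test_single_selected_forest_equals_normalized_importances(self):
        ds, coll, _ = ks.generate(
            n_samples=40, n_sets=4, set_size_range=(5, 6), n_causal=4, seed=41
        )
        # G large + 2 usable sets, but force selection to one by dropping others
        model = ks.train(ds, coll, _cfg(seed=3))
        if len(model.selected_forests) == 1:
            f = model.selected_forests[0]
            imp = f.importances / f.importances.sum()
            got = model.feature_weights[f.feature_names].to_numpy()
            assert np.allclose(np.sort(got), np.sort(imp))

    def test_weighted_sharing_formula(self):
        """Feature in two sets with weights .6/.4 and per-forest importances
        .5/.5 contributes .5 before renormalization."""
        from kernelstack.stacking import _aggregate_importances
        from kernelstack.forest import FittedForest

        def mini(name, feats, imps):
            return FittedForest(
                set_name=name, feature_names=feats, task="classification",
                classes=np.array([0, 1]), trees=[], bfs_maps=[],
                oob_mask=np.ones((1, 1), bool), tree_predictions=np.zeros((1, 1)),
                leaf_matrix=np.zeros((1, 1), int), oob_prediction=np.empty(0),
                oob_probability=None, importances=np.asarray(imps, float),
            )

        f1 = mini("A", ["shared", "a2"], [0.5, 0.5])
        f2 = mini("B", ["shared", "b2"], [0.5, 0.5])
        w = pd.Series({"A": 0.6, "B": 0.4})
        fw, dt = _aggregate_importances([f1, f2], w)
        # shared: 0.6*0.5 + 0.4*0.5 = 0.5 before renormalization (total = 1)
        assert fw["shared"] == pytest.approx(0.5)

    def test_global_features_form_own_datatype(self):
        ds, coll, _ = ks.generate(
            n_samples=50, n_sets=4, set_size_range=(5, 7), n_causal=4, seed=43
        )
        ds = ks.generate_global_features(ds, n_globals=2, informativeness=0.9, seed=1)
        model = ks.train(ds, coll, _cfg(seed=4))
        assert "global" in model.datatype_weights.index
        assert model.datatype_weights.sum() == pytest.approx(1.0)


def test_derive_seed_stable_and_distinct():
    a = derive_seed(1, "setA")
    assert a == derive_seed(1, "setA")
    assert a != derive_seed(1, "setB")
    assert a != derive_seed(2, "setA")
    assert 0 <= a < 2**31 - 1
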