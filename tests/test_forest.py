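import numpy as np
import pandas as pd
import pytest

from mobrf import (
    ForestControl,
    InputError,
    MobControl,
    NodeModelSpec,
    build_forest,
    draw_resample,
    get_predicted_values,
    parse_formula,
)
from mobrf.forest import MobForestOutput, validate_inputs, write_predictions_csv

from conftest import GAUSSIAN_PARTITION_VARS


class TestDrawResample:
    def test_subsample_sizes_exact(self):
        control = ForestControl(fraction=0.632, replace=False)
        rng = np.random.default_rng(0)
        rs = draw_resample(1000, control, rng)
        assert rs.in_bag_counts.sum() == 632
        assert rs.oob_mask.sum() == 368
        assert set(np.unique(rs.in_bag_counts)) <= {0, 1}

    def test_bootstrap_draws_n(self):
        control = ForestControl(replace=True)
        rs = draw_resample(500, control, np.random.default_rng(1))
        assert rs.in_bag_counts.sum() == 500
        assert np.array_equal(rs.oob_mask, rs.in_bag_counts == 0)

    def test_full_fraction_leaves_no_oob(self):
        control = ForestControl(fraction=1.0, replace=False)
        rs = draw_resample(100, control, np.random.default_rng(2))
        assert rs.oob_mask.sum() == 0

    def test_empty_in_bag_rejected(self):
        control = ForestControl(fraction=0.4, replace=False)
        with pytest.raises(InputError):
            draw_resample(1, control, np.random.default_rng(3))


class TestBuildForest:
    def test_bookkeeping_shapes(self, gaussian_forest):
        data, out = gaussian_forest
        ntree = out.control.ntree
        assert len(out.trees) == ntree == len(out.resamples)
        assert out.predictions_oob.shape == (len(data), ntree)
        assert out.predictions_all.shape == (len(data), ntree)

    def test_oob_exclusivity(self, gaussian_forest):
        _, out = gaussian_forest
        for k, rs in enumerate(out.resamples):
            col = out.predictions_oob[:, k]
            assert np.isnan(col[~rs.oob_mask]).all()
            assert not np.isnan(col[rs.oob_mask]).any()

    def test_in_bag_size_constant_under_subsampling(self, gaussian_forest):
        data, out = gaussian_forest
        expected = int(np.floor(out.control.fraction * len(data)))
        assert all(rs.in_bag_counts.sum() == expected for rs in out.resamples)

    def test_degenerate_ensemble_identical_trees(self, gaussian_data):
        data, _ = gaussian_data
        control = ForestControl(ntree=4, mtry=10, fraction=1.0, replace=False, seed=1)
        with pytest.warns(UserWarning):
            out = build_forest(data, parse_formula("y ~ x"), GAUSSIAN_PARTITION_VARS, control)
        first = out.trees[0].to_json()
        assert all(t.to_json() == first for t in out.trees)
        sd = np.std(out.predictions_all, axis=1)
        assert np.allclose(sd, 0.0, atol=1e-12)
        per_tree = out.accuracy.per_tree_all_metric
        assert np.allclose(per_tree, out.accuracy.forest_all_metric)

    def test_processors_do_not_change_results(self, gaussian_data):
        data, _ = gaussian_data
        pv = GAUSSIAN_PARTITION_VARS
        spec = parse_formula("y ~ x")
        o1 = build_forest(data, spec, pv, ForestControl(ntree=4, mtry=5, seed=21, processors=1))
        o2 = build_forest(data, spec, pv, ForestControl(ntree=4, mtry=5, seed=21, processors=2))
        assert np.array_equal(o1.predictions_all, o2.predictions_all)
        assert np.array_equal(o1.predictions_oob, o2.predictions_oob, equal_nan=True)
        assert np.array_equal(o1.importance.raw_scores, o2.importance.raw_scores)

    def test_jensen_variance_reduction_on_test_set(self, gaussian_data):
        from mobrf import fixture_spec, generate_subgroup_data, mean_squared_error

        data, _ = gaussian_data
        test, _ = generate_subgroup_data(fixture_spec("two_subgroup_gaussian", n=200, seed=99))
        out = build_forest(
            data,
            parse_formula("y ~ x"),
            GAUSSIAN_PARTITION_VARS,
            ForestControl(ntree=6, mtry=5, seed=4),
            new_test_data=test,
        )
        per_tree = [
            mean_squared_error(out.y_test, out.predictions_test[:, k])
            for k in range(out.control.ntree)
        ]
        forest_mse = mean_squared_error(out.y_test, out.predictions_test.mean(axis=1))
        assert forest_mse <= np.mean(per_tree) + 1e-12

    def test_validation_names_offending_column(self, gaussian_data):
        data, _ = gaussian_data
        spec = parse_formula("y ~ x", "binomial")
        with pytest.raises(InputError, match="'y'"):
            validate_inputs(data, spec, GAUSSIAN_PARTITION_VARS)
        bad = data.copy()
        bad.loc[3, "z02"] = np.nan
        with pytest.raises(InputError, match="z02"):
            validate_inputs(bad, parse_formula("y ~ x"), GAUSSIAN_PARTITION_VARS)
        with pytest.raises(InputError, match="nope"):
            validate_inputs(data, parse_formula("y ~ x"), ["nope"])


def _fake_output(pred_oob, pred_all, y, family="gaussian", ntree=None):
    ntree = ntree or pred_all.shape[1]
    spec = NodeModelSpec("y", ("x",), family)
    control = ForestControl(ntree=ntree, mtry=1, seed=0)
    return MobForestOutput(
        trees=[],
        resamples=[],
        predictions_oob=pred_oob,
        predictions_all=pred_all,
        predictions_test=None,
        y=y,
        y_test=None,
        spec=spec,
        partition_variables=("z",),
        control=control,
    )


class TestGetPredictedValues:
    def test_mean_and_sample_sd(self):
        # subject 0 OOB in trees 2 and 5 with predictions 1.0 and 3.0
        pred_oob = np.full((2, 6), np.nan)
        pred_oob[0, [1, 4]] = [1.0, 3.0]
        pred_oob[1, :] = 2.0
        out = _fake_output(pred_oob, np.zeros((2, 6)), y=np.array([4.0, 2.0]))
        frame = get_predicted_values(out, use_oob=True)
        assert frame.loc[0, "mean_prediction"] == pytest.approx(2.0)
        assert frame.loc[0, "sd_prediction"] == pytest.approx(np.sqrt(2.0))
        assert frame.loc[0, "residual"] == pytest.approx(2.0)

    def test_single_prediction_sd_zero(self):
        pred_oob = np.full((1, 3), np.nan)
        pred_oob[0, 0] = 1.5
        out = _fake_output(pred_oob, np.zeros((1, 3)), y=np.array([2.0]))
        frame = get_predicted_values(out, use_oob=True)
        assert frame.loc[0, "sd_prediction"] == 0.0

    def test_never_oob_subject_missing_with_warning(self):
        pred_oob = np.full((2, 3), np.nan)
        pred_oob[1, :] = 1.0
        out = _fake_output(pred_oob, np.zeros((2, 3)), y=np.array([1.0, 1.0]))
        with pytest.warns(UserWarning, match="never out-of-bag"):
            frame = get_predicted_values(out, use_oob=True)
        assert frame.loc[0].isna().all()

    def test_logistic_family_has_no_residual_column(self):
        pred_oob = np.array([[0.2, 0.4], [0.6, 0.8]])
        out = _fake_output(pred_oob, pred_oob, y=np.array([0.0, 1.0]), family="binomial")
        frame = get_predicted_values(out, use_oob=True)
        assert "residual" not in frame.columns
        assert "residual" in frame.attrs.get("residuals", "residual")

    def test_newdata_requires_test_set(self):
        out = _fake_output(np.zeros((1, 2)), np.zeros((1, 2)), y=np.array([0.0]))
        with pytest.raises(InputError):
            get_predicted_values(out, use_newdata=True)

    def test_predictions_csv_schema(self, tmp_path, gaussian_forest):
        _, out = gaussian_forest
        path = tmp_path / "pred.csv"
        write_predictions_csv(get_predicted_values(out, use_oob=True), path)
        frame = pd.read_csv(path)
        assert list(frame.columns) == ["id", "mean_prediction", "sd_prediction", "residual"]
        assert len(frame) == len(out.y)
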