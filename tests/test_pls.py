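"""Unit and property tests for the NIPALS PLS core."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pulsepore as pp
from pulsepore.pls import autoscale, r2_score_corr, r2_score_ss


class TestSampleTable:
    def test_duplicate_ids_rejected(self, reference_table):
        df = reference_table.df.copy()
        df.loc[1, "sample_id"] = df.loc[0, "sample_id"]
        with pytest.raises(ValueError, match="duplicate"):
            pp.SampleTable(df)

    def test_rate_out_of_range_rejected(self, reference_table):
        df = reference_table.df.copy()
        df.loc[0, "yp_rate"] = 105.0
        with pytest.raises(ValueError, match="yp_rate"):
            pp.SampleTable(df)

    def test_missing_values_rejected(self, reference_table):
        df = reference_table.df.copy()
        df.loc[0, "pi_rate"] = np.nan
        with pytest.raises(ValueError, match="pi_rate"):
            pp.SampleTable(df)

    def test_csv_round_trip(self, reference_table, tmp_path):
        path = tmp_path / "t.csv"
        reference_table.to_csv(path)
        back = pp.SampleTable.from_csv(path)
        pd.testing.assert_frame_equal(back.df, reference_table.df)

    def test_empty_csv_raises_no_samples(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(ValueError, match="no samples"):
            pp.SampleTable.from_csv(path)


class TestAutoscale:
    def test_training_column_statistics(self, reference_table):
        # frozen from the arithmetic mean/sd of the 8 training rows
        train = reference_table.subset("train")
        _, _, scaler = autoscale(train)
        assert scaler.x_means == pytest.approx([56.625, 28.625])
        assert scaler.x_sds == pytest.approx([37.1250, 28.1980], abs=1e-3)
        assert scaler.y_mean == pytest.approx(4.1025)

    def test_scaled_columns_standardized(self, reference_table):
        Xs, ys, _ = autoscale(reference_table.subset("train"))
        assert np.allclose(Xs.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(Xs.std(axis=0, ddof=1), 1, atol=1e-12)
        assert abs(ys.mean()) < 1e-12 and abs(ys.std(ddof=1) - 1) < 1e-12

    def test_idempotent_on_standardized_column(self):
        # a column already at mean 0 / sd 1 comes back unchanged
        rng = np.random.default_rng(0)
        col = rng.normal(size=10)
        col = (col - col.mean()) / col.std(ddof=1)
        df = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(10)],
                "pulse_width_ns": 1.0, "field_strength_kv_cm": 1.0,
                "yp_rate": np.clip(col * 10 + 50, 0, 100),
                "pi_rate": np.clip(col * 5 + 50, 0, 100),
                "fusion_rate": np.abs(col), "role": "unassigned",
            }
        )
        df["yp_rate"] = (df["yp_rate"] - df["yp_rate"].mean()) / df["yp_rate"].std(ddof=1) + 50
        # direct check on the raw standardized vector instead
        table = pp.SampleTable(df)
        Xs, _, scaler = autoscale(table)
        reconstructed = scaler.inverse_x(Xs)
        assert np.allclose(reconstructed, table.predictors(), atol=1e-12)

    def test_round_trip_exact(self, reference_table):
        Xs, ys, scaler = autoscale(reference_table)
        assert np.allclose(scaler.inverse_x(Xs), reference_table.predictors(),
                           atol=1e-12)
        assert np.allclose(scaler.inverse_y(ys), reference_table.response(),
                           atol=1e-12)

    def test_zero_variance_column_named(self, reference_table):
        df = reference_table.df.copy()
        df["pi_rate"] = 50.0
        with pytest.raises(ValueError, match="pi_rate"):
            autoscale(pp.SampleTable(df))

    def test_fewer_than_two_rows_rejected(self, reference_table):
        single = pp.SampleTable(reference_table.df.iloc[[0]])
        with pytest.raises(ValueError, match="2 rows"):
            autoscale(single)


class TestFitPLS:
    def test_first_weight_is_normalized_cross_covariance(self, reference_table):
        Xs, ys, _ = autoscale(reference_table.subset("train"))
        model = pp.fit_pls(Xs, ys, 1)
        w_closed = Xs.T @ ys
        w_closed /= np.linalg.norm(w_closed)
        assert np.allclose(np.abs(model.W[:, 0]), np.abs(w_closed), atol=1e-9)

    def test_published_weight_vector(self, reference_model):
        # YP weight 0.52, PI weight 0.86 after rounding
        w = np.abs(reference_model.W[:, 0])
        assert np.round(w, 2).tolist() == [0.52, 0.86]

    def test_single_signal_degenerate_weight(self):
        # y proportional to the first column, second column exactly
        # uncorrelated with it: the weight vector is (1, 0) up to sign
        rng = np.random.default_rng(1)
        x1 = rng.normal(size=20)
        x2 = rng.normal(size=20)
        x1 -= x1.mean()
        x2 -= x2.mean()
        x2 -= (x2 @ x1) / (x1 @ x1) * x1  # orthogonalize
        X = np.column_stack([x1 / x1.std(ddof=1), x2 / x2.std(ddof=1)])
        y = 3.0 * X[:, 0]
        model = pp.fit_pls(X, y / y.std(ddof=1), 1)
        assert np.allclose(np.abs(model.W[:, 0]), [1.0, 0.0], atol=1e-9)

    def test_weight_columns_unit_norm(self, reference_table):
        Xs, ys, _ = autoscale(reference_table.subset("train"))
        model = pp.fit_pls(Xs, ys, 2)
        assert np.allclose(np.linalg.norm(model.W, axis=0), 1.0, atol=1e-9)

    def test_score_columns_orthogonal(self, reference_table):
        Xs, ys, _ = autoscale(reference_table.subset("train"))
        model = pp.fit_pls(Xs, ys, 2)
        off = model.T.T @ model.T - np.diag(np.diag(model.T.T @ model.T))
        assert np.abs(off).max() < 1e-8

    def test_full_rank_equals_ols(self, reference_table):
        # closed-form OLS oracle on the training rows
        train = reference_table.subset("train")
        Xs, ys, scaler = autoscale(train)
        model = pp.fit_pls(Xs, ys, 2, scaler=scaler)
        X1 = np.column_stack([np.ones(len(ys)), Xs])
        beta = np.linalg.lstsq(X1, ys, rcond=None)[0]
        ols_pred = scaler.inverse_y(X1 @ beta)
        assert np.allclose(pp.predict(model, train), ols_pred, atol=1e-8)

    def test_one_component_closed_form(self, reference_table):
        # PLS1: prediction = y_mean + y_sd * c * (x_scaled . w)
        train = reference_table.subset("train")
        Xs, ys, scaler = autoscale(train)
        model = pp.fit_pls(Xs, ys, 1, scaler=scaler)
        w = Xs.T @ ys
        w /= np.linalg.norm(w)
        t = Xs @ w
        c = float(t @ ys / (t @ t))
        closed = scaler.inverse_y(c * (Xs @ w))
        assert np.allclose(pp.predict(model, train), closed, atol=1e-10)

    def test_matches_sklearn_oracle(self, reference_table):
        # independent cross-check of the NIPALS path
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
        train = reference_table.subset("train")
        X, y = train.predictors(), train.response()
        ref = sklearn_pls.PLSRegression(n_components=1, scale=True)
        ref.fit(X, y)
        model = pp.fit_table(reference_table, 1)
        assert np.allclose(
            pp.predict(model, reference_table),
            ref.predict(reference_table.predictors()).ravel(),
            atol=1e-8,
        )

    def test_too_many_components_rejected(self, reference_table):
        Xs, ys, _ = autoscale(reference_table.subset("train"))
        with pytest.raises(ValueError, match="n_components"):
            pp.fit_pls(Xs, ys, 3)

    def test_nan_rejected(self):
        X = np.array([[1.0, 2.0], [np.nan, 0.0], [0.5, 1.0]])
        with pytest.raises(ValueError, match="NaN"):
            pp.fit_pls(X, np.zeros(3), 1)


class TestPredict:
    @pytest.mark.parametrize(
        "yp, pi, expected",
        [(90.0, 82.0, 13.49), (86.0, 62.0, 10.50), (14.0, 10.0, -1.11)],
    )
    def test_published_predictions(self, reference_model, yp, pi, expected):
        pred = pp.predict(reference_model, np.array([[yp, pi]]))
        assert pred[0] == pytest.approx(expected, abs=0.01)

    def test_input_at_training_means_maps_to_mean_response(self, reference_model):
        pred = pp.predict(reference_model, np.array([[56.625, 28.625]]))
        assert pred[0] == pytest.approx(4.1025, abs=1e-9)

    def test_column_mismatch_rejected(self, reference_model):
        with pytest.raises(ValueError, match="predictor columns"):
            pp.predict(reference_model, np.ones((2, 3)))
        with pytest.raises(ValueError, match="missing"):
            pp.predict(reference_model, pd.DataFrame({"yp_rate": [1.0]}))

    @settings(max_examples=25, deadline=None)
    @given(scale=st.floats(min_value=0.01, max_value=100.0))
    def test_scale_equivariance(self, scale):
        # multiplying a raw predictor column by a positive constant leaves
        # predictions unchanged because of autoscaling
        table = pp.load_reference_table()
        model = pp.fit_table(table, 1)
        base = pp.predict(model, table)
        df = table.df.copy()
        df["pi_rate"] = df["pi_rate"] * scale
        # rescale back within [0,100] bounds not needed: build from raw arrays
        X = table.predictors().copy()
        X[:, 1] *= scale
        y = table.response()
        train_mask = (table.df["role"] == "train").to_numpy()
        Xs = (X[train_mask] - X[train_mask].mean(0)) / X[train_mask].std(0, ddof=1)
        ys = (y[train_mask] - y[train_mask].mean()) / y[train_mask].std(ddof=1)
        m2 = pp.fit_pls(Xs, ys, 1)
        pred2 = (
            y[train_mask].mean()
            + y[train_mask].std(ddof=1)
            * ((X - X[train_mask].mean(0)) / X[train_mask].std(0, ddof=1))
            @ m2.coef_scaled
        )
        assert np.allclose(pred2, base, atol=1e-9)


class TestFitStats:
    def test_published_training_r2(self, reference_model, reference_table):
        stats = pp.fit_stats(reference_model, reference_table, compute_q2=False)
        assert stats.r2_train == pytest.approx(0.672, abs=0.001)

    def test_both_heldout_definitions_reported(self, reference_model, reference_table):
        # the squared-correlation definition gives ~0.749 on the test rows;
        # the SS definition gives a different number — both are surfaced
        stats = pp.fit_stats(reference_model, reference_table, compute_q2=False)
        assert stats.r2_test_corr == pytest.approx(0.7495, abs=0.001)
        assert stats.r2_test_ss == pytest.approx(0.670, abs=0.001)
        assert stats.r2_test_corr != stats.r2_test_ss

    def test_perfect_prediction_gives_unity(self, linear_table):
        model = pp.fit_table(linear_table, 2)
        stats = pp.fit_stats(model, linear_table)
        assert stats.r2_train == pytest.approx(1.0, abs=1e-9)
        assert stats.r2_test_ss == pytest.approx(1.0, abs=1e-9)
        assert stats.r2_test_corr == pytest.approx(1.0, abs=1e-9)
        assert stats.q2_loo == pytest.approx(1.0, abs=1e-9)

    def test_zero_response_variance_rejected(self):
        with pytest.raises(ValueError, match="zero response variance"):
            r2_score_ss(np.ones(5), np.zeros(5))
        with pytest.raises(ValueError, match="zero response variance"):
            r2_score_corr(np.ones(5), np.arange(5.0))


class TestModelSerialization:
    def test_json_round_trip_preserves_predictions(self, reference_model,
                                                   reference_table, tmp_path):
        path = tmp_path / "model.json"
        reference_model.to_json(path)
        restored = pp.PLSModel.from_json(path)
        assert np.allclose(
            pp.predict(restored, reference_table),
            pp.predict(reference_model, reference_table),
            atol=1e-12,
        )
        doc = json.loads(path.read_text())
        assert doc["n_components"] == 1
        assert doc["predictor_names"] == ["yp_rate", "pi_rate"]
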