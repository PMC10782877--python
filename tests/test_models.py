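"""Regressors, inversion baseline, and validation protocols."""

import numpy as np
import pytest

from wirdrs.errors import make_condition_dataset
from wirdrs.features import FEATURE_NAMES, extract_feature_table
from wirdrs.forward import forward_closure, generate_grid_dataset
from wirdrs.models import (
    DenseNNRegressor,
    SpectralMatchingInverter,
    WIRRegressor,
    feature_importances,
    kfold_cv,
    leave_one_group_out,
    mci_invert,
    raw_spectra_matrix,
    robustness_experiment,
    rmse_percent,
)


@pytest.fixture(scope="module")
def features_and_labels(mini_dataset):
    table = extract_feature_table(mini_dataset)
    return table[list(FEATURE_NAMES)], mini_dataset.labels


@pytest.fixture(scope="module")
def forward(probe, chromo, standard):
    return forward_closure(probe, chromo, standard)


@pytest.fixture(scope="module")
def inverter(forward):
    return SpectralMatchingInverter(forward=forward, coarse=(60, 60)).fit()


class TestRMSEPercent:
    def test_perfect_prediction(self):
        assert rmse_percent(np.array([1.0, 2.0]), np.array([1.0, 2.0])) == 0.0

    def test_single_pair(self):
        assert rmse_percent(np.array([1.1]), np.array([1.0])) == pytest.approx(10.0)

    def test_symmetric_pair(self):
        pred, truth = np.array([1.1, 0.9]), np.array([1.0, 1.0])
        assert rmse_percent(pred, truth) == pytest.approx(10.0)

    def test_zero_truth_rejected(self):
        with pytest.raises(ValueError):
            rmse_percent(np.array([1.0]), np.array([0.0]))

    def test_mean_normalized_mode(self):
        pred, truth = np.array([1.2, 0.8]), np.array([2.0, 2.0])
        assert rmse_percent(pred, truth, mode="mean_normalized") == pytest.approx(
            np.sqrt(((pred - truth) ** 2).mean()) / 2.0 * 100
        )


class TestWIRRegressor:
    def test_deterministic_given_seed(self, features_and_labels):
        X, y = features_and_labels
        p1 = WIRRegressor().fit(X, y).predict(X)
        p2 = WIRRegressor().fit(X, y).predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_predictions_within_training_label_range(self, features_and_labels):
        X, y = features_and_labels
        model = WIRRegressor().fit(X, y)
        pred = model.predict(X)
        assert pred[:, 0].min() >= y[:, 0].min() and pred[:, 0].max() <= y[:, 0].max()
        assert pred[:, 1].min() >= y[:, 1].min() and pred[:, 1].max() <= y[:, 1].max()

    def test_layout_mismatch_rejected(self, features_and_labels):
        X, y = features_and_labels
        model = WIRRegressor().fit(X, y)
        with pytest.raises(ValueError):
            model.predict(X.iloc[:, :-3])
        with pytest.raises(ValueError):
            model.fit(X.rename(columns={"skew_G": "bogus"}), y)

    def test_importances_normalised(self, features_and_labels):
        X, y = features_and_labels
        model = WIRRegressor().fit(X, y)
        ranked = feature_importances(model)
        for target in ("mu_a", "mu_s_prime"):
            imp = ranked[target]
            assert imp.sum() == pytest.approx(1.0, abs=1e-9)
            assert (imp >= 0).all()
            assert imp.is_monotonic_decreasing


class TestDenseNN:
    def test_architecture_and_raw_input_width(self, mini_dataset):
        X = raw_spectra_matrix(mini_dataset)
        assert X.shape[1] == 4 * mini_dataset.grid.n_columns
        model = DenseNNRegressor(input_mode="raw_spectra", max_iter=30)
        model.fit(X, mini_dataset.labels)
        assert model.hidden_layer_sizes_ == (25, 25)
        mlp = model.estimators_["mu_a"][-1]
        assert mlp.hidden_layer_sizes == (25, 25)

    def test_reproducible_with_fixed_seed(self, features_and_labels):
        X, y = features_and_labels
        p1 = DenseNNRegressor(max_iter=30).fit(X, y).predict(X)
        p2 = DenseNNRegressor(max_iter=30).fit(X, y).predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_width_mismatch_rejected(self, mini_dataset, features_and_labels):
        X, y = features_and_labels
        model = DenseNNRegressor(input_mode="raw_spectra", max_iter=10)
        model.fit(raw_spectra_matrix(mini_dataset), mini_dataset.labels)
        with pytest.raises(ValueError):
            model.predict(raw_spectra_matrix(mini_dataset)[:, :80])


class TestInversion:
    def test_objective_zero_at_true_labels(self, mini_dataset, forward, inverter):
        i = 13
        obj = inverter.objective(
            mini_dataset.gray[i], mini_dataset.mu_a[i], mini_dataset.mu_s_prime[i]
        )
        assert obj == pytest.approx(0.0, abs=1e-20)

    def test_noiseless_recovery_on_mini_grid(self, mini_dataset, inverter):
        pred = inverter.predict(mini_dataset.gray)
        assert rmse_percent(pred[:, 0], mini_dataset.mu_a) <= 0.01
        assert rmse_percent(pred[:, 1], mini_dataset.mu_s_prime) <= 0.01

    def test_matches_brute_force_grid_argmin(self, mini_dataset, forward, inverter):
        # independent oracle: dense-grid argmin of the matching objective,
        # evaluated in chunks to keep memory bounded
        a_grid = np.linspace(0.3, 3.0, 300)
        s_grid = np.linspace(5.5, 10.5, 300)
        aa, ss = (v.ravel() for v in np.meshgrid(a_grid, s_grid, indexing="ij"))
        specs = mini_dataset.gray[::6]
        best_sse = np.full(len(specs), np.inf)
        best_idx = np.zeros(len(specs), dtype=int)
        for lo in range(0, aa.size, 4000):
            hi = lo + 4000
            library = forward(aa[lo:hi], ss[lo:hi])
            sse = ((library[None, :, :] - specs[:, None, :]) ** 2).sum(axis=2)
            chunk_best = sse.argmin(axis=1)
            chunk_sse = sse[np.arange(len(specs)), chunk_best]
            better = chunk_sse < best_sse
            best_sse[better] = chunk_sse[better]
            best_idx[better] = chunk_best[better] + lo
        refined = inverter.predict(specs)
        step_a = a_grid[1] - a_grid[0]
        step_s = s_grid[1] - s_grid[0]
        assert np.all(np.abs(refined[:, 0] - aa[best_idx]) <= step_a)
        assert np.all(np.abs(refined[:, 1] - ss[best_idx]) <= step_s)

    def test_single_spectrum_wrapper(self, mini_dataset, forward, inverter):
        spectra, props, *_ = mini_dataset.record(6)
        est = mci_invert(spectra.gray, forward, inverter=inverter)
        assert est.mu_a == pytest.approx(props.mu_a, rel=1e-4)
        assert est.mu_s_prime == pytest.approx(props.mu_s_prime, rel=1e-4)

    def test_mci_less_accurate_than_wir_on_compounded_errors(
        self, mini_dataset, inverter
    ):
        # the qualitative robustness ordering on the all-errors dataset
        ds = make_condition_dataset(mini_dataset, "all", seed=5)
        mci_pred = inverter.predict(ds.gray)
        mci = {
            "mu_a": rmse_percent(mci_pred[:, 0], ds.mu_a),
            "mu_s_prime": rmse_percent(mci_pred[:, 1], ds.mu_s_prime),
        }
        bigger = generate_grid_dataset(8, 8, grid=ds.grid)
        big_all = make_condition_dataset(bigger, "all", seed=5)
        report = kfold_cv(big_all, k=5, seed=0)
        assert mci["mu_a"] > report.value(target="mu_a")
        assert mci["mu_s_prime"] > report.value(target="mu_s_prime")


class TestValidationProtocols:
    def test_folds_disjoint_and_cover(self, mini_dataset):
        report = kfold_cv(mini_dataset, k=5, seed=0)
        folds = report.fold_assignment_
        assert folds.shape == (25,)
        assert set(folds) == set(range(5))
        report2 = kfold_cv(mini_dataset, k=5, seed=0)
        np.testing.assert_array_equal(folds, report2.fold_assignment_)

    def test_leave_one_out_degenerate_case(self, grid):
        ds = generate_grid_dataset(3, 2, grid=grid)
        report = kfold_cv(ds, k=len(ds), seed=0)
        assert set(report.fold_assignment_) == set(range(len(ds)))

    def test_k_bounds(self, mini_dataset):
        with pytest.raises(ValueError):
            kfold_cv(mini_dataset, k=1)

    def test_leave_one_group_out_structure(self, mini_dataset):
        report = leave_one_group_out(mini_dataset, seed=0)
        per_group = report.rmse[report.rmse["group"] != "mean"]
        assert sorted(set(per_group["group"])) == sorted(set(mini_dataset.group_id))
        for target in ("mu_a", "mu_s_prime"):
            sub = per_group[per_group["target"] == target]["rmse_percent"]
            assert report.value(target=target, group="mean") == pytest.approx(
                sub.mean()
            )

    def test_logo_augmentation_never_tested(self, mini_dataset):
        from wirdrs.errors import apply_error_row

        aug = apply_error_row(mini_dataset, 2, seed=1)
        report = leave_one_group_out(mini_dataset, augmentation=aug, seed=0)
        tested = report.rmse[report.rmse["group"] != "mean"]["group"]
        assert set(tested) <= set(mini_dataset.group_id)

    def test_single_group_rejected(self, mini_dataset):
        solo = mini_dataset.copy()
        solo.group_id = np.array(["only"] * len(solo), dtype=object)
        with pytest.raises(ValueError):
            leave_one_group_out(solo)


class TestRobustnessExperiment:
    def test_report_shape_and_bounds(self, grid):
        report = robustness_experiment(
            seed=0,
            n_mu_a=5,
            n_mu_s=4,
            models=("mci", "wir"),
            k=2,
        )
        df = report.rmse
        assert set(df["condition"]) == {
            "perfect", "noise", "shifted", "scaled", "compressed", "rotated", "all",
        }
        assert set(df["model"]) == {"mci", "wir"}
        assert set(df["target"]) == {"mu_a", "mu_s_prime"}
        assert len(df) == 7 * 2 * 2
        assert (df["rmse_percent"] >= 0).all()
        assert report.value(condition="perfect", model="mci", target="mu_a") <= 0.01
        assert "mci" in report.timings_s and "wir" in report.timings_s
        assert report.importances  # fitted on the all-errors condition


class TestPersistence:
    def test_save_load_round_trip_and_layout_guard(self, tmp_path, features_and_labels):
        import json

        from wirdrs.pipeline import load_model, save_model

        X, y = features_and_labels
        model = WIRRegressor().fit(X, y)
        path = tmp_path / "model"
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_array_equal(back.predict(X), model.predict(X))

        manifest = json.loads((path / "manifest.json").read_text())
        manifest["feature_names"][0] = "tampered"
        (path / "manifest.json").write_text(json.dumps(manifest))
        with pytest.raises(ValueError):
            load_model(path)
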