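"""Optical-property regressors, the spectral-matching inversion baseline,
and the validation protocols.

Three routes from a diffuse reflectance spectrum to (mu_a, mu_s'):

* :class:`WIRRegressor` — the wavelength-independent regressor: one
  gradient-boosted tree ensemble per target trained on the 35 whole-spectrum
  features (200 estimators, depth 5, min 3 samples per leaf, random state 0).
* :class:`DenseNNRegressor` — dense neural-network baseline (two hidden
  layers of 25 units) fed either the same features or the raw concatenated
  gray+R+G+B spectra.
* :class:`SpectralMatchingInverter` — the classical inversion: find the
  (mu_a, mu_s') whose forward-model spectrum best matches the measurement
  wavelength by wavelength (coarse grid search + local least-squares
  refinement).

Prediction error is reported as RMSE% — the root-mean-square of relative
errors, in percent — which is comparable across the two targets' scales.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .errors import CONDITIONS, ErrorConfig, make_condition_dataset
from .features import FEATURE_NAMES, extract_feature_table
from .forward import (
    ChromophoreModel,
    LabeledDataset,
    OpticalProperties,
    default_chromophore,
    default_standard,
    forward_closure,
    generate_grid_dataset,
)
from .spectra import ProbeGeometry, ReflectanceStandard, Spectrum

__all__ = [
    "TARGETS",
    "rmse_percent",
    "WIRRegressor",
    "DenseNNRegressor",
    "SpectralMatchingInverter",
    "mci_invert",
    "raw_spectra_matrix",
    "EvaluationReport",
    "kfold_cv",
    "leave_one_group_out",
    "feature_importances",
    "robustness_experiment",
]

TARGETS = ("mu_a", "mu_s_prime")


def rmse_percent(pred: np.ndarray, truth: np.ndarray, mode: str = "relative") -> float:
    """Root-mean-square prediction error in percent.

    ``relative`` (default): sqrt(mean(((pred-truth)/truth)^2)) * 100.
    ``mean_normalized``: sqrt(mean((pred-truth)^2)) / mean(truth) * 100.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.size < 1:
        raise ValueError("pred and truth must have equal nonzero length")
    if mode == "relative":
        if np.any(truth == 0):
            raise ValueError("relative RMSE undefined for zero truth values")
        return float(np.sqrt(np.mean(((pred - truth) / truth) ** 2)) * 100.0)
    if mode == "mean_normalized":
        return float(np.sqrt(np.mean((pred - truth) ** 2)) / truth.mean() * 100.0)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# feature-matrix plumbing
# ---------------------------------------------------------------------------


def _design_matrix(X) -> np.ndarray:
    """Validate the frozen 35-feature layout and one-hot encode the probe."""
    if isinstance(X, pd.DataFrame):
        missing = [c for c in FEATURE_NAMES if c not in X.columns]
        if missing:
            raise ValueError(f"feature table is missing columns {missing}")
        X = X[list(FEATURE_NAMES)].to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(FEATURE_NAMES):
        raise ValueError(
            f"expected {len(FEATURE_NAMES)} features in the frozen order, "
            f"got shape {X.shape}"
        )
    probe = X[:, -1]
    onehot = np.column_stack([(probe == 1).astype(float), (probe == 2).astype(float)])
    return np.column_stack([X[:, :-1], onehot])


def _target_frame(y) -> pd.DataFrame:
    if isinstance(y, pd.DataFrame):
        return y[list(TARGETS)]
    y = np.asarray(y, dtype=float)
    if y.ndim != 2 or y.shape[1] != 2:
        raise ValueError("y must be (n, 2): columns mu_a, mu_s_prime")
    return pd.DataFrame(y, columns=list(TARGETS))


def raw_spectra_matrix(dataset: LabeledDataset) -> np.ndarray:
    """Raw-input design matrix: gray, R, G, B spectra concatenated (n, 4N)."""
    return np.hstack([dataset.gray, dataset.red, dataset.green, dataset.blue])


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


class WIRRegressor(BaseEstimator, RegressorMixin):
    """Wavelength-independent regressor: per-target gradient-boosted trees.

    Fits one :class:`~sklearn.ensemble.GradientBoostingRegressor` per optical
    property on the 35-feature layout.  Tree ensembles do not extrapolate;
    predictions are additionally clipped to the per-target training label
    range, which is stored on the fitted model.
    """

    def __init__(
        self,
        n_estimators: int = 200,
        max_depth: int = 5,
        min_samples_leaf: int = 3,
        random_state: int = 0,
    ) -> None:
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state

    def fit(self, X, y) -> "WIRRegressor":
        Xd = _design_matrix(X)
        yd = _target_frame(y)
        if Xd.shape[0] < 2:
            raise ValueError("need at least two training samples")
        self.feature_names_ = list(FEATURE_NAMES)
        self.estimators_ = {}
        self.label_range_ = {}
        for target in TARGETS:
            est = GradientBoostingRegressor(
                n_estimators=self.n_estimators,
                max_depth=self.max_depth,
                min_samples_leaf=self.min_samples_leaf,
                random_state=self.random_state,
            )
            est.fit(Xd, yd[target].to_numpy())
            self.estimators_[target] = est
            col = yd[target]
            self.label_range_[target] = (float(col.min()), float(col.max()))
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "estimators_")
        Xd = _design_matrix(X)
        cols = []
        for target in TARGETS:
            lo, hi = self.label_range_[target]
            cols.append(np.clip(self.estimators_[target].predict(Xd), lo, hi))
        return np.column_stack(cols)

    @property
    def feature_importances_(self) -> dict[str, pd.Series]:
        check_is_fitted(self, "estimators_")
        out = {}
        for target, est in self.estimators_.items():
            imp = est.feature_importances_
            # fold the probe one-hot back into a single categorical feature
            merged = np.concatenate([imp[:-2], [imp[-2:].sum()]])
            total = merged.sum()
            if total > 0:
                merged = merged / total
            out[target] = pd.Series(merged, index=list(FEATURE_NAMES))
        return out


class DenseNNRegressor(BaseEstimator, RegressorMixin):
    """Dense neural-network baseline: two hidden layers of 25 units per target.

    ``input_mode='features'`` consumes the 35-feature layout;
    ``input_mode='raw_spectra'`` consumes the concatenated 4N raw spectra.
    Trained with MSE loss, adam, early stopping on a 10% validation split.
    Baseline plumbing only — no accuracy contract.
    """

    def __init__(
        self,
        input_mode: str = "features",
        hidden_units: int = 25,
        max_iter: int = 500,
        random_state: int = 0,
    ) -> None:
        self.input_mode = input_mode
        self.hidden_units = hidden_units
        self.max_iter = max_iter
        self.random_state = random_state

    def _prepare(self, X) -> np.ndarray:
        if self.input_mode == "features":
            return _design_matrix(X)
        if self.input_mode == "raw_spectra":
            X = np.asarray(X, dtype=float)
            if X.ndim != 2 or X.shape[1] % 4 != 0:
                raise ValueError("raw-mode input must be (n, 4N) concatenated spectra")
            return X
        raise ValueError(f"unknown input_mode {self.input_mode!r}")

    def fit(self, X, y) -> "DenseNNRegressor":
        Xd = self._prepare(X)
        yd = _target_frame(y)
        self.n_features_in_ = Xd.shape[1]
        self.estimators_ = {}
        for k, target in enumerate(TARGETS):
            net = make_pipeline(
                StandardScaler(),
                MLPRegressor(
                    hidden_layer_sizes=(self.hidden_units, self.hidden_units),
                    max_iter=self.max_iter,
                    early_stopping=True,
                    validation_fraction=0.1,
                    random_state=self.random_state + k,
                ),
            )
            with warnings.catch_warnings():
                from sklearn.exceptions import ConvergenceWarning

                warnings.simplefilter("ignore", ConvergenceWarning)
                net.fit(Xd, yd[target].to_numpy())
            self.estimators_[target] = net
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "estimators_")
        Xd = self._prepare(X)
        if Xd.shape[1] != self.n_features_in_:
            raise ValueError("input width does not match the fitted network")
        return np.column_stack([self.estimators_[t].predict(Xd) for t in TARGETS])

    @property
    def hidden_layer_sizes_(self) -> tuple[int, int]:
        check_is_fitted(self, "estimators_")
        return (self.hidden_units, self.hidden_units)


class SpectralMatchingInverter(BaseEstimator):
    """Classical inversion: match measured spectra to forward-model spectra.

    ``fit`` precomputes a coarse library of forward spectra over the search
    box (slightly wider than the generation ranges); ``predict`` finds each
    spectrum's best coarse match by summed squared wavelength-by-wavelength
    differences, then refines it with bounded least squares to relative
    tolerance ``tol``.  Records that fail to converge keep their best-found
    values and are flagged in ``converged_``.
    """

    def __init__(
        self,
        forward=None,
        mu_a_bounds: tuple[float, float] = (0.3, 3.0),
        mu_s_bounds: tuple[float, float] = (5.5, 10.5),
        coarse: tuple[int, int] = (200, 200),
        tol: float = 1e-6,
    ) -> None:
        self.forward = forward
        self.mu_a_bounds = mu_a_bounds
        self.mu_s_bounds = mu_s_bounds
        self.coarse = coarse
        self.tol = tol

    def fit(self, X=None, y=None) -> "SpectralMatchingInverter":
        if self.forward is None:
            raise ValueError("a forward closure is required")
        na, ns = self.coarse
        a = np.linspace(*self.mu_a_bounds, na)
        s = np.linspace(*self.mu_s_bounds, ns)
        aa, ss = (arr.ravel() for arr in np.meshgrid(a, s, indexing="ij"))
        # build in chunks to bound peak memory; keep the library in float32
        chunks = []
        step = 5000
        for i in range(0, aa.size, step):
            chunks.append(
                np.asarray(self.forward(aa[i : i + step], ss[i : i + step]), np.float32)
            )
        self.library_ = np.vstack(chunks)
        self.library_labels_ = np.column_stack([aa, ss])
        self.library_norms_ = np.einsum("ij,ij->i", self.library_, self.library_)
        return self

    def objective(self, spec: np.ndarray, mu_a: float, mu_s_prime: float) -> float:
        """Summed squared intensity difference at one candidate label pair."""
        model = self.forward(mu_a, mu_s_prime)
        return float(np.sum((model - np.asarray(spec, float)) ** 2))

    def predict(self, gray: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "library_")
        gray = np.atleast_2d(np.asarray(gray, dtype=float))
        # coarse pass: argmin ||L - s||^2 = ||L||^2 - 2 L.s  (+ const)
        scores = self.library_norms_[None, :] - 2.0 * (
            gray.astype(np.float32) @ self.library_.T
        )
        seeds = self.library_labels_[scores.argmin(axis=1)]

        lo = np.array([self.mu_a_bounds[0], self.mu_s_bounds[0]])
        hi = np.array([self.mu_a_bounds[1], self.mu_s_bounds[1]])
        preds = np.empty_like(seeds)
        converged = np.empty(len(seeds), dtype=bool)
        for i, (spec, x0) in enumerate(zip(gray, seeds)):
            res = least_squares(
                lambda p: self.forward(p[0], p[1]) - spec,
                x0=np.clip(x0, lo, hi),
                bounds=(lo, hi),
                xtol=self.tol * 1e-2,
                ftol=self.tol * 1e-2,
                gtol=None,
            )
            preds[i] = res.x
            converged[i] = res.status > 0
        self.converged_ = converged
        if not converged.all():
            warnings.warn(
                f"{(~converged).sum()} inversion(s) did not converge; "
                "best-found values returned",
                RuntimeWarning,
            )
        return preds


def mci_invert(
    spec: Spectrum | np.ndarray,
    forward,
    inverter: SpectralMatchingInverter | None = None,
    **kwargs,
) -> OpticalProperties:
    """Invert one gray spectrum against a forward closure (convenience wrapper)."""
    if inverter is None:
        inverter = SpectralMatchingInverter(forward=forward, **kwargs).fit()
    y = spec.intensity if isinstance(spec, Spectrum) else np.asarray(spec, float)
    mu_a, mu_s = inverter.predict(y[None, :])[0]
    return OpticalProperties(float(mu_a), float(mu_s))


# ---------------------------------------------------------------------------
# validation protocols
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Tidy evaluation results: one row per (condition, model, target, group)."""

    rmse: pd.DataFrame
    timings_s: dict[str, float] = field(default_factory=dict)
    importances: dict[str, pd.Series] = field(default_factory=dict)

    def value(self, **filters) -> float:
        sub = self.rmse
        for k, v in filters.items():
            sub = sub[sub[k] == v]
        if len(sub) != 1:
            raise KeyError(f"filters {filters} match {len(sub)} rows")
        return float(sub["rmse_percent"].iloc[0])

    def to_csv(self, path) -> None:
        self.rmse.to_csv(path, index=False)


def _make_model(model_spec, seed: int):
    if isinstance(model_spec, str):
        if model_spec == "wir":
            return WIRRegressor(random_state=seed)
        if model_spec == "nn_features":
            return DenseNNRegressor(input_mode="features", random_state=seed)
        if model_spec == "nn_raw":
            return DenseNNRegressor(input_mode="raw_spectra", random_state=seed)
        raise ValueError(f"unknown model spec {model_spec!r}")
    return model_spec


def _inputs_for(model, dataset: LabeledDataset):
    if isinstance(model, DenseNNRegressor) and model.input_mode == "raw_spectra":
        return raw_spectra_matrix(dataset)
    return extract_feature_table(dataset)[list(FEATURE_NAMES)]


def kfold_cv(
    dataset: LabeledDataset,
    k: int = 5,
    model_spec="wir",
    seed: int = 0,
) -> EvaluationReport:
    """K-fold cross-validation with random folds; pooled RMSE% per target."""
    n = len(dataset)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError("dataset smaller than k")
    X = _inputs_for(_make_model(model_spec, seed), dataset)
    y = dataset.labels
    Xv = X.to_numpy() if isinstance(X, pd.DataFrame) else X

    pred = np.empty_like(y)
    fold_of = np.empty(n, dtype=int)
    for f, (tr, te) in enumerate(
        KFold(n_splits=k, shuffle=True, random_state=seed).split(Xv)
    ):
        model = _make_model(model_spec, seed)
        model.fit(Xv[tr], y[tr])
        pred[te] = model.predict(Xv[te])
        fold_of[te] = f

    condition = str(dataset.error_tag[0]) if n else ""
    rows = [
        {
            "condition": condition,
            "model": model_spec if isinstance(model_spec, str) else type(model_spec).__name__,
            "target": t,
            "group": "pooled",
            "rmse_percent": rmse_percent(pred[:, j], y[:, j]),
        }
        for j, t in enumerate(TARGETS)
    ]
    report = EvaluationReport(rmse=pd.DataFrame(rows))
    report.fold_assignment_ = fold_of
    report.predictions_ = pred
    return report


def leave_one_group_out(
    dataset: LabeledDataset,
    augmentation: LabeledDataset | None = None,
    model_spec="wir",
    seed: int = 0,
) -> EvaluationReport:
    """Leave-one-group-out validation (synthetic titration / experiment groups).

    Each group in turn is the test set; the training set is every other group
    plus, optionally, an augmentation dataset whose records never enter any
    test fold.  The mean row is the arithmetic mean of per-group RMSE%.
    """
    groups = np.asarray(dataset.group_id)
    unique = pd.unique(groups)
    if len(unique) < 2:
        raise ValueError("need at least two groups")
    X = _inputs_for(_make_model(model_spec, seed), dataset)
    Xv = X.to_numpy() if isinstance(X, pd.DataFrame) else X
    y = dataset.labels
    if augmentation is not None:
        Xa = _inputs_for(_make_model(model_spec, seed), augmentation)
        Xa = Xa.to_numpy() if isinstance(Xa, pd.DataFrame) else Xa
        ya = augmentation.labels

    rows = []
    for g in unique:
        te = groups == g
        Xtr, ytr = Xv[~te], y[~te]
        if augmentation is not None:
            Xtr = np.vstack([Xtr, Xa])
            ytr = np.vstack([ytr, ya])
        model = _make_model(model_spec, seed)
        model.fit(Xtr, ytr)
        pred = model.predict(Xv[te])
        for j, t in enumerate(TARGETS):
            rows.append(
                {
                    "condition": str(dataset.error_tag[0]),
                    "model": model_spec if isinstance(model_spec, str) else type(model_spec).__name__,
                    "target": t,
                    "group": str(g),
                    "rmse_percent": rmse_percent(pred[:, j], y[te, j]),
                }
            )
    df = pd.DataFrame(rows)
    means = (
        df.groupby(["condition", "model", "target"], as_index=False)["rmse_percent"]
        .mean()
        .assign(group="mean")
    )
    return EvaluationReport(rmse=pd.concat([df, means], ignore_index=True))


def feature_importances(model: WIRRegressor) -> dict[str, pd.Series]:
    """Impurity-based importances per target, normalised and sorted descending."""
    return {
        target: imp.sort_values(ascending=False)
        for target, imp in model.feature_importances_.items()
    }


def robustness_experiment(
    seed: int = 0,
    n_mu_a: int = 40,
    n_mu_s: int = 38,
    models: tuple[str, ...] = ("mci", "wir", "nn_features", "nn_raw"),
    conditions: tuple[str, ...] = tuple(CONDITIONS),
    error_config: ErrorConfig | None = None,
    probe: ProbeGeometry | None = None,
    chromo: ChromophoreModel | None = None,
    standard: ReflectanceStandard | None = None,
    k: int = 5,
    timing_subset: int = 304,
) -> EvaluationReport:
    """The robustness experiment: every model on every corruption condition.

    Generates the label-grid dataset, derives the corrupted variants, and
    reports RMSE% per (condition, model, target).  Learned models are scored
    by k-fold cross-validation; the spectral-matching inversion needs no
    training and is scored directly.  Wall-clock prediction timings for a
    ``timing_subset``-sample test set are informational only.
    """
    base = generate_grid_dataset(
        n_mu_a, n_mu_s, probe=probe, chromo=chromo, standard=standard
    )
    probe = probe or ProbeGeometry(1)
    chromo = chromo or default_chromophore(base.grid)
    standard = standard or default_standard(base.grid)
    error_config = error_config or ErrorConfig()

    seed_seq = np.random.SeedSequence(seed)
    cond_seeds = dict(zip(CONDITIONS, seed_seq.spawn(len(CONDITIONS))))

    inverter = None
    if "mci" in models:
        inverter = SpectralMatchingInverter(
            forward=forward_closure(probe, chromo, standard)
        ).fit()

    frames = []
    timings: dict[str, float] = {}
    importances: dict[str, pd.Series] = {}
    for condition in conditions:
        ds = make_condition_dataset(base, condition, error_config, seed=cond_seeds[condition])
        for model_spec in models:
            if model_spec == "mci":
                t0 = time.perf_counter()
                pred = inverter.predict(ds.gray)
                dt = time.perf_counter() - t0
                timings.setdefault("mci", dt / len(ds) * timing_subset)
                rows = [
                    {
                        "condition": condition,
                        "model": "mci",
                        "target": t,
                        "group": "pooled",
                        "rmse_percent": rmse_percent(pred[:, j], ds.labels[:, j]),
                    }
                    for j, t in enumerate(TARGETS)
                ]
                frames.append(pd.DataFrame(rows))
            else:
                report = kfold_cv(ds, k=k, model_spec=model_spec, seed=seed)
                frames.append(report.rmse)
                if model_spec not in timings:
                    model = _make_model(model_spec, seed)
                    X = _inputs_for(model, ds)
                    Xv = X.to_numpy() if isinstance(X, pd.DataFrame) else X
                    model.fit(Xv, ds.labels)
                    sub = Xv[:timing_subset]
                    t0 = time.perf_counter()
                    model.predict(sub)
                    timings[model_spec] = time.perf_counter() - t0
                if model_spec == "wir" and condition == "all":
                    model = WIRRegressor(random_state=seed).fit(
                        extract_feature_table(ds)[list(FEATURE_NAMES)], ds.labels
                    )
                    importances = feature_importances(model)

    return EvaluationReport(
        rmse=pd.concat(frames, ignore_index=True),
        timings_s=timings,
        importances=importances,
    )
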