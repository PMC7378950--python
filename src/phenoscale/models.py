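"""The eight phenology models as scikit-learn style estimators.

Every model maps a site-year's daily temperature record (plus derived
covariates) to a predicted day of year (DOY) for a phenological event
(budburst or flowering).  Six of the eight are thermal-forcing accumulation
models: daily mean temperature ``Ti`` is transformed through a model-specific
forcing function ``Rf``, accumulated from a start day, and the event is
predicted on the first day the running total meets the required forcing.

=============  =====================================  ==========================
model          requirement                            daily forcing Rf(Ti)
=============  =====================================  ==========================
Naive          (constant: mean DOY)                   --
Linear         DOY = b1 + b2 * Tmean_spring           --
GDD            sum from t1 >= F*                      max(Ti - Tbase, 0)
Fixed GDD      sum from DOY 1 >= F*                   max(Ti, 0)
Alternating    sum from DOY 1 >= a + b*exp(c*NCD(t))  max(Ti - 5, 0)
Uniforc        sum from t1 >= F*                      1 / (1 + exp(b*(Ti - c)))
M1             sum from t1 >= (L/24)^k * F*           max(Ti - Tbase, 0)
MSB            sum from DOY 1 >=                      max(Ti - 5, 0)
               a + b*exp(c*NCD(t)) + d*Tmean_spring
=============  =====================================  ==========================

``NCD(t)`` is the number of chill days (daily mean below 0 degC) since
1 January, re-evaluated each day; ``L`` is the photoperiod in hours, also
evaluated daily; ``Tmean_spring`` is the 1 January - 31 March mean
temperature.  A prediction that never meets its requirement within the
season window is the no-event marker :data:`NO_EVENT` (NaN).

Estimator protocol
------------------
Each estimator takes a design matrix ``X`` of shape ``(n_events, 342)``:
columns ``0..340`` are daily mean temperatures on the canonical DOY grid
(-90..250) and column ``341`` is site latitude (see
:func:`phenoscale.io.build_design_matrix`).  ``fit(X, y)`` estimates the
parameters by differential evolution minimising the RMSE of predicted DOY,
then refits on bootstrap resamples; ``predict(X)`` returns, by default, the
mean of the per-bootstrap predictions.  Fitted attributes carry a trailing
underscore (``params_``, ``bootstrap_params_``, ``rmse_train_``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .covariates import (
    DOY_GRID,
    N_DAYS,
    SPRING_WINDOW,
    cumulative_chill_days,
    photoperiod_hours,
)

__all__ = [
    "NO_EVENT",
    "ModelSpec",
    "MODEL_REGISTRY",
    "get_model",
    "NaiveModel",
    "LinearModel",
    "GDDModel",
    "FixedGDDModel",
    "AlternatingModel",
    "UniforcModel",
    "M1Model",
    "MSBModel",
]

#: Marker for "requirement never met within the season window".
NO_EVENT = np.nan

#: Number of design-matrix columns: daily temps on the DOY grid + latitude.
N_FEATURES = N_DAYS + 1


@dataclass(frozen=True)
class ModelSpec:
    """Registry entry describing a model's parameterisation."""

    name: str
    parameter_names: tuple
    bounds: dict
    requires: frozenset


# ---------------------------------------------------------------------------
# design-matrix helpers
# ---------------------------------------------------------------------------

def _validate_X(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if X.ndim != 2 or X.shape[1] != N_FEATURES:
        raise ValueError(
            f"X must have shape (n_events, {N_FEATURES}): {N_DAYS} daily "
            f"temperatures on DOY {DOY_GRID[0]}..{DOY_GRID[-1]} plus latitude; "
            f"got {X.shape}"
        )
    if not np.isfinite(X[:, :N_DAYS]).all():
        raise ValueError("temperature block of X contains NaN/inf; gaps must be "
                         "resolved before model fitting")
    return X


def temps_of(X: np.ndarray) -> np.ndarray:
    return X[:, :N_DAYS]


def latitudes_of(X: np.ndarray) -> np.ndarray:
    return X[:, N_DAYS]


def spring_mean_of(X: np.ndarray) -> np.ndarray:
    lo, hi = SPRING_WINDOW
    i0 = lo - DOY_GRID[0]
    return temps_of(X)[:, i0 : i0 + (hi - lo + 1)].mean(axis=1)


def photoperiod_matrix(latitudes: np.ndarray) -> np.ndarray:
    """Daylength (hours) for each event row across the DOY grid."""
    calendar_doy = ((DOY_GRID - 1) % 365) + 1
    rows = np.empty((latitudes.size, N_DAYS))
    # photoperiod depends only on latitude; compute once per unique site latitude
    for lat in np.unique(latitudes):
        rows[latitudes == lat] = photoperiod_hours(float(lat), calendar_doy)
    return rows


def _first_crossing(cum: np.ndarray, threshold: np.ndarray, start_doy: int) -> np.ndarray:
    """First DOY >= ``start_doy`` where cumulative forcing meets the threshold.

    ``threshold`` broadcasts against ``cum`` (scalar, per-event column, or a
    full per-event-per-day matrix for the day-varying requirements).  Rows
    with no crossing get :data:`NO_EVENT`.
    """
    candidate = DOY_GRID >= start_doy
    met = (cum >= threshold) & candidate
    any_met = met.any(axis=1)
    idx = met.argmax(axis=1)
    out = DOY_GRID[idx].astype(float)
    out[~any_met] = NO_EVENT
    return out


def accumulate_forcing(forcing: np.ndarray, start_doy: int) -> np.ndarray:
    """Running sum of daily forcing from ``start_doy`` on the DOY grid.

    Contributions from days before ``start_doy`` are zero.
    """
    start_doy = int(start_doy)
    if start_doy < DOY_GRID[0] or start_doy > DOY_GRID[-1]:
        raise ValueError(
            f"start_doy {start_doy} outside series range "
            f"[{DOY_GRID[0]}, {DOY_GRID[-1]}]"
        )
    forcing = np.atleast_2d(forcing)
    masked = np.where(DOY_GRID >= start_doy, forcing, 0.0)
    return np.cumsum(masked, axis=1)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class BasePhenologyModel(RegressorMixin, BaseEstimator):
    """Shared fit/predict machinery for all phenology models.

    Subclasses define ``parameter_names``, ``default_bounds`` and
    ``_predict_core(X, params)`` — a pure function from a validated design
    matrix and a parameter vector to predicted DOYs (NaN = no event).
    """

    parameter_names: tuple = ()
    default_bounds: dict = {}

    def __init__(
        self,
        bounds=None,
        n_bootstrap=250,
        population=30,
        mutation=(0.5, 1.0),
        recombination=0.7,
        maxiter=500,
        tol=1e-3,
        prediction_method="bootstrap_mean",
        random_state=None,
    ):
        self.bounds = bounds
        self.n_bootstrap = n_bootstrap
        self.population = population
        self.mutation = mutation
        self.recombination = recombination
        self.maxiter = maxiter
        self.tol = tol
        self.prediction_method = prediction_method
        self.random_state = random_state

    # -- parameter plumbing -------------------------------------------------

    def resolved_bounds(self) -> list:
        merged = dict(self.default_bounds)
        if self.bounds:
            unknown = set(self.bounds) - set(self.parameter_names)
            if unknown:
                raise ValueError(
                    f"unknown parameter(s) {sorted(unknown)} for model "
                    f"{self.model_name!r}; expected {self.parameter_names}"
                )
            merged.update(self.bounds)
        return [tuple(merged[p]) for p in self.parameter_names]

    @property
    def model_name(self) -> str:
        return MODEL_NAMES[type(self)]

    def _params_dict(self, vector) -> dict:
        return dict(zip(self.parameter_names, np.asarray(vector, dtype=float)))

    # -- core API -----------------------------------------------------------

    def _predict_core(self, X: np.ndarray, params: dict) -> np.ndarray:
        raise NotImplementedError

    def predict_with_params(self, X, params) -> np.ndarray:
        """Predict event DOYs for an explicit parameter vector or dict."""
        X = _validate_X(X)
        if not isinstance(params, dict):
            params = self._params_dict(params)
        missing = set(self.parameter_names) - set(params)
        if missing:
            raise ValueError(f"missing parameter(s) {sorted(missing)}")
        return self._predict_core(X, params)

    def fit(self, X, y):
        """Estimate parameters by differential evolution, then bootstrap.

        ``y`` holds observed event DOYs (one per row of ``X``).  The point
        fit minimises training RMSE; ``n_bootstrap`` refits on n-out-of-n
        resamples with replacement populate ``bootstrap_params_``.
        """
        from . import fitting  # local import: fitting depends on this module

        X = _validate_X(X)
        y = np.asarray(y, dtype=float)
        if y.ndim != 1 or y.size != X.shape[0]:
            raise ValueError(f"y must be 1-D with {X.shape[0]} entries; got {y.shape}")
        if y.size == 0:
            raise ValueError("cannot fit on an empty training set")

        result = fitting.fit_differential_evolution(
            self.predict_with_params, X, y,
            bounds=self.resolved_bounds(),
            settings=fitting.DESettings(
                population=self.population,
                mutation=self.mutation,
                recombination=self.recombination,
                maxiter=self.maxiter,
                tol=self.tol,
            ),
            seed=self.random_state,
        )
        self.params_ = self._params_dict(result.x)
        self.rmse_train_ = float(result.fun)
        self.n_train_ = int(y.size)
        self.n_features_in_ = X.shape[1]
        self.optimizer_result_ = result

        self.bootstrap_params_, self.n_bootstrap_failures_ = fitting.bootstrap_fit(
            self.predict_with_params, X, y,
            bounds=self.resolved_bounds(),
            settings=fitting.DESettings(
                population=self.population,
                mutation=self.mutation,
                recombination=self.recombination,
                maxiter=self.maxiter,
                tol=self.tol,
            ),
            reps=self.n_bootstrap,
            seed=self.random_state,
        )
        return self

    def predict(self, X, method=None) -> np.ndarray:
        """Predict event DOYs; NaN marks no-event.

        ``method='point'`` uses the point parameter vector;
        ``method='bootstrap_mean'`` (default) averages the per-bootstrap
        predictions, excluding no-event bootstrap draws when at least one
        bootstrap yields a real prediction.
        """
        check_is_fitted(self, "params_")
        X = _validate_X(X)
        method = method or self.prediction_method
        if method == "point":
            return self._predict_core(X, self.params_)
        if method != "bootstrap_mean":
            raise ValueError(f"unknown prediction method {method!r}")
        if self.bootstrap_params_.shape[0] == 0:
            raise ValueError("no usable bootstrap parameter vectors")
        preds = np.stack([
            self._predict_core(X, self._params_dict(vec))
            for vec in self.bootstrap_params_
        ])
        with np.errstate(invalid="ignore"):
            out = np.nanmean(preds, axis=0)  # all-NaN columns stay NO_EVENT
        return out

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.input_tags.allow_nan = True  # latitude column may be NaN for non-spatial models
        return tags


class NaiveModel(BasePhenologyModel):
    """Constant predictor: the mean DOY of prior observations."""

    parameter_names = ("mean_doy",)
    default_bounds = {"mean_doy": (1.0, 250.0)}

    def _predict_core(self, X, params):
        return np.full(X.shape[0], float(params["mean_doy"]))


class LinearModel(BasePhenologyModel):
    """Linear regression of event DOY on mean spring temperature."""

    parameter_names = ("beta1", "beta2")
    default_bounds = {"beta1": (0.0, 250.0), "beta2": (-20.0, 20.0)}

    def _predict_core(self, X, params):
        return params["beta1"] + params["beta2"] * spring_mean_of(X)


class GDDModel(BasePhenologyModel):
    """Growing-degree-day model: forcing max(Ti - Tbase, 0) from fitted t1."""

    parameter_names = ("t1", "t_base", "f_star")
    default_bounds = {"t1": (-30.0, 120.0), "t_base": (-10.0, 15.0), "f_star": (0.0, 1000.0)}

    def _predict_core(self, X, params):
        t1 = int(np.rint(params["t1"]))
        forcing = np.maximum(temps_of(X) - params["t_base"], 0.0)
        cum = accumulate_forcing(forcing, t1)
        return _first_crossing(cum, np.float64(params["f_star"]), t1)


class FixedGDDModel(BasePhenologyModel):
    """GDD with start day and base temperature fixed (t1 = 1 Jan, Tbase = 0 degC)."""

    parameter_names = ("f_star",)
    default_bounds = {"f_star": (0.0, 1000.0)}

    def _predict_core(self, X, params):
        forcing = np.maximum(temps_of(X), 0.0)
        cum = accumulate_forcing(forcing, 1)
        return _first_crossing(cum, np.float64(params["f_star"]), 1)


class AlternatingModel(BasePhenologyModel):
    """Chill-modulated requirement: a + b*exp(c*NCD(t)), forcing base 5 degC.

    The requirement is re-evaluated daily with that day's running chill-day
    count, so warm winters (few chill days) demand more forcing.
    """

    parameter_names = ("a", "b", "c")
    default_bounds = {"a": (0.0, 1000.0), "b": (0.0, 2000.0), "c": (-2.0, 0.0)}

    @staticmethod
    def _threshold(X, params):
        ncd = cumulative_chill_days(temps_of(X))
        with np.errstate(over="ignore"):
            thresh = params["a"] + params["b"] * np.exp(params["c"] * ncd)
        return np.where(np.isfinite(thresh), thresh, np.inf)

    def _predict_core(self, X, params):
        forcing = np.maximum(temps_of(X) - 5.0, 0.0)
        cum = accumulate_forcing(forcing, 1)
        return _first_crossing(cum, self._threshold(X, params), 1)


class UniforcModel(BasePhenologyModel):
    """Sigmoid forcing 1/(1 + exp(b*(Ti - c))) accumulated from fitted t1.

    ``b`` is constrained negative so forcing increases with temperature.
    """

    parameter_names = ("t1", "b", "c", "f_star")
    default_bounds = {
        "t1": (-30.0, 120.0),
        "b": (-20.0, -0.1),
        "c": (-10.0, 25.0),
        "f_star": (0.0, 200.0),
    }

    def _predict_core(self, X, params):
        t1 = int(np.rint(params["t1"]))
        with np.errstate(over="ignore"):
            forcing = 1.0 / (1.0 + np.exp(params["b"] * (temps_of(X) - params["c"])))
        cum = accumulate_forcing(forcing, t1)
        return _first_crossing(cum, np.float64(params["f_star"]), t1)


class M1Model(BasePhenologyModel):
    """GDD extended with a daylength correction on the required forcing.

    The daily requirement is (L/24)^k * F* with L the photoperiod on that
    day, so longer days lower (k > 0) the remaining requirement.  The forcing
    floor defaults to 0, matching the GDD analogy and the model's original
    formulation; ``forcing_floor=5`` selects the variant with a minimum daily
    forcing of 5 units.
    """

    parameter_names = ("t1", "t_base", "f_star", "k")
    default_bounds = {
        "t1": (-30.0, 120.0),
        "t_base": (-10.0, 15.0),
        "f_star": (0.0, 1000.0),
        "k": (0.0, 50.0),
    }

    def __init__(
        self,
        bounds=None,
        n_bootstrap=250,
        population=30,
        mutation=(0.5, 1.0),
        recombination=0.7,
        maxiter=500,
        tol=1e-3,
        prediction_method="bootstrap_mean",
        random_state=None,
        forcing_floor=0.0,
    ):
        super().__init__(
            bounds=bounds, n_bootstrap=n_bootstrap, population=population,
            mutation=mutation, recombination=recombination, maxiter=maxiter,
            tol=tol, prediction_method=prediction_method, random_state=random_state,
        )
        self.forcing_floor = forcing_floor

    def _predict_core(self, X, params):
        t1 = int(np.rint(params["t1"]))
        forcing = np.maximum(temps_of(X) - params["t_base"], self.forcing_floor)
        cum = accumulate_forcing(forcing, t1)
        daylength = photoperiod_matrix(latitudes_of(X))
        threshold = (daylength / 24.0) ** params["k"] * params["f_star"]
        return _first_crossing(cum, threshold, t1)


class MSBModel(BasePhenologyModel):
    """Alternating model plus a spring-temperature correction d*Tmean."""

    parameter_names = ("a", "b", "c", "d")
    default_bounds = {
        "a": (0.0, 1000.0),
        "b": (0.0, 2000.0),
        "c": (-2.0, 0.0),
        "d": (-200.0, 200.0),
    }

    def _predict_core(self, X, params):
        forcing = np.maximum(temps_of(X) - 5.0, 0.0)
        cum = accumulate_forcing(forcing, 1)
        base = AlternatingModel._threshold(X, params)
        threshold = base + params["d"] * spring_mean_of(X)[:, None]
        return _first_crossing(cum, threshold, 1)


MODEL_REGISTRY = {
    "naive": NaiveModel,
    "linear": LinearModel,
    "gdd": GDDModel,
    "fixed_gdd": FixedGDDModel,
    "alternating": AlternatingModel,
    "uniforc": UniforcModel,
    "m1": M1Model,
    "msb": MSBModel,
}
MODEL_NAMES = {cls: name for name, cls in MODEL_REGISTRY.items()}

_REQUIRES = {
    "naive": frozenset(),
    "linear": frozenset({"tmean_spring"}),
    "gdd": frozenset({"temperature"}),
    "fixed_gdd": frozenset({"temperature"}),
    "alternating": frozenset({"temperature", "ncd"}),
    "uniforc": frozenset({"temperature"}),
    "m1": frozenset({"temperature", "photoperiod"}),
    "msb": frozenset({"temperature", "ncd", "tmean_spring"}),
}


def get_model(name: str, **kwargs) -> BasePhenologyModel:
    """Instantiate a model by registry name."""
    try:
        cls = MODEL_REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown model {name!r}; choose from {sorted(MODEL_REGISTRY)}"
        ) from None
    return cls(**kwargs)


def model_spec(name: str) -> ModelSpec:
    """Registry metadata (parameter names, default bounds, covariate needs)."""
    cls = MODEL_REGISTRY[name]
    return ModelSpec(
        name=name,
        parameter_names=tuple(cls.parameter_names),
        bounds=dict(cls.default_bounds),
        requires=_REQUIRES[name],
    )
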