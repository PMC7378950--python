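"""Parameter estimation: differential evolution, bootstrap, holdout splitting.

All models are fit by minimising the root mean square error (RMSE) of the
predicted event day of year with differential evolution (DE), a global,
population-based optimiser that needs no gradients — essential here because
the forcing-accumulation models predict integer DOYs, making the objective
piecewise constant.  Parameter uncertainty comes from an n-out-of-n bootstrap:
the model is refit (default 250 times) on resamples drawn with replacement,
and downstream predictions use the mean of the per-bootstrap predicted DOYs.

A no-event prediction (requirement never met within the season window)
contributes a fixed penalty residual of :data:`NO_EVENT_PENALTY` days, which
dwarfs any real residual and steers the optimiser away from degenerate
parameter regions while keeping the objective finite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution

__all__ = [
    "NO_EVENT_PENALTY",
    "DESettings",
    "SplitDataset",
    "rmse",
    "rmse_objective",
    "fit_differential_evolution",
    "bootstrap_fit",
    "holdout_split",
]

logger = logging.getLogger(__name__)

#: Residual (days) assigned to a no-event prediction in the fitting objective.
NO_EVENT_PENALTY = 1000.0

GROUP_KEYS = ["species", "phenophase_class"]


@dataclass(frozen=True)
class DESettings:
    """Differential-evolution hyperparameters.

    ``population`` is the total number of population members (scipy's
    ``popsize`` is a per-parameter multiplier; we convert).  Mutation is
    dithered over the given range each generation.
    """

    population: int = 30
    mutation: tuple = (0.5, 1.0)
    recombination: float = 0.7
    maxiter: int = 500
    tol: float = 1e-3

    def popsize_multiplier(self, n_params: int) -> int:
        return max(5, math.ceil(self.population / n_params))


@dataclass
class SplitDataset:
    """Train/test partition of events, stratified by species-phenophase group."""

    train_events: pd.DataFrame
    test_events: pd.DataFrame
    fraction_test: float
    seed: object = None


def rmse(predicted: np.ndarray, observed: np.ndarray) -> float:
    """RMSE in days, mapping no-event (NaN) predictions to the penalty residual."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if observed.size == 0:
        raise ValueError("cannot compute RMSE on an empty set of events")
    resid = predicted - observed
    resid = np.where(np.isnan(predicted), NO_EVENT_PENALTY, resid)
    return float(np.sqrt(np.mean(resid**2)))


def rmse_objective(params, predict_fn, X, y) -> float:
    """Training objective: RMSE of ``predict_fn(X, params)`` against ``y``."""
    value = rmse(predict_fn(X, params), y)
    return value if np.isfinite(value) else NO_EVENT_PENALTY * 10


def fit_differential_evolution(predict_fn, X, y, bounds, settings=None, seed=None):
    """Global RMSE minimisation over the given parameter bounds.

    Parameters
    ----------
    predict_fn : callable
        ``predict_fn(X, params_vector) -> predicted DOYs`` (NaN = no event).
    X, y : arrays
        Design matrix and observed event DOYs.
    bounds : list of (lo, hi)
        Finite box bounds, one per parameter.
    settings : DESettings, optional
    seed : int, optional
        Makes the search bit-reproducible.

    Returns
    -------
    scipy.optimize.OptimizeResult
        ``x`` is the best parameter vector, ``fun`` the training RMSE.
    """
    settings = settings or DESettings()
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("empty training set")
    for lo, hi in bounds:
        if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
            raise ValueError(f"bounds must be finite with lo <= hi; got ({lo}, {hi})")

    result = differential_evolution(
        rmse_objective,
        bounds=bounds,
        args=(predict_fn, X, y),
        popsize=settings.popsize_multiplier(len(bounds)),
        mutation=settings.mutation,
        recombination=settings.recombination,
        maxiter=settings.maxiter,
        tol=settings.tol,
        seed=seed,
        polish=True,
        init="latinhypercube",
    )
    return result


def bootstrap_fit(predict_fn, X, y, bounds, settings=None, reps=250, seed=None):
    """Refit on ``reps`` n-out-of-n resamples drawn with replacement.

    Each resample gets an independent seed derived from the master seed.  A
    failed refit is retried once on a fresh resample, then recorded as
    missing (excluded from the returned array and logged).

    Returns
    -------
    (numpy.ndarray, int)
        Parameter matrix of shape ``(n_successful, n_params)`` in bootstrap
        order, and the count of resamples that failed twice.
    """
    settings = settings or DESettings()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    rng = np.random.default_rng(seed)
    # one optimiser seed for all reps: bootstrap randomness lives entirely in
    # the resampling, so identical resamples give identical refits
    de_seed = int(rng.integers(0, 2**31 - 1))
    vectors = []
    failures = 0
    for rep in range(reps):
        vec = None
        for _attempt in range(2):
            idx = rng.integers(0, n, size=n)
            try:
                res = fit_differential_evolution(
                    predict_fn, X[idx], y[idx], bounds,
                    settings=settings, seed=de_seed,
                )
                if np.isfinite(res.fun):
                    vec = res.x
                    break
            except Exception:  # noqa: BLE001 - a single resample must not kill the run
                logger.exception("bootstrap refit %d failed", rep)
        if vec is None:
            failures += 1
            logger.warning("bootstrap refit %d failed twice; recorded as missing", rep)
        else:
            vectors.append(vec)
    return (
        np.array(vectors) if vectors else np.empty((0, len(bounds))),
        failures,
    )


def _n_test(n: int, fraction: float) -> int:
    # banker's rounding on fraction*n, but never an empty test set
    return max(1, round(fraction * n))


def holdout_split(events: pd.DataFrame, fraction: float = 0.20, seed=None) -> SplitDataset:
    """Hold out a random fraction of events from each species-phenophase group.

    Sampling is uniform without replacement within each group and
    deterministic given ``seed``.  Groups with fewer than 5 events are
    refused: a 20% holdout would be empty or degenerate.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1); got {fraction}")
    for key in GROUP_KEYS:
        if key not in events.columns:
            raise ValueError(f"events table lacks required column {key!r}")
    rng = np.random.default_rng(seed)
    test_idx = []
    for name, group in events.groupby(GROUP_KEYS, sort=True):
        n = len(group)
        if n < 5:
            raise ValueError(
                f"group {name} has only {n} events; need >= 5 for a holdout split"
            )
        k = _n_test(n, fraction)
        test_idx.extend(rng.choice(group.index.to_numpy(), size=k, replace=False))
    test_mask = events.index.isin(test_idx)
    return SplitDataset(
        train_events=events.loc[~test_mask].copy(),
        test_events=events.loc[test_mask].copy(),
        fraction_test=fraction,
        seed=seed,
    )
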