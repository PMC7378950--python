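"""Shared fixtures: series builders and an independent day-by-day oracle.

The oracle predicts event DOYs with a plain Python loop — one day at a
time, accumulating forcing and re-evaluating the requirement — entirely
independent of the vectorised numpy implementation it checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from phenoscale.covariates import DOY_GRID, N_DAYS, TemperatureSeries, photoperiod_hours


def make_series(temps, site_id="s1", year=2015, latitude=40.0):
    """TemperatureSeries from a scalar, an array on the grid, or a dict."""
    if isinstance(temps, dict):
        return TemperatureSeries.from_mapping(site_id, year, temps, latitude)
    arr = np.broadcast_to(np.asarray(temps, dtype=float), (N_DAYS,)).copy()
    return TemperatureSeries(site_id=site_id, year=year, temps=arr, latitude=latitude)


def design_row(series: TemperatureSeries) -> np.ndarray:
    """1-row design matrix for a single series."""
    return np.concatenate([series.temps, [series.latitude]])[None, :]


def random_series(rng, latitude=None) -> TemperatureSeries:
    """A plausible season of daily temperatures: sinusoid + noise."""
    lat = latitude if latitude is not None else float(rng.uniform(30, 50))
    mean = rng.uniform(2, 15)
    amplitude = rng.uniform(5, 15)
    temps = mean + amplitude * np.cos(2 * np.pi * (DOY_GRID - 200) / 365.0)
    temps += rng.normal(0, rng.uniform(0.5, 4.0), size=N_DAYS)
    return make_series(temps, latitude=lat)


def oracle_predict(model_name, series: TemperatureSeries, params: dict,
                   forcing_floor: float = 0.0):
    """Day-by-day reference prediction; returns a DOY or None (no event).

    Walks the season one day at a time keeping a running forcing total and,
    where needed, a running chill-day count, checking the requirement after
    each day's contribution.
    """
    temps = {int(d): float(t) for d, t in zip(DOY_GRID, series.temps)}
    if model_name in ("gdd", "uniforc", "m1"):
        start = int(round(params["t1"]))
    else:
        start = 1

    acc = 0.0
    ncd = 0
    for d in range(int(DOY_GRID[0]), int(DOY_GRID[-1]) + 1):
        if 1 <= d and temps[d] < 0.0:
            ncd += 1
        if d < start:
            continue
        Ti = temps[d]
        if model_name == "gdd":
            acc += max(Ti - params["t_base"], 0.0)
            req = params["f_star"]
        elif model_name == "fixed_gdd":
            acc += max(Ti, 0.0)
            req = params["f_star"]
        elif model_name == "uniforc":
            acc += 1.0 / (1.0 + np.exp(params["b"] * (Ti - params["c"])))
            req = params["f_star"]
        elif model_name == "alternating":
            acc += max(Ti - 5.0, 0.0)
            req = params["a"] + params["b"] * np.exp(params["c"] * ncd)
        elif model_name == "msb":
            acc += max(Ti - 5.0, 0.0)
            tmean = float(np.mean([temps[x] for x in range(1, 91)]))
            req = (params["a"] + params["b"] * np.exp(params["c"] * ncd)
                   + params["d"] * tmean)
        elif model_name == "m1":
            acc += max(Ti - params["t_base"], forcing_floor)
            calendar_doy = ((d - 1) % 365) + 1
            L = photoperiod_hours(series.latitude, calendar_doy)
            req = (L / 24.0) ** params["k"] * params["f_star"]
        else:
            raise ValueError(model_name)
        if np.isfinite(req) and acc >= req:
            return d
    return None


def random_params(model_name, rng) -> dict:
    """Plausible random parameter draws for oracle cross-checks."""
    if model_name == "gdd":
        return {"t1": float(rng.integers(-30, 120)),
                "t_base": float(rng.uniform(-5, 10)),
                "f_star": float(rng.uniform(10, 600))}
    if model_name == "fixed_gdd":
        return {"f_star": float(rng.uniform(10, 800))}
    if model_name == "uniforc":
        return {"t1": float(rng.integers(-30, 120)),
                "b": float(rng.uniform(-10, -0.5)),
                "c": float(rng.uniform(-5, 20)),
                "f_star": float(rng.uniform(2, 100))}
    if model_name == "alternating":
        return {"a": float(rng.uniform(0, 400)),
                "b": float(rng.uniform(0, 800)),
                "c": float(rng.uniform(-1.5, 0.0))}
    if model_name == "msb":
        return {"a": float(rng.uniform(0, 400)),
                "b": float(rng.uniform(0, 800)),
                "c": float(rng.uniform(-1.5, 0.0)),
                "d": float(rng.uniform(-30, 30))}
    if model_name == "m1":
        return {"t1": float(rng.integers(-30, 120)),
                "t_base": float(rng.uniform(-5, 10)),
                "f_star": float(rng.uniform(10, 600)),
                "k": float(rng.uniform(0, 10))}
    raise ValueError(model_name)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def constant_series():
    return make_series(10.0)


def status_row(ind, date, status, species="sp1", phenophase="breaking_leaf_buds",
               site="s1"):
    return {"individual_id": ind, "site_id": site, "species": species,
            "phenophase": phenophase, "date": date, "status": status}


def make_status(rows) -> pd.DataFrame:
    return pd.DataFrame([status_row(*r[:3], **(r[3] if len(r) > 3 else {})) for r in rows])
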