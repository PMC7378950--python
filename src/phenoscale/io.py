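"""CSV contracts and the event design matrix.

File formats (UTF-8 CSV with header row, ISO-8601 dates):

* status records: ``individual_id, site_id, species, phenophase, date, status``
* daily temperature: ``site_id, date, tmean_c``
* site metadata: ``site_id, latitude, longitude``
* events: ``species, phenophase_class, site_id, individual_id, year, doy``

The design matrix consumed by every model estimator has one row per event:
the 341 daily mean temperatures of the event's site-year on the canonical
season-relative DOY grid (-90..250, DOY 1 = 1 January of the event year)
followed by the site latitude.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .covariates import DOY_GRID, N_DAYS, TemperatureSeries
from .observations import EVENT_COLUMNS, STATUS_COLUMNS

__all__ = [
    "TemperatureCollection",
    "read_status_csv",
    "read_site_csv",
    "read_temperature_csv",
    "read_events_csv",
    "write_events_csv",
    "build_design_matrix",
    "save_fitted_model",
    "load_fitted_params",
]


class TemperatureCollection(dict):
    """Mapping from ``(site_id, year)`` to :class:`TemperatureSeries`."""

    def series(self, site_id: str, year: int) -> TemperatureSeries:
        try:
            return self[(str(site_id), int(year))]
        except KeyError:
            raise KeyError(
                f"no temperature series for site {site_id!r} year {year}"
            ) from None


def read_status_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"individual_id": str, "site_id": str})
    missing = [c for c in STATUS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: status CSV lacks column(s) {missing}")
    df["date"] = pd.to_datetime(df["date"])
    return df


def read_site_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"site_id": str})
    for col in ("site_id", "latitude"):
        if col not in df.columns:
            raise ValueError(f"{path}: site CSV lacks column {col!r}")
    return df


def read_temperature_csv(path, sites: pd.DataFrame, years=None) -> TemperatureCollection:
    """Load per-site daily temperatures into season-relative series.

    For each site and candidate event year ``Y``, dates are mapped to DOY
    relative to 1 January of ``Y`` (prior-autumn days get DOY <= 0) and a
    series over the canonical grid is built.  Days absent from the file stay
    NaN gaps; gap handling is deferred to the point of use.
    """
    df = pd.read_csv(path, dtype={"site_id": str})
    for col in ("site_id", "date", "tmean_c"):
        if col not in df.columns:
            raise ValueError(f"{path}: temperature CSV lacks column {col!r}")
    df["date"] = pd.to_datetime(df["date"])
    lat = sites.set_index("site_id")["latitude"].to_dict()

    collection = TemperatureCollection()
    for site_id, grp in df.groupby("site_id"):
        daily = grp.drop_duplicates("date").set_index("date")["tmean_c"]
        candidates = years if years is not None else sorted(grp["date"].dt.year.unique())
        for year in candidates:
            origin = pd.Timestamp(int(year), 1, 1)
            dates = origin + pd.to_timedelta(DOY_GRID - 1, unit="D")
            temps = daily.reindex(dates).to_numpy(dtype=float)
            if np.isnan(temps).all():
                continue
            collection[(site_id, int(year))] = TemperatureSeries(
                site_id=site_id,
                year=int(year),
                temps=temps,
                latitude=float(lat.get(site_id, np.nan)),
            )
    return collection


def read_events_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"individual_id": str, "site_id": str})
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: events CSV lacks column(s) {missing}")
    return df


def write_events_csv(events: pd.DataFrame, path) -> None:
    cols = EVENT_COLUMNS + [c for c in events.columns if c not in EVENT_COLUMNS]
    events[cols].to_csv(path, index=False)


def build_design_matrix(events: pd.DataFrame, temperatures: TemperatureCollection):
    """Assemble ``(X, y)`` for model fitting: one row per event.

    Raises ``KeyError`` if any event's site-year has no temperature series.
    """
    X = np.empty((len(events), N_DAYS + 1))
    for i, row in enumerate(events.itertuples(index=False)):
        series = temperatures.series(row.site_id, row.year)
        X[i, :N_DAYS] = series.temps
        X[i, N_DAYS] = series.latitude
    y = events["doy"].to_numpy(dtype=float)
    return X, y


def save_fitted_model(model, json_path, bootstrap_csv_path=None) -> None:
    """Serialise a fitted estimator: params/bounds/settings to JSON, bootstrap to CSV."""
    payload = {
        "model": model.model_name,
        "parameter_names": list(model.parameter_names),
        "point_params": {k: float(v) for k, v in model.params_.items()},
        "bounds": [list(map(float, b)) for b in model.resolved_bounds()],
        "rmse_train": model.rmse_train_,
        "n_train": model.n_train_,
        "seed": model.random_state,
        "optimizer_settings": {
            "population": model.population,
            "mutation": list(model.mutation),
            "recombination": model.recombination,
            "maxiter": model.maxiter,
            "tol": model.tol,
        },
        "n_bootstrap": int(model.bootstrap_params_.shape[0]),
        "n_bootstrap_failures": model.n_bootstrap_failures_,
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2)
    if bootstrap_csv_path is not None:
        pd.DataFrame(model.bootstrap_params_, columns=list(model.parameter_names)).to_csv(
            bootstrap_csv_path, index=False
        )


def load_fitted_params(json_path) -> dict:
    with open(json_path) as fh:
        return json.load(fh)
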