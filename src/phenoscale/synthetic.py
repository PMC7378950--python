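"""Synthetic study system: sites, climate, true events, observation campaigns.

The generator emulates the statistical structure of a cross-scale phenology
study without any external data:

* a handful of **intensive** sites visited on a regular 3-7 day schedule
  (long-term research station style), versus many **broad-scale** sites
  visited sparsely and irregularly with per-year dropout (citizen-science
  style);
* per-site daily mean temperature from a latitude-dependent sinusoidal
  climatology plus white noise;
* true event dates produced by a known thermal-forcing model, with optional
  across-site parameter variation (the "local adaptation" scenario) and
  individual-level noise;
* status records (yes/no per visit) that censor the true date between
  consecutive visits, so the downstream cleaning pipeline must recover it
  as a midpoint.

Everything is deterministic given the config seed: each site-year's weather
stream is seeded by (seed, site index, year), so regenerating any one
series in isolation reproduces it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import DOY_GRID, TemperatureSeries
from .io import TemperatureCollection
from .models import get_model

__all__ = [
    "TempClimatology",
    "CampaignConfig",
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_sites",
    "generate_temperature",
    "generate_true_events",
    "generate_campaign",
    "generate_dataset",
]

_BUDBURST_PHASE = "breaking_leaf_buds"
_FLOWERS_PHASE = "open_flowers"


@dataclass(frozen=True)
class TempClimatology:
    """Sinusoidal climate: Ti(d) = M(lat) + A*cos(2*pi*(d - peak)/365) + noise.

    ``M(lat) = annual_mean_at_ref_lat + lapse_per_degree_lat * (lat - ref_lat)``
    makes high-latitude sites colder.  Defaults roughly match a humid
    temperate gradient (annual mean 12 degC at 40N, ~0.7 degC lost per degree
    of latitude, 13 degC seasonal amplitude peaking in late July).
    """

    annual_mean_at_ref_lat: float = 12.0
    ref_lat: float = 40.0
    lapse_per_degree_lat: float = -0.7
    amplitude: float = 13.0
    peak_doy: float = 200.0
    daily_noise_sd: float = 3.0


@dataclass(frozen=True)
class CampaignConfig:
    """Observation-campaign structure for the two scales.

    Intensive sites are visited on a regular schedule with an interval drawn
    once per individual-year from ``intensive_interval_days``.  Broad-scale
    visits occur independently each day with probability ``broad_visit_rate``
    (default one visit per ~10 d on average), and a whole individual-year is
    skipped with probability ``broad_dropout_prob``.
    """

    intensive_interval_days: tuple = (3, 7)
    broad_visit_rate: float = 0.1
    broad_dropout_prob: float = 0.3
    first_visit_doy: int = 1
    last_visit_doy: int = 220


@dataclass
class SyntheticConfig:
    """Full description of a synthetic cross-scale study."""

    n_sites_broad: int = 20
    n_sites_intensive: int = 2
    years: tuple = tuple(range(2009, 2017))
    latitude_range: tuple = (32.0, 47.0)
    temp_params: TempClimatology = field(default_factory=TempClimatology)
    generative_model: str = "fixed_gdd"
    true_params: dict = field(default_factory=lambda: {"f_star": 200.0})
    #: across-species sd of each parameter (species differ in requirements)
    species_param_sd: dict = field(default_factory=lambda: {"f_star": 40.0})
    #: across-site sd of each parameter (local adaptation / microclimate)
    param_spatial_sd: dict = field(default_factory=dict)
    event_noise_sd: float = 2.0
    campaign: CampaignConfig = field(default_factory=CampaignConfig)
    n_species: int = 4
    n_individuals_intensive: int = 5
    n_individuals_broad: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.event_noise_sd < 0 or any(v < 0 for v in self.param_spatial_sd.values()):
            raise ValueError("noise standard deviations must be >= 0")
        if self.generative_model in ("naive", "linear"):
            raise ValueError("generative model must be a thermal-forcing model")


@dataclass
class SyntheticDataset:
    """Everything a pipeline run needs, plus the withheld truth table."""

    sites: pd.DataFrame
    temperatures: TemperatureCollection
    status_intensive: pd.DataFrame
    status_broad: pd.DataFrame
    truth: pd.DataFrame
    site_params: pd.DataFrame


def _site_rng(config: SyntheticConfig, site_index: int, year: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed), 7, int(site_index), int(year)])
    )


def generate_sites(config: SyntheticConfig) -> pd.DataFrame:
    """Draw site locations: columns ``site_id, latitude, longitude, scale``."""
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    lo, hi = config.latitude_range
    rows = []
    for i in range(config.n_sites_intensive):
        rows.append(("intensive_%02d" % i, "intensive"))
    for i in range(config.n_sites_broad):
        rows.append(("broad_%02d" % i, "broad"))
    sites = pd.DataFrame(rows, columns=["site_id", "scale"])
    sites["latitude"] = rng.uniform(lo, hi, size=len(sites)).round(3)
    sites["longitude"] = rng.uniform(-120.0, -70.0, size=len(sites)).round(3)
    return sites[["site_id", "latitude", "longitude", "scale"]]


def generate_temperature(
    config: SyntheticConfig, site_index: int, latitude: float, year: int, site_id: str
) -> TemperatureSeries:
    """One site-year of daily mean temperature on the canonical DOY grid."""
    p = config.temp_params
    rng = _site_rng(config, site_index, year)
    mean = p.annual_mean_at_ref_lat + p.lapse_per_degree_lat * (latitude - p.ref_lat)
    seasonal = mean + p.amplitude * np.cos(2 * np.pi * (DOY_GRID - p.peak_doy) / 365.0)
    noise = rng.normal(0.0, p.daily_noise_sd, size=DOY_GRID.size) if p.daily_noise_sd else 0.0
    return TemperatureSeries(
        site_id=site_id, year=year, temps=seasonal + noise, latitude=latitude
    )


def _species_table(config: SyntheticConfig) -> pd.DataFrame:
    """Species names, phenophases and per-species true parameters."""
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 2]))
    rows = []
    for i in range(config.n_species):
        params = dict(config.true_params)
        for pname, sd in config.species_param_sd.items():
            if sd > 0:
                params[pname] = params[pname] + rng.normal(0.0, sd)
        phase = _BUDBURST_PHASE if i % 2 == 0 else _FLOWERS_PHASE
        rows.append({"species": f"species_{i:02d}", "phenophase": phase, **params})
    return pd.DataFrame(rows)


def _site_params(config: SyntheticConfig, sites: pd.DataFrame, species: pd.DataFrame) -> pd.DataFrame:
    """Per site x species parameter vectors: species truth + spatial deviation."""
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 3]))
    pnames = list(config.true_params)
    rows = []
    for _, site in sites.iterrows():
        for _, sp in species.iterrows():
            params = {p: float(sp[p]) for p in pnames}
            for pname in pnames:
                sd = config.param_spatial_sd.get(pname, 0.0)
                if sd > 0:
                    params[pname] = params[pname] + rng.normal(0.0, sd)
            rows.append({
                "site_id": site["site_id"], "species": sp["species"],
                "phenophase": sp["phenophase"], **params,
            })
    return pd.DataFrame(rows)


def generate_true_events(
    config: SyntheticConfig,
    temperatures: TemperatureCollection,
    sites: pd.DataFrame,
    site_params: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """True event dates from the generative model under site-level parameters.

    One event per site x species x year x individual: the model prediction
    under the site's parameter vector plus Normal(0, event_noise_sd)
    individual noise, rounded to the day.  Site-years where the model never
    reaches its requirement are skipped and counted in the ``n_no_event``
    attribute of the returned frame.
    """
    species = _species_table(config)
    if site_params is None:
        site_params = _site_params(config, sites, species)
    model = get_model(config.generative_model)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 4]))
    scale_of = sites.set_index("site_id")["scale"].to_dict()
    n_ind = {
        "intensive": config.n_individuals_intensive,
        "broad": config.n_individuals_broad,
    }
    rows = []
    n_no_event = 0
    for _, sp_row in site_params.iterrows():
        site_id = sp_row["site_id"]
        params = {p: float(sp_row[p]) for p in config.true_params}
        scale = scale_of[site_id]
        for year in config.years:
            if (site_id, year) not in temperatures:
                continue
            series = temperatures[(site_id, int(year))]
            X = np.concatenate([series.temps, [series.latitude]])[None, :]
            base = model.predict_with_params(X, params)[0]
            if np.isnan(base):
                n_no_event += 1
                continue
            for ind in range(n_ind[scale]):
                noise = rng.normal(0.0, config.event_noise_sd) if config.event_noise_sd else 0.0
                doy = float(np.rint(base + noise))
                rows.append({
                    "species": sp_row["species"],
                    "phenophase": sp_row["phenophase"],
                    "site_id": site_id,
                    "individual_id": f"{site_id}_{sp_row['species']}_ind{ind}",
                    "year": int(year),
                    "true_doy": doy,
                    "scale": scale,
                })
    truth = pd.DataFrame(rows)
    truth.attrs["n_no_event"] = n_no_event
    return truth


def generate_campaign(
    config: SyntheticConfig, truth: pd.DataFrame, style: str
) -> pd.DataFrame:
    """Status records produced by visiting the true events.

    Each visit before the true DOY records "no", each visit on or after it
    records "yes".  Visit schedules differ by ``style``: regular 3-7 d
    intervals (intensive) versus sparse Bernoulli visits with per-year
    dropout (broad).
    """
    if style not in ("intensive", "broad"):
        raise ValueError(f"style must be 'intensive' or 'broad', got {style!r}")
    c = config.campaign
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), 5 if style == "intensive" else 6])
    )
    days = np.arange(c.first_visit_doy, c.last_visit_doy + 1)
    rows = []
    subset = truth[truth["scale"] == style]
    for r in subset.itertuples(index=False):
        if style == "intensive":
            interval = int(rng.integers(c.intensive_interval_days[0],
                                        c.intensive_interval_days[1] + 1))
            offset = int(rng.integers(0, interval))
            visit_doys = days[offset::interval]
        else:
            if rng.random() < c.broad_dropout_prob:
                continue
            visit_doys = days[rng.random(days.size) < c.broad_visit_rate]
        origin = pd.Timestamp(int(r.year), 1, 1)
        for doy in visit_doys:
            rows.append({
                "individual_id": r.individual_id,
                "site_id": r.site_id,
                "species": r.species,
                "phenophase": r.phenophase,
                "date": (origin + pd.Timedelta(days=int(doy) - 1)).date().isoformat(),
                "status": "yes" if doy >= r.true_doy else "no",
            })
    return pd.DataFrame(
        rows,
        columns=["individual_id", "site_id", "species", "phenophase", "date", "status"],
    )


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Run the full generator: sites, climate, truth, and both campaigns."""
    sites = generate_sites(config)
    temperatures = TemperatureCollection()
    for idx, site in sites.iterrows():
        for year in config.years:
            temperatures[(site["site_id"], int(year))] = generate_temperature(
                config, int(idx), float(site["latitude"]), int(year), site["site_id"]
            )
    species = _species_table(config)
    site_params = _site_params(config, sites, species)
    truth = generate_true_events(config, temperatures, sites, site_params)
    return SyntheticDataset(
        sites=sites,
        temperatures=temperatures,
        status_intensive=generate_campaign(config, truth, "intensive"),
        status_broad=generate_campaign(config, truth, "broad"),
        truth=truth,
        site_params=site_params,
    )


def write_dataset(dataset: SyntheticDataset, outdir) -> dict:
    """Write the dataset to CSVs; returns the paths.

    The truth table is withheld from fitting: it exists so tests and audits
    can score recovery, and is written alongside for transparency.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    temps = pd.DataFrame(
        [
            {
                "site_id": s.site_id,
                "date": (pd.Timestamp(s.year, 1, 1) + pd.Timedelta(days=int(d) - 1)).date().isoformat(),
                "tmean_c": round(float(t), 3),
            }
            for s in dataset.temperatures.values()
            for d, t in zip(DOY_GRID, s.temps)
        ]
    )
    for name, frame in [
        ("sites", dataset.sites),
        ("temperatures", temps),
        ("status_intensive", dataset.status_intensive),
        ("status_broad", dataset.status_broad),
        ("truth", dataset.truth),
    ]:
        path = os.path.join(outdir, f"{name}.csv")
        frame.to_csv(path, index=False)
        paths[name] = path
    return paths
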