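"""End-to-end workflow: prepare -> split -> fit both collections -> compare.

The pipeline reproduces a cross-scale model-comparison experiment: the same
set of phenology models is fit independently to an intensive-monitoring
dataset and to a broad-scale, sparsely sampled dataset, and the two fitted
collections are then compared on parameters, predictions, and out-of-sample
error.  Inputs are either CSV files (status records, daily temperatures,
site metadata) or the built-in synthetic generator.

Configuration is a YAML/JSON file validated against a strict schema
(unknown keys are rejected).  All randomness flows from the single config
seed; stage-specific seeds are derived from it, so a rerun with the same
config is identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import comparison as cmp
from . import observations
from .fitting import holdout_split
from .io import (
    TemperatureCollection,
    build_design_matrix,
    read_site_csv,
    read_status_csv,
    read_temperature_csv,
    save_fitted_model,
)
from .models import MODEL_REGISTRY, get_model
from .synthetic import CampaignConfig, SyntheticConfig, generate_dataset

__all__ = ["PipelineConfig", "load_config", "run_pipeline", "fit_collection"]

logger = logging.getLogger(__name__)

_GROUP = ["species", "phenophase_class"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FilterSettings(_Strict):
    max_gap_days: int = 30
    budburst_cutoff: int = 172
    flowers_cutoff: int = 213
    min_n: int = 30
    min_n_inclusive: bool = True


class FitSettings(_Strict):
    n_bootstrap: int = 250
    population: int = 30
    maxiter: int = 500
    tol: float = 1e-3
    holdout_fraction: float = 0.20
    m1_forcing_floor: float = 0.0


class ComparisonSettings(_Strict):
    prediction_method: str = "bootstrap_mean"


class PathSettings(_Strict):
    status_intensive: str | None = None
    status_broad: str | None = None
    temperatures: str | None = None
    sites: str | None = None
    output_dir: str = "phenoscale_output"


class SyntheticSettings(_Strict):
    enabled: bool = True
    n_sites_broad: int = 20
    n_sites_intensive: int = 2
    years: list[int] = Field(default_factory=lambda: list(range(2009, 2017)))
    latitude_range: tuple[float, float] = (32.0, 47.0)
    generative_model: str = "fixed_gdd"
    true_params: dict[str, float] = Field(default_factory=lambda: {"f_star": 200.0})
    species_param_sd: dict[str, float] = Field(default_factory=lambda: {"f_star": 40.0})
    param_spatial_sd: dict[str, float] = Field(default_factory=dict)
    event_noise_sd: float = 2.0
    n_species: int = 4
    n_individuals_intensive: int = 5
    n_individuals_broad: int = 3
    intensive_interval_days: tuple[int, int] = (3, 7)
    broad_visit_rate: float = 0.1
    broad_dropout_prob: float = 0.3


class PipelineConfig(_Strict):
    seed: int = 42
    models: list[str] = Field(default_factory=lambda: sorted(MODEL_REGISTRY))
    filters: FilterSettings = Field(default_factory=FilterSettings)
    fitting: FitSettings = Field(default_factory=FitSettings)
    comparison: ComparisonSettings = Field(default_factory=ComparisonSettings)
    paths: PathSettings = Field(default_factory=PathSettings)
    synthetic: SyntheticSettings = Field(default_factory=SyntheticSettings)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (file locations excluded)."""
        payload = self.model_dump(mode="json", exclude={"paths"})
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)


def synthetic_config(cfg: PipelineConfig) -> SyntheticConfig:
    s = cfg.synthetic
    return SyntheticConfig(
        n_sites_broad=s.n_sites_broad,
        n_sites_intensive=s.n_sites_intensive,
        years=tuple(s.years),
        latitude_range=tuple(s.latitude_range),
        generative_model=s.generative_model,
        true_params=dict(s.true_params),
        species_param_sd=dict(s.species_param_sd),
        param_spatial_sd=dict(s.param_spatial_sd),
        event_noise_sd=s.event_noise_sd,
        campaign=CampaignConfig(
            intensive_interval_days=tuple(s.intensive_interval_days),
            broad_visit_rate=s.broad_visit_rate,
            broad_dropout_prob=s.broad_dropout_prob,
        ),
        n_species=s.n_species,
        n_individuals_intensive=s.n_individuals_intensive,
        n_individuals_broad=s.n_individuals_broad,
        seed=cfg.seed,
    )


def _load_inputs(cfg: PipelineConfig):
    """Return (status_intensive, status_broad, temperatures, sites)."""
    if cfg.synthetic.enabled:
        ds = generate_dataset(synthetic_config(cfg))
        return ds.status_intensive, ds.status_broad, ds.temperatures, ds.sites
    p = cfg.paths
    for name in ("status_intensive", "status_broad", "temperatures", "sites"):
        if getattr(p, name) is None:
            raise ValueError(f"paths.{name} is required when synthetic data is disabled")
    sites = read_site_csv(p.sites)
    temps = read_temperature_csv(p.temperatures, sites)
    return read_status_csv(p.status_intensive), read_status_csv(p.status_broad), temps, sites


def prepare(cfg: PipelineConfig, status: pd.DataFrame) -> pd.DataFrame:
    f = cfg.filters
    return observations.prepare_events(
        status,
        max_gap_days=f.max_gap_days,
        cutoffs={"budburst": f.budburst_cutoff, "flowers": f.flowers_cutoff},
        min_n=f.min_n,
        min_n_inclusive=f.min_n_inclusive,
    )


def _make_model(cfg: PipelineConfig, name: str, seed: int):
    kwargs = dict(
        n_bootstrap=cfg.fitting.n_bootstrap,
        population=cfg.fitting.population,
        maxiter=cfg.fitting.maxiter,
        tol=cfg.fitting.tol,
        prediction_method=cfg.comparison.prediction_method,
        random_state=seed,
    )
    if name == "m1":
        kwargs["forcing_floor"] = cfg.fitting.m1_forcing_floor
    return get_model(name, **kwargs)


def fit_collection(
    cfg: PipelineConfig,
    train_events: pd.DataFrame,
    temperatures: TemperatureCollection,
    model_names=None,
    seed_offset: int = 0,
) -> dict:
    """Fit every configured model to every species-phenophase group.

    Returns ``{model_name: {(species, phenophase_class): fitted estimator}}``.
    """
    model_names = model_names or cfg.models
    fitted = {name: {} for name in model_names}
    for gi, (group, events) in enumerate(train_events.groupby(_GROUP, sort=True)):
        X, y = build_design_matrix(events, temperatures)
        for mi, name in enumerate(model_names):
            seed = int(
                np.random.SeedSequence(
                    [cfg.seed, seed_offset, gi, mi]
                ).generate_state(1)[0] % (2**31 - 1)
            )
            model = _make_model(cfg, name, seed)
            model.fit(X, y)
            fitted[name][group] = model
            logger.info(
                "fit %s to %s (n=%d): train RMSE %.2f d", name, group, len(events),
                model.rmse_train_,
            )
    return fitted


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full experiment; returns the comparison report dict.

    Artifacts (events, fitted models, comparison CSV/JSON) are written under
    ``paths.output_dir``, stamped with the config hash and seed.
    """
    out = cfg.paths.output_dir
    os.makedirs(out, exist_ok=True)

    status_int, status_broad, temperatures, sites = _load_inputs(cfg)
    scale_of = sites.set_index("site_id")["scale"].to_dict() if "scale" in sites else {}

    events = {}
    for label, status in [("intensive", status_int), ("broad", status_broad)]:
        ev = prepare(cfg, status)
        if ev.empty:
            raise RuntimeError(f"stage prepare[{label}]: no events survived filtering")
        events[label] = ev
        ev.to_csv(os.path.join(out, f"events_{label}.csv"), index=False)

    # keep only species-phenophase groups present in both datasets
    shared = set(map(tuple, events["intensive"][_GROUP].drop_duplicates().to_numpy()))
    shared &= set(map(tuple, events["broad"][_GROUP].drop_duplicates().to_numpy()))
    if len(shared) < 3:
        raise RuntimeError(
            f"stage prepare: only {len(shared)} shared species-phenophase groups; "
            "need >= 3 for comparison"
        )
    for label in events:
        mask = events[label][_GROUP].apply(tuple, axis=1).isin(shared)
        events[label] = events[label][mask]

    splits = {
        label: holdout_split(
            ev, fraction=cfg.fitting.holdout_fraction,
            seed=np.random.SeedSequence([cfg.seed, 11, i]).generate_state(1)[0] % (2**31),
        )
        for i, (label, ev) in enumerate(events.items())
    }

    collections = {
        label: fit_collection(cfg, split.train_events, temperatures, seed_offset=i)
        for i, (label, split) in enumerate(splits.items())
    }

    # pooled holdout events, tagged with the scale they were observed at
    holdout = pd.concat(
        [splits["intensive"].test_events, splits["broad"].test_events],
        ignore_index=True,
    )
    holdout["scale"] = holdout["site_id"].map(scale_of)
    X_hold, _ = build_design_matrix(holdout, temperatures)

    report = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_groups": len(shared),
        "models": {},
    }
    rows = []
    for name in cfg.models:
        coll_a = collections["intensive"][name]
        coll_b = collections["broad"][name]
        res = cmp.ComparisonResult(model_name=name)
        res.parameter_r2 = cmp.compare_parameters(coll_a, coll_b)
        res.prediction_r2 = cmp.compare_predictions(coll_a, coll_b, holdout, X_hold)
        for scale in ("intensive", "broad"):
            sub = holdout[holdout["scale"] == scale]
            X_sub, _ = build_design_matrix(sub, temperatures)
            diff = cmp.rmse_difference_tests(
                coll_a, coll_b, sub, X_sub,
                prediction_method=cfg.comparison.prediction_method,
            )
            res.rmse_difference[scale] = diff
        report["models"][name] = {
            "parameter_r2": res.parameter_r2,
            "prediction_r2": res.prediction_r2,
            "rmse_difference": {
                scale: {
                    "mean_diff": d.mean_diff,
                    "t_stat": d.t_stat,
                    "p_value": d.p_value,
                    "degenerate": d.degenerate,
                    "n_groups": len(d.groups),
                }
                for scale, d in res.rmse_difference.items()
            },
        }
        for pname, r2 in res.parameter_r2.items():
            rows.append({"model": name, "kind": "parameter_r2", "key": pname, "value": r2})
        for scale, r2 in res.prediction_r2.items():
            rows.append({"model": name, "kind": "prediction_r2", "key": scale, "value": r2})
        for scale, d in res.rmse_difference.items():
            rows.append({"model": name, "kind": "mean_rmse_diff", "key": scale,
                         "value": d.mean_diff})

        for label in collections:
            for group, model in collections[label][name].items():
                tag = f"{name}_{label}_{group[0]}_{group[1]}"
                save_fitted_model(
                    model,
                    os.path.join(out, f"fit_{tag}.json"),
                    os.path.join(out, f"bootstrap_{tag}.csv"),
                )

    pd.DataFrame(rows).to_csv(os.path.join(out, "comparison_report.csv"), index=False)
    with open(os.path.join(out, "comparison_report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    logger.info("pipeline complete: %d models, %d groups", len(cfg.models), len(shared))
    return report
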