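"""Convert raw phenophase status records into inferred event dates.

Status-based monitoring asks an observer, on each visit to a plant, whether a
phenophase (e.g. "breaking leaf buds", "open flowers") is currently present:
"yes", "no", or "unsure".  The event date is never observed directly; it is
censored between the first "yes" and the most recent preceding "no".  The
cleaning rules implemented here:

* "unsure" records are dropped;
* duplicate records for one plant-phenophase-date are collapsed (a yes/no
  tie on the same date resolves to yes, logged);
* per plant, phenophase and calendar year, the first "yes" yields an event
  only if a "no" precedes it by at most ``max_gap_days`` (default 30; 15 is
  the stricter sensitivity setting), and the event day of year (DOY) is the
  midpoint of the two dates — half-integers are kept;
* late outliers are cut: budburst events past DOY 172 and flowering events
  past DOY 213 are dropped;
* species-phenophase groups with too few events (default: fewer than 30)
  are dropped, counting after the cutoff filter.

Individual plants are never pooled to one site-level record: within-site
variability is part of the signal.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "PHENOPHASE_CLASSES",
    "DOY_CUTOFFS",
    "classify_phenophase",
    "infer_events",
    "apply_doy_cutoffs",
    "apply_minimum_count",
    "binarize_intensive_metrics",
    "prepare_events",
]

logger = logging.getLogger(__name__)

#: Map from recognised phenophases to the two analysis classes.
PHENOPHASE_CLASSES = {
    "breaking_leaf_buds": "budburst",
    "breaking_needle_buds": "budburst",
    "emerging_needles": "budburst",
    "open_flowers": "flowers",
}

#: Latest admissible event DOY per class ("past" the cutoff means strictly later).
DOY_CUTOFFS = {"budburst": 172, "flowers": 213}

STATUS_COLUMNS = ["individual_id", "site_id", "species", "phenophase", "date", "status"]
EVENT_COLUMNS = ["species", "phenophase_class", "site_id", "individual_id", "year", "doy"]


def classify_phenophase(phenophase: str) -> str:
    """Map a phenophase name to its analysis class (budburst or flowers)."""
    try:
        return PHENOPHASE_CLASSES[phenophase]
    except KeyError:
        raise ValueError(
            f"unrecognised phenophase {phenophase!r}; accepted values: "
            f"{sorted(PHENOPHASE_CLASSES)}"
        ) from None


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame({
        "species": pd.Series(dtype=str),
        "phenophase_class": pd.Series(dtype=str),
        "site_id": pd.Series(dtype=str),
        "individual_id": pd.Series(dtype=str),
        "year": pd.Series(dtype=int),
        "doy": pd.Series(dtype=float),
    })


def infer_events(records: pd.DataFrame, max_gap_days: int = 30) -> pd.DataFrame:
    """Infer one event per plant-phenophase-year from yes/no status records.

    The event DOY is the midpoint between the first "yes" of the year and the
    most recent preceding "no"; a "yes" with no "no" within ``max_gap_days``
    yields no event (counted and logged, not an error).

    Returns a table with columns ``species, phenophase_class, site_id,
    individual_id, year, doy``.
    """
    missing = [c for c in STATUS_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"status table lacks column(s) {missing}")
    rec = records.copy()
    rec["date"] = pd.to_datetime(rec["date"])

    n_unsure = int((rec["status"] == "unsure").sum())
    if n_unsure:
        logger.info("dropping %d 'unsure' records", n_unsure)
    rec = rec[rec["status"].isin(["yes", "no"])]

    # collapse duplicates: yes wins a same-date tie
    key = ["individual_id", "site_id", "species", "phenophase", "date"]
    dup = rec.duplicated(subset=key, keep=False)
    if dup.any():
        ties = (
            rec[dup].groupby(key)["status"].nunique() > 1
        ).sum()
        if ties:
            logger.info("%d same-date yes/no ties resolved to yes", int(ties))
        rec = (
            rec.sort_values("status", ascending=False)  # 'yes' > 'no'
            .drop_duplicates(subset=key, keep="first")
        )

    rec["year"] = rec["date"].dt.year
    rec["doy"] = rec["date"].dt.dayofyear

    events = []
    n_unmatched = 0
    group_cols = ["individual_id", "site_id", "species", "phenophase", "year"]
    for (ind, site, species, phase, year), grp in rec.groupby(group_cols, sort=True):
        grp = grp.sort_values("date")
        yes = grp[grp["status"] == "yes"]
        if yes.empty:
            continue
        first_yes = yes.iloc[0]
        prior_no = grp[(grp["status"] == "no") & (grp["date"] < first_yes["date"])]
        if prior_no.empty:
            n_unmatched += 1
            continue
        last_no = prior_no.iloc[-1]
        gap = (first_yes["date"] - last_no["date"]).days
        if gap > max_gap_days:
            n_unmatched += 1
            continue
        events.append({
            "species": species,
            "phenophase_class": classify_phenophase(phase),
            "site_id": site,
            "individual_id": ind,
            "year": int(year),
            "doy": (float(first_yes["doy"]) + float(last_no["doy"])) / 2.0,
        })
    if n_unmatched:
        logger.info(
            "%d first-yes records had no 'no' within %d d and were dropped",
            n_unmatched, max_gap_days,
        )
    if not events:
        return _empty_events()
    return pd.DataFrame(events, columns=EVENT_COLUMNS)


def apply_doy_cutoffs(events: pd.DataFrame, cutoffs: dict | None = None) -> pd.DataFrame:
    """Drop events strictly past the per-class DOY cutoff (172 / 213)."""
    cutoffs = cutoffs or DOY_CUTOFFS
    limit = events["phenophase_class"].map(cutoffs)
    if limit.isna().any():
        bad = sorted(events.loc[limit.isna(), "phenophase_class"].unique())
        raise ValueError(f"no DOY cutoff defined for class(es) {bad}")
    keep = events["doy"] <= limit
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("DOY cutoff filter dropped %d late events", n_dropped)
    return events[keep].copy()


def apply_minimum_count(
    events: pd.DataFrame, min_n: int = 30, inclusive: bool = True
) -> pd.DataFrame:
    """Keep only species-phenophase groups with enough events.

    ``inclusive=True`` keeps groups with count >= ``min_n`` (default);
    ``inclusive=False`` requires strictly more than ``min_n``.
    """
    counts = events.groupby(["species", "phenophase_class"])["doy"].transform("size")
    keep = counts >= min_n if inclusive else counts > min_n
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("minimum-count filter dropped %d events in small groups", n_dropped)
    return events[keep].copy()


def binarize_intensive_metrics(
    table: pd.DataFrame, threshold: float = 0.0, metric_column: str = "metric"
) -> pd.DataFrame:
    """Convert a numeric per-visit phenology metric to yes/no status records.

    Intensive-study protocols record quantities such as percent of buds open
    or number of flowering stems; any value strictly above ``threshold``
    (default 0) counts as phenophase presence.
    """
    if metric_column not in table.columns:
        raise ValueError(f"table lacks metric column {metric_column!r}")
    metric = pd.to_numeric(table[metric_column], errors="coerce")
    bad = metric.isna() & table[metric_column].notna()
    if bad.any():
        row = table.index[bad][0]
        raise ValueError(
            f"non-numeric metric value {table.loc[row, metric_column]!r} at row {row}"
        )
    out = table.drop(columns=[metric_column]).copy()
    out["status"] = np.where(metric > threshold, "yes", "no")
    return out[[c for c in STATUS_COLUMNS if c in out.columns] ]


def prepare_events(
    records: pd.DataFrame,
    max_gap_days: int = 30,
    cutoffs: dict | None = None,
    min_n: int = 30,
    min_n_inclusive: bool = True,
) -> pd.DataFrame:
    """Full cleaning pipeline: infer events, cut late outliers, drop small groups."""
    events = infer_events(records, max_gap_days=max_gap_days)
    events = apply_doy_cutoffs(events, cutoffs=cutoffs)
    events = apply_minimum_count(events, min_n=min_n, inclusive=min_n_inclusive)
    logger.info("prepared %d events", len(events))
    return events
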