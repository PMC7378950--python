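"""Comparing two fitted-model collections across observation scales.

The scientific question: do phenology models fit to intensive, single-site
monitoring data and to sparse, broad-scale (citizen-science style) data agree
— in their parameters, in their predicted event dates, and in out-of-sample
error?  A *collection* here is a mapping from species-phenophase group to a
fitted model (one model type per collection object); the "A" collection is
conventionally the intensive-data fit and "B" the broad-scale fit.

Three comparisons:

1. **Parameter agreement** — for each parameter, pair the bootstrap-mean
   values across groups and score agreement with the 1:1 line
   (:func:`identity_line_r2`).
2. **Prediction agreement** — pair the two collections' mean-of-bootstrap
   predictions on held-out events, scored with the same identity-line R²,
   separately per evaluation scale.
3. **Out-of-sample error** — per group, the difference in holdout RMSE
   (A minus B) on the same events, with a one-sample two-sided t-test of
   mean difference = 0.  Negative values mean the intensive-derived model
   predicts better.

The identity-line R², 1 - sum((y-x)^2) / sum((y-ybar)^2), measures deviation
from the 1:1 line relative to the variance of y and is unbounded below:
negative values mean agreement is worse than simply predicting the mean.
No multiple-testing correction is applied to the t-tests; raw p-values are
reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import rmse

__all__ = [
    "identity_line_r2",
    "pearson_correlation",
    "compare_parameters",
    "compare_predictions",
    "rmse_difference_tests",
    "RMSEDifferenceResult",
    "ComparisonResult",
]

logger = logging.getLogger(__name__)


def identity_line_r2(x, y) -> float:
    """Agreement of paired values with the 1:1 line.

    ``1 - sum((y_i - x_i)^2) / sum((y_i - mean(y))^2)``.  Equals 1 when
    x == y exactly; can be negative when the 1:1 line fits worse than the
    mean of ``y``.

    Raises
    ------
    ValueError
        If fewer than 3 pairs, or ``y`` has zero variance (undefined result).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 pairs, got {x.size}")
    ss_res = float(np.sum((y - x) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("y has zero variance; identity-line R2 undefined")
    return 1.0 - ss_res / ss_tot


def pearson_correlation(x, y) -> float:
    """Pearson correlation coefficient of two paired samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError(f"need at least 3 pairs, got {x.size}")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("constant input; Pearson correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class RMSEDifferenceResult:
    """Holdout RMSE differences (A minus B) per group, with a t-test."""

    groups: list
    diffs: np.ndarray
    mean_diff: float
    t_stat: float
    p_value: float
    degenerate: bool = False  # zero variance of differences: t undefined


@dataclass
class ComparisonResult:
    """All three comparisons for one model type."""

    model_name: str
    parameter_r2: dict = field(default_factory=dict)
    prediction_r2: dict = field(default_factory=dict)
    rmse_difference: dict = field(default_factory=dict)
    pearson_r: dict = field(default_factory=dict)


def _common_groups(collection_a: dict, collection_b: dict) -> list:
    common = sorted(set(collection_a) & set(collection_b))
    skipped = set(collection_a) ^ set(collection_b)
    if skipped:
        logger.info("groups present in only one collection skipped: %s", sorted(skipped))
    return common


def compare_parameters(collection_a: dict, collection_b: dict) -> dict:
    """Per-parameter identity-line R² of bootstrap-mean parameter values.

    ``collection_a`` / ``collection_b`` map species-phenophase group keys to
    fitted estimators of the same model type.  The A (intensive) value is x
    and the B (broad) value is y, so the variance anchoring the R² is that
    of the broad-scale collection.
    """
    common = _common_groups(collection_a, collection_b)
    if len(common) < 3:
        raise ValueError(f"need >= 3 shared groups, got {len(common)}")
    names = collection_a[common[0]].parameter_names
    out = {}
    for j, pname in enumerate(names):
        x = np.array([collection_a[g].bootstrap_params_[:, j].mean() for g in common])
        y = np.array([collection_b[g].bootstrap_params_[:, j].mean() for g in common])
        try:
            out[pname] = identity_line_r2(x, y)
        except ValueError:
            out[pname] = float("nan")
    return out


def _paired_holdout_predictions(collection_a, collection_b, holdout_events, X):
    """Mean-of-bootstrap predictions from both collections for each event."""
    pred_a = np.full(len(holdout_events), np.nan)
    pred_b = np.full(len(holdout_events), np.nan)
    pos = {idx: i for i, idx in enumerate(holdout_events.index)}
    for g, grp in holdout_events.groupby(["species", "phenophase_class"], sort=True):
        if g not in collection_a or g not in collection_b:
            continue
        rows = np.array([pos[i] for i in grp.index])
        pred_a[rows] = collection_a[g].predict(X[rows], method="bootstrap_mean")
        pred_b[rows] = collection_b[g].predict(X[rows], method="bootstrap_mean")
    return pred_a, pred_b


def compare_predictions(
    collection_a: dict,
    collection_b: dict,
    holdout_events: pd.DataFrame,
    X: np.ndarray,
    scale_column: str = "scale",
) -> dict:
    """Identity-line R² between the two collections' holdout predictions.

    Computed separately for each evaluation scale in
    ``holdout_events[scale_column]`` (e.g. events at intensive sites vs at
    broad-scale sites).  No-event predictions are excluded pairwise.
    """
    pred_a, pred_b = _paired_holdout_predictions(
        collection_a, collection_b, holdout_events, X
    )
    out = {}
    scales = holdout_events[scale_column].to_numpy()
    for scale in np.unique(scales):
        mask = (scales == scale) & np.isfinite(pred_a) & np.isfinite(pred_b)
        n_dropped = int(((scales == scale) & ~mask).sum())
        if n_dropped:
            logger.info("scale %s: %d events excluded (no-event prediction)", scale, n_dropped)
        out[str(scale)] = identity_line_r2(pred_a[mask], pred_b[mask])
    return out


def rmse_difference_tests(
    collection_a: dict,
    collection_b: dict,
    holdout_events: pd.DataFrame,
    X: np.ndarray,
    prediction_method: str = "bootstrap_mean",
) -> RMSEDifferenceResult:
    """Per-group holdout RMSE difference (A minus B) and its t-test.

    Both collections predict the *same* held-out events of each group, so
    the differences are exactly paired.  Zero variance across groups makes
    the t statistic undefined; the result is then flagged degenerate and
    carries the mean difference only.
    """
    common = _common_groups(collection_a, collection_b)
    if len(common) < 3:
        raise ValueError(f"need >= 3 shared groups, got {len(common)}")
    pos = {idx: i for i, idx in enumerate(holdout_events.index)}
    diffs, groups = [], []
    for g, grp in holdout_events.groupby(["species", "phenophase_class"], sort=True):
        if g not in common:
            continue
        rows = np.array([pos[i] for i in grp.index])
        y = grp["doy"].to_numpy(dtype=float)
        rmse_a = rmse(collection_a[g].predict(X[rows], method=prediction_method), y)
        rmse_b = rmse(collection_b[g].predict(X[rows], method=prediction_method), y)
        diffs.append(rmse_a - rmse_b)
        groups.append(g)
    diffs = np.asarray(diffs)
    mean_diff = float(diffs.mean())
    if np.allclose(diffs, diffs[0]):
        return RMSEDifferenceResult(
            groups=groups, diffs=diffs, mean_diff=mean_diff,
            t_stat=float("nan"), p_value=float("nan"), degenerate=True,
        )
    t_res = stats.ttest_1samp(diffs, popmean=0.0)
    return RMSEDifferenceResult(
        groups=groups, diffs=diffs, mean_diff=mean_diff,
        t_stat=float(t_res.statistic), p_value=float(t_res.pvalue),
    )
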