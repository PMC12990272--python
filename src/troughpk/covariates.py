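"""Per-subject summaries of longitudinal laboratory variables.

Each (subject, variable) series is reduced to three scalars:

- mean over the monitoring period (the "average physiological state");
- baseline at treatment initiation, reported with the ``_baseline`` suffix;
- mean trajectory derivative (units/day), reported with the ``_trajectory``
  suffix: a penalized cubic smoothing spline is fitted to (day, value), the
  smooth is evaluated on a 200-point uniform grid spanning the observed
  range, and the mean of the 199 forward differences is returned.  By
  telescoping this equals (yhat_last - yhat_first) / (day_max - day_min)
  exactly; the gridded form is kept because it mirrors how downstream users
  inspect the fitted trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .cohort import CohortDataset, CovariateSeries

__all__ = [
    "CovariateSummary",
    "GRID_POINTS",
    "summarize_covariate",
    "trajectory_slope",
    "covariate_summary_table",
    "wide_covariate_table",
]

#: Evaluation grid density for the fitted smooth.
GRID_POINTS = 200

#: Minimum observations for the spline smoother; below this an ordinary
#: least-squares line slope is used and flagged.
_MIN_SPLINE_POINTS = 5


@dataclass(frozen=True)
class CovariateSummary:
    subject_id: str
    variable: str
    mean_value: float
    baseline_value: float
    trajectory_slope: float | None
    n_obs: int
    slope_method: str  # "spline" | "ols_fallback" | "unavailable"


def summarize_covariate(series: CovariateSeries, initiation_day: int = 1):
    """(mean, baseline): baseline is the earliest measurement at or before
    treatment initiation, else the first available measurement."""
    if len(series.measurements) == 0:
        raise ValueError(f"{series.subject_id}/{series.variable}: empty covariate series")
    vals = series.values
    days = series.days
    at_or_before = days <= initiation_day
    baseline = float(vals[at_or_before][0]) if at_or_before.any() else float(vals[0])
    return float(np.mean(vals)), baseline


def trajectory_slope(series: CovariateSeries) -> tuple[float, str]:
    """Mean derivative of the smoothed trajectory, units/day.

    Returns (slope, method).  The smoothing parameter is selected by
    generalized cross-validation; with fewer than 5 points the smoother is
    not identifiable and an OLS line slope is returned with method
    ``"ols_fallback"``.  Requires >= 2 distinct days.
    """
    days = series.days.astype(float)
    vals = series.values
    if len(np.unique(days)) < 2:
        raise ValueError(
            f"{series.subject_id}/{series.variable}: trajectory needs >= 2 distinct days")
    if len(days) < _MIN_SPLINE_POINTS:
        slope = float(np.polyfit(days, vals, 1)[0])
        return slope, "ols_fallback"
    spline = make_smoothing_spline(days, vals)  # lam=None -> GCV
    grid = np.linspace(days[0], days[-1], GRID_POINTS)
    yhat = spline(grid)
    step = grid[1] - grid[0]
    slopes = np.diff(yhat) / step
    return float(np.mean(slopes)), "spline"


def covariate_summary_table(dataset: CohortDataset, initiation_day: int = 1) -> pd.DataFrame:
    """Long table: subject_id, variable, kind{mean,baseline,trajectory}, value."""
    rows = []
    for (sid, var) in sorted(dataset.covariates):
        series = dataset.covariates[(sid, var)]
        mean_v, base_v = summarize_covariate(series, initiation_day=initiation_day)
        rows.append({"subject_id": sid, "variable": var, "kind": "mean", "value": mean_v})
        rows.append({"subject_id": sid, "variable": var, "kind": "baseline", "value": base_v})
        try:
            slope, _method = trajectory_slope(series)
        except ValueError:
            slope = np.nan
        rows.append({"subject_id": sid, "variable": var, "kind": "trajectory", "value": slope})
    return pd.DataFrame(rows, columns=["subject_id", "variable", "kind", "value"])


def wide_covariate_table(long_table: pd.DataFrame) -> pd.DataFrame:
    """Pivot to one row per subject; columns use the `_baseline` /
    `_trajectory` suffix convention (mean summaries keep the bare name)."""
    df = long_table.copy()
    suffix = {"mean": "", "baseline": "_baseline", "trajectory": "_trajectory"}
    df["column"] = df.variable + df.kind.map(suffix)
    wide = df.pivot(index="subject_id", columns="column", values="value")
    wide.columns.name = None
    return wide.reset_index()
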