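"""Trough-derived surrogate pharmacokinetic endpoints.

Because intensive post-dose sampling is infeasible immediately after
transplantation, exposure is summarized from the longitudinal trough
profile itself.  Five per-subject endpoints are computed:

- ``c0_max``: highest observed trough (ng/mL) — accumulation plateau proxy;
- ``t_c0_max``: 1-based day of that maximum (earliest on ties) — a
  time-to-steady-state surrogate, not a single-dose Tmax;
- ``auc_c0_time``: linear-trapezoid area under the trough-versus-day curve
  over the monitoring window (ng*day/mL), a partial cumulative exposure;
- ``avg_accumulation_ratio``: mean of within-subject ratios of each trough
  to the first measurable trough (the first ratio is exactly 1);
- ``auc_per_dose``: auc_c0_time divided by cumulative dose, a
  dose-normalized exposure index.

``remove_outliers`` implements the Tukey-hinge boxplot fence (the R
``boxplot.stats`` convention: hinges from the five-number summary, fences
at hinge +/- 1.5 * hinge-IQR, values strictly outside are removed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortDataset, DoseHistory, TroughSeries

__all__ = [
    "PkSurrogates",
    "PK_ENDPOINTS",
    "remove_outliers",
    "tukey_fences",
    "compute_auc",
    "compute_peak",
    "accumulation_index",
    "compute_pk_surrogates",
    "pk_table",
]

#: Endpoint column order used throughout the pipeline.
PK_ENDPOINTS = ("c0_max", "t_c0_max", "auc_c0_time", "avg_accumulation_ratio", "auc_per_dose")


@dataclass(frozen=True)
class PkSurrogates:
    subject_id: str
    c0_max: float
    t_c0_max: int
    auc_c0_time: float
    avg_accumulation_ratio: float
    auc_per_dose: float
    accumulation_index: tuple[tuple[int, float], ...]


def _fivenum(x: np.ndarray) -> np.ndarray:
    """Tukey five-number summary (min, lower hinge, median, upper hinge, max)."""
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    n4 = np.floor((n + 3) / 2) / 2.0
    d = np.array([1.0, n4, (n + 1) / 2.0, n + 1 - n4, float(n)])
    return 0.5 * (x[np.floor(d).astype(int) - 1] + x[np.ceil(d).astype(int) - 1])


def tukey_fences(values, coef: float = 1.5) -> tuple[float, float]:
    """Lower/upper boxplot fences: hinge -/+ coef * (upper hinge - lower hinge)."""
    fn = _fivenum(np.asarray(values, dtype=float))
    iqr = fn[3] - fn[1]
    return fn[1] - coef * iqr, fn[3] + coef * iqr


def remove_outliers(values, coef: float = 1.5) -> tuple[np.ndarray, np.ndarray]:
    """Drop values strictly outside the Tukey-hinge fences.

    Returns (kept values in original order, removed positions).  NaNs are
    ignored for fence computation and never removed (they are missing, not
    outlying).  Raises if every finite value would be removed.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if not finite.any():
        raise ValueError("remove_outliers requires at least one finite value")
    lo, hi = tukey_fences(x[finite], coef=coef)
    removed_mask = finite & ((x < lo) | (x > hi))
    if removed_mask.sum() == finite.sum():
        raise ValueError("degenerate input: all finite values flagged as outliers")
    removed = np.flatnonzero(removed_mask)
    return x[~removed_mask], removed


def compute_auc(series: TroughSeries) -> float:
    """Linear trapezoidal area under the trough-day curve (ng*day/mL)."""
    if len(series) < 2:
        raise ValueError(f"{series.subject_id}: AUC requires >= 2 observations")
    return float(np.trapezoid(series.concentrations, series.days))


def compute_peak(series: TroughSeries) -> tuple[float, int]:
    """(c0_max, t_c0_max); ties broken by the earliest day."""
    if len(series) == 0:
        raise ValueError(f"{series.subject_id}: empty trough series")
    conc = series.concentrations
    i = int(np.argmax(conc))  # first occurrence = earliest day (days sorted)
    return float(conc[i]), int(series.days[i])


def accumulation_index(series: TroughSeries) -> tuple[tuple[tuple[int, float], ...], float]:
    """Per-day ratio to the first measurable trough, and the mean ratio.

    The first ratio is exactly 1 and is included in the mean.
    """
    if len(series) == 0:
        raise ValueError(f"{series.subject_id}: empty trough series")
    c0 = series.concentrations[0]
    if not c0 > 0:
        raise ValueError(f"{series.subject_id}: first measurable trough must be > 0")
    ratios = series.concentrations / c0
    ratios[0] = 1.0
    idx = tuple((int(d), float(r)) for d, r in zip(series.days, ratios))
    return idx, float(np.mean(ratios))


def compute_pk_surrogates(series: TroughSeries, dose_history: DoseHistory) -> PkSurrogates:
    """Assemble the five endpoints for one subject."""
    if series.subject_id != dose_history.subject_id:
        raise ValueError(
            f"subject mismatch: troughs {series.subject_id} vs doses {dose_history.subject_id}")
    total = dose_history.total_dose
    if not total > 0:
        raise ValueError(f"{series.subject_id}: total dose must be > 0 for dose-normalized AUC")
    try:
        auc = compute_auc(series)
        c0_max, t_c0_max = compute_peak(series)
        idx, avg_ratio = accumulation_index(series)
    except ValueError as exc:
        raise ValueError(f"subject {series.subject_id}: {exc}") from exc
    return PkSurrogates(
        subject_id=series.subject_id,
        c0_max=c0_max,
        t_c0_max=t_c0_max,
        auc_c0_time=auc,
        avg_accumulation_ratio=avg_ratio,
        auc_per_dose=auc / total,
        accumulation_index=idx,
    )


def pk_table(dataset: CohortDataset) -> pd.DataFrame:
    """Per-subject endpoint table (one row per subject with >= 2 troughs)."""
    rows = []
    for sid in sorted(dataset.troughs):
        ts = dataset.troughs[sid]
        if len(ts) < 2:
            continue
        pk = compute_pk_surrogates(ts, dataset.doses[sid])
        rows.append({
            "subject_id": sid,
            "c0_max": pk.c0_max,
            "t_c0_max": pk.t_c0_max,
            "auc_c0_time": pk.auc_c0_time,
            "avg_accumulation_ratio": pk.avg_accumulation_ratio,
            "auc_per_dose": pk.auc_per_dose,
            "total_dose": dataset.doses[sid].total_dose,
        })
    return pd.DataFrame(rows, columns=["subject_id", *PK_ENDPOINTS, "total_dose"])
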