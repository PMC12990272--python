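"""Shared fixtures: small hand-built cohorts and generator shortcuts."""

import numpy as np
import pytest
from hypothesis import settings

from troughpk.cohort import CohortDataset, CovariateSeries, DoseHistory, TroughSeries

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


def make_series(sid, days, concs, **kw) -> TroughSeries:
    return TroughSeries(sid, tuple((int(d), float(c)) for d, c in zip(days, concs)), **kw)


def make_dataset(trough_map, dose=3.0, covariates=None) -> CohortDataset:
    """Build a cohort from {subject: (days, concs)} with flat daily dosing."""
    troughs, doses = {}, {}
    for sid, (days, concs) in trough_map.items():
        troughs[sid] = make_series(sid, days, concs)
        doses[sid] = DoseHistory(sid, tuple((int(d), dose) for d in range(1, max(days) + 1)))
    return CohortDataset(troughs=troughs, doses=doses, covariates=covariates or {})


@pytest.fixture
def three_subject_dataset() -> CohortDataset:
    rng = np.random.default_rng(7)
    trough_map = {
        f"P{i}": (list(range(1, 11)), (5 + rng.random(10) * 3).round(3).tolist())
        for i in range(3)
    }
    ds = make_dataset(trough_map)
    ds.covariates[("P0", "ALT")] = CovariateSeries(
        "P0", "ALT", ((0, 120.0), (3, 100.0), (7, 80.0)))
    return ds
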