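"""Domain types, validation, and CSV round-trip for trough-monitoring cohorts.

A cohort bundles, per transplant recipient, the longitudinal tacrolimus
trough concentrations measured under routine therapeutic drug monitoring,
the daily oral doses, longitudinal clinical laboratory covariates,
recipient/donor SNP genotypes, and antibiotic co-medication flags.

Day convention: day 1 is the first day of tacrolimus administration
(initiated within hours of surgery); covariates may additionally carry a
pre-initiation baseline at day 0.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_LLOQ",
    "LOCUS_ALLELES",
    "ANTIBIOTIC_DRUGS",
    "SchemaError",
    "CohortValidationError",
    "TroughSeries",
    "DoseHistory",
    "CovariateSeries",
    "GenotypeRecord",
    "AntibioticExposure",
    "CohortDataset",
    "read_cohort",
    "write_cohort",
]

#: Lower limit of quantification of the whole-blood immunoassay, ng/mL.
DEFAULT_LLOQ = 0.5

#: Declared allele sets for the genotyped loci (ABCB1 in recipients,
#: CYP3A5/CYP3A4 in donors).
LOCUS_ALLELES: dict[str, frozenset[str]] = {
    "rs1045642": frozenset("CT"),
    "rs2032582": frozenset("ACT"),
    "rs776746": frozenset("AG"),
    "rs15524": frozenset("AG"),
    "rs2242480": frozenset("CT"),
    "rs2246709": frozenset("AG"),
    "rs4646437": frozenset("AG"),
}

#: Antibiotics recorded as binary exposure flags.
ANTIBIOTIC_DRUGS = (
    "cefoperazone_sulbactam",
    "ceftazidime",
    "cefuroxime",
    "ceftriaxone_sodium",
    "meropenem",
    "vancomycin",
    "cefotaxime_sodium",
)


class SchemaError(ValueError):
    """A CSV file does not match its declared schema."""


class CohortValidationError(ValueError):
    """A dataset violates a declared invariant.

    Attributes
    ----------
    reason : str
        Machine-readable reason code, e.g. ``"duplicate_trough_day"``.
    """

    def __init__(self, reason: str, message: str):
        self.reason = reason
        super().__init__(f"[{reason}] {message}")


def _as_int_day(day, context: str, minimum: int = 1) -> int:
    d = int(day)
    if d != day or d < minimum:
        raise CohortValidationError(
            "bad_day", f"{context}: day must be an integer >= {minimum}, got {day!r}"
        )
    return d


@dataclass(frozen=True)
class TroughSeries:
    """One subject's (day, trough concentration) measurements.

    Concentrations below ``lloq`` are not retained as observations; their
    days are recorded in ``censored_days``.  ``imputed_days`` marks
    observations that were filled in by the mixed-model imputation stage
    rather than measured.
    """

    subject_id: str
    observations: tuple[tuple[int, float], ...]
    lloq: float = DEFAULT_LLOQ
    censored_days: frozenset[int] = frozenset()
    imputed_days: frozenset[int] = frozenset()

    def __post_init__(self):
        obs = tuple((_as_int_day(d, f"trough {self.subject_id}"), float(c))
                    for d, c in self.observations)
        object.__setattr__(self, "observations", obs)
        object.__setattr__(self, "censored_days", frozenset(int(d) for d in self.censored_days))
        object.__setattr__(self, "imputed_days", frozenset(int(d) for d in self.imputed_days))
        days = [d for d, _ in obs]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise CohortValidationError(
                "days_not_increasing",
                f"trough days for {self.subject_id} must be strictly increasing: {days}",
            )
        for d, c in obs:
            if not math.isfinite(c) or c < self.lloq:
                raise CohortValidationError(
                    "below_lloq",
                    f"{self.subject_id} day {d}: retained concentration {c} < LLOQ {self.lloq}",
                )
        unknown = self.imputed_days - set(days)
        if unknown:
            raise CohortValidationError(
                "imputed_not_observed",
                f"{self.subject_id}: imputed_days {sorted(unknown)} not among observation days",
            )

    @property
    def days(self) -> np.ndarray:
        return np.array([d for d, _ in self.observations], dtype=int)

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for _, c in self.observations], dtype=float)

    def __len__(self) -> int:
        return len(self.observations)


@dataclass(frozen=True)
class DoseHistory:
    """Per-day tacrolimus doses (mg) for one subject."""

    subject_id: str
    records: tuple[tuple[int, float], ...]

    def __post_init__(self):
        recs = tuple((_as_int_day(d, f"dose {self.subject_id}"), float(v))
                     for d, v in self.records)
        object.__setattr__(self, "records", recs)
        for d, v in recs:
            if not math.isfinite(v) or v < 0:
                raise CohortValidationError(
                    "negative_dose", f"{self.subject_id} day {d}: dose {v} mg < 0"
                )

    @property
    def total_dose(self) -> float:
        """Cumulative dose over the monitoring window, mg (exact sum)."""
        return float(math.fsum(v for _, v in self.records))


@dataclass(frozen=True)
class CovariateSeries:
    """Longitudinal measurements of one laboratory variable for one subject."""

    subject_id: str
    variable: str
    measurements: tuple[tuple[int, float], ...]

    def __post_init__(self):
        meas = tuple((_as_int_day(d, f"covariate {self.subject_id}/{self.variable}", minimum=0),
                      float(v)) for d, v in self.measurements)
        object.__setattr__(self, "measurements", meas)
        days = [d for d, _ in meas]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise CohortValidationError(
                "duplicate_covariate_day",
                f"{self.subject_id}/{self.variable}: at most one value per day, "
                f"days must increase: {days}",
            )

    @property
    def days(self) -> np.ndarray:
        return np.array([d for d, _ in self.measurements], dtype=int)

    @property
    def values(self) -> np.ndarray:
        return np.array([v for _, v in self.measurements], dtype=float)


@dataclass(frozen=True)
class GenotypeRecord:
    """One SNP call; the allele pair is unordered and stored sorted ("CA" == "AC")."""

    subject_id: str
    origin: str  # "recipient" | "donor"
    locus: str
    genotype: str

    def __post_init__(self):
        if self.origin not in ("recipient", "donor"):
            raise CohortValidationError(
                "bad_origin", f"origin must be recipient|donor, got {self.origin!r}"
            )
        g = "".join(sorted(self.genotype.strip().upper()))
        if len(g) != 2 or not g.isalpha():
            raise CohortValidationError(
                "bad_genotype", f"{self.subject_id} {self.locus}: genotype {self.genotype!r}"
            )
        alleles = LOCUS_ALLELES.get(self.locus)
        if alleles is not None and not set(g) <= alleles:
            raise CohortValidationError(
                "allele_not_declared",
                f"{self.subject_id} {self.locus}: alleles {g} not in {sorted(alleles)}",
            )
        object.__setattr__(self, "genotype", g)


@dataclass(frozen=True)
class AntibioticExposure:
    subject_id: str
    drug: str
    exposed: bool


@dataclass
class CohortDataset:
    """All cohort components, keyed by subject id.

    Invariants: every trough subject has a dose history, and every component
    subject id is in ``subjects``.
    """

    troughs: dict[str, TroughSeries] = field(default_factory=dict)
    doses: dict[str, DoseHistory] = field(default_factory=dict)
    covariates: dict[tuple[str, str], CovariateSeries] = field(default_factory=dict)
    genotypes: dict[tuple[str, str, str], GenotypeRecord] = field(default_factory=dict)
    antibiotics: dict[tuple[str, str], AntibioticExposure] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self):
        self.validate()

    @property
    def subjects(self) -> list[str]:
        ids = set(self.troughs) | set(self.doses)
        ids |= {s for s, _ in self.covariates}
        ids |= {s for s, _, _ in self.genotypes}
        ids |= {s for s, _ in self.antibiotics}
        return sorted(ids)

    def validate(self) -> None:
        for sid in self.troughs:
            if sid not in self.doses:
                raise CohortValidationError(
                    "trough_without_dose", f"subject {sid} has troughs but no dose history"
                )
        for key, ts in self.troughs.items():
            if key != ts.subject_id:
                raise CohortValidationError("key_mismatch", f"trough key {key} != {ts.subject_id}")
        for key, dh in self.doses.items():
            if key != dh.subject_id:
                raise CohortValidationError("key_mismatch", f"dose key {key} != {dh.subject_id}")

    def config_hash(self) -> str:
        h = hashlib.sha256()
        for sid in self.subjects:
            h.update(sid.encode())
            ts = self.troughs.get(sid)
            if ts is not None:
                h.update(repr(ts.observations).encode())
                h.update(repr(sorted(ts.censored_days)).encode())
        return h.hexdigest()[:16]

    def genotype_of(self, origin: str, locus: str) -> dict[str, str]:
        """Map subject -> genotype string for one (origin, locus)."""
        return {
            s: rec.genotype
            for (s, o, l), rec in self.genotypes.items()
            if o == origin and l == locus
        }

    def exposure_of(self, drug: str) -> dict[str, bool]:
        return {s: rec.exposed for (s, d), rec in self.antibiotics.items() if d == drug}


# ---------------------------------------------------------------------------
# CSV schemas
# ---------------------------------------------------------------------------

_SCHEMAS = {
    "troughs.csv": ["subject_id", "day", "concentration_ng_ml"],
    "doses.csv": ["subject_id", "day", "dose_mg"],
    "covariates.csv": ["subject_id", "day", "variable", "value"],
    "genotypes.csv": ["subject_id", "origin", "rsid", "genotype"],
    "antibiotics.csv": ["subject_id", "drug", "exposed"],
}


def _read_csv(path, name: str) -> pd.DataFrame:
    # round_trip float parsing keeps write->read exact to the last ulp
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    for col in _SCHEMAS[name]:
        if col not in df.columns:
            raise SchemaError(f"{name}: missing required column {col!r}")
    return df


def read_cohort(
    trough_path,
    dose_path,
    covariate_path,
    genotype_path,
    antibiotic_path,
    lloq: float = DEFAULT_LLOQ,
) -> CohortDataset:
    """Load and validate a cohort from its five canonical CSVs.

    Trough rows with concentration below ``lloq`` (or empty, the round-trip
    encoding of a censored day) are excluded from observations and recorded
    in ``censored_days``.  Malformed rows raise with 1-based data line
    numbers (header = line 1).
    """
    tr = _read_csv(trough_path, "troughs.csv")
    do = _read_csv(dose_path, "doses.csv")
    cv = _read_csv(covariate_path, "covariates.csv")
    gt = _read_csv(genotype_path, "genotypes.csv")
    ab = _read_csv(antibiotic_path, "antibiotics.csv")

    has_imputed = "imputed" in tr.columns
    troughs: dict[str, TroughSeries] = {}
    for sid, grp in tr.groupby("subject_id", sort=True):
        obs, censored, imputed = [], set(), set()
        seen = {}
        for idx, row in grp.iterrows():
            line = idx + 2  # header line 1
            try:
                day = int(row["day"])
            except (TypeError, ValueError):
                raise SchemaError(f"troughs.csv line {line}: non-integer day {row['day']!r}")
            if day in seen:
                raise CohortValidationError(
                    "duplicate_trough_day",
                    f"troughs.csv line {line}: duplicate (subject {sid}, day {day}), "
                    f"first at line {seen[day]}",
                )
            seen[day] = line
            conc = row["concentration_ng_ml"]
            if pd.isna(conc):
                censored.add(day)
                continue
            try:
                conc = float(conc)
            except (TypeError, ValueError):
                raise SchemaError(
                    f"troughs.csv line {line}: non-numeric concentration {conc!r}"
                )
            if conc < lloq:
                censored.add(day)
                continue
            obs.append((day, conc))
            if has_imputed and bool(row["imputed"]):
                imputed.add(day)
        obs.sort()
        troughs[sid] = TroughSeries(
            subject_id=sid,
            observations=tuple(obs),
            lloq=lloq,
            censored_days=frozenset(censored),
            imputed_days=frozenset(imputed),
        )

    doses: dict[str, DoseHistory] = {}
    for sid, grp in do.groupby("subject_id", sort=True):
        recs = sorted((int(r["day"]), float(r["dose_mg"])) for _, r in grp.iterrows())
        doses[sid] = DoseHistory(subject_id=sid, records=tuple(recs))

    covariates: dict[tuple[str, str], CovariateSeries] = {}
    for (sid, var), grp in cv.groupby(["subject_id", "variable"], sort=True):
        meas = sorted((int(r["day"]), float(r["value"])) for _, r in grp.iterrows())
        covariates[(sid, var)] = CovariateSeries(sid, var, tuple(meas))

    genotypes: dict[tuple[str, str, str], GenotypeRecord] = {}
    for idx, row in gt.iterrows():
        rec = GenotypeRecord(str(row["subject_id"]), str(row["origin"]),
                             str(row["rsid"]), str(row["genotype"]))
        key = (rec.subject_id, rec.origin, rec.locus)
        if key in genotypes:
            raise CohortValidationError(
                "duplicate_genotype",
                f"genotypes.csv line {idx + 2}: duplicate record for {key}",
            )
        genotypes[key] = rec

    antibiotics: dict[tuple[str, str], AntibioticExposure] = {}
    for idx, row in ab.iterrows():
        exposed = row["exposed"]
        if isinstance(exposed, str):
            exposed = exposed.strip().lower() in ("true", "yes", "1")
        rec = AntibioticExposure(str(row["subject_id"]), str(row["drug"]), bool(exposed))
        key = (rec.subject_id, rec.drug)
        if key in antibiotics:
            raise CohortValidationError(
                "duplicate_antibiotic",
                f"antibiotics.csv line {idx + 2}: duplicate record for {key}",
            )
        antibiotics[key] = rec

    return CohortDataset(
        troughs=troughs, doses=doses, covariates=covariates,
        genotypes=genotypes, antibiotics=antibiotics,
    )


def write_cohort(dataset: CohortDataset, out_dir) -> dict[str, int]:
    """Write the five canonical CSVs; returns {filename: row count}.

    Censored trough days are written with an empty concentration so the
    round trip preserves them; the ``imputed`` flag column is emitted only
    when the dataset carries imputed observations.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    any_imputed = any(ts.imputed_days for ts in dataset.troughs.values())
    rows = []
    for sid in sorted(dataset.troughs):
        ts = dataset.troughs[sid]
        merged = [(d, c, False) for d, c in ts.observations]
        merged += [(d, None, True) for d in sorted(ts.censored_days)]
        for d, c, _cens in sorted(merged):
            r = {"subject_id": sid, "day": d, "concentration_ng_ml": c}
            if any_imputed:
                r["imputed"] = (d in ts.imputed_days)
            rows.append(r)
    cols = ["subject_id", "day", "concentration_ng_ml"] + (["imputed"] if any_imputed else [])
    pd.DataFrame(rows, columns=cols).to_csv(out / "troughs.csv", index=False)

    dose_rows = [
        {"subject_id": sid, "day": d, "dose_mg": v}
        for sid in sorted(dataset.doses)
        for d, v in dataset.doses[sid].records
    ]
    pd.DataFrame(dose_rows, columns=_SCHEMAS["doses.csv"]).to_csv(out / "doses.csv", index=False)

    cov_rows = [
        {"subject_id": s, "day": d, "variable": v, "value": val}
        for (s, v) in sorted(dataset.covariates)
        for d, val in dataset.covariates[(s, v)].measurements
    ]
    pd.DataFrame(cov_rows, columns=_SCHEMAS["covariates.csv"]).to_csv(
        out / "covariates.csv", index=False)

    gt_rows = [
        {"subject_id": s, "origin": o, "rsid": l, "genotype": dataset.genotypes[(s, o, l)].genotype}
        for (s, o, l) in sorted(dataset.genotypes)
    ]
    pd.DataFrame(gt_rows, columns=_SCHEMAS["genotypes.csv"]).to_csv(
        out / "genotypes.csv", index=False)

    ab_rows = [
        {"subject_id": s, "drug": d, "exposed": dataset.antibiotics[(s, d)].exposed}
        for (s, d) in sorted(dataset.antibiotics)
    ]
    pd.DataFrame(ab_rows, columns=_SCHEMAS["antibiotics.csv"]).to_csv(
        out / "antibiotics.csv", index=False)

    return {
        "troughs.csv": len(rows),
        "doses.csv": len(dose_rows),
        "covariates.csv": len(cov_rows),
        "genotypes.csv": len(gt_rows),
        "antibiotics.csv": len(ab_rows),
    }
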