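"""Dose-adjusted association testing between covariates and PK endpoints.

Continuous covariates: a partial rank correlation controlling for cumulative
dose.  Both the covariate and the endpoint are rank-transformed (average
ranks on ties), each rank vector is regressed by OLS on raw total dose,

    rank(outcome) = alpha0 + alpha1 * total_dose + eta,

and the Spearman correlation between the two residual vectors is reported.
Results are retained only with at least ``min_pairs`` complete pairs
(default 16, i.e. 80% of a 20-subject cohort; for other cohort sizes the
screen uses max(min_pairs, ceil(0.8 n))).

Categorical covariates: the branch depends on a Shapiro–Wilk normality test
of the endpoint (alpha = 0.05).  Normal endpoints are fitted on the original
scale with ``outcome ~ factor + total_dose``; non-normal endpoints are
rank-transformed first.  The factor's partial (drop-one) F and p are
reported.  Dose-normalized endpoints (``auc_c0_time``, ``auc_per_dose``) are
never dose-adjusted.

The genotype-antibiotic interaction model detects aliasing (a rank-deficient
design, e.g. every antibiotic-unexposed subject carrying one genotype) and
falls back to a composite genotype|exposure factor analyzed by dose-adjusted
one-way ANOVA.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .cohort import ANTIBIOTIC_DRUGS, CohortDataset
from .pk import remove_outliers

__all__ = [
    "AssociationResult",
    "DOSE_NORMALIZED_ENDPOINTS",
    "dose_adjusted_spearman",
    "test_categorical",
    "interaction_model",
    "combined_factor",
    "combined_factor_anova",
    "run_association_screen",
    "results_table",
]

#: Endpoints already normalized by (or integrating) dose; never dose-adjusted.
DOSE_NORMALIZED_ENDPOINTS = frozenset({"auc_c0_time", "auc_per_dose"})

DEFAULT_MIN_PAIRS = 16
DEFAULT_SHAPIRO_ALPHA = 0.05


@dataclass(frozen=True)
class AssociationResult:
    outcome: str
    covariate: str
    method: str
    n_complete: int
    statistic: float | None
    p_value: float | None
    dose_adjusted: bool
    notes: str = ""
    extra: dict = field(default_factory=dict)

    @property
    def applicable(self) -> bool:
        return self.p_value is not None


def _complete(*arrays) -> np.ndarray:
    mask = np.ones(len(arrays[0]), dtype=bool)
    for a in arrays:
        a = np.asarray(a)
        if a.dtype.kind in "fiu":
            mask &= np.isfinite(np.asarray(a, dtype=float))
        else:
            mask &= pd.notna(a)
    return mask


def _residualize_on_dose(values: np.ndarray, dose: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones_like(dose), dose])
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    return values - X @ beta


def dose_adjusted_spearman(
    x, y, total_dose,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    outcome: str = "outcome",
    covariate: str = "covariate",
    dose_adjust: bool = True,
) -> AssociationResult:
    """Partial rank correlation of ``x`` and ``y`` given cumulative dose.

    With ``dose_adjust=False`` (dose-normalized endpoints, or constant dose)
    this reduces exactly to the plain Spearman correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dose = np.asarray(total_dose, dtype=float)
    mask = _complete(x, y, dose)
    n = int(mask.sum())
    base = dict(outcome=outcome, covariate=covariate, method="rank_residual_spearman",
                n_complete=n, dose_adjusted=dose_adjust)
    if n < min_pairs:
        return AssociationResult(**base, statistic=None, p_value=None,
                                 notes=f"insufficient pairs (<{min_pairs})")
    x, y, dose = x[mask], y[mask], dose[mask]
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return AssociationResult(**base, statistic=None, p_value=None, notes="constant input")
    if dose_adjust:
        rx = _residualize_on_dose(rx, dose)
        ry = _residualize_on_dose(ry, dose)
    rho, p = stats.spearmanr(rx, ry)
    return AssociationResult(**base, statistic=float(rho), p_value=float(p))


def _factor_partial_f(df: pd.DataFrame, formula: str):
    """Partial (drop-one) F and p for the `factor` term of an OLS fit."""
    fit = smf.ols(formula, data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = anova_lm(fit, typ=2)
    row = table.loc["C(factor)"]
    return float(row["F"]), float(row["PR(>F)"]), fit


def test_categorical(
    outcome, factor, total_dose,
    outcome_name: str = "outcome",
    covariate_name: str = "factor",
    shapiro_alpha: float = DEFAULT_SHAPIRO_ALPHA,
    min_n: int | None = None,
    method_name: str | None = None,
) -> AssociationResult:
    """Dose-adjusted group comparison with a Shapiro–Wilk branched scale.

    Endpoints in :data:`DOSE_NORMALIZED_ENDPOINTS` are fitted without the
    dose term.  Raises on a single-level factor or n < 3 (Shapiro–Wilk is
    undefined below 3 observations).
    """
    y = np.asarray(outcome, dtype=float)
    fac = pd.array(factor)
    dose = np.asarray(total_dose, dtype=float)
    dose_adjust = outcome_name not in DOSE_NORMALIZED_ENDPOINTS
    mask = _complete(y, fac, dose)
    y, fac, dose = y[mask], np.asarray(fac[mask]).astype(str), dose[mask]
    n = len(y)
    levels = pd.unique(fac)
    if len(levels) < 2:
        raise ValueError(f"factor {covariate_name!r} has a single non-empty level")
    if n < 3:
        raise ValueError(f"n={n} < 3: Shapiro-Wilk normality test undefined")
    base = dict(outcome=outcome_name, covariate=covariate_name,
                method=method_name or "lm_anova", n_complete=n, dose_adjusted=dose_adjust)
    if min_n is not None and n < min_n:
        return AssociationResult(**base, statistic=None, p_value=None,
                                 notes=f"insufficient pairs (<{min_n})")
    if np.ptp(y) == 0:
        return AssociationResult(**base, statistic=None, p_value=None, notes="constant input")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        shapiro_p = float(stats.shapiro(y).pvalue)
    normal = shapiro_p >= shapiro_alpha
    df = pd.DataFrame({"y": y if normal else stats.rankdata(y, method="average"),
                       "factor": fac, "dose": dose})
    formula = "y ~ C(factor)" + (" + dose" if dose_adjust else "")
    F, p, fit = _factor_partial_f(df, formula)
    branch = "normal" if normal else "rank"
    method = method_name or ("lm_anova" if normal else "rank_lm_anova")
    base["method"] = method
    return AssociationResult(
        **base, statistic=F, p_value=p,
        notes=f"branch={branch}; shapiro_p={shapiro_p:.4g}",
        extra={"shapiro_p": shapiro_p, "branch": branch,
               "adj_r2": float(fit.rsquared_adj)},
    )


# the name follows the operation it implements; tell pytest it is not a test
test_categorical.__test__ = False  # type: ignore[attr-defined]


def interaction_model(
    outcome, genotype, antibiotic, total_dose=None,
    outcome_name: str = "t_c0_max",
) -> AssociationResult:
    """Linear model outcome ~ genotype + antibiotic + genotype:antibiotic.

    When the interaction columns are aliased (rank-deficient design, e.g.
    one factor level perfectly predicting the other factor) the interaction
    p is not applicable and the additive model's adjusted R-squared is
    reported instead.  ``total_dose`` is optional; when given it enters as
    an additive covariate.
    """
    y = np.asarray(outcome, dtype=float)
    g = pd.array(genotype)
    a = pd.array(antibiotic)
    arrays = [y, g, a]
    if total_dose is not None:
        dose = np.asarray(total_dose, dtype=float)
        arrays.append(dose)
    mask = _complete(*arrays)
    df = pd.DataFrame({
        "y": y[mask],
        "genotype": np.asarray(g[mask]).astype(str),
        "antibiotic": np.asarray(a[mask]).astype(str),
    })
    dose_term = ""
    if total_dose is not None:
        df["dose"] = dose[mask]
        dose_term = " + dose"
    full_formula = f"y ~ C(genotype) * C(antibiotic){dose_term}"
    additive_formula = f"y ~ C(genotype) + C(antibiotic){dose_term}"

    full_model = smf.ols(full_formula, data=df)
    n, p_cols = full_model.exog.shape
    rank = int(np.linalg.matrix_rank(full_model.exog))
    if n <= p_cols:
        raise ValueError(f"fewer complete cases ({n}) than model columns ({p_cols})")
    additive_fit = smf.ols(additive_formula, data=df).fit()
    adj_r2 = float(additive_fit.rsquared_adj)
    base = dict(outcome=outcome_name, covariate="genotype:antibiotic",
                method="interaction_lm", n_complete=n,
                dose_adjusted=total_dose is not None)
    if rank < p_cols:
        return AssociationResult(
            **base, statistic=None, p_value=None,
            notes="aliased: interaction inestimable (collinear factors)",
            extra={"adj_r2_additive": adj_r2, "aliased": True},
        )
    full_fit = full_model.fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = anova_lm(full_fit, typ=2)
    row = table.loc["C(genotype):C(antibiotic)"]
    return AssociationResult(
        **base, statistic=float(row["F"]), p_value=float(row["PR(>F)"]),
        notes="full-rank interaction",
        extra={"adj_r2_additive": adj_r2, "adj_r2_full": float(full_fit.rsquared_adj),
               "aliased": False},
    )


def combined_factor(genotypes: dict, exposures: dict) -> tuple[dict, str]:
    """Merge genotype and exposure into a composite factor per subject.

    Levels are ``"<genotype>|cef+"`` / ``"<genotype>|cef-"``; empty
    combinations simply never appear.  Subjects missing either component are
    excluded and counted in the returned notes string.
    """
    levels: dict[str, str] = {}
    excluded = 0
    for sid in sorted(set(genotypes) | set(exposures)):
        g = genotypes.get(sid)
        e = exposures.get(sid)
        if g is None or e is None or (isinstance(g, float) and math.isnan(g)):
            excluded += 1
            continue
        levels[sid] = f"{g}|{'cef+' if e else 'cef-'}"
    notes = f"excluded={excluded}" if excluded else ""
    return levels, notes


def combined_factor_anova(
    outcome, composite, total_dose,
    outcome_name: str = "t_c0_max",
    shapiro_alpha: float = DEFAULT_SHAPIRO_ALPHA,
    min_n: int | None = None,
) -> AssociationResult:
    """Dose-adjusted one-way ANOVA of the composite genotype-treatment factor.

    Delegates to :func:`test_categorical` (inheriting the normality branch
    and the dose-adjustment rule for the endpoint).
    """
    return test_categorical(
        outcome, composite, total_dose,
        outcome_name=outcome_name, covariate_name="genotype|antibiotic",
        shapiro_alpha=shapiro_alpha, min_n=min_n,
        method_name="combined_factor_anova",
    )


def _screen_outlier_mask(values: np.ndarray) -> np.ndarray:
    """True where the value survives Tukey-fence outlier removal."""
    keep = np.zeros(len(values), dtype=bool)
    finite = np.isfinite(values)
    if finite.sum() == 0:
        return keep
    try:
        _, removed = remove_outliers(values)
    except ValueError:
        return finite
    keep[finite] = True
    keep[removed] = False
    return keep


def run_association_screen(
    dataset: CohortDataset,
    pk: pd.DataFrame,
    covariate_summaries: pd.DataFrame,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    shapiro_alpha: float = DEFAULT_SHAPIRO_ALPHA,
) -> list[AssociationResult]:
    """Screen every endpoint against every covariate.

    Continuous covariates (the mean/baseline/trajectory summaries) use the
    rank-residual Spearman; categorical covariates (genotypes per origin and
    locus, antibiotic exposures) use the Shapiro-branched dose-adjusted
    ANOVA.  Tukey-fence outlier removal is applied per numeric variable,
    across subjects, before each test.  The completeness rule is
    max(min_pairs, ceil(0.8 n)) complete pairs, applied uniformly to both
    covariate types.  Per-pair failures become not-applicable rows.
    """
    from .covariates import wide_covariate_table
    from .pk import PK_ENDPOINTS

    pk = pk.set_index("subject_id").sort_index()
    subjects = list(pk.index)
    n_subj = len(subjects)
    threshold = max(min_pairs, math.ceil(0.8 * n_subj))
    dose = pk["total_dose"].to_numpy(dtype=float)

    wide = wide_covariate_table(covariate_summaries).set_index("subject_id")
    wide = wide.reindex(subjects)
    continuous_vars = sorted(wide.columns)

    categorical: dict[str, dict[str, str]] = {}
    origins_loci = sorted({(o, l) for (_s, o, l) in dataset.genotypes})
    for origin, locus in origins_loci:
        categorical[f"{origin}_{locus}"] = dataset.genotype_of(origin, locus)
    for drug in ANTIBIOTIC_DRUGS:
        expo = dataset.exposure_of(drug)
        if expo:
            categorical[drug] = {s: ("yes" if e else "no") for s, e in expo.items()}

    results: list[AssociationResult] = []
    for endpoint in PK_ENDPOINTS:
        y_raw = pk[endpoint].to_numpy(dtype=float)
        y_keep = _screen_outlier_mask(y_raw)
        dose_adjust = endpoint not in DOSE_NORMALIZED_ENDPOINTS

        for var in continuous_vars:
            x_raw = wide[var].to_numpy(dtype=float)
            x_keep = _screen_outlier_mask(x_raw)
            keep = x_keep & y_keep
            res = dose_adjusted_spearman(
                np.where(keep, x_raw, np.nan), np.where(keep, y_raw, np.nan), dose,
                min_pairs=threshold, outcome=endpoint, covariate=var,
                dose_adjust=dose_adjust,
            )
            results.append(res)

        for name, mapping in sorted(categorical.items()):
            fac = np.array([mapping.get(s) for s in subjects], dtype=object)
            yk = np.where(y_keep, y_raw, np.nan)
            try:
                res = test_categorical(
                    yk, fac, dose, outcome_name=endpoint, covariate_name=name,
                    shapiro_alpha=shapiro_alpha, min_n=threshold,
                )
            except ValueError as exc:
                res = AssociationResult(
                    outcome=endpoint, covariate=name, method="lm_anova",
                    n_complete=int(_complete(yk, fac, dose).sum()),
                    statistic=None, p_value=None, dose_adjusted=dose_adjust,
                    notes=f"not applicable: {exc}",
                )
            results.append(res)
    return results


def results_table(results: list[AssociationResult]) -> pd.DataFrame:
    """Long results table mirroring associations.csv."""
    rows = [{
        "outcome": r.outcome, "covariate": r.covariate, "method": r.method,
        "n_complete": r.n_complete,
        "statistic": np.nan if r.statistic is None else r.statistic,
        "p_value": np.nan if r.p_value is None else r.p_value,
        "dose_adjusted": r.dose_adjusted, "notes": r.notes,
    } for r in results]
    return pd.DataFrame(rows, columns=[
        "outcome", "covariate", "method", "n_complete",
        "statistic", "p_value", "dose_adjusted", "notes"])
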