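# Methods

`troughpk` analyzes tacrolimus exposure in the first post-transplant month
from the only data routinely available there: longitudinal pre-dose (trough)
concentrations collected under therapeutic drug monitoring. This note
documents the statistical procedures, the tunable parameters, the synthetic
data-generating model used for validation, and the design choices made where
the problem was genuinely open.

## Trough-derived surrogate endpoints

Intensive post-dose sampling is infeasible immediately after transplantation,
so classical single-dose parameters (Cmax, Tmax, dosing-interval AUC) are not
estimable. Instead, five per-subject descriptors of trough accumulation are
computed from the (day, C0) profile:

| endpoint | definition | units |
|---|---|---|
| `c0_max` | highest observed trough | ng/mL |
| `t_c0_max` | day of that maximum (1-based; earliest day on ties) | day |
| `auc_c0_time` | linear-trapezoid area under the trough–day curve over the monitoring window | ng·day/mL |
| `avg_accumulation_ratio` | mean of within-subject ratios C0(day)/C0(first measurable day) | — |
| `auc_per_dose` | `auc_c0_time` / cumulative dose | (ng·day/mL)/mg |

These are accumulation and time-to-plateau surrogates, not absorption-phase
kinetics; `auc_c0_time` is a partial cumulative-exposure index, not an
AUC0–24. The first accumulation ratio is exactly 1 and is included in the
mean; excluding it would shift every subject's mean by a known amount, and
including it follows the "ratio at each time point" definition. Ties in the
peak are broken toward the earliest day, which is deterministic and reads as
"time to first attainment" of the plateau.

Day convention: day 1 is the first day of tacrolimus administration.
Concentrations below the assay lower limit of quantification (LLOQ,
0.5 ng/mL by default) are excluded from analysis but retained as censored
metadata — exclusion is the conservative TDM convention; substitution
schemes (LLOQ/2 etc.) are deliberately not offered.

## Outlier removal

Numeric variables are screened before any analysis with the Tukey boxplot
rule: hinges from the five-number summary, fences at hinge ± 1.5 × hinge-IQR,
values strictly outside removed. Hinge-based fences (rather than type-7
quantiles) are used to match the classic `boxplot.stats` convention. Removal
is per variable, across subjects, independently for each analysis pair.

## Mixed-model daily imputation

The TDM schedule leaves gaps (alternate days in week 2, every 3–4 days
after). To obtain one concentration per day, a linear mixed model is fitted
to log troughs:

    log C_ij = (β₀ + b0_i) + (β₁ + b1_i)·day_ij + e_ij

with subject-level random intercept and random slope. The random effects are
mutually independent (diagonal covariance): at ~20 subjects a free 2×2
covariance is weakly identified, and the diagonal structure is markedly more
stable; an intercept-only structure is available
(`random_effects="intercept"`), and the fit falls back to it automatically
when the slope variance sits on the boundary and defeats the optimization.
Estimation is REML. Because the REML surface near variance boundaries can
stall a single optimizer, the implementation keeps the best objective over
L-BFGS and Powell and then polishes from that point at tight tolerance
(factr = 10, pgtol = 1e-12); the balanced-design closed-form REML estimator
is reproduced to ~1e-11. A cohort whose points lie exactly on one common
line is short-circuited to the OLS solution with zero variance components
(the REML optimum is on the boundary and iterative fitting is singular
there).

Gaps are filled only between each subject's first and last observed day (no
extrapolation) with exp of the subject-specific predicted log concentration
(fixed effects + BLUPs), without back-transform bias correction — predicted
values are used directly. Observed values are never altered; censored days
are not re-filled. Endpoints before vs after imputation are compared with
two-sided paired Wilcoxon signed-rank tests (exact null distribution at
n ≤ 25 without zero differences); a metric with all-zero paired differences
is reported as "identical" rather than given a fabricated p-value.

## Covariate trajectory summaries

Each longitudinal laboratory variable is reduced to three per-subject
scalars: the mean over the monitoring period, the baseline (earliest
measurement at or before the initiation day, else the first available —
reported with suffix `_baseline`), and a trajectory slope (suffix
`_trajectory`). The slope is the mean derivative of a penalized cubic
smoothing spline evaluated on a 200-point uniform grid over the observed
range, with forward (consecutive-pair) differences. By telescoping this
equals (ŷ_last − ŷ_first)/(day range) exactly; the identity is asserted in
the tests. The smoothing parameter is selected by generalized
cross-validation; GCV was chosen because the smoothing-spline implementation
with built-in GCV is substantially more robust at ~10 observations per
series than REML-selected alternatives available here, and for these smooth,
low-noise summaries the two criteria give practically identical mean
derivatives. With fewer than 5 points the smoother is not identifiable and
an OLS line slope is substituted and flagged (`ols_fallback`).

## Dose-adjusted association testing

Cumulative dose is the obvious confounder of any exposure metric, so
continuous covariate–endpoint associations use a rank-residual partial
Spearman correlation: both variables are rank-transformed (average ranks on
ties), each rank vector is OLS-regressed on raw total dose
(`rank(outcome) = α₀ + α₁·total_dose + η`), and the Spearman correlation of
the two residual vectors is reported with its two-sided p. When total dose
is constant this reduces exactly to the plain Spearman correlation, and the
statistic is invariant under strictly increasing transforms of either
variable. Results require at least `min_pairs` complete pairs (default 16 =
80% of a 20-subject cohort); for other cohort sizes the screen applies
max(min_pairs, ⌈0.8·n⌉), uniformly to continuous and categorical tests.

Categorical covariates (genotypes, antibiotic exposures) are tested with a
linear model `outcome ~ factor + total_dose`, on the original scale when a
Shapiro–Wilk test does not reject normality of the outcome (α = 0.05, the
conventional threshold) and on average ranks otherwise; the branch taken is
recorded. The factor's partial (drop-one, type-II) F and p are reported —
with the factor entered first, sequential and partial F coincide when dose
is balanced across levels, and the partial F is the well-defined choice
otherwise. Endpoints that are dose-normalized or integrate dose
(`auc_per_dose`, `auc_c0_time`) are never dose-adjusted. No multiple-testing
correction is applied; the results table carries everything needed to apply
FDR control downstream.

### Genotype–antibiotic combined effect

The interaction model `t(C0,max) ~ genotype + antibiotic +
genotype:antibiotic` is fitted by OLS (dose optionally additive). Before
fitting, the design matrix rank is checked: when one factor level perfectly
predicts the other (e.g. every antibiotic-unexposed subject carries one
genotype), interaction columns are aliased; the interaction p is then
reported as not applicable with reason "aliased" while the additive model's
adjusted R² is still returned. In that case the two variables are merged
into a composite factor with levels `genotype|cef+` / `genotype|cef-`
(empty combinations never materialize) and analyzed by the dose-adjusted
one-way ANOVA above. When the co-factor is constant the composite test is
identical to the plain factor test, and this identity is asserted.

## Synthetic cohort generator

The generator exists to give every stage a testable ground truth; it
emulates the *structure* of early post-transplant TDM data, not liver
physiology. Each subject's noiseless trough curve is a peak-normalized
two-exponential,

    μ_i(t) = S_i · (e^{−λ_i t} − e^{−k_i t}) / f(t*_i),  t*_i = ln(k_i/λ_i)/(k_i − λ_i),

rising with accumulation rate k, declining with rate λ, with a closed-form
interior peak day t*. Observations are μ_i(t)·e^ε with lognormal noise.
Genotype and antibiotic effects act multiplicatively on k (so they shift
timing), covariate loadings act on the scale S (so they shift magnitude);
the two effect channels are separable in recovery tests, and dt*/dk < 0
makes the qualitative prediction — carriers and exposed subjects peak
earlier — exact in truth.

Shipped defaults (chosen once as plausible early post-transplant conditions;
soft range checks at n = 2000 confirm the median peak day falls inside the
reported 3–26-day window and ≥80% of peak troughs inside ~4–10 ng/mL):

- n = 20 subjects, follow-up uniform on 18–30 days;
- sampling daily days 1–7, days 9/11/13, then gaps alternating 3, 4 days;
- S₀ = 7 ng/mL, k₀ = 0.18/day, λ₀ = 0.05/day (t* ≈ 9.9 days);
- β_geno = 0.5 (log-k shift for recipient rs2032582 AC), β_abx = 0.4
  (log-k shift under cefoperazone/sulbactam);
- between-subject SDs τ_k = 0.20, τ_S = 0.12; residual σ = 0.08;
- covariate loadings on log S: total bilirubin 0.12, hematocrit 0.06;
- cefoperazone/sulbactam exposure probability 0.80, other antibiotics at
  cohort-typical frequencies; genotype frequencies plausible for an East
  Asian transplant population;
- dose 3.0 mg/day titrated to 3.5 (day 8) and 4.0 (day 15) — illustrative
  only, no TDM-guided feedback;
- 10% missingness per scheduled sample; LLOQ 0.5 ng/mL.

One RNG stream per component (design, genotypes/antibiotics, trough
kinetics, covariates, missingness), all derived from the master seed, so
toggling one component leaves the others' draws unchanged. Identical spec +
seed gives byte-identical output.

What the generator does **not** emulate — and hence what passing tests do
not establish about real cohorts: dose-adaptation feedback (real TDM doses
respond to measured levels, making dose endogenous), non-lognormal assay
error, informative missingness, within-subject covariate–concentration
feedback, linkage disequilibrium between loci, and any mechanistic PK
(absorption, clearance, hematocrit binding). Recovery and calibration
results demonstrate the statistical machinery is correct under its stated
assumptions, not that those assumptions hold clinically.

## Problem sizes and numerical choices

Validation uses: 100+ random instances of ≤25 subjects for exact oracle
agreement (≤1e-10 relative); 20 seeds × 200 subjects for mixed-model
recovery; 600 replicates of 40-subject null cohorts for type-I calibration
(acceptance band 0.03–0.07 at nominal 0.05); 40 replicates of 200-subject
cohorts for power (≥90% required); n = 2000 for generator range checks.
Degenerate inputs are errors with machine-readable reasons (all values
outlying, single-level factors, n < 3 for Shapiro–Wilk, first trough
censored) rather than silently producing numbers.

## Known limitations

- The linear-in-day log-concentration imputation model is a working
  approximation to a rising-then-plateauing profile; it is adequate for
  filling 1–3-day interior gaps but would bias long extrapolations, which is
  one reason extrapolation is refused.
- `t_c0_max` is measured on the sampling grid, so its resolution degrades to
  the 3–4-day schedule gap late in the window; on noiseless data the
  observed peak day is guaranteed only within one schedule gap of t*.
- The rank-residual partial Spearman controls for a single linear dose term;
  nonlinear dose confounding is not removed.
- With ~20 subjects the categorical tests have small cells for rare
  genotypes; p-values from the rank branch are asymptotic and the type-I
  calibration shown at n = 40 should not be assumed at much smaller n.
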