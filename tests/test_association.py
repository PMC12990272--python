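"""Association engine vs explicit normal-equations / rank oracles."""

import math

import numpy as np
import pytest
from scipy import stats

from troughpk.association import (
    combined_factor,
    combined_factor_anova,
    dose_adjusted_spearman,
    interaction_model,
    results_table,
    run_association_screen,
    test_categorical,
)
from troughpk.covariates import covariate_summary_table
from troughpk.pk import pk_table
from troughpk.simulate import SyntheticSpec, generate_cohort


# --- independent oracles ----------------------------------------------------

def oracle_rank(x):
    """Average ranks by explicit sort-and-tie-walk (no scipy)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(n)
    i = 0
    sx = x[order]
    while i < n:
        j = i
        while j + 1 < n and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def oracle_pearson(a, b):
    a = a - a.mean()
    b = b - b.mean()
    return float((a @ b) / math.sqrt((a @ a) * (b @ b)))


def oracle_residual_spearman(x, y, dose):
    """Explicit ranks -> normal-equations dose residuals -> Pearson of re-ranks."""
    rx, ry = oracle_rank(x), oracle_rank(y)
    X = np.column_stack([np.ones(len(dose)), dose])
    ex = rx - X @ np.linalg.solve(X.T @ X, X.T @ rx)
    ey = ry - X @ np.linalg.solve(X.T @ X, X.T @ ry)
    rho = oracle_pearson(oracle_rank(ex), oracle_rank(ey))
    n = len(x)
    t = rho * math.sqrt((n - 2) / max(1e-300, 1 - rho * rho))
    p = 2 * stats.t.sf(abs(t), n - 2)
    return rho, p


def oracle_dummies(factor):
    levels = sorted(set(factor))
    return np.column_stack([[1.0 if f == l else 0.0 for f in factor] for l in levels[1:]])


def oracle_factor_f(y, factor, dose=None):
    """Partial F for the factor block: explicit RSS of full vs reduced fits."""
    n = len(y)
    base_cols = [np.ones(n)]
    if dose is not None:
        base_cols.append(np.asarray(dose, dtype=float))
    D = oracle_dummies(factor)
    X_full = np.column_stack(base_cols + [D])
    X_red = np.column_stack(base_cols)

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    df1 = D.shape[1]
    df2 = n - X_full.shape[1]
    F = ((rss(X_red) - rss(X_full)) / df1) / (rss(X_full) / df2)
    return F, float(stats.f.sf(F, df1, df2))


def oracle_adjusted_r2(y, X_no_intercept):
    n = len(y)
    X = np.column_stack([np.ones(n), X_no_intercept])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1 - ss_res / ss_tot
    p = X.shape[1] - 1
    return 1 - (1 - r2) * (n - 1) / (n - p - 1)


# --- continuous: rank-residual Spearman --------------------------------------

class TestDoseAdjustedSpearman:
    def test_constant_dose_reduces_to_plain_spearman_exactly(self):
        rng = np.random.default_rng(0)
        x = rng.random(20)
        y = np.exp(x) + 1  # strictly increasing in x
        res = dose_adjusted_spearman(x, y, np.full(20, 80.0))
        assert res.statistic == 1.0
        plain = stats.spearmanr(x, rng.permutation(y))  # sanity: different data differ
        assert plain.statistic != 1.0

    def test_constant_dose_equals_plain_spearman_on_noise(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x, y = rng.random(18), rng.random(18)
            res = dose_adjusted_spearman(x, y, np.full(18, 50.0))
            plain = stats.spearmanr(x, y)
            assert res.statistic == plain.statistic
            assert res.p_value == plain.pvalue

    def test_insufficient_pairs_not_applicable(self):
        rng = np.random.default_rng(2)
        res = dose_adjusted_spearman(rng.random(15), rng.random(15), rng.random(15))
        assert res.p_value is None and "insufficient pairs" in res.notes
        assert res.n_complete == 15

    def test_constant_input_not_applicable(self):
        res = dose_adjusted_spearman(np.ones(20), np.random.default_rng(3).random(20),
                                     np.arange(20.0))
        assert res.p_value is None and res.notes == "constant input"

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(16, 26))
            x = rng.normal(0, 1, n)
            dose = rng.uniform(50, 120, n)
            y = 0.5 * x + 0.01 * dose + rng.normal(0, 1, n)
            res = dose_adjusted_spearman(x, y, dose)
            rho, p = oracle_residual_spearman(x, y, dose)
            assert res.statistic == pytest.approx(rho, rel=1e-10, abs=1e-12)
            assert res.p_value == pytest.approx(p, rel=1e-10, abs=1e-12)

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(9)
        x = rng.random(20) + 0.1
        y = rng.random(20) + 0.1
        dose = rng.uniform(50, 100, 20)
        base = dose_adjusted_spearman(x, y, dose)
        for fx, fy in [(np.log, np.sqrt), (lambda v: v ** 3, np.exp)]:
            res = dose_adjusted_spearman(fx(x), fy(y), dose)
            assert res.statistic == base.statistic
            assert res.p_value == base.p_value

    def test_missing_values_reduce_n_complete(self):
        rng = np.random.default_rng(4)
        x = rng.random(20)
        x[:3] = np.nan
        res = dose_adjusted_spearman(x, rng.random(20), rng.random(20), min_pairs=10)
        assert res.n_complete == 17


# --- categorical: Shapiro-branched dose-adjusted ANOVA -----------------------

class TestCategorical:
    def test_single_level_factor_is_an_error(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="single"):
            test_categorical(rng.random(10), ["a"] * 10, rng.random(10))

    def test_tiny_n_is_an_error(self):
        with pytest.raises(ValueError, match="Shapiro"):
            test_categorical([1.0, 2.0], ["a", "b"], [1.0, 1.0])

    def test_branches_recorded_and_match_oracle(self):
        rng = np.random.default_rng(7)
        for i in range(60):
            n = int(rng.integers(12, 26))
            factor = rng.choice(["g1", "g2", "g3"], n).tolist()
            if len(set(factor)) < 2:
                continue
            dose = rng.uniform(40, 100, n)
            y = rng.normal(0, 1, n) + (rng.random() < 0.5) * rng.exponential(2, n)
            res = test_categorical(y, factor, dose, outcome_name="c0_max")
            shapiro_p = stats.shapiro(y).pvalue
            y_used = y if shapiro_p >= 0.05 else oracle_rank(y)
            F, p = oracle_factor_f(y_used, factor, dose)
            assert res.statistic == pytest.approx(F, rel=1e-10)
            assert res.p_value == pytest.approx(p, rel=1e-10)
            assert res.extra["branch"] == ("normal" if shapiro_p >= 0.05 else "rank")

    def test_dose_normalized_outcomes_skip_dose_term(self):
        rng = np.random.default_rng(8)
        n = 20
        y = rng.normal(5, 1, n)
        factor = (["a"] * 10) + (["b"] * 10)
        dose = rng.uniform(40, 100, n)
        res = dose_free = test_categorical(y, factor, dose, outcome_name="auc_per_dose")
        assert not res.dose_adjusted
        shapiro_p = stats.shapiro(y).pvalue
        y_used = y if shapiro_p >= 0.05 else oracle_rank(y)
        F, p = oracle_factor_f(y_used, factor, dose=None)
        assert dose_free.statistic == pytest.approx(F, rel=1e-10)

    def test_large_group_shift_detected(self):
        rng = np.random.default_rng(11)
        n = 40
        factor = np.array(["a"] * 20 + ["b"] * 20)
        y = rng.normal(0, 1, n) + 3.0 * (factor == "b")
        res = test_categorical(y, factor.tolist(), rng.uniform(40, 100, n))
        assert res.p_value < 0.001


# --- interaction and combined factor ------------------------------------------

class TestInteraction:
    def test_balanced_design_full_rank_reports_interaction(self):
        rng = np.random.default_rng(0)
        n = 40
        geno = np.repeat(["AC", "AA"], 20)
        abx = np.tile(np.repeat(["yes", "no"], 10), 2)
        y = rng.normal(10, 1, n) + 2 * (geno == "AC") + 1.5 * (abx == "yes")
        res = interaction_model(y, geno, abx)
        assert not res.extra["aliased"]
        assert res.p_value is not None

    def test_collinear_pattern_flags_aliasing(self):
        """All antibiotic-unexposed subjects share one genotype level: the
        interaction is inestimable and must be reported as aliased."""
        rng = np.random.default_rng(1)
        geno = ["AC"] * 10 + ["AA"] * 5 + ["CC"] * 5
        abx = ["no"] * 4 + ["yes"] * 16  # the 4 unexposed are all AC
        y = rng.normal(10, 2, 20)
        res = interaction_model(np.asarray(y), geno, abx)
        assert res.extra["aliased"] and res.p_value is None
        assert "adj_r2_additive" in res.extra
        # agreement with an explicit matrix-rank computation
        D_g, D_a = oracle_dummies(geno), oracle_dummies(abx)
        inter = np.column_stack([D_g[:, i] * D_a[:, j]
                                 for i in range(D_g.shape[1]) for j in range(D_a.shape[1])])
        X = np.column_stack([np.ones(20), D_g, D_a, inter])
        assert np.linalg.matrix_rank(X) < X.shape[1]

    def test_additive_adjusted_r2_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        n = 200
        geno = rng.choice(["AC", "AA", "CC"], n)
        abx = rng.choice(["yes", "no"], n)
        y = 10 + 2 * (geno == "AC") + 1.5 * (abx == "yes") + rng.normal(0, 1, n)
        res = interaction_model(y, geno, abx)
        X = np.column_stack([oracle_dummies(geno.tolist()), oracle_dummies(abx.tolist())])
        assert res.extra["adj_r2_additive"] == pytest.approx(
            oracle_adjusted_r2(y, X), rel=1e-10)

    def test_too_few_cases_is_an_error(self):
        with pytest.raises(ValueError, match="complete cases"):
            interaction_model([1.0, 2.0, 3.0], ["a", "b", "a"], ["y", "n", "n"])


class TestCombinedFactor:
    def test_level_algebra_with_empty_cell(self):
        genos = {"S1": "AC", "S2": "AC", "S3": "AA", "S4": "AA"}
        expos = {"S1": True, "S2": False, "S3": True, "S4": True}
        levels, notes = combined_factor(genos, expos)
        assert set(levels.values()) == {"AC|cef+", "AC|cef-", "AA|cef+"}
        assert notes == ""

    def test_missing_component_excluded_and_counted(self):
        levels, notes = combined_factor({"S1": "AC"}, {"S1": True, "S2": False})
        assert levels == {"S1": "AC|cef+"}
        assert notes == "excluded=1"

    def test_constant_cofactor_reduces_to_plain_factor_test(self):
        rng = np.random.default_rng(5)
        n = 24
        geno = rng.choice(["AC", "AA"], n)
        dose = rng.uniform(50, 100, n)
        y = rng.normal(8, 2, n) + (geno == "AC")
        comp = [f"{g}|cef-" for g in geno]
        res_comp = combined_factor_anova(y, comp, dose, outcome_name="t_c0_max")
        res_plain = test_categorical(y, geno.tolist(), dose, outcome_name="t_c0_max")
        assert res_comp.statistic == res_plain.statistic
        assert res_comp.p_value == res_plain.p_value

    def test_collinear_cohort_levels_contain_no_empty_cells(self):
        genos = {f"S{i}": ("AC" if i < 12 else ["AA", "AT", "CC"][i % 3]) for i in range(20)}
        expos = {f"S{i}": (i >= 4) for i in range(20)}  # 4 unexposed, all AC
        levels, _ = combined_factor(genos, expos)
        observed = set(levels.values())
        assert "AC|cef-" in observed and "AC|cef+" in observed
        assert all("|" in l for l in observed)


# --- the full screen ----------------------------------------------------------

class TestScreen:
    def test_empty_covariates_give_categorical_only_rows(self):
        ds, _ = generate_cohort(SyntheticSpec(n_subjects=20, seed=1))
        ds.covariates.clear()
        pk = pk_table(ds)
        cov = covariate_summary_table(ds)
        results = run_association_screen(ds, pk, cov)
        table = results_table(results)
        assert set(table.outcome) == {
            "c0_max", "t_c0_max", "auc_c0_time", "avg_accumulation_ratio", "auc_per_dose"}
        assert not any(table.method == "rank_residual_spearman")

    def test_row_cardinality(self):
        ds, _ = generate_cohort(SyntheticSpec(n_subjects=20, seed=1))
        pk = pk_table(ds)
        cov = covariate_summary_table(ds)
        results = run_association_screen(ds, pk, cov)
        n_cont = cov.variable.nunique() * 3  # mean/baseline/trajectory
        n_cat = 7 + 7  # 7 loci + 7 antibiotics
        assert len(results) == 5 * (n_cont + n_cat)

    def test_dose_adjustment_rule_per_endpoint(self):
        ds, _ = generate_cohort(SyntheticSpec(n_subjects=20, seed=2))
        table = results_table(run_association_screen(
            ds, pk_table(ds), covariate_summary_table(ds)))
        normalized = table.outcome.isin(["auc_c0_time", "auc_per_dose"])
        assert not table.loc[normalized, "dose_adjusted"].any()
        spearman_rows = table.method == "rank_residual_spearman"
        assert table.loc[~normalized & spearman_rows, "dose_adjusted"].all()

    def test_small_cohort_rows_flagged_insufficient(self):
        ds, _ = generate_cohort(SyntheticSpec(n_subjects=10, seed=3))
        table = results_table(run_association_screen(
            ds, pk_table(ds), covariate_summary_table(ds), min_pairs=16))
        spearman = table[table.method == "rank_residual_spearman"]
        assert spearman.p_value.isna().all()
        assert spearman.notes.str.contains("insufficient").all()
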