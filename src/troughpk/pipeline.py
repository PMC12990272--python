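"""End-to-end orchestration: simulate -> impute -> pk -> covariates -> associate.

A run is fully described by a :class:`RunConfig` (YAML round-trippable).
Given the same config and seed, outputs are byte-identical.  Each stage
writes its CSV into the output directory; a plain-text ``run.log`` records
one line per decision taken (normality branch, rows dropped, aliasing), and
``manifest.json`` lists every file written with the config hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import (
    DEFAULT_MIN_PAIRS,
    DEFAULT_SHAPIRO_ALPHA,
    combined_factor,
    combined_factor_anova,
    interaction_model,
    results_table,
    run_association_screen,
)
from .cohort import CohortDataset, read_cohort, write_cohort
from .covariates import covariate_summary_table
from .imputation import compare_original_imputed, fit_lmm_log_troughs, impute_daily
from .pk import pk_table
from .simulate import SyntheticSpec, generate_cohort

__all__ = ["RunConfig", "run_pipeline", "load_dataset"]


@dataclass
class RunConfig:
    """Parameters of one pipeline run (YAML round-trippable)."""

    out_dir: str = "troughpk_run"
    input_dir: str | None = None       # read an existing cohort from here ...
    simulate: bool = True              # ... or generate one
    seed: int = 0
    n_subjects: int = 20
    imputation: bool = True
    random_effects: str = "intercept_slope"
    min_pairs: int = DEFAULT_MIN_PAIRS
    shapiro_alpha: float = DEFAULT_SHAPIRO_ALPHA
    version: str = field(default_factory=lambda: __version__)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_dataset(input_dir) -> CohortDataset:
    d = Path(input_dir)
    return read_cohort(
        d / "troughs.csv", d / "doses.csv", d / "covariates.csv",
        d / "genotypes.csv", d / "antibiotics.csv",
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    manifest_files: list[str] = []
    t0 = time.time()

    def log(msg: str) -> None:
        log_lines.append(msg)

    def stage(name: str):
        log(f"stage {name} at +{time.time() - t0:.2f}s")

    # --- input ------------------------------------------------------------
    stage("input")
    if config.simulate:
        spec = SyntheticSpec(n_subjects=config.n_subjects, seed=config.seed)
        dataset, truth = generate_cohort(spec)
        counts = write_cohort(dataset, out)
        manifest_files += sorted(counts)
        truth.per_subject.to_csv(out / "truth.csv", index=False)
        manifest_files.append("truth.csv")
        spec.to_yaml(out / "synthetic_spec.yaml")
        manifest_files.append("synthetic_spec.yaml")
        log(f"simulated cohort: {config.n_subjects} subjects, seed {config.seed}")
    else:
        if config.input_dir is None:
            raise ValueError("config.input_dir required when simulate is off")
        dataset = load_dataset(config.input_dir)
        log(f"loaded cohort from {config.input_dir}: {len(dataset.troughs)} subjects")

    # --- pk on original data ----------------------------------------------
    stage("pk_original")
    pk_original = pk_table(dataset)
    pk_original.to_csv(out / "pk_surrogates_original.csv", index=False)
    manifest_files.append("pk_surrogates_original.csv")

    # --- imputation ---------------------------------------------------------
    analysis_dataset = dataset
    if config.imputation:
        stage("impute")
        fit = fit_lmm_log_troughs(dataset, random_effects=config.random_effects)
        log(f"mixed model ({fit.structure}): beta0={fit.beta0:.4f} beta1={fit.beta1:.5f} "
            f"var_b0={fit.var_intercept:.3g} var_b1={fit.var_slope:.3g} "
            f"var_e={fit.var_resid:.3g} converged={fit.converged}")
        analysis_dataset = impute_daily(dataset, fit)
        n_filled = sum(len(ts.imputed_days) for ts in analysis_dataset.troughs.values())
        log(f"imputed {n_filled} daily values")
        imp_counts = write_cohort(analysis_dataset, out / "imputed")
        manifest_files += [f"imputed/{name}" for name in sorted(imp_counts)]
        pk_imputed = pk_table(analysis_dataset)
        comparison = compare_original_imputed(pk_original, pk_imputed)
        comparison.to_csv(out / "imputation_comparison.csv", index=False)
        manifest_files.append("imputation_comparison.csv")
        for _, row in comparison.iterrows():
            log(f"original-vs-imputed {row.metric}: "
                + (f"p={row.p_value:.4g}" if row.reason == "" else row.reason))

    stage("pk")
    pk = pk_table(analysis_dataset)
    pk.to_csv(out / "pk_surrogates.csv", index=False)
    manifest_files.append("pk_surrogates.csv")

    # --- covariates ---------------------------------------------------------
    stage("covariates")
    covsum = covariate_summary_table(analysis_dataset)
    covsum.to_csv(out / "covariate_summaries.csv", index=False)
    manifest_files.append("covariate_summaries.csv")

    # --- association screen ---------------------------------------------------
    stage("associate")
    results = run_association_screen(
        analysis_dataset, pk, covsum,
        min_pairs=config.min_pairs, shapiro_alpha=config.shapiro_alpha,
    )
    assoc = results_table(results)
    assoc.to_csv(out / "associations.csv", index=False)
    manifest_files.append("associations.csv")
    n_na = int(assoc.p_value.isna().sum())
    log(f"association screen: {len(assoc)} pairs, {n_na} not applicable")
    for r in results:
        if r.notes:
            log(f"  {r.outcome} ~ {r.covariate}: {r.notes}")

    # --- combined genotype-antibiotic factor on t(C0,max) -------------------
    stage("combined_factor")
    genos = analysis_dataset.genotype_of("recipient", "rs2032582")
    expos = analysis_dataset.exposure_of("cefoperazone_sulbactam")
    pk_idx = pk.set_index("subject_id")
    subjects = list(pk_idx.index)
    y = pk_idx["t_c0_max"].to_numpy(dtype=float)
    dose = pk_idx["total_dose"].to_numpy(dtype=float)
    inter = interaction_model(
        y, [genos.get(s) for s in subjects],
        [("yes" if expos.get(s) else "no") for s in subjects],
    )
    log(f"interaction model: {inter.notes}; adj R2 (additive) = "
        f"{inter.extra.get('adj_r2_additive'):.4f}")
    comp_map, comp_notes = combined_factor(genos, expos)
    comp = [comp_map.get(s) for s in subjects]
    combined = combined_factor_anova(y, comp, dose, outcome_name="t_c0_max",
                                     shapiro_alpha=config.shapiro_alpha)
    log(f"combined factor ANOVA: F={combined.statistic}, p={combined.p_value} "
        f"({combined.notes}{'; ' + comp_notes if comp_notes else ''})")
    pd.concat([
        results_table([inter]), results_table([combined]),
    ]).to_csv(out / "combined_effect.csv", index=False)
    manifest_files.append("combined_effect.csv")

    # --- manifest -----------------------------------------------------------
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    manifest_files += ["run.log", "manifest.json"]
    manifest = {
        "version": config.version,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "files": sorted(manifest_files),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
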