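"""End-to-end orchestration of the rare-variant metabolite analysis.

Stages run in a fixed order — simulate (or load) → preprocess → variants →
association → significance — each exposed as a function so the numbered
driver scripts, the test suite and ``run_pipeline`` share one code path.
Every output carries the run seed and a hash of the configuration; rerunning
with an identical config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import preprocess as prep
from . import significance as sig
from . import variants as var
from .simulate import GeneSpec, SimulationConfig, simulate_cohort

__all__ = ["RunConfig", "load_run_config", "run_pipeline",
           "preprocess_stage", "association_stage", "significance_stage"]

logger = logging.getLogger("uromet")

COVARIATE_COLUMNS = ["age", "sex", "egfr", "uacr", "pc1", "pc2", "pc3"]


@dataclass
class RunConfig:
    """Structured run configuration (YAML/JSON file with flag-style overrides)."""

    output_dir: str = "results/run"
    seed: int = 0
    alpha: float = 0.05
    maf_max: float = 0.01
    min_mac: int = 10
    min_variants: int = 2
    min_observations: int = 300
    n_tests: int = 2
    covariate_columns: list[str] = field(default_factory=lambda: list(COVARIATE_COLUMNS))
    ratios: bool = False
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_run_config(path: str | Path, **overrides) -> RunConfig:
    """Load a YAML or JSON run config; keyword overrides take precedence."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    sim = data.pop("simulation", {})
    genes = [GeneSpec(**g) for g in sim.pop("genes", [])] or None
    sim_cfg = SimulationConfig(**sim, **({"genes": genes} if genes else {}))
    data.update(overrides)
    known = {f for f in RunConfig.__dataclass_fields__ if f != "simulation"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    return RunConfig(simulation=sim_cfg, **data)


def preprocess_stage(
    metabolites: prep.MetaboliteMatrix, config: RunConfig
) -> tuple[prep.MetaboliteMatrix, prep.RatioMatrix | None]:
    """Outlier masking → PQN → min-observation filter → (ratios) → INT."""
    masked = prep.mask_outliers(metabolites)
    normalized = prep.pqn_normalize(masked)
    filtered = prep.filter_min_observations(normalized, config.min_observations)
    transformed = prep.transform_matrix(filtered)
    ratios = None
    if config.ratios:
        ratio_raw = prep.build_ratio_matrix(filtered)
        ratio_filtered = prep.filter_min_observations(ratio_raw, config.min_observations)
        ratios = prep.transform_matrix(ratio_filtered)
    return transformed, ratios


def association_stage(
    genotypes: var.GenotypeData,
    annotations: pd.DataFrame,
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame,
    config: RunConfig,
) -> pd.DataFrame:
    """Burden + SKAT for every gene group x phenotype, complete cases per phenotype."""
    missing_cov = [c for c in config.covariate_columns if c not in covariates.columns]
    if missing_cov:
        raise ValueError(f"covariate column(s) missing from table: {missing_cov}")
    qualifying = var.qualify_variants(genotypes, annotations, config.maf_max)
    groups = var.build_gene_groups(qualifying, genotypes, config.min_mac, config.min_variants)
    if not groups:
        logger.warning("no gene group passed the filters; empty result table")
        return _empty_results()
    X_full = np.column_stack(
        [np.ones(len(covariates))]
        + [covariates[c].to_numpy(dtype=float) for c in config.covariate_columns]
    )
    rows = []
    for pheno in phenotypes.columns:
        y = phenotypes[pheno].to_numpy(dtype=float)
        complete = ~(np.isnan(y) | np.isnan(X_full).any(axis=1))
        null = assoc.fit_null_model(y[complete], X_full[complete])
        for group in groups:
            G = var.mean_impute(genotypes.subset(group.variant_ids))[complete]
            mafs = genotypes.variants.loc[group.variant_ids, "maf"].to_numpy()
            try:
                beta, se, p_b = assoc.burden_test(null, G, assoc.FLAT)
                q, p_s, fb = assoc.skat_test(null, G, assoc.BETA_1_25, mafs)
            except ValueError:
                continue  # degenerate group on this phenotype's complete cases
            rows.append(
                {
                    "gene": group.gene,
                    "phenotype": pheno,
                    "p_burden": p_b,
                    "effect": beta,
                    "se": se,
                    "p_skat": p_s,
                    "q_skat": q,
                    "n_snps": len(group.variant_ids),
                    "total_mac": group.total_mac,
                    "cumulative_maf": group.cumulative_maf,
                    "n": null.n,
                    "skat_fallback": fb,
                }
            )
    return pd.DataFrame(rows) if rows else _empty_results()


def _empty_results() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["gene", "phenotype", "p_burden", "effect", "se", "p_skat", "q_skat",
                 "n_snps", "total_mac", "cumulative_maf", "n", "skat_fallback"]
    )


def significance_stage(
    results: pd.DataFrame, config: RunConfig, n_phenotypes: int | None = None
) -> dict:
    """Bonferroni thresholds and significant/suggestive tables."""
    if results.empty:
        return {"threshold": None, "suggestive_threshold": None,
                "tables": {"significant": results, "suggestive": results}}
    n_genes = results.groupby("phenotype")["gene"].nunique().max()
    n_phen = n_phenotypes or results["phenotype"].nunique()
    spec = sig.ThresholdSpec(config.alpha, int(n_genes), int(n_phen), config.n_tests)
    threshold = sig.bonferroni_threshold(spec)
    suggestive = sig.bonferroni_threshold(
        sig.ThresholdSpec(config.alpha, int(n_genes), 1, config.n_tests)
    )
    tables = sig.assemble_results(results, threshold, suggestive)
    return {"threshold": threshold, "suggestive_threshold": suggestive, "tables": tables}


def run_pipeline(config: RunConfig) -> dict:
    """Simulate a cohort and run preprocess → variants → association → significance.

    Writes the association table, significant/suggestive tables and a JSON
    run summary (with seed, config hash and thresholds) into
    ``config.output_dir`` and returns them.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("simulating cohort (seed=%d)", config.simulation.seed)
    covariates, genotypes, annotations, raw, truth = simulate_cohort(config.simulation)
    transformed, ratios = preprocess_stage(raw, config)
    phenotypes = transformed.values
    if ratios is not None and not ratios.values.empty:
        phenotypes = pd.concat([phenotypes, ratios.values], axis=1)
    results = association_stage(genotypes, annotations, phenotypes, covariates, config)
    summary = significance_stage(results, config)
    results.to_csv(out / "gene_tests.tsv", sep="\t", index=False)
    for name, table in summary["tables"].items():
        table.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    truth.to_frame().to_csv(out / "truth.tsv", sep="\t", index=False)
    sig.write_run_summary(
        out / "run_summary.json",
        seed=config.seed,
        config_hash=config.config_hash(),
        threshold=summary["threshold"],
        suggestive_threshold=summary["suggestive_threshold"],
        n_results=len(results),
        n_significant=len(summary["tables"]["significant"]),
    )
    return {"results": results, "truth": truth, **summary}
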