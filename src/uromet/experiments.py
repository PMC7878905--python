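"""Simulation experiments: calibration, parameter recovery, oracle agreement.

These are the package's reusable study drivers — each function simulates data
under stated conditions, runs the corresponding analysis code path, and
returns summary numbers.  The numbered analysis scripts and the acceptance
checks call them with the problem sizes documented in the methods note.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .association import (
    BETA_1_25,
    FLAT,
    burden_test,
    fit_null_model,
    skat_test,
)
from .enrichment import GeneSetDB, mc_enrichment
from .pipeline import COVARIATE_COLUMNS
from .preprocess import inverse_normal_transform, mask_outliers, pqn_normalize
from .simulate import GeneSpec, SimulationConfig, simulate_cohort, simulate_covariates
from .variants import mean_impute


def _design(covariates: pd.DataFrame) -> np.ndarray:
    return np.column_stack(
        [np.ones(len(covariates))]
        + [covariates[c].to_numpy(dtype=float) for c in COVARIATE_COLUMNS]
    )


def type_i_error_calibration(
    n_samples: int = 2000,
    n_variants: int = 6,
    maf: float = 0.005,
    n_replicates: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Null-phenotype type-I error of burden and SKAT at fixed genotypes.

    One gene with ``n_variants`` variants at the given MAF; phenotypes are
    pure noise, so the fraction of p-values below alpha estimates the type-I
    error, and the p-value distributions should be uniform.
    """
    ss = np.random.SeedSequence(seed).spawn(2)
    rng = np.random.default_rng(ss[0])
    G = rng.binomial(2, maf, (n_samples, n_variants)).astype(float)
    mafs = G.mean(axis=0) / 2.0
    covariates = simulate_covariates(n_samples, int(ss[1].generate_state(1)[0] % 2**31))
    X = _design(covariates)
    p_burden, p_skat = [], []
    for _ in range(n_replicates):
        y = rng.standard_normal(n_samples)
        null = fit_null_model(y, X)
        _, _, pb = burden_test(null, G, FLAT)
        _, ps, _ = skat_test(null, G, BETA_1_25, mafs)
        p_burden.append(pb)
        p_skat.append(ps)
    p_burden, p_skat = np.array(p_burden), np.array(p_skat)
    return {
        "type_i_burden": float((p_burden < alpha).mean()),
        "type_i_skat": float((p_skat < alpha).mean()),
        "ks_p_burden": float(stats.kstest(p_burden, "uniform").pvalue),
        "ks_p_skat": float(stats.kstest(p_skat, "uniform").pvalue),
        "p_burden": p_burden,
        "p_skat": p_skat,
        "n_replicates": n_replicates,
    }


def burden_recovery(
    effect: float = 0.7,
    n_samples: int = 4864,
    n_replicates: int = 200,
    seed: int = 0,
) -> dict:
    """Full-chain recovery of a per-allele effect through the preprocessing.

    Each replicate simulates a cohort (one causal gene, ~6 variants at MAF
    ~1e-3, so total MAC ~ 60), runs masking → PQN → INT on the target
    metabolite and the covariate-adjusted burden test, and records the
    estimate, its SE, and whether the 95% CI covers the injected effect.
    """
    child_seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % 2**31
    betas, ses, covered, macs = [], [], 0, []
    for rep_seed in child_seeds:
        cfg = SimulationConfig(
            n_samples=n_samples,
            genes=[GeneSpec("G1", 6, effect)],
            seed=int(rep_seed),
        )
        covariates, genotypes, _, metabolites, _ = simulate_cohort(cfg)
        normalized = pqn_normalize(mask_outliers(metabolites))
        y = inverse_normal_transform(normalized.values["MET_G1"]).to_numpy()
        X = _design(covariates)
        keep = ~np.isnan(y)
        null = fit_null_model(y[keep], X[keep])
        vids = [v for v in genotypes.variants.index if v.startswith("G1_")]
        G = mean_impute(genotypes.subset(vids))[keep]
        b, se, _ = burden_test(null, G, FLAT)
        betas.append(b)
        ses.append(se)
        covered += b - 1.96 * se <= effect <= b + 1.96 * se
        macs.append(int(genotypes.variants.loc[vids, "mac"].sum()))
    betas = np.array(betas)
    return {
        "effect_true": effect,
        "mean_beta": float(betas.mean()),
        "bias": float(betas.mean() - effect),
        "coverage": covered / n_replicates,
        "mean_total_mac": float(np.mean(macs)),
        "mean_se": float(np.mean(ses)),
        "n_replicates": n_replicates,
    }


def enrichment_hypergeom_agreement(
    n_configs: int = 20, n_draws: int = 100_000, seed: int = 0
) -> dict:
    """Monte-Carlo enrichment p versus the exact hypergeometric upper tail.

    Random configurations (universe, set and query sizes, planted overlap);
    returns the worst absolute deviation in Monte-Carlo standard errors.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    worst_z, details = 0.0, []
    for i in range(n_configs):
        N = int(rng.integers(60, 400))
        K = int(rng.integers(10, max(11, N // 3)))
        k = int(rng.integers(5, 31))
        universe = [f"g{j:04d}" for j in range(N)]
        members = list(rng.choice(N, K, replace=False))
        db = GeneSetDB({"s": frozenset(universe[j] for j in members)}, frozenset(universe))
        query = [universe[j] for j in rng.choice(N, k, replace=False)]
        (res,) = mc_enrichment(query, db, n_draws=n_draws, seed=int(rng.integers(2**31)))
        exact = float(stats.hypergeom.sf(res.observed - 1, N, K, k))
        se = max(np.sqrt(exact * (1 - exact) / n_draws), 1.0 / n_draws)
        z = abs(res.p - exact) / se
        worst_z = max(worst_z, z)
        details.append({"N": N, "K": K, "k": k, "p_mc": res.p, "p_exact": exact, "z": z})
    return {"worst_z": worst_z, "configs": details, "n_draws": n_draws}


def quadform_monte_carlo_agreement(
    lambdas=(2.0, 1.0), q_grid=(2.0, 5.0, 10.0, 16.0), n_draws: int = 10**6, seed: int = 0
) -> dict:
    """Numerical quadratic-form tail versus brute-force chi-square mixture draws."""
    from .association import quadform_pvalue

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    lam = np.asarray(lambdas, dtype=float)
    draws = (lam[:, None] * rng.chisquare(1, (len(lam), n_draws))).sum(axis=0)
    worst_z = 0.0
    for q in q_grid:
        p, _ = quadform_pvalue(q, lam)
        emp = float((draws > q).mean())
        se = max(np.sqrt(emp * (1 - emp) / n_draws), 1.0 / n_draws)
        worst_z = max(worst_z, abs(p - emp) / se)
    return {"worst_z": worst_z, "n_draws": n_draws}


def burden_ols_oracle_agreement(n_instances: int = 100, seed: int = 0) -> dict:
    """Burden beta/SE versus an explicit joint least-squares refit.

    The oracle rebuilds the design as (X, s) with s the weighted burden score
    and solves the normal equations directly; the score test's beta must
    match the joint-fit coefficient (its SE differs only by the residual
    variance convention, which is rescaled here).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    worst_rel = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(40, 120))
        m = int(rng.integers(1, 5))
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 3))])
        G = rng.binomial(2, 0.1, (n, m)).astype(float)
        if G.sum() == 0:
            continue
        w = rng.uniform(0.5, 2.0, m)
        y = rng.standard_normal(n) + 0.3 * (G @ w)
        null = fit_null_model(y, X)
        try:
            b, se, _ = burden_test(null, G, w)
        except ValueError:
            continue
        Z = np.column_stack([X, G @ w])
        beta_joint = np.linalg.solve(Z.T @ Z, Z.T @ y)[-1]
        sps = float(((G @ w) - X @ np.linalg.solve(X.T @ X, X.T @ (G @ w))) @ (G @ w))
        se_oracle = np.sqrt(null.sigma2 / sps)
        worst_rel = max(
            worst_rel,
            abs(b - beta_joint) / max(abs(beta_joint), 1e-12),
            abs(se - se_oracle) / se_oracle,
        )
    return {"worst_rel": worst_rel, "n_instances": n_instances}
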