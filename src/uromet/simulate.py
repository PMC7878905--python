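"""Synthetic cohort generator for the rare-variant urine-metabolome analysis.

Every downstream stage is testable without access to restricted cohort data:
this module emulates the statistical structure the analysis assumes —

* covariates of a moderate-CKD cohort (mean age 60 y, 60% men, mean eGFR
  49.5 ml/min/1.73m^2, median UACR ~50 mg/g, standard-normal genetic PCs),
* rare qualifying variants (in-sample MAF < 1% by construction, consequence
  classes drawn from a configurable mix) plus common background variants,
* metabolite intensities built generatively to mirror the analysis model:
  per-allele genetic effects act additively on a latent standard-normal
  scale, the latent value is mapped to a positive concentration via exp, and
  a per-sample log-normal dilution factor plus missingness produce the raw
  matrix,
* tissue-labeled expression matrices with planted tissue-specific genes,
* three analytically solvable toy metabolic models (degrader / producer /
  capacity-limited) exercising the knockout direction classes.

Randomness derives from one root seed via ``numpy.random.SeedSequence``
child streams (one per component, in a documented fixed order), so identical
seeds give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .fba import MetabolicModel, Reaction
from .preprocess import MetaboliteMatrix
from .variants import GenotypeData

__all__ = [
    "GeneSpec",
    "SimulationConfig",
    "TrueParameters",
    "simulate_covariates",
    "simulate_genotypes",
    "simulate_metabolites",
    "simulate_cohort",
    "simulate_expression",
    "toy_metabolic_models",
]

DEFAULT_CONSEQUENCE_MIX = {
    "nonsynonymous": 0.70,
    "stop gain": 0.10,
    "stop loss": 0.05,
    "splicing": 0.15,
}

#: covariate coefficients of the generative phenotype model (latent SD units
#: per SD of the standardized covariate); modest kidney-function dependence.
DEFAULT_COVARIATE_COEFS = {"age": -0.05, "sex": 0.05, "egfr": 0.10, "uacr": -0.05}


@dataclass
class GeneSpec:
    """One configured gene: its qualifying-variant count and true effect."""

    gene: str
    n_variants: int = 6
    effect: float = 0.7  # latent SD units per qualifying allele
    consequence_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONSEQUENCE_MIX)
    )

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if not math.isfinite(self.effect):
            raise ValueError("effect must be finite")


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic cohort.

    Defaults follow the emulated study: n = 4864 participants, qualifying
    variants with MAF below 1%, per-allele effects in the 0.4-1.6 SD range of
    the reported per-gene estimates.
    """

    n_samples: int = 4864
    genes: list[GeneSpec] = field(default_factory=lambda: [GeneSpec("GENE1")])
    maf_range: tuple[float, float] = (5e-4, 1.5e-3)
    background_common_variants: int = 10
    n_null_metabolites: int = 100
    n_reference_metabolites: int = 80  # well-measured nulls, no missingness
    dilution_sd: float = 0.5
    missing_rate: float = 0.05
    missing_mode: str = "mcar"  # or "left-censor" (below-detection)
    dosage_missing_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 0.01):
            raise ValueError("maf_range must lie within (0, 0.01)")
        for p in (self.missing_rate, self.dosage_missing_rate):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must be in [0, 1]")
        if self.dilution_sd < 0:
            raise ValueError("dilution_sd must be non-negative")
        if self.missing_mode not in ("mcar", "left-censor"):
            raise ValueError("missing_mode must be 'mcar' or 'left-censor'")


@dataclass
class TrueParameters:
    """Ground truth recorded alongside every simulated dataset."""

    beta_true: dict[str, float]  # gene -> latent SD units per qualifying allele
    dilution: np.ndarray  # per-sample dilution factor d_i (positive)
    covariate_coefs: dict[str, float]
    gene_metabolite: dict[str, str]  # gene -> target metabolite id

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": list(self.beta_true),
                "beta_true": list(self.beta_true.values()),
                "metabolite": [self.gene_metabolite[g] for g in self.beta_true],
            }
        )


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Component RNG streams: SeedSequence(seed).spawn in fixed order."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_covariates(n_samples: int, seed: int) -> pd.DataFrame:
    """Covariate table: age, sex, eGFR, UACR and three genetic PCs.

    Distribution centers follow the emulated cohort: age ~ N(60, 10) clipped
    to the 18-74 enrollment window, 60% men (sex = 1), eGFR ~ N(49.5, 15)
    floored at 5, UACR log-normal with median ~50 mg/g, PCs standard normal.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    age = np.clip(rng.normal(60.0, 10.0, n_samples), 18.0, 74.0)
    sex = (rng.random(n_samples) < 0.60).astype(float)
    egfr = np.maximum(rng.normal(49.5, 15.0, n_samples), 5.0)
    uacr = np.exp(rng.normal(math.log(50.1), 1.5, n_samples))
    pcs = rng.standard_normal((n_samples, 3))
    return pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "egfr": egfr,
            "uacr": uacr,
            "pc1": pcs[:, 0],
            "pc2": pcs[:, 1],
            "pc3": pcs[:, 2],
        },
        index=[f"S{i+1:05d}" for i in range(n_samples)],
    )


def _draw_rare_variant(
    rng: np.random.Generator, n: int, maf_lo: float, maf_hi: float, max_tries: int = 1000
) -> np.ndarray:
    """Dosages with realized in-sample MAF in (0, 0.01): resample until satisfied."""
    for _ in range(max_tries):
        maf = rng.uniform(maf_lo, maf_hi)
        d = rng.binomial(2, maf, n).astype(float)
        mac = d.sum()
        if 0 < mac / (2 * n) < 0.01:
            return d
    raise ValueError(
        f"could not realize a rare variant with MAF in ({maf_lo}, {maf_hi}) at n={n}; "
        "config infeasible"
    )


def simulate_genotypes(config: SimulationConfig) -> tuple[GenotypeData, pd.DataFrame]:
    """Genotypes and annotation table for the configured genes plus background.

    Qualifying-eligible variants have realized in-sample MAF < 1% by
    construction (resampled until satisfied).  Background variants are common
    (MAF uniform in (0.05, 0.5)) and annotated synonymous so they never
    qualify.  Dosage missingness is injected at ``dosage_missing_rate``.
    """
    rng_geno, rng_miss = _child_rngs(config.seed, 5)[1:3]
    n = config.n_samples
    cols, records, ann_rows = [], [], []
    pos = 0
    for spec in config.genes:
        classes = sorted(spec.consequence_mix)
        probs = np.array([spec.consequence_mix[c] for c in classes], dtype=float)
        probs = probs / probs.sum()
        for j in range(spec.n_variants):
            pos += 1000
            vid = f"{spec.gene}_v{j+1}"
            d = _draw_rare_variant(rng_geno, n, *config.maf_range)
            cols.append(d)
            records.append(
                {"variant_id": vid, "chrom": "1", "pos": pos, "ref": "A", "alt": "G"}
            )
            cons = classes[rng_geno.choice(len(classes), p=probs)]
            ann_rows.append({"variant_id": vid, "gene": spec.gene, "consequence": cons})
    for j in range(config.background_common_variants):
        pos += 1000
        vid = f"BG_v{j+1}"
        maf = rng_geno.uniform(0.05, 0.5)
        cols.append(rng_geno.binomial(2, maf, n).astype(float))
        records.append({"variant_id": vid, "chrom": "2", "pos": pos, "ref": "C", "alt": "T"})
        ann_rows.append({"variant_id": vid, "gene": f"BG{j+1:04d}", "consequence": "synonymous"})
    dosages = np.column_stack(cols) if cols else np.empty((n, 0))
    if config.dosage_missing_rate > 0 and dosages.size:
        miss = rng_miss.random(dosages.shape) < config.dosage_missing_rate
        # keep at least one observed dosage per variant
        miss[:, miss.all(axis=0)] = False
        dosages = np.where(miss, np.nan, dosages)
    variants = pd.DataFrame(records).set_index("variant_id")
    samples = [f"S{i+1:05d}" for i in range(n)]
    genotypes = GenotypeData.from_raw(samples, variants, dosages)
    annotations = pd.DataFrame(ann_rows, columns=["variant_id", "gene", "consequence"])
    return genotypes, annotations


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def simulate_metabolites(
    genotypes: GenotypeData,
    covariates: pd.DataFrame,
    config: SimulationConfig,
    covariate_coefs: dict[str, float] | None = None,
) -> tuple[MetaboliteMatrix, TrueParameters]:
    """Raw metabolite matrix with injected genetic effects and dilution.

    Generative model per metabolite m and sample i:

        z_im = sum_g beta_g * (qualifying allele count of i in g, if m is the
               target of g) + sum_c gamma_c * covariate_ic + eps_im,
        raw_im = exp(z_im) * d_i,   log d_i ~ N(0, dilution_sd),

    so effects are injected on the latent (inverse-normal) scale and are
    directly comparable to downstream burden estimates.  Each configured gene
    targets its own metabolite ("MET_<gene>"); ``n_null_metabolites`` extra
    metabolites carry covariate and noise structure only.  Missingness is
    MCAR by default; mode "left-censor" instead deletes each metabolite's
    lowest raw values (below-detection).
    """
    if list(covariates.index) != list(genotypes.samples):
        raise ValueError("covariate and genotype sample sets must align")
    rngs = _child_rngs(config.seed, 5)
    rng_noise, rng_missm = rngs[3], rngs[4]
    n = len(covariates)
    coefs = dict(DEFAULT_COVARIATE_COEFS if covariate_coefs is None else covariate_coefs)
    cov_term = np.zeros(n)
    for name, gamma in coefs.items():
        cov_term += gamma * _standardize(covariates[name].to_numpy(dtype=float))

    dilution = np.exp(rng_noise.normal(0.0, config.dilution_sd, n))
    beta_true, gene_met = {}, {}
    values = {}
    pathways = {}
    dframe = genotypes.dosage_frame()
    for spec in config.genes:
        met = f"MET_{spec.gene}"
        beta_true[spec.gene] = spec.effect
        gene_met[spec.gene] = met
        vids = [v for v in genotypes.variants.index if v.startswith(f"{spec.gene}_v")]
        burden = np.nansum(dframe[vids].to_numpy(dtype=float), axis=1)
        z = spec.effect * burden + cov_term + rng_noise.standard_normal(n)
        values[met] = np.exp(z) * dilution
        pathways[met] = "amino acid"
    for j in range(config.n_null_metabolites):
        met = f"MET_NULL{j+1}"
        z = cov_term + rng_noise.standard_normal(n)
        values[met] = np.exp(z) * dilution
        pathways[met] = "amino acid" if j % 2 == 0 else "lipid-fatty acid"

    matrix = pd.DataFrame(values, index=covariates.index)
    if config.missing_rate > 0:
        # the first n_reference_metabolites null metabolites stay fully
        # observed, emulating well-measured endogenous metabolites from which
        # the PQN reference spectrum can be derived
        reference = {
            f"MET_NULL{j+1}"
            for j in range(min(config.n_reference_metabolites, config.n_null_metabolites))
        }
        if config.missing_mode == "mcar":
            mask = rng_missm.random(matrix.shape) < config.missing_rate
        else:  # left-censor: lowest raw values fall below detection
            q = matrix.quantile(config.missing_rate, axis=0)
            mask = matrix.lt(q, axis=1).to_numpy()
        mask = mask & ~matrix.columns.isin(sorted(reference))[None, :]
        matrix = matrix.mask(mask)
    truth = TrueParameters(beta_true, dilution, coefs, gene_met)
    return MetaboliteMatrix(matrix, pathways, "raw"), truth


def simulate_cohort(config: SimulationConfig):
    """Covariates + genotypes + raw metabolites + truth, from one root seed."""
    covariates = simulate_covariates(config.n_samples, config.seed)
    genotypes, annotations = simulate_genotypes(config)
    metabolites, truth = simulate_metabolites(genotypes, covariates, config)
    return covariates, genotypes, annotations, metabolites, truth


def simulate_expression(
    n_genes: int,
    tissues: Sequence[str],
    n_specific_per_tissue: int = 5,
    fold: float = 10.0,
    seed: int = 0,
    samples_per_tissue: int = 10,
):
    """Expression matrix with planted tissue-specific genes.

    Baseline expression is log-normal (TPM-like); each designated gene's mean
    is multiplied by ``fold`` in its home tissue.  Returns the
    :class:`~uromet.enrichment.ExpressionData` and the ground-truth
    ``{tissue: [genes]}`` specificity labels.
    """
    from .enrichment import ExpressionData

    tissues = list(tissues)
    if not tissues:
        raise ValueError("tissue list must not be empty")
    if n_specific_per_tissue * len(tissues) > n_genes:
        raise ValueError("more designated specific genes than genes")
    if fold <= 0:
        raise ValueError("fold must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    genes = [f"G{i+1:05d}" for i in range(n_genes)]
    columns, labels = [], []
    base = np.exp(rng.normal(1.0, 1.0, n_genes))  # per-gene baseline TPM
    specific: dict[str, list[str]] = {}
    mult = np.ones((n_genes, len(tissues)))
    gi = 0
    for tj, t in enumerate(tissues):
        specific[t] = genes[gi : gi + n_specific_per_tissue]
        mult[gi : gi + n_specific_per_tissue, tj] = fold
        gi += n_specific_per_tissue
    data = {}
    for tj, t in enumerate(tissues):
        for s in range(samples_per_tissue):
            col = f"{t}_{s+1}"
            noise = np.exp(rng.normal(0.0, 0.25, n_genes))
            data[col] = base * mult[:, tj] * noise
            labels.append(t)
    values = pd.DataFrame(data, index=genes)
    expr = ExpressionData(values, pd.Series(labels, index=values.columns))
    return expr, specific


def toy_metabolic_models() -> dict[str, MetabolicModel]:
    """Three analytically solvable knockout fixtures.

    * ``degrader`` — the gene's enzyme consumes the metabolite; knockout
      raises the maximal urine excretion (healthy 2 -> KO 10).
    * ``producer`` — the enzyme synthesizes the metabolite; knockout
      abolishes urine excretion (healthy 10 -> KO 0).
    * ``capacity-limited`` — tubular transport into urine is capped at 1
      independently of the enzyme; knockout leaves urine excretion unchanged
      (1 -> 1) while the blood demand maximum rises (2 -> 10).
    """
    degrader = MetabolicModel(
        "degrader",
        {"met[c]": "c", "byp[c]": "c", "met[u]": "u"},
        [
            Reaction("UPT_met", {"met[c]": 1.0}, 0.0, 10.0),
            Reaction("DEG_met", {"met[c]": -1.0, "byp[c]": 1.0}, 0.0, 8.0, ("GDEG",), "kidney"),
            Reaction("SINK_byp", {"byp[c]": -1.0}, 0.0, math.inf),
            Reaction("EX_met[u]", {"met[c]": -1.0, "met[u]": 1.0}, 0.0, 1000.0),
        ],
    )
    producer = MetabolicModel(
        "producer",
        {"pre[c]": "c", "met[c]": "c", "met[u]": "u"},
        [
            Reaction("UPT_pre", {"pre[c]": 1.0}, 0.0, 10.0),
            Reaction("SYN_met", {"pre[c]": -1.0, "met[c]": 1.0}, 0.0, 1000.0, ("GPROD",), "liver"),
            Reaction("EX_met[u]", {"met[c]": -1.0, "met[u]": 1.0}, 0.0, 1000.0),
        ],
    )
    capacity = MetabolicModel(
        "capacity-limited",
        {"met[c]": "c", "byp[c]": "c", "met[tu]": "c", "met[u]": "u"},
        [
            Reaction("UPT_met", {"met[c]": 1.0}, 0.0, 10.0),
            Reaction("DEG_met", {"met[c]": -1.0, "byp[c]": 1.0}, 0.0, 8.0, ("GCAP",), "liver"),
            Reaction("SINK_byp", {"byp[c]": -1.0}, 0.0, math.inf),
            # tubular secretion cap independent of the enzyme
            Reaction("TUB_met", {"met[c]": -1.0, "met[tu]": 1.0}, 0.0, 1.0),
            Reaction("EX_met[u]", {"met[tu]": -1.0, "met[u]": 1.0}, 0.0, 1000.0),
        ],
    )
    return {"degrader": degrader, "producer": producer, "capacity-limited": capacity}
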