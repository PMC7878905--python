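# uromet

Rare-variant gene-based association analysis of urine metabolite levels and
ratios, packaged as a reproducible analysis pipeline with a synthetic cohort
generator in place of restricted individual-level study data.

## The problem

Urine metabolite concentrations integrate metabolic reactions across organs:
enzymes and transporters generate, break down, filter, reabsorb and secrete
small molecules, and rare loss-of-function variants in their genes can shift
metabolite levels substantially — the same genes cause inborn errors of
metabolism when both copies are lost.  Detecting these effects requires
aggregating rare variants per gene (single carriers are too few), careful
normalization of urine dilution, and multiple-testing control over thousands
of genes × metabolites.  This package implements that full chain for
geneticists and metabolomics analysts:

1. **Preprocessing** — per-metabolite outlier masking (values > 5 SD set to
   missing), probabilistic quotient normalization (PQN) against a reference
   spectrum of well-measured metabolites, a ≥ 300-observation filter,
   pairwise metabolite ratios within super-pathways, and rank-based inverse
   normal transformation (INT).
2. **Gene-based tests** — for a gene's qualifying variants (in-sample
   MAF < 1%, nonsynonymous / stop gain / stop loss / splicing; ≥ 2 variants
   and total minor allele count ≥ 10 per gene), covariate-adjusted score
   tests under the linear null model y = Xβ + ε:
   * burden: collapse dosages to sᵢ = Σⱼ wⱼ gᵢⱼ and test its slope,
     β̂ = sᵀr / sᵀPs, SE = σ̂ / √(sᵀPs), with flat weights so β̂ is the
     average effect per copy of a rare allele (in SD units of the INT
     phenotype);
   * SKAT: Q = ‖WGᵀr‖² with Beta(MAF; 1, 25) weights, p-value from the
     χ²-mixture null Σₖ λₖχ²₁ via characteristic-function inversion
     (Imhof-type integration, saddlepoint fallback in far tails).
3. **Significance** — Bonferroni thresholds over genes × phenotypes × 2
   tests; for ratios, the p-gain statistic
   p-gain = min(p_A, p_B) / p_ratio (computed in log space) with a
   retention threshold of 10 × (number of ratios).
4. **Conditional analysis** — re-running both tests with a nearby common
   index variant's dosage in the design, reporting the conditional effect as
   a percentage of the unconditional one.
5. **Enrichment** — top-decile specific-expression gene sets from t-statistics
   of tissue-indicator regressions, Monte-Carlo enrichment p-values from
   random gene draws, 2×2 odds ratios with Haldane–Anscombe correction, and
   Bonferroni / Benjamini-Hochberg adjustment.
6. **In silico knockouts** — flux balance analysis on stoichiometric models:
   close a gene's reactions in all organs, compare the maximal
   urine-excretion (`EX_<met>[u]`) and blood-demand (`DM_<met>[bc]`) fluxes
   against a healthy-reference model with the gene's reactions pinned at
   their joint maximum, and call the direction of change; concordance with
   observed directions is scored by an exact binomial test.

A seeded synthetic-cohort generator (`uromet.simulate`) produces genotypes,
covariates, dilution-confounded metabolite intensities with known per-allele
effects, tissue-labeled expression matrices, and three analytically solvable
toy metabolic models, so every stage is testable end to end.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic data
and write their tables under `results/`.  For example:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_preprocess_metabolites.py
python analysis/03_gene_based_tests.py
```

prints, among other things:

```
cohort: n=4864, 28 variants, 103 metabolites -> results/cohort/
  ENZ2: 8 qualifying variants, total MAC 71, cumulative MAF 0.73%, 71 carriers (1.5%)
...
tested 3 genes x 103 phenotypes; threshold 8.09e-05, suggestive 0.00833
  significant: ENZ2 x MET_ENZ2 (burden p=1.74e-24, effect +1.26 +/- 0.12,
               SKAT p=2.06e-15, test Both)
```

i.e. the gene with a true per-allele effect of 1.4 SD is recovered at
β̂ = 1.26 ± 0.12 and is significant in both tests at the Bonferroni threshold
recomputed from the realized numbers of genes and phenotypes, while the
weak-effect transporter gene stays below threshold.  The knockout script

```bash
python analysis/06_insilico_knockouts.py
```

prints the three analytic fixture cases — an enzyme that degrades its
metabolite (maximal urine flux 2 → 10 under knockout, direction "up"), one
that produces it (10 → 0, "down"), and a transport-capacity-limited case
(1 → 1 in urine, blood demand 2 → 10) — and the exact binomial concordance
of predicted versus observed directions.

Other drivers: `04_calibration_and_recovery.py` (type-I error of both tests
over 2,000 null phenotypes and full-chain recovery of a 0.7 SD effect over
200 replicates) and `05_expression_enrichment.py` (planted liver/kidney
specific genes recovered by Monte-Carlo set enrichment).

## Layout

```
src/uromet/        library: simulate, preprocess, variants, association,
                   significance, enrichment, fba, experiments, pipeline
analysis/          numbered narrative drivers (write under results/)
scripts/           acceptance.py
tests/             pytest suite (unit, property and acceptance tests)
docs/methods.md    model assumptions, parameter choices, limitations
```
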