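# Methods

## Statistical model

All phenotypes (metabolite levels and pairwise ratios) are analyzed after
rank-based inverse normal transformation, so effects are in SD units of the
transformed scale.  The null model is ordinary least squares,

    y = Xβ + ε,  ε ~ N(0, σ²I),

with X = intercept + age, sex, eGFR, UACR and three genetic principal
components (conditional analyses append common index-variant dosages).
σ̂² uses the n − p denominator.  Both gene-based tests are score tests
against this null, so the null model is fitted once per phenotype and reused
across genes:

* **Burden.**  With weights w (flat by default, so β̂ is "per copy of a rare
  qualifying allele") and s = Gw, the estimate is β̂ = sᵀr/sᵀPs with
  SE = σ̂/√(sᵀPs), where P is the residual projector of X and r the null
  residuals; p-values use the standard normal reference.  At n in the
  thousands the difference from a t reference is far below the reporting
  precision.
* **SKAT.**  Q = ‖WGᵀr‖² with W = diag(Beta(MAF; 1, 25) densities).  The
  null distribution is Σₖ λₖ χ²₁ with λₖ the eigenvalues of σ̂²·(WGᵀPGW).
  Neither test's weights are dictated by the analysis design; flat burden
  weights and Beta(1, 25) SKAT weights are the conventions of the
  rare-variant testing literature and are what this package defaults to.

**Quadratic-form p-values.**  P(Q > q) is computed by Gil-Pelaez/Imhof
inversion of the characteristic function.  The integrand
sin θ(u)/(u·ρ(u)) has a u^(−1−m/2) envelope and oscillates asymptotically at
frequency q/2, so the integral is split at U = 10/λ_max: adaptive Gauss–
Kronrod quadrature on [0, U] (absolute target 1e-9) and Fourier-weight
(QAWF) quadrature on [U, ∞) after factoring the slowly varying phase.  This
matches the χ²₁/χ²₂ closed forms to ~1e-13.  Inversion is an
absolute-accuracy method; below p ≈ 1e-11 the implementation switches to a
Lugannani–Rice saddlepoint tail (cumulant generating function
−½Σ log(1−2ζλₖ)), and if that fails to a Liu-type skewness/kurtosis
moment match.  Any non-inversion route is flagged in the result
(`skat_fallback`), never silent.  Reported p-values are clipped into (0, 1].

**Qualifying variants and gene groups.**  In-sample MAF (after minor-allele
orientation) strictly below 1% and consequence in {nonsynonymous, stop gain,
stop loss, splicing}; genes kept with ≥ 2 qualifying variants and total
MAC ≥ 10.  In-sample frequencies are authoritative (the analysis is a
cohort-level statistic, not a reference-panel lookup).  Missing dosages are
mean-imputed per variant before testing, which keeps n constant per
phenotype and matches common score-test practice; phenotype/covariate
missingness is handled by complete-case analysis per phenotype (so n varies
across metabolites).  Variants annotated to several genes count for each.

**Significance.**  Bonferroni: α/(n_genes·n_phenotypes·n_tests), with
n_genes the maximum number of filter-passing genes across phenotypes,
recomputed from the data at hand.  Ratios are additionally filtered by the
p-gain min(p_A, p_B)/p_ratio, computed in log10 space (a ratio p of 1e-300
gives a p-gain of 1e300 without overflow), with retention threshold
10 × n_ratios.  p-gain is computed within each test (burden p-gain from
burden p-values, SKAT from SKAT), mirroring how the two tests are tabulated.
Printed-precision values round half away from zero; full precision is always
retained alongside.

## Preprocessing

The cleaning order is: outlier masking → PQN → ≥ 300-observation filter →
ratios → INT.  Masking precedes PQN so extreme values cannot corrupt the
quotients; ratios are formed on normalized concentrations rather than INT
values because INT is rank-only and ratios of ranks are meaningless.

* **Masking** uses a single pass per metabolite on the current (raw) scale,
  candidate included, strict inequality |x − mean| > k·SD with k = 5;
  zero-SD columns mask nothing.  On light-tailed columns with isolated gross
  errors the operation is idempotent; on heavy-tailed raw intensities a
  second application can mask further values (the SD shrinks once extremes
  are removed) — the pipeline applies it exactly once.
* **PQN** builds the reference spectrum from per-metabolite medians over
  metabolites with < 1% missing values; each sample is divided by its median
  ratio to the reference.  On noise-free profile × dilution data this
  removes dilution exactly, up to one global factor (the median dilution)
  absorbed into the reference — rows become identical to machine precision.
* **INT** maps observed values to Φ⁻¹((rank − 0.5)/n_obs) with average ranks
  for ties; the offset is symmetric, hence zero mean for tie-free data.
  Whether INT is applied to ratios of normalized values or to log-ratios is
  immaterial: both have identical ranks for positive values, so the INT
  output is the same.
* **Ratios** are formed per unordered pair of eligible metabolites
  (amino-acid, peptide and lipid-fatty-acid super-pathways), oriented
  lexicographically; a zero denominator yields a missing value, not an
  error.  p-gain is invariant to the orientation choice.

## Synthetic cohort generator

The generator emulates the statistical structure of a moderate-CKD urine
metabolomics cohort so the analysis chain can be exercised without
restricted data:

* **Covariates**: age ~ N(60, 10) clipped to the 18–74 enrollment window,
  60% men, eGFR ~ N(49.5, 15) ml/min/1.73 m² floored at 5, UACR log-normal
  with median ≈ 50 mg/g, PCs standard normal.  Defaults: n = 4864.
* **Genotypes**: qualifying variants are independent binomial dosages with
  MAF drawn from (5e-4, 1.5e-3), resampled until the realized in-sample MAF
  is strictly below 1% and MAC ≥ 1; at the defaults a 6-variant gene has
  expected total MAC ≈ 58.  Consequences are drawn from a configurable mix
  over the qualifying classes.  Common background variants (MAF 0.05–0.5,
  synonymous) exercise the filters.  Dosage missingness is injected at a
  small MCAR rate (0.2%) to exercise imputation.
* **Metabolites**: the generative model mirrors the analysis model — per
  metabolite, a latent standard-normal variable carries the additive genetic
  effect (β SD per qualifying allele in the gene targeting it) plus small
  covariate terms; raw intensity is exp(latent) × per-sample dilution factor
  (log-normal, SD 0.5).  Each configured gene targets one metabolite; 100
  null metabolites provide the normalization panel, 80 of them fully
  observed so a PQN reference (< 1% missing) always exists, the remainder
  subject to 5% missingness.  Missingness is MCAR by default; a left-censor
  mode deletes each metabolite's lowest values instead (below-detection).
  The cohort's true missingness mechanism is not identifiable from the
  published description, so both modes are provided without asserting which
  is real.
* **RNG**: one root seed; component streams derive from
  `numpy.random.SeedSequence(seed).spawn` in a fixed order, so identical
  seeds give bit-identical outputs.

What the generator does **not** model: linkage disequilibrium (variants are
independent), population stratification, batch effects, and
technically-correlated metabolite panels.  Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
generative model, not robustness to those real-data complications.

### Known attenuation of recovered effects

Because raw intensities are log-normal, the 5 SD outlier mask on the raw
scale preferentially removes the highest values — which are enriched for
carriers — and INT standardizes total (not residual) variance.  Together
these attenuate recovered per-allele effects by ≈ 0.03–0.04 SD at β = 0.7
(measured by the recovery experiment; within its |bias| < 0.05 band).  This
is a property of the analysis procedure itself on skewed data, not an
implementation artifact.

## Enrichment

Specific-expression sets take the top ⌈10%·G⌉ genes per tissue/cell-type
ranked by the t-statistic of a label-indicator coefficient in a per-gene
linear model of log10(TPM + 1) across all samples (the realized special case
is the pooled-variance two-group t); ties at the decile boundary break by
gene id for determinism.  Enrichment p-values are Monte-Carlo: draws are
uniform k-subsets of the universe without replacement and
p = (1 + #{overlap ≥ observed})/(1 + n_draws), so p is never zero and
converges to the hypergeometric upper tail.  The default 1e5 draws is a
desk-scale choice (the production scale of 1e7–1e8 draws is configurable);
at 1e5 the Monte-Carlo SE is ~1.6e-3 at p = 0.5 and proportionally smaller
in the tails.  Odds ratios come from the 2×2 membership table over the
universe with 0.5 added to every cell when any cell is zero (flagged).
Shared liver+kidney sets are intersections of the per-tissue lists.
Adjustment: Bonferroni across tissues, Benjamini-Hochberg across GO/KEGG
terms.

## Constraint-based knockouts

Models are stored in a versioned JSON schema (metabolites with compartment
tags; reactions with stoichiometry, bounds, gene associations, organ tags).
Urine ([u]) and blood ([bc]) metabolites are boundary species excluded from
the steady-state constraint, so `EX_<met>[u]` / `DM_<met>[bc]` reactions
simply produce them; a demand reaction is created on the fly when absent.
FBA solves max v_obj s.t. S v = 0, lb ≤ v ≤ ub with HiGHS; unbounded and
infeasible statuses are reported honestly, and optima are checked against
mass balance at 1e-8.  Knockout closes all reactions of a gene in all
organs; genes sharing a reaction with isozymes are refused (a knockout would
not be interpretable).  The healthy reference maximizes the summed flux of
the gene's reactions jointly and pins each at that optimum — joint
maximization is feasibility-safe where sequential per-reaction maximization
can be order-dependent.  Direction calls use a relative tolerance of 1e-6
with an absolute floor of 1e-9.  Concordance of predicted versus observed
directions uses the exact one-sided binomial tail by direct summation; the
chance probability is an explicit argument (1/3 for a three-outcome
direction call) since the appropriate null depends on the direction
vocabulary.

The three fixtures are built so the healthy/knockout maxima are analytic:
degrader (uptake 10, enzyme 8: urine 2 → 10), producer (uptake 10: urine
10 → 0), capacity-limited (tubular transport capped at 1 upstream of the
urine exchange, so opening the exchange does not lift the cap: urine 1 → 1,
blood demand 2 → 10).  Whole-body physiological constraints (diet, urine
production rate) are out of scope; fixtures encode capacity limits directly
in bounds.

## Problem sizes

The simulation experiments run at: calibration 2,000 null phenotypes
(n = 2,000, one 6-variant gene at MAF 0.005); recovery 200 replicates of the
full chain (n = 4,864, β = 0.7, total MAC ≈ 58); enrichment oracle 20 random
configurations at 1e5 draws; quadform Monte-Carlo 1e6 draws.  These sizes
were chosen to give Monte-Carlo standard errors well inside the asserted
bands while keeping a full run in the low minutes on a single CPU.

## Orchestration

`uromet.pipeline.run_pipeline` executes simulate → preprocess → variants →
association → significance from a single `RunConfig` (YAML/JSON file with
keyword overrides; overrides > file > defaults).  Outputs carry the seed and
a config hash; reruns with identical configuration are bit-identical.  The
numbered scripts under `analysis/` are thin drivers over the same stage
functions, so results in `results/` always reflect library behavior.
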