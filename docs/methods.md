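# Methods

## Scope and data model

The package implements a two-stage multienvironment genomic-prediction
analysis for an autotetraploid diversity panel. Stage 1 turns plot-level
trial data into per-genotype adjusted means (BLUEs); stage 2 fits G-BLUP
models across environments with an explicit genetic covariance between
environments, and evaluates breeding-relevant prediction scenarios by
cross-validation. "Environment" means either a trial (location × year) or a
region, depending on the scenario.

## Genomic relationship matrix

Dosages `M` (n × m, entries 0..k for ploidy k) are column-centred with
in-sample allele frequencies `p_m = mean(M[:,m])/k`:

    Z = M − k·p ,   G = ZZ' / (k · Σ_m p_m (1 − p_m)).

At k = 2 this is VanRaden method 1; the denominator is the summed binomial
dosage variance, so `diag(G)` averages ≈ 1 for an unrelated panel in
Hardy–Weinberg-like proportions. Which polyploid normalisation a given
published analysis used is rarely stated exactly; the choice rescales
absolute variance components but leaves prediction abilities essentially
unchanged (correlations are invariant to a global rescaling of `G` once the
variance components are refitted). Missing dosages are mean-imputed
(equivalently, centred entries set to 0). `min_maf` filtering is off by
default — dosage panels are normally filtered upstream. An optional ridge
(fraction of the mean diagonal) keeps `G` strictly positive definite for
Cholesky-based simulation; the REML engine itself only needs PSD.

## Stage 1: trial analysis

Per trial, the model is `y = genotype + block + row + column + plot error`
with genotype and block fixed, independent random row and column effects,
and i.i.d. plot error. Variance components are REML estimates from a
generic dense engine (log-variance parametrization, L-BFGS-B); BLUEs are
the GLS fixed-effect solution at those components, with blocks coded
sum-to-zero so genotype coefficients are adjusted means directly.

Broad-sense heritability is reported on the entry-mean basis

    H² = σ²_g / (σ²_g + σ²_ε / n_rep),   n_rep = number of complete blocks,

with genotype random. Row/column variances are excluded from the
denominator: they are design noise, removed by the adjustment, not
genotype-by-replicate noise. A plot-basis formula (adding σ²_row + σ²_col +
σ²_ε undivided) would give systematically lower values; users comparing
against published per-trial heritabilities should check which basis those
used, as the basis is often unstated.

## Stage 2: multienvironment REML

Observations are BLUEs `y_ij` (genotype i, environment j):

    y_ij = μ_j + g_ij + ε_ij,  vec(g) ~ N(0, G ⊗ Σ_E),  ε_ij ~ N(0, r_j),

with environment means the only fixed effects (BLUEs are already
design-adjusted) and a diagonal heterogeneous residual `R = diag(r_j)`.
Four nested `Σ_E` structures: ME (rank-one, all entries σ²_g — genotypic
main effect only, no G×E), CS (common variance σ₁², common covariance σ₂²),
UN.het (per-environment variances, single correlation ρ), US (fully
unstructured).

**Estimation.** Direct maximisation of the restricted log-likelihood

    ℓ_R = −½ [ log|V| + log|X'V⁻¹X| + y'Py + (N − p) log 2π ]

by L-BFGS-B with finite-difference gradients on unconstrained transforms:
log variances; Fisher-z for ρ with |ρ| ≤ 0.999; a log-Cholesky factor for
US (PSD by construction); log residual variances floored at 1e-10.
With n ≤ a few hundred and J ≤ 6 this is cheap and robust; an
average-information scheme would add complexity without a practical gain at
this size. When the genotype × environment table is complete, rotating by
the eigenvectors of `G` reduces `V` to n independent J×J blocks
`λ_i Σ_E + R` (one O(n³) eigendecomposition, then O(nJ³) per likelihood
evaluation, evaluated with batched Cholesky factorizations). Incomplete
patterns use a dense observed-records likelihood.

**CS parametrization.** CS is written as main-effect plus interaction
variance (off-diagonal σ₂² = main, diagonal σ₁² = σ₂² + σ²_int with
σ²_int ≥ 0), so the implied correlation σ₂²/σ₁² lies in [0, 1]. A negative
common genetic covariance across trials of the same trait is biologically
implausible here; software that permits it can in principle find slightly
different CS optima on data where the unconstrained optimum would be
negative.

**Starting values and local optima.** Starts come from a method-of-moments
split of the sample covariance of environment-wise genotype values (half
genetic, half residual, scaled by mean diag G). Because UN.het and US have
genuinely multimodal surfaces on some draws, each cold fit additionally
tries a start embedded from a fit of the next-simpler nested structure
(ME→CS→UN.het→US); this preserves the nesting ordering of log-likelihoods
in practice. Optional jittered restarts are available; cross-validation
loops instead warm-start every repetition from the full-data fit of the
same structure, which is both faster and more stable. Convergence: L-BFGS-B
with ftol 1e-11, gtol 1e-6, max 500 iterations; boundary estimates (zero
variances) are floored and flagged in the convergence record.

**Model comparison.** Likelihood-ratio tests use χ² with df = difference in
free `Σ_E` parameters (residuals and means are common to both models). For
ME ⊂ CS the null lies on the boundary of the CS space (σ²_int = 0), so the
plain χ² p-value is conservative (true size ≈ α/2 at df 1); it is reported
as-is with this caveat rather than mixture-corrected, matching common
practice. CS ⊂ UN.het and UN.het ⊂ US are interior nulls and calibrate at
nominal level (verified by simulation in the test suite).

## Prediction

BLUPs for any genotype in any fitted environment use the conditional-mean
form `ĝ = C V⁻¹ (y − Xμ̂)` with `C = G[test, train] ⊗ Σ_E[target, ·]`
restricted to observed training records — test genotypes need never appear
in training; their information flows through `G`.

Scenario definitions (defaults: 105 of 147 genotypes per training split,
100 repetitions, both configurable):

1. *Tested genotypes, new year.* Training = the sampled genotypes' records
   in all of the other year's trials, environments = regions (J = 3), or
   the target region alone for the single-environment (SE) baseline.
   Evaluation = the same sampled genotypes' BLUEs in the target region and
   year. Year-to-year transfer is deliberate extrapolation: the fitted
   region effects are carried forward. An `evaluate_all` flag switches
   evaluation to the whole panel for sensitivity analysis, since the
   sampled-genotypes reading, while the natural one, is a choice.
2. *Untested genotypes, known trial.* Training = sampled genotypes in all
   six trials (J = 6); prediction for the held-out genotypes in the target
   trial; held-out genotypes never enter training. `environment_dropout`
   removes named trials from training while keeping the same partitions,
   for paired with/without comparisons of training-set composition.
3. *Untested genotypes, new year.* Scenario-1 training, held-out genotypes
   evaluated.

Ability is the Pearson correlation of predicted genotypic effects with
observed BLUEs. Repetition k of any run draws its partition from a
generator seeded by (seed, k) only, so comparisons across models and
dropout variants are paired. Degenerate repetitions (zero variance on
either side, e.g. exactly unrelated candidates) yield an undefined
correlation: they are recorded as missing and excluded from means with a
count, never imputed as zero.

## G×E summaries

Genetic correlations `ρ_jk = σ_jk/(σ_j σ_k)` come from the US fit and are
PSD whenever the fitted `Σ_E` is (guaranteed by the log-Cholesky
parametrization). GGE scores are the SVD of the environment-centred
genotype × environment table — genotype main effect plus G×E retained,
environments centred but **not** scaled (the standard GGE convention;
scaling to unit variance would equalise arrow lengths and hide variance
heterogeneity), singular values split symmetrically between genotype and
environment scores. With all components, the cosine between environment
vectors equals the Pearson correlation of the centred columns exactly and
squared vector length equals the centred sum of squares; the 2-component
plot is an approximation, so both full-space and 2-component cosines are
reported to make truncation distortion visible.

## Synthetic data generator

The generator exists so that every stage is testable without any download,
and doubles as the package's demonstration data. It emulates a European
potato variety-testing programme: 147 tetraploid genotypes, ~39k SNP
dosages, six trials (NL/PL/SP × 2017/2018) in row–column resolvable designs
with 2 complete blocks.

- **Dosages** are Binomial(4, p_m) with marker frequencies uniform on a
  configurable range — a panel with weak population structure. An optional
  half-sib scheme (each family shares one parent; offspring draw 2 of 4
  alleles from the parent's gamete, 2 from the population) creates additive
  relationships ≈ 0.25 within families. The study-scale presets use 21
  families of 7: without relatedness, untested-genotype prediction from an
  independent-marker panel would be uninformative, which real panels with
  shared ancestry and LD are not.
- **BLUEs** are drawn exactly under the stage-2 model, `g` via the Cholesky
  factors of `G` and `Σ_E` (so vec(g) has covariance `G ⊗ Σ_E`), plus
  independent per-environment residuals. True genetic values are returned
  so recovery tests need no re-derivation.
- **Trait presets** use genetic correlation matrices and per-trial
  heritabilities typical of three potato traits — tuber weight (strong,
  patchy G×E: correlations 0.24–0.80, one trial poorly correlated with all
  others), tuber length (moderate: 0.64–0.87), dry matter (little G×E:
  0.84–0.96, same-location pairs most alike) — with stage-2 residuals set
  from the heritabilities as `r_j = σ²_gj (1/H²_j − 1)`. Per-trial genetic
  variances for the heterogeneous trait, and the plot-level row/column/block
  variances (0.1/0.1/0.05 on a unit genetic-variance scale), are not
  published quantities; they were fixed once at values that land stage-1
  heritabilities in the 0.6–0.98 band and are configuration, not claims.
- **Field layouts** enforce the resolvable-blocks property and distinct
  rows/columns across blocks where dimensions allow (a repair pass swaps
  conflicting plots), approximating a latinized row–column design without
  reproducing any specific randomisation software's output.

What the generator does **not** emulate: linkage disequilibrium and QTL
architecture (markers are independent and effects implicitly infinitesimal
through `G`), spatial autocorrelation beyond row/column bands, outliers and
missing plots, and real panels' continuous kinship gradients (relatedness
is blocky by family). Tests passing on this generator therefore validate
the estimation and prediction machinery under the model's own assumptions
— exactness of likelihoods, parameter recovery, scenario mechanics — not
the field performance of genomic prediction on any particular real panel.

## Numerical and testing choices

- Eigenvalues of `G` are clipped at 0; batched J×J Cholesky failures mark a
  parameter point as infeasible (large objective) rather than aborting.
- `pivot_blues` preserves first-appearance order of genotypes and
  environments; silent lexical sorting would permute `Σ_E` against the
  caller's environment order.
- Test oracles are independent routes: a dense no-rotation REML likelihood,
  a brute-force double-loop GRM, Henderson's mixed-model equations for
  BLUPs, a 2-parameter likelihood grid for the single-environment fit, and
  the closed-form balanced one-way ANOVA REML for the generic
  variance-component engine.
- Study-scale recovery checks average US-fit correlation estimates over
  several generator seeds (8 for the heterogeneous preset, 3 for the
  near-homogeneous one) so that Monte-Carlo error at n = 147 is small
  relative to the tolerance being checked; replicate counts were sized from
  the estimator's sampling spread (per-entry SD ≈ 0.1 at n = 147).
- LRT calibration is verified at the interior null (CS truth, CS vs
  UN.het, 500 replicates) and checked for conservativeness at the boundary
  null (ME truth, ME vs CS).
- Heavier simulations are scaled to keep the default suite fast: parameter
  recovery at n = 300, J = 4, 20 seeds; scenario orderings at 20 paired
  repetitions; acceptance-script scenarios at 10 repetitions per target
  with 8k markers. Defaults in the package itself remain at the
  study-scale values (39k markers, 105/100 splits).

## Known limitations

- No factor-analytic or spatial (AR1×AR1) structures; no dominance or
  digenic relationship matrices; no Bayesian alternatives.
- Scenario 1/3 support exactly one training year per direction;
  multi-year forecasting is out of scope.
- The dense incomplete-pattern path is O(N³) per likelihood evaluation and
  meant for modest record counts (hundreds).
- Boundary LRT p-values are reported uncorrected (flagged, not mixture-
  adjusted).
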