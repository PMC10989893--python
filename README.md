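# tetragp

Multienvironment genomic prediction for tetraploid crops: G-BLUP with
explicit genotype-by-environment (G×E) covariance modelling, built for
variety-testing programmes of the kind run for potato — a diversity panel of
~150 tetraploid genotypes scored at tens of thousands of SNP allele dosages
and phenotyped in a handful of trials (locations × years).

## Who this is for

Quantitative geneticists and breeders who need to

- build an additive genomic relationship matrix (GRM) from **allele dosages**
  (0–4 in a tetraploid),
- extract per-trial adjusted genotype means (BLUEs) and heritabilities from
  row–column resolvable field designs,
- fit multienvironment G-BLUP models whose genetic covariance between
  environments is structured, and pick the structure a trait actually needs,
- quantify G×E through genetic correlations and GGE biplot scores, and
- estimate cross-validated **prediction ability** for realistic breeding
  questions: forecasting tested material into a new year, predicting new
  material in known trials, and predicting new material into a new year.

## The model

Stage 1 reduces each trial to BLUEs with the per-plot model
`y = genotype + block + row + column + error` (genotype and block fixed,
rows/columns random), and reports entry-mean broad-sense heritability
`H² = σ²_g / (σ²_g + σ²_ε / n_blocks)`.

Stage 2 is the multienvironment G-BLUP

```
y_ij = μ_j + g_ij + ε_ij ,    vec(g) ~ N(0, G ⊗ Σ_E) ,   ε_ij ~ N(0, r_j)
```

where `G = ZZ' / (k · Σ_m p_m(1−p_m))` is the dosage-based GRM at ploidy
`k = 4` (`Z` the column-centred dosages) and `Σ_E` is the J×J genetic
covariance between environments. Four nested parametrizations of `Σ_E` are
fitted by REML:

| kind    | structure                                          | free parameters |
|---------|----------------------------------------------------|-----------------|
| ME      | σ²_g · (all-ones) — no G×E                         | 1               |
| CS      | common variance, common covariance                 | 2               |
| UN.het  | per-environment variances, one correlation ρ       | J + 1           |
| US      | unstructured: all variances and covariances free   | J(J+1)/2        |

Because every genotype is typically observed in every environment, the
restricted likelihood is evaluated through the eigendecomposition of `G`,
which factors the nJ×nJ covariance into n independent J×J blocks — fits take
seconds at n ≈ 150, J = 6. Structures are compared by restricted
log-likelihood and likelihood-ratio tests; genetic correlations
`ρ_jk = σ_jk / (σ_j σ_k)` come from the US fit.

Prediction scenarios (all with repeated, model-paired train/test splits;
ability = Pearson correlation of predicted genotypic effects with observed
BLUEs):

1. **tested genotypes, new year** — train on one year's trials
   (environments = regions), predict the same genotypes in a region the
   following year;
2. **untested genotypes, known trial** — train on 105 of 147 genotypes in
   all six trials, predict the held-out 42 in one target trial;
3. **untested genotypes, new year** — scenario-1 training, held-out
   genotypes evaluated.

## Worked example

```bash
python examples/05_prediction_scenarios.py
```

```
scenario 1 vs 3 - NL 2018 from the 2017 trials (ME model, 10 splits):
  tested genotypes (scenario 1):   ability = 0.573
  untested genotypes (scenario 3): ability = 0.269
  forecasting known material is much easier than predicting new material.

scenario 2 - untested genotypes in PL.18, all 6 trials train (10 splits):
  SE      ability = 0.223
  ME      ability = 0.228
  CS      ability = 0.262
  US      ability = 0.303
  PL.18 correlates poorly with the other trials, so structures that model
  per-trial variances and correlations (US) have the advantage.
```

The example simulates a 147-genotype, six-trial panel with a strongly
heterogeneous (tuber-weight-like) G×E truth, then runs the scenarios. The
0.57-vs-0.27 gap shows how much harder prediction is without phenotypes on
the candidates; the SE→US progression at PL.18 shows a trial with low
genetic correlation to the rest rewarding the unstructured covariance.
Other examples cover the GRM (`01`), stage-1 BLUEs and H² (`02`), structure
selection by LRT (`03`) and G×E summaries (`04`).

A configuration-driven runner reproduces the whole workflow
(`tetragp all config.yaml`, or `tetragp simulate/grm/blues/fit/predict/
summarize` for individual stages; see `tetragp --help`).

## Layout

```
src/tetragp/
  genomics.py        dosage I/O, allele frequencies, tetraploid GRM
  synthetic_data.py  generator for dosages, multienvironment BLUEs, trial plots
  trial_stage.py     stage-1 BLUEs and broad-sense heritability
  reml_core.py       REML engine: SE + four multienvironment structures, LRT
  prediction.py      BLUP prediction and the three CV scenarios
  gxe_summary.py     genetic correlations, GGE biplot scores
  pipeline.py, cli.py  end-to-end runner and thin CLI
docs/methods.md      modelling assumptions, parametrizations, design choices
examples/            one short narrative script per capability
```
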