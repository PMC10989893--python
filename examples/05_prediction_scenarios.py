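"""The three breeding prediction scenarios, cross-validated.

Scenario 1 forecasts *tested* genotypes into a new year; scenario 2 predicts
*untested* genotypes in a known trial using all trials; scenario 3 predicts
untested genotypes into a new year. Prediction ability is the correlation
between predicted genotypic effects and observed adjusted means in the
evaluation set, averaged over repeated train/test splits (paired across
models: repetition k always uses the same split).
"""

from tetragp import (
    ScenarioSpec,
    compute_grm,
    run_scenario1,
    run_scenario2,
    run_scenario3,
    simulate_dosages,
    simulate_multienv_blues,
    tuber_weight_config,
)

cfg = tuber_weight_config(seed=5, n_markers=3000)
dosages = simulate_dosages(cfg)
gr = compute_grm(dosages, ridge=1e-6)
blues, _ = simulate_multienv_blues(dosages, cfg, G=gr.G)

print("scenario 1 vs 3 - NL 2018 from the 2017 trials (ME model, 10 splits):")
s1 = run_scenario1(blues, gr, ScenarioSpec(scenario=1, target=("NL", 2018),
                                           model="ME", n_reps=10, seed=2))
s3 = run_scenario3(blues, gr, ScenarioSpec(scenario=3, target=("NL", 2018),
                                           model="ME", n_reps=10, seed=2))
print(f"  tested genotypes (scenario 1):   ability = {s1.mean_ability:.3f}")
print(f"  untested genotypes (scenario 3): ability = {s3.mean_ability:.3f}")
print("  forecasting known material is much easier than predicting new material.\n")

print("scenario 2 - untested genotypes in PL.18, all 6 trials train (10 splits):")
for model in ("SE", "ME", "CS", "US"):
    res = run_scenario2(blues, gr, ScenarioSpec(scenario=2, target="PL.18",
                                                model=model, n_reps=10, seed=2))
    print(f"  {model:7} ability = {res.mean_ability:.3f}")
print("  PL.18 correlates poorly with the other trials, so structures that"
      " model per-trial variances and correlations (US) have the advantage.")
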