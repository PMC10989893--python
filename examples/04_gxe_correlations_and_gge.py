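"""Quantify G x E: genetic correlations from the US fit, plus GGE scores.

Genetic correlations below 1 and heterogeneous genetic variances are the two
signatures of genotype-by-environment interaction. The GGE biplot summarises
the same structure geometrically: arrow length ~ genetic standard deviation
in an environment, cosine between arrows ~ genetic correlation.
"""

import numpy as np

from tetragp import (
    compute_grm,
    genetic_correlations,
    gge_scores,
    reml_fit_multienv,
    simulate_dosages,
    simulate_multienv_blues,
    tuber_weight_config,
)

cfg = tuber_weight_config(seed=1, n_markers=3000)
dosages = simulate_dosages(cfg)
gr = compute_grm(dosages, ridge=1e-6)
blues, _ = simulate_multienv_blues(dosages, cfg, G=gr.G)

us = reml_fit_multienv(blues, gr.to_frame(), "US")
corr = genetic_correlations(us)
print("genetic correlations between trials (US fit):")
print(corr.to_frame().round(2).to_string())
iu = np.triu_indices(6, 1)
print(f"\nrange {corr.rho[iu].min():.2f}..{corr.rho[iu].max():.2f} -> "
      "strongly heterogeneous G x E (the low-correlation trial ranks genotypes differently)")

gge = gge_scores(blues)
print(f"\nGGE: first two components explain "
      f"{100 * gge.variance_explained[:2].sum():.0f}% of the centred variation")
print("environment scores (arrows in the biplot):")
print(gge.to_frames()["env_scores"].round(2).to_string())
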