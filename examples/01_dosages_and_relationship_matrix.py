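"""Simulate a tetraploid SNP panel and compute its genomic relationship matrix.

Allele dosages (0-4 copies of the alternative allele) are drawn for a
half-sib structured panel; the GRM is the VanRaden-style matrix generalised
to ploidy 4. Within-family entries should sit near 0.25 (half-sibs), the
diagonal near 1.
"""

import numpy as np

from tetragp import SimConfig, compute_grm, simulate_dosages

cfg = SimConfig(n_genotypes=60, n_markers=3000, family_size=6, seed=11)
dosages = simulate_dosages(cfg)
print(f"dosage matrix: {dosages.shape[0]} genotypes x {dosages.shape[1]} markers, "
      f"values {dosages.dosages.min():.0f}..{dosages.dosages.max():.0f}")

gr = compute_grm(dosages)
fam = np.arange(60) // 6
same_family = (fam[:, None] == fam[None, :]) & ~np.eye(60, dtype=bool)
print(f"mean diagonal of G:        {np.mean(np.diag(gr.G)):.3f}   (~1 for a panel in HWE)")
print(f"mean within-family G:      {gr.G[same_family].mean():.3f}   (~0.25 for half-sibs)")
print(f"mean between-family G:     {gr.G[~same_family & ~np.eye(60, dtype=bool)].mean():.3f}   (~0, row sums are 0)")
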