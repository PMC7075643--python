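"""Simulate a two-group panel with admixed DH progeny.

Builds 100 dent-like and 100 flint-like inbred founders (Balding-Nichols
differentiation, F_ST = 0.1) plus 100 admixed doubled haploids, each a
single recombinant D x F gamete doubled, and polygenic phenotypes.
"""

import numpy as np

from admixgwas import SimConfig, simulate_panel

cfg = SimConfig(seed=1, n_dent=100, n_flint=100, n_admixed=100,
                n_markers=1000, n_chromosomes=5, fst=0.1)
panel = simulate_panel(cfg)

G = panel.genotypes
props = [panel.tracks[l].group_proportion("D") for l in panel.tracks]
print(f"panel: {G.n_lines} lines x {G.n_markers} markers "
      f"on {cfg.n_chromosomes} chromosomes")
print(f"dent genome proportion of admixed lines: "
      f"mean {np.mean(props):.3f}, range {min(props):.2f}-{max(props):.2f}")
print(f"phenotype: mean {panel.phenotypes.mean():.3f}, "
      f"sd {panel.phenotypes.std():.3f} (polygenic h2 = 0.5 by construction)")
# A mean near 0.5 with a wide range is the signature of single-meiosis
# DH lines: each genome is one recombinant gamete, so the admixture
# fraction varies strongly between sibs.
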