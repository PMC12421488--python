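"""Simulate one 50 kb window under the urban/rural isolation-with-
migration model and summarise its differentiation and diversity.

The default model is the study system: a 78-diploid urban deme that
split from a large source population 32 generations ago, with high
immigration into the urban deme and elevated urban inbreeding.
"""

import numpy as np

from urbanpurge import DemographicModel, simulate_im, window_fst

model = DemographicModel()
pis, fsts, n_sites = [], [], []
for seed in range(10):  # 10 independent 50 kb windows
    gm = simulate_im(model, seed=seed)  # 32 urban + 12 rural diploids
    d, n = gm.derived_counts(gm.pop_indices("rural"))
    poly = (d > 0) & (d < n)
    pi = float((2 * d[poly] * (n[poly] - d[poly]) / (n[poly] * (n[poly] - 1.0))).sum())
    pis.append(pi / model.window_length)
    fsts.append(window_fst(gm, "urban", "rural"))
    n_sites.append(gm.n_sites)

print(f"mean segregating sites per window : {np.mean(n_sites):.0f}")
print(f"mean rural pi per bp              : {np.mean(pis):.2e}")
print(f"mean urban-rural window FST       : {np.mean(fsts):.4f}")
print(f"median window FST                 : {np.median(fsts):.4f}")
print()
print("pi near 5e-4/bp matches the diversity of real non-urban anole")
print("populations; window FST of a few percent is the weak neutral")
print("differentiation expected after ~32 generations with gene flow.")
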