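"""Windowed FST / pi / Tajima's D / PBS scan over simulated windows.

Simulates independent 50 kb windows (one of them under a strong sweep
in the urban deme), concatenates them into a small genome and runs the
sliding-window scan with three groups so the population branch
statistic (PBS) localises differentiation to the urban lineage.
"""

import numpy as np

from urbanpurge import DemographicModel, concatenate, make_scenario, simulate_im, window_scan

base = DemographicModel()
windows = []
for k in range(9):
    gm = simulate_im(base, 32, 24, seed=k, chrom=f"w{k}")
    windows.append(gm)
sweep = simulate_im(make_scenario(base, "sweep"), 32, 24, seed=99, chrom="w9")
windows.append(sweep)

# split the rural sample into 'rural' + 'outgroup' so PBS has 3 groups
for gm in windows:
    rural = np.flatnonzero(gm.pop == "rural")
    gm.pop[rural[12:]] = "outgroup"

genome = concatenate(windows)
scan = window_scan(genome, ["urban", "rural", "outgroup"], window_bp=50_000, step_bp=50_000)
cols = ["chrom", "n_snps", "pi", "tajd", "fst", "pbs"]
print(scan[cols].round(4).to_string(index=False))
print()
print("the sweep window (w9) stands out with high FST and PBS and")
print("collapsed urban diversity; neutral windows sit near the")
print("genome-wide background.")
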