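"""Simulation-calibrated FST thresholds and joint FST+PBS outlier calls.

The calibration mirrors the study design: many 50 kb windows are
simulated under three scenarios — neutral isolation-with-migration,
strong background selection + inbreeding (all population sizes scaled by
0.1), and a strong sweep (s = 1 conditioned on fixation in the urban
deme) — and the resulting window-FST distributions locate thresholds
separating drift from selection.  Candidate windows must both exceed the
moderate FST threshold and sit in the genome-wide top PBS percentile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import SCENARIOS, DemographicModel, make_scenario
from .scan import window_fst
from .simulate import simulate_im

QUANTILES = (50.0, 95.0, 99.0, 99.9)


@dataclass
class CalibrationResult:
    fst: dict[str, np.ndarray]
    quantiles: pd.DataFrame
    thresholds: tuple[float, float] = (0.2, 0.35)

    def scenario_quantile(self, scenario: str, q: float) -> float:
        return float(np.nanpercentile(self.fst[scenario], q))


def run_calibration(
    base: DemographicModel,
    reps_per_scenario: int = 10_000,
    n_sample_urban: int = 32,
    n_sample_rural: int = 12,
    seed: int = 0,
    scenarios: tuple[str, ...] = SCENARIOS,
    thresholds: tuple[float, float] = (0.2, 0.35),
) -> CalibrationResult:
    """Window-FST null/alternative distributions for each scenario.

    Each replicate simulates one independent window and records its
    ratio-of-sums Bhatia FST between the urban and rural samples.  In
    scenarios whose rescaled deme sizes fall below the requested sample
    sizes (the BGS x0.1 scaling), samples are clamped to the deme size.
    """
    if reps_per_scenario < 100:
        raise ValueError("need >= 100 replicates per scenario for stable quantiles")
    fst: dict[str, np.ndarray] = {}
    for s_i, kind in enumerate(scenarios):
        model = make_scenario(base, kind)
        n_su = min(n_sample_urban, model.n_urban)
        n_sr = min(n_sample_rural, model.n_rural)
        vals = np.empty(reps_per_scenario)
        for r in range(reps_per_scenario):
            rep_seed = int(
                np.random.default_rng([seed, s_i, r]).integers(0, 2**31 - 1)
            )
            gm = simulate_im(model, n_su, n_sr, seed=rep_seed)
            vals[r] = window_fst(gm, "urban", "rural")
        fst[kind] = vals
    rows = []
    for kind, vals in fst.items():
        row = {"scenario": kind}
        for q in QUANTILES:
            row[f"q{q:g}"] = float(np.nanpercentile(vals, q))
        rows.append(row)
    return CalibrationResult(
        fst=fst, quantiles=pd.DataFrame(rows), thresholds=thresholds
    )


@dataclass
class OutlierCall:
    chrom: str
    start: int
    end: int
    fst: float
    pbs: float
    exceeds_moderate: bool
    exceeds_strict: bool
    pbs_top: bool
    candidate: bool


def call_outliers(
    windows: pd.DataFrame,
    fst_threshold: float = 0.2,
    strict_threshold: float = 0.35,
    pbs_quantile: float = 0.95,
) -> pd.DataFrame:
    """Flag windows by the joint FST + PBS rule.

    ``windows`` must carry chrom/start/end/fst/pbs columns (as produced
    by :func:`urbanpurge.scan.window_scan` with three groups).  The PBS
    cutoff is the genome-wide ``pbs_quantile`` percentile over finite
    PBS values, compared with >= (ties included).  ``candidate`` is
    ``exceeds_moderate AND pbs_top``.
    """
    required = {"chrom", "start", "end", "fst", "pbs"}
    if not required.issubset(windows.columns):
        raise ValueError(f"windows table missing columns {required - set(windows.columns)}")
    fst = windows["fst"].to_numpy(float)
    pbs_v = windows["pbs"].to_numpy(float)
    finite = np.isfinite(pbs_v)
    if finite.any():
        cutoff = float(np.percentile(pbs_v[finite], 100 * pbs_quantile))
    else:
        cutoff = np.inf
    out = windows[["chrom", "start", "end", "fst", "pbs"]].copy()
    out["exceeds_moderate"] = np.isfinite(fst) & (fst >= fst_threshold)
    out["exceeds_strict"] = np.isfinite(fst) & (fst >= strict_threshold)
    out["pbs_top"] = finite & (pbs_v >= cutoff)
    out["candidate"] = out["exceeds_moderate"] & out["pbs_top"]
    return out
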