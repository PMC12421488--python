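"""Umbrella pipeline: synthetic cohort -> QC -> SFS -> load -> scan ->
calibration -> outliers -> permutation test, with per-stage artifacts
and a JSON report.

All randomness flows from one config seed through named substreams, so
every stage is independently reproducible and a rerun with the same
seed produces an identical report.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calibrate as _calibrate
from . import intervals as _intervals
from . import load as _load
from . import qc as _qc
from . import scan as _scan
from . import sfs as _sfs
from . import vcfio
from .genotypes import GenotypeMatrix, concatenate
from .model import DemographicModel, EffectDFE
from .simulate import load_cohort_model, simulate_load_cohort, simulate_windows

STAGES = ("qc", "filter", "sfs", "load", "scan", "calibrate", "outliers", "permtest")


@dataclass
class RunConfig:
    """Configuration of a full synthetic-cohort pipeline run."""

    seed: int = 0
    out_dir: str = "urbanpurge_run"
    # cohort (QC / SFS / load stages)
    model: dict = field(default_factory=dict)
    dfe: dict = field(default_factory=dict)
    n_cohort_urban: int = 64
    n_cohort_rural: int = 16
    n_sample_urban: int = 32
    n_sample_rural: int = 12
    # filtering
    max_missing: float = 1.0 / 3.0
    maf_min: float = 0.0
    # projections
    n_proj_urban: int = 64
    n_proj_rural: int = 24
    neutral_n: int = 20_000
    n_blocks: int = 100
    n_boot_reps: int = 100
    # QC thresholds
    theta_thr: float = 0.125
    r_thr: float = 0.25
    # scan / calibration
    scan_windows: int = 40
    window_bp: int = 50_000
    step_bp: int = 50_000
    calib_reps: int = 500
    fst_threshold: float = 0.2
    strict_threshold: float = 0.35
    pbs_quantile: float = 0.95
    # permutation test
    n_perm: int = 500

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _stream(seed: int, name: str) -> int:
    """Named substream seed (stable across processes)."""
    tag = zlib.crc32(name.encode()) % (2**31)
    h = np.random.SeedSequence([seed, tag])
    return int(h.generate_state(1)[0] % (2**31 - 1))


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return (and persist) the JSON report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}

    model = load_cohort_model(**config.model)
    dfe = EffectDFE(**config.dfe) if config.dfe else EffectDFE()
    cohort = simulate_load_cohort(
        model,
        dfe,
        n_sample_urban=config.n_cohort_urban,
        n_sample_rural=config.n_cohort_rural,
        seed=_stream(config.seed, "cohort"),
    )
    vcfio.write_vcf(cohort, out / "cohort.vcf")

    # ---- qc
    kin = _qc.pairwise_kinship(cohort)
    coverage = {str(s): 30.0 for s in cohort.samples}  # error-free synthetic calls
    kept = _qc.prune_related(kin, coverage, config.theta_thr, config.r_thr)
    f_urban = _qc.cohort_inbreeding(cohort, "urban")
    f_rural = _qc.cohort_inbreeding(cohort, "rural")
    kin.to_csv(out / "kinship.tsv", sep="\t", index=False)
    report["qc"] = {
        "n_pairs": int(len(kin)),
        "n_flagged": int(
            ((kin["phi"] > config.theta_thr) & (kin["r"] > config.r_thr)).sum()
        ),
        "kept": kept,
        "mean_f_urban": float(f_urban["f_hat"].mean()),
        "mean_f_rural": float(f_rural["f_hat"].mean()),
        "f_per_individual": dict(
            zip(
                list(f_urban["id"]) + list(f_rural["id"]),
                [round(v, 6) for v in list(f_urban["f_hat"]) + list(f_rural["f_hat"])],
            )
        ),
    }

    # ---- filter
    keep_idx = [k for k, s in enumerate(cohort.samples) if str(s) in kept]
    cohort_kept = cohort.take_individuals(np.array(keep_idx))
    filtered = _sfs.filter_sites(cohort_kept, config.max_missing, config.maf_min)
    report["filter"] = {
        "n_sites_in": int(cohort.n_sites),
        "n_sites_out": int(filtered.n_sites),
        "n_individuals": int(filtered.n_individuals),
    }

    # ---- sfs
    sfs_block: dict = {}
    for cat in ("intergenic", "low", "moderate", "high"):
        sites = np.flatnonzero(filtered.effect == cat)
        if sites.size == 0:
            continue
        s = _sfs.sfs_from_genotypes(filtered, "urban", config.n_proj_urban, sites)
        sfs_block[cat] = {
            "n": s.n,
            "n_sites": round(s.n_sites, 3),
            "singleton_mass": round(float(s.counts[1]), 3),
        }
    report["sfs"] = sfs_block

    # ---- load
    load_df = _load.load_analysis(
        filtered,
        n_x=config.n_proj_urban,
        n_y=config.n_proj_rural,
        neutral_n=config.neutral_n,
        n_blocks=config.n_blocks,
        n_reps=config.n_boot_reps,
        seed=_stream(config.seed, "load"),
    )
    load_df.to_csv(out / "load.tsv", sep="\t", index=False)
    report["load"] = {
        row["category"]: {
            "rxy_prime": round(row["rxy_prime"], 4),
            "ci_low": round(row["ci_low"], 4),
            "ci_high": round(row["ci_high"], 4),
        }
        for _, row in load_df.iterrows()
    }

    # ---- scan (third group: a disjoint rural draw standing in for the
    # wider-region outgroup)
    win_model = DemographicModel(**config.model) if config.model else DemographicModel()
    wins = simulate_windows(
        win_model,
        config.scan_windows,
        n_sample_urban=config.n_sample_urban,
        n_sample_rural=2 * config.n_sample_rural,
        seed=_stream(config.seed, "scan"),
    )
    for gm in wins:
        half = config.n_sample_rural
        rural_cols = np.flatnonzero(gm.pop == "rural")
        gm.pop[rural_cols[half:]] = "outgroup"
    genome = concatenate(wins)
    windows = _scan.window_scan(
        genome,
        ["urban", "rural", "outgroup"],
        window_bp=config.window_bp,
        step_bp=config.step_bp,
    )
    windows.to_csv(out / "windows.tsv", sep="\t", index=False)
    fin = windows["fst"].to_numpy(float)
    report["scan"] = {
        "n_windows": int(len(windows)),
        "mean_fst": float(np.nanmean(fin)),
        "mean_pi": float(np.nanmean(windows["pi"])),
    }

    # ---- calibrate
    calib = _calibrate.run_calibration(
        win_model,
        reps_per_scenario=config.calib_reps,
        n_sample_urban=config.n_sample_urban,
        n_sample_rural=config.n_sample_rural,
        seed=_stream(config.seed, "calibrate"),
        thresholds=(config.fst_threshold, config.strict_threshold),
    )
    calib.quantiles.to_json(out / "calibration.json", orient="records", indent=2)
    report["calibrate"] = {
        r["scenario"]: {k: round(v, 4) for k, v in r.items() if k != "scenario"}
        for r in calib.quantiles.to_dict("records")
    }

    # ---- outliers
    calls = _calibrate.call_outliers(
        windows,
        fst_threshold=config.fst_threshold,
        strict_threshold=config.strict_threshold,
        pbs_quantile=config.pbs_quantile,
    )
    calls.to_csv(out / "outliers.tsv", sep="\t", index=False)
    report["outliers"] = {
        "n_exceeds_moderate": int(calls["exceeds_moderate"].sum()),
        "n_exceeds_strict": int(calls["exceeds_strict"].sum()),
        "n_candidates": int(calls["candidate"].sum()),
    }

    # ---- permtest: are candidate windows (or the top-FST windows when
    # none) enriched for high FST relative to rotation null?
    win_set = _intervals.IntervalSet(
        chrom=windows["chrom"].to_numpy(),
        start=windows["start"].to_numpy(),
        end=windows["end"].to_numpy(),
        chrom_lengths=genome.chrom_lengths,
    )
    cand_rows = calls[calls["candidate"]]
    if len(cand_rows) == 0:
        cand_rows = windows.nlargest(5, "fst")
    cand_set = _intervals.IntervalSet(
        chrom=cand_rows["chrom"].to_numpy(),
        start=cand_rows["start"].to_numpy(),
        end=cand_rows["end"].to_numpy(),
        chrom_lengths=genome.chrom_lengths,
    )
    perm = _intervals.circular_permutation_test(
        win_set,
        windows["fst"].to_numpy(float),
        cand_set,
        n_perm=config.n_perm,
        seed=_stream(config.seed, "permtest"),
    )
    report["permtest"] = {
        "observed_mean_fst": round(perm.observed, 5),
        "p_greater": round(perm.p_greater, 5),
        "p_less": round(perm.p_less, 5),
        "n_perm": perm.n_perm,
    }

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
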