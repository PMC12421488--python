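"""R_XY / R'XY mutation-load statistics and block-bootstrap intervals.

R_XY compares, in expectation over pairs of genomes, the number of
derived alleles seen in population X but not Y against the converse.  It
is evaluated directly on the joint 2D SFS:

    R_XY = sum_ij S[i,j] (i/n_x)(1 - j/n_y) / sum_ij S[i,j] (j/n_y)(1 - i/n_x)

R'XY normalises a variant category's R_XY by the same statistic at
putatively neutral markers (a seeded subsample of polymorphic intergenic
sites, 20,000 by default), so R'XY < 1 indicates relative depletion —
e.g. purging — of that category in X.  Uncertainty comes from a
100-block bootstrap over contiguous, equal-SNP-count genome blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .sfs import SFS2D, joint_sfs

logger = logging.getLogger(__name__)


class RxyUndefinedError(ValueError):
    """Raised when an R_XY numerator or denominator has zero mass
    (e.g. a spectrum concentrated on shared fixed sites)."""


@dataclass
class BootstrapResult:
    point: float
    replicates: np.ndarray
    ci_low: float
    ci_high: float
    n_blocks: int
    n_reps: int

    def covers(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high


def _rxy_sums(sfs2: SFS2D) -> tuple[float, float]:
    i = np.arange(sfs2.n_x + 1)[:, None] / sfs2.n_x
    j = np.arange(sfs2.n_y + 1)[None, :] / sfs2.n_y
    num = float((sfs2.counts * i * (1.0 - j)).sum())
    den = float((sfs2.counts * j * (1.0 - i)).sum())
    return num, den


def rxy(sfs2: SFS2D) -> float:
    """R_XY from a joint spectrum (X on rows, Y on columns)."""
    num, den = _rxy_sums(sfs2)
    if den <= 0:
        raise RxyUndefinedError(
            f"R_XY undefined: numerator={num:g}, denominator={den:g}"
        )
    return num / den


def rxy_prime(sfs2_category: SFS2D, sfs2_neutral: SFS2D) -> float:
    """Category R_XY normalised by the neutral-marker R_XY."""
    return rxy(sfs2_category) / rxy(sfs2_neutral)


def neutral_site_subsample(
    gm: GenotypeMatrix,
    size: int = 20_000,
    category: str = "intergenic",
    seed: int = 0,
) -> np.ndarray:
    """Seeded subsample of polymorphic sites of the neutral category
    (all of them when fewer than ``size``); returns sorted site indices."""
    derived, n_called = gm.derived_counts()
    poly = (derived > 0) & (derived < n_called)
    cand = np.flatnonzero((gm.effect == category) & poly)
    if cand.size == 0:
        raise ValueError(f"no polymorphic {category!r} sites to normalise with")
    if cand.size <= size:
        return cand
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(cand, size=size, replace=False))


def make_blocks(n_sites: int, n_blocks: int = 100) -> list[np.ndarray]:
    """Contiguous near-equal-SNP-count blocks in genome order (chromosome
    boundaries may be crossed to equalise counts)."""
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    if n_sites < n_blocks:
        raise ValueError(f"need >= {n_blocks} sites, got {n_sites}")
    return np.array_split(np.arange(n_sites), n_blocks)


def block_bootstrap(
    gm: GenotypeMatrix,
    statistic,
    n_blocks: int = 100,
    n_reps: int = 100,
    seed: int = 0,
) -> BootstrapResult:
    """Generic block bootstrap of ``statistic(gm, site_indices)``.

    The genome is partitioned into ``n_blocks`` contiguous blocks of
    near-equal SNP count; each replicate resamples blocks with
    replacement and recomputes the statistic on the concatenated sites.
    Replicates where the statistic is undefined (raises ``ValueError``)
    are dropped; more than 50% undefined is an error.
    """
    blocks = make_blocks(gm.n_sites, n_blocks)
    point = float(statistic(gm, np.arange(gm.n_sites)))
    rng = np.random.default_rng(seed)
    reps = []
    n_failed = 0
    for _ in range(n_reps):
        chosen = rng.integers(0, n_blocks, size=n_blocks)
        sites = np.concatenate([blocks[b] for b in chosen])
        try:
            reps.append(float(statistic(gm, sites)))
        except ValueError:
            n_failed += 1
    if n_failed > n_reps / 2:
        raise RuntimeError(
            f"statistic undefined in {n_failed}/{n_reps} bootstrap replicates"
        )
    reps = np.asarray(reps)
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return BootstrapResult(point, reps, float(lo), float(hi), n_blocks, n_reps)


def load_analysis(
    gm: GenotypeMatrix,
    pop_x: str = "urban",
    pop_y: str = "rural",
    n_x: int = 64,
    n_y: int = 24,
    categories: tuple[str, ...] = ("low", "moderate", "high"),
    neutral_category: str = "intergenic",
    neutral_n: int = 20_000,
    n_blocks: int = 100,
    n_reps: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-category R_XY and R'XY with 100-block bootstrap CIs.

    The neutral subsample is drawn once and resampled with the blocks.
    Block spectra are additive, so each bootstrap replicate sums
    precomputed per-block 2D spectra instead of re-projecting sites.
    Returns a DataFrame with columns category, rxy, rxy_prime, ci_low,
    ci_high (CI on R'XY), n_sites.
    """
    neutral_sites = neutral_site_subsample(gm, neutral_n, neutral_category, seed)
    blocks = make_blocks(gm.n_sites, n_blocks)
    block_of = np.empty(gm.n_sites, dtype=np.int64)
    for b, idx in enumerate(blocks):
        block_of[idx] = b

    def per_block_spectra(sites: np.ndarray) -> np.ndarray:
        out = np.zeros((n_blocks, n_x + 1, n_y + 1))
        for b in range(n_blocks):
            sub = sites[block_of[sites] == b]
            if sub.size:
                out[b] = joint_sfs(gm, pop_x, pop_y, n_x, n_y, sites=sub).counts
        return out

    neut_blocks = per_block_spectra(neutral_sites)
    cat_blocks = {}
    for cat in categories:
        sites = np.flatnonzero(gm.effect == cat)
        if sites.size == 0:
            logger.warning("no sites in category %r", cat)
        cat_blocks[cat] = per_block_spectra(sites)

    def rxy_of(spectra_sum: np.ndarray) -> float:
        return rxy(SFS2D(n_x, n_y, spectra_sum))

    rng = np.random.default_rng(seed + 1)
    draws = rng.integers(0, n_blocks, size=(n_reps, n_blocks))
    rows = []
    for cat in categories:
        point_r = rxy_of(cat_blocks[cat].sum(axis=0))
        point_neut = rxy_of(neut_blocks.sum(axis=0))
        point = point_r / point_neut
        reps = []
        n_failed = 0
        for rep in range(n_reps):
            sel = draws[rep]
            try:
                reps.append(
                    rxy_of(cat_blocks[cat][sel].sum(axis=0))
                    / rxy_of(neut_blocks[sel].sum(axis=0))
                )
            except RxyUndefinedError:
                n_failed += 1
        if n_failed > n_reps / 2:
            raise RuntimeError(
                f"R'XY undefined in {n_failed}/{n_reps} replicates for {cat!r}"
            )
        reps = np.asarray(reps)
        lo, hi = np.percentile(reps, [2.5, 97.5])
        rows.append(
            {
                "category": cat,
                "rxy": point_r,
                "rxy_prime": point,
                "ci_low": float(lo),
                "ci_high": float(hi),
                "n_sites": int((gm.effect == cat).sum()),
            }
        )
    return pd.DataFrame(rows)
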