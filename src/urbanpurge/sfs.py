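"""Site filtering, site-frequency spectra and hypergeometric projection.

Spectra are built from hard genotypes and projected down to a fixed
haploid sample size per population with the hypergeometric estimator
(each site contributes the probability mass of every possible derived
count in a without-replacement subsample of its called alleles).  Sites
with fewer called alleles than the projection target are skipped and
counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import gammaln

from .genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class SFS1D:
    """Polarised 1D spectrum: ``counts[j]`` is the site mass at derived
    count j out of ``n`` sampled alleles."""

    n: int
    counts: np.ndarray
    polarised: bool = True
    n_skipped: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.n + 1,):
            raise ValueError("counts must have length n+1")
        if (self.counts < -1e-12).any():
            raise ValueError("negative SFS mass")

    @property
    def n_sites(self) -> float:
        return float(self.counts.sum())


@dataclass
class SFS2D:
    """Joint spectrum over two populations; ``counts[i, j]`` is the site
    mass at derived counts (i of n_x, j of n_y)."""

    n_x: int
    n_y: int
    counts: np.ndarray
    polarised: bool = True
    n_skipped: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.n_x + 1, self.n_y + 1):
            raise ValueError("counts must be (n_x+1, n_y+1)")
        if (self.counts < -1e-12).any():
            raise ValueError("negative SFS mass")

    @property
    def n_sites(self) -> float:
        return float(self.counts.sum())

    def transpose(self) -> "SFS2D":
        return SFS2D(self.n_y, self.n_x, self.counts.T.copy(), self.polarised)

    def mask_fixed(self) -> "SFS2D":
        """Zero the (0,0) and (n_x,n_y) corners (sites monomorphic in the
        joint sample)."""
        c = self.counts.copy()
        c[0, 0] = 0.0
        c[-1, -1] = 0.0
        return SFS2D(self.n_x, self.n_y, c, self.polarised, self.n_skipped)


def filter_sites(
    gm: GenotypeMatrix, max_missing: float = 1.0 / 3.0, maf_min: float = 0.0
) -> GenotypeMatrix:
    """Drop sites with too much missingness, then (optionally) low MAF.

    A site is removed when the fraction of missing genotypes exceeds
    ``max_missing``, or when its minor-allele frequency computed on
    non-missing genotypes is below ``maf_min`` (when ``maf_min > 0``).
    Site order is preserved.
    """
    g = gm.genotypes
    miss_frac = (g == MISSING).mean(axis=1)
    keep = miss_frac <= max_missing
    if maf_min > 0:
        derived, n_called = gm.derived_counts()
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_called > 0, derived / np.maximum(n_called, 1), 0.0)
        maf = np.minimum(p, 1.0 - p)
        keep &= (n_called > 0) & (maf >= maf_min)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("filter_sites: removed %d of %d sites", n_drop, gm.n_sites)
    return gm.take_sites(np.flatnonzero(keep))


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def project_site(i: int, n_obs: int, n_target: int) -> np.ndarray:
    """Hypergeometric projection mass of one site.

    Returns the length ``n_target+1`` vector
    ``P[j] = C(i,j) C(n_obs-i, n_target-j) / C(n_obs, n_target)`` — the
    distribution of the derived count in a without-replacement subsample
    of ``n_target`` of the ``n_obs`` called alleles.
    """
    if n_target > n_obs:
        raise ValueError("projection target exceeds observed allele count")
    if not (0 <= i <= n_obs):
        raise ValueError("derived count outside [0, n_obs]")
    j = np.arange(n_target + 1)
    valid = (j <= i) & (n_target - j <= n_obs - i)
    out = np.zeros(n_target + 1)
    jj = j[valid]
    out[valid] = np.exp(
        _log_comb(i, jj)
        + _log_comb(n_obs - i, n_target - jj)
        - _log_comb(n_obs, n_target)
    )
    return out


@lru_cache(maxsize=64)
def projection_matrix(n_obs: int, n_target: int) -> np.ndarray:
    """Stack of :func:`project_site` rows for every i in 0..n_obs."""
    return np.vstack([project_site(i, n_obs, n_target) for i in range(n_obs + 1)])


def _projected_masses(derived, n_called, n_target):
    """Per-site projection mass matrix (n_usable, n_target+1) plus the
    usable-site mask; sites with n_called < n_target are skipped."""
    usable = n_called >= n_target
    masses = np.zeros((int(usable.sum()), n_target + 1))
    d_u = derived[usable]
    n_u = n_called[usable]
    for n_obs in np.unique(n_u):
        P = projection_matrix(int(n_obs), n_target)
        sel = n_u == n_obs
        masses[sel] = P[d_u[sel]]
    return masses, usable


def sfs_from_genotypes(
    gm: GenotypeMatrix, pop: str, n_target: int, sites: np.ndarray | None = None
) -> SFS1D:
    """Projected 1D SFS of one population.

    ``sites`` restricts to a subset of site indices (e.g. one effect
    category).  Mass conservation: the spectrum sums to the number of
    usable sites.
    """
    if n_target < 2:
        raise ValueError("n_target must be >= 2")
    idx = gm.pop_indices(pop)
    sub = gm if sites is None else gm.take_sites(np.asarray(sites))
    derived, n_called = sub.derived_counts(idx)
    masses, usable = _projected_masses(derived, n_called, n_target)
    counts = masses.sum(axis=0) if masses.size else np.zeros(n_target + 1)
    n_skip = int((~usable).sum())
    if n_skip:
        logger.info("sfs_from_genotypes(%s): skipped %d sites", pop, n_skip)
    return SFS1D(n=n_target, counts=counts, n_skipped=n_skip)


def joint_sfs(
    gm: GenotypeMatrix,
    pop_x: str,
    pop_y: str,
    n_x: int,
    n_y: int,
    sites: np.ndarray | None = None,
) -> SFS2D:
    """Projected joint 2D SFS between two populations.

    Each usable site contributes the outer product of its two
    per-population projection masses; sites where either population has
    fewer called alleles than its target are skipped (and counted).
    """
    if n_x < 2 or n_y < 2:
        raise ValueError("projection targets must be >= 2")
    ix = gm.pop_indices(pop_x)
    iy = gm.pop_indices(pop_y)
    sub = gm if sites is None else gm.take_sites(np.asarray(sites))
    d_x, c_x = sub.derived_counts(ix)
    d_y, c_y = sub.derived_counts(iy)
    usable = (c_x >= n_x) & (c_y >= n_y)
    mx, _ = _projected_masses(d_x[usable], c_x[usable], n_x)
    my, _ = _projected_masses(d_y[usable], c_y[usable], n_y)
    counts = mx.T @ my if mx.size else np.zeros((n_x + 1, n_y + 1))
    n_skip = int((~usable).sum())
    if n_skip:
        logger.info("joint_sfs(%s,%s): skipped %d sites", pop_x, pop_y, n_skip)
    return SFS2D(n_x=n_x, n_y=n_y, counts=counts, n_skipped=n_skip)
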