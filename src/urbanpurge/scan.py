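"""Windowed diversity and differentiation scans: pi, Tajima's D,
Hudson/Bhatia FST and the population branch statistic (PBS).

Window FST is the ratio of sums of per-site Hudson numerators and
denominators with Bhatia et al.'s finite-sample correction — per-site
ratios are never averaged.  Nucleotide diversity divides the summed
per-site heterozygosity by the number of called sites in the window,
monomorphic sites included, so windows with few SNPs are not inflated.
Per-site sample sizes are the called allele counts at that site
(missingness-aware).  Haploid mode (``ploidy=1``) treats each individual
as a single allele.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

#: sentinel for statistics that are undefined in a window (e.g. D with S=0)
UNDEFINED = float("nan")


@dataclass
class WindowStat:
    chrom: str
    start: int
    end: int
    n_sites: int
    n_snps: int
    pi: float
    tajd: float
    fst_num: float
    fst_den: float
    fst: float
    pbs: float = UNDEFINED


def site_fst_components(p1, n1, p2, n2):
    """Per-site Hudson FST numerator/denominator with Bhatia correction.

    ``p`` are derived-allele frequencies, ``n`` haploid called-allele
    counts (must be >= 2).  Vectorised over numpy arrays.

        num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
        den = p1(1-p2) + p2(1-p1)
    """
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    n1 = np.asarray(n1, float)
    n2 = np.asarray(n2, float)
    if (n1 <= 1).any() or (n2 <= 1).any():
        raise ValueError("called allele counts must be >= 2 at every site")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def pi_from_counts(derived, n_called, n_sites) -> float:
    """Per-site nucleotide diversity over a window.

    ``pi = sum_sites 2 i (n_i - i) / (n_i (n_i - 1)) / n_sites`` where
    ``n_sites`` counts all called sites (monomorphic included).
    """
    derived = np.asarray(derived, float)
    n = np.asarray(n_called, float)
    if n_sites <= 0:
        return UNDEFINED
    h = 2.0 * derived * (n - derived) / (n * (n - 1.0))
    return float(h.sum()) / n_sites


def tajima_constants(n: int) -> dict[str, float]:
    """Tajima (1989) normalising constants for sample size n."""
    if n < 2:
        raise ValueError("need n >= 2")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(n: int, n_snps: int, pi_hat: float) -> float:
    """Tajima's D from sample size, segregating sites and mean pairwise
    differences (``pi_hat`` is the *sum* over sites of per-site
    heterozygosity, i.e. average pairwise differences per window, not
    per bp).  Returns the undefined sentinel when S = 0."""
    if n_snps == 0:
        return UNDEFINED
    k = tajima_constants(n)
    theta_w = n_snps / k["a1"]
    var = k["e1"] * n_snps + k["e2"] * n_snps * (n_snps - 1)
    if var <= 0:
        return UNDEFINED
    return (pi_hat - theta_w) / math.sqrt(var)


def pbs(fst_ab, fst_ac, fst_bc):
    """Population branch statistic of population A from three pairwise
    FST values: T_xy = -log(1 - FST_xy), pbs_a = (T_ab + T_ac - T_bc)/2.

    Negative FST is clamped to 0 and FST to 1 - 1e-9 before the log;
    NaN inputs propagate.
    """
    def t(x):
        x = np.clip(np.asarray(x, float), 0.0, 1.0 - 1e-9)
        return -np.log(1.0 - x)

    out = (t(fst_ab) + t(fst_ac) - t(fst_bc)) / 2.0
    return float(out) if np.ndim(out) == 0 else out


def _pop_freqs(gm: GenotypeMatrix, idx: np.ndarray, ploidy: int):
    g = gm.genotypes[:, idx]
    called = g != MISSING
    if ploidy == 1:
        # each individual contributes a single allele; diploid calls are
        # collapsed to presence of the derived allele
        derived = np.where(called, (g > 0).astype(np.int64), 0).sum(axis=1)
        n_called = called.sum(axis=1)
    else:
        derived = np.where(called, g, 0).sum(axis=1, dtype=np.int64)
        n_called = called.sum(axis=1) * 2
    return derived, n_called.astype(np.int64)


def window_scan(
    gm: GenotypeMatrix,
    pops: list[str],
    window_bp: int = 50_000,
    step_bp: int = 10_000,
    ploidy: int = 2,
    focal: str | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Sliding-window scan over every chromosome in ``gm``.

    ``pops`` supplies two or three population labels.  pi and Tajima's D
    are reported for ``focal`` (default: first label); FST for the first
    pair; with three labels, PBS of the focal population is added from
    the three pairwise window FSTs.  Windows are coordinate-based
    ``[start, start + window_bp)``; all positions within the window are
    assumed callable, so ``n_sites`` is the window's bp length (clipped
    to the chromosome length when known).  Windows with no SNPs are
    emitted with sentinel values, never dropped.
    """
    if len(pops) not in (2, 3):
        raise ValueError("pops must list two or three population labels")
    focal = focal or pops[0]
    if focal not in pops:
        raise ValueError("focal population must be among pops")
    chrom_lengths = chrom_lengths or gm.chrom_lengths
    pop_idx = {p: gm.pop_indices(p) for p in pops}
    per_pop = {p: _pop_freqs(gm, pop_idx[p], ploidy) for p in pops}
    pairs = [(pops[0], pops[1])]
    if len(pops) == 3:
        pairs += [(pops[0], pops[2]), (pops[1], pops[2])]
    # per-site components for each pair, defined where both n >= 2
    comp = {}
    for a, b in pairs:
        da, na = per_pop[a]
        db, nb = per_pop[b]
        ok = (na >= 2) & (nb >= 2)
        num = np.zeros(gm.n_sites)
        den = np.zeros(gm.n_sites)
        if ok.any():
            pa = da[ok] / na[ok]
            pb = db[ok] / nb[ok]
            num[ok], den[ok] = site_fst_components(pa, na[ok], pb, nb[ok])
        comp[(a, b)] = (num, den, ok)

    d_f, n_f = per_pop[focal]
    rows = []
    for c in dict.fromkeys(gm.chrom):
        on_c = np.flatnonzero(gm.chrom == c)
        pos_c = gm.pos[on_c]
        clen = chrom_lengths.get(c, int(pos_c.max()) + 1 if pos_c.size else window_bp)
        start = 0
        while start < clen:
            end = min(start + window_bp, clen)
            in_w = on_c[(pos_c >= start) & (pos_c < end)]
            n_sites = end - start
            stat = _window_row(
                c, start, end, n_sites, in_w, d_f, n_f, comp, pairs
            )
            rows.append(stat)
            start += step_bp
            if end == clen:
                break
    return pd.DataFrame([vars(r) for r in rows])


def _window_row(chrom, start, end, n_sites, in_w, d_f, n_f, comp, pairs):
    ok_f = in_w[n_f[in_w] >= 2]
    n_snps = int(((d_f[ok_f] > 0) & (d_f[ok_f] < n_f[ok_f])).sum())
    pi = pi_from_counts(d_f[ok_f], n_f[ok_f], n_sites) if ok_f.size else 0.0
    pi_hat = pi * n_sites
    # D uses the window's minimum focal sample size (conservative for
    # missingness-varying sites)
    tajd = (
        tajimas_d(int(n_f[ok_f].min()), n_snps, pi_hat) if ok_f.size else UNDEFINED
    )
    fsts = {}
    for a, b in pairs:
        num, den, ok = comp[(a, b)]
        w_ok = in_w[ok[in_w]]
        s_num = float(num[w_ok].sum())
        s_den = float(den[w_ok].sum())
        fsts[(a, b)] = (s_num, s_den, s_num / s_den if s_den > 0 else UNDEFINED)
    f_ab = fsts[pairs[0]]
    row = WindowStat(
        chrom=chrom,
        start=int(start),
        end=int(end),
        n_sites=int(n_sites),
        n_snps=n_snps,
        pi=pi,
        tajd=tajd,
        fst_num=f_ab[0],
        fst_den=f_ab[1],
        fst=f_ab[2],
    )
    if len(pairs) == 3:
        row.pbs = pbs(f_ab[2], fsts[pairs[1]][2], fsts[pairs[2]][2])
    return row


def window_fst(gm: GenotypeMatrix, pop_a: str, pop_b: str, ploidy: int = 2) -> float:
    """Single ratio-of-sums Bhatia FST over all sites of a matrix
    (one window = one replicate).  NaN when no informative site."""
    da, na = _pop_freqs(gm, gm.pop_indices(pop_a), ploidy)
    db, nb = _pop_freqs(gm, gm.pop_indices(pop_b), ploidy)
    ok = (na >= 2) & (nb >= 2)
    if not ok.any():
        return UNDEFINED
    num, den = site_fst_components(da[ok] / na[ok], na[ok], db[ok] / nb[ok], nb[ok])
    s_den = float(den.sum())
    return float(num.sum()) / s_den if s_den > 0 else UNDEFINED
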