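"""Cohort quality control: pairwise kinship, relative pruning and
per-individual inbreeding coefficients.

Kinship uses the KING-robust estimator on hard genotypes:

    phi = (N_het,het - 2 N_opposite_hom) / (N_het(i) + N_het(j))

over jointly called sites, with relatedness R_AB = 2 phi.  Pairs with
Theta > 0.125 and R_AB > 0.25 (putative first/second-degree relatives)
are pruned greedily, removing the lower-coverage member of each flagged
pair; an alternative single threshold Theta > 0.0884 (the lower
confidence bound for such relatives) is available.  Individual
inbreeding is the heterozygosity-deficit moment estimator
F = 1 - observed/expected heterozygosity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

#: alternative single-statistic threshold: lower confidence bound of
#: Theta for first/second-degree relatives
THETA_LOWER_BOUND = 0.0884


@dataclass
class PairKinship:
    id_i: str
    id_j: str
    phi: float
    r: float
    n_sites: int


@dataclass
class IndividualF:
    id: str
    f_hat: float
    n_sites: int


class KinshipUndefinedError(ValueError):
    pass


def king_kinship(gm: GenotypeMatrix, i: int, j: int) -> PairKinship:
    """KING-robust kinship between individuals ``i`` and ``j`` (column
    indices)."""
    gi = gm.genotypes[:, i]
    gj = gm.genotypes[:, j]
    both = (gi != MISSING) & (gj != MISSING)
    gi, gj = gi[both], gj[both]
    het_i = gi == 1
    het_j = gj == 1
    n_hh = int((het_i & het_j).sum())
    n_opp = int(((gi == 0) & (gj == 2)).sum() + ((gi == 2) & (gj == 0)).sum())
    denom = int(het_i.sum() + het_j.sum())
    if denom == 0:
        raise KinshipUndefinedError(
            f"no heterozygous sites between {gm.samples[i]} and {gm.samples[j]}"
        )
    phi = (n_hh - 2.0 * n_opp) / denom
    return PairKinship(
        id_i=str(gm.samples[i]),
        id_j=str(gm.samples[j]),
        phi=phi,
        r=2.0 * phi,
        n_sites=int(both.sum()),
    )


def pairwise_kinship(gm: GenotypeMatrix) -> pd.DataFrame:
    """All pairwise KING-robust kinships (vectorised)."""
    g = gm.genotypes
    n = gm.n_individuals
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            k = king_kinship(gm, i, j)
            rows.append(vars(k))
    return pd.DataFrame(rows)


def prune_related(
    kinships: pd.DataFrame,
    coverage: dict[str, float],
    theta_thr: float | None = 0.125,
    r_thr: float | None = 0.25,
) -> list[str]:
    """Greedy relative pruning: repeatedly drop the lower-coverage member
    of a flagged pair until no flagged pair remains among kept
    individuals.

    A pair is flagged when phi > theta_thr and r > r_thr (a threshold of
    ``None`` disables that condition; pass
    ``theta_thr=THETA_LOWER_BOUND, r_thr=None`` for the single-statistic
    rule).  Flags are re-evaluated against the current kept set after
    each removal; coverage ties break by individual id order.  Returns
    the kept ids, input order preserved.
    """
    ids = list(dict.fromkeys(list(kinships["id_i"]) + list(kinships["id_j"])))
    missing = [s for s in ids if s not in coverage]
    if missing:
        raise ValueError(f"no coverage rank for {missing}")
    flagged = kinships[
        ((kinships["phi"] > theta_thr) if theta_thr is not None else True)
        & ((kinships["r"] > r_thr) if r_thr is not None else True)
    ][["id_i", "id_j"]].to_numpy().tolist()
    kept = set(ids)
    while True:
        active = [(a, b) for a, b in flagged if a in kept and b in kept]
        if not active:
            break
        a, b = active[0]
        drop = min(a, b, key=lambda s: (coverage[s], ids.index(s)))
        kept.discard(drop)
    return [s for s in ids if s in kept]


def inbreeding_f(
    gm: GenotypeMatrix,
    individual: int,
    freqs: np.ndarray | None = None,
    n_called: np.ndarray | None = None,
) -> IndividualF:
    """Heterozygosity-deficit inbreeding coefficient of one individual.

    ``freqs`` are per-site population derived-allele frequencies
    (computed from the whole matrix when omitted); expected
    heterozygosity is ``sum 2 p (1-p)`` over sites called in the
    individual.  When the per-site called-allele counts behind the
    frequency estimates are known (``n_called``, supplied automatically
    when frequencies are computed internally), the unbiased expected
    heterozygosity ``2 p (1-p) n/(n-1)`` is used — without it, rare
    variants (always heterozygous when singletons) bias F downward in
    small cohorts.
    """
    g = gm.genotypes[:, individual]
    called = g != MISSING
    if freqs is None:
        derived, n_called = gm.derived_counts()
        if (n_called[called] < 4).any():
            raise ValueError("population frequencies need >= 2 individuals")
        freqs = np.where(n_called > 0, derived / np.maximum(n_called, 1), 0.0)
    freqs = np.asarray(freqs, float)
    p = freqs[called]
    if n_called is not None:
        nc = np.asarray(n_called, float)[called]
        corr = nc / np.maximum(nc - 1.0, 1.0)
    else:
        corr = 1.0
    expected = float((2.0 * p * (1.0 - p) * corr).sum())
    if expected <= 0:
        raise ValueError("expected heterozygosity is zero over called sites")
    observed = int((g[called] == 1).sum())
    return IndividualF(
        id=str(gm.samples[individual]),
        f_hat=1.0 - observed / expected,
        n_sites=int(called.sum()),
    )


def cohort_inbreeding(gm: GenotypeMatrix, pop: str | None = None) -> pd.DataFrame:
    """Per-individual F within one population (frequencies estimated from
    that population's members)."""
    idx = gm.pop_indices(pop) if pop else np.arange(gm.n_individuals)
    sub = gm.take_individuals(idx)
    derived, n_called = sub.derived_counts()
    freqs = np.where(n_called > 0, derived / np.maximum(n_called, 1), 0.0)
    rows = [
        vars(inbreeding_f(sub, k, freqs, n_called)) for k in range(sub.n_individuals)
    ]
    return pd.DataFrame(rows)
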