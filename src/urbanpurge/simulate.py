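"""Forward Wright-Fisher simulation of the two-deme urban/rural system.

The engine is a discrete-generation forward simulator with partial
selfing (inbreeding), migration, multiplicative selection across sites
and infinite-sites mutation.  The ancestral population is initialised at
neutral mutation-drift equilibrium — from a coalescent sample (msprime)
when sites are fully linked within the window, or from the exchangeable
Watterson stationary spectrum when sites segregate independently — and
the forward engine takes over from there: optional ancestral burn-in
(used to equilibrate selected sites in load cohorts), the split, and
every post-split generation.

Two linkage modes are supported:

``"none"``
    no recombination inside the window; a gamete is one parental
    haplotype.  Used for the 50 kb scan/calibration windows, which are
    treated as independent replicates.
``"free"``
    every site segregates independently.  Used for genome-wide load
    cohorts, where sites are drawn from across the genome and a single
    shared genealogy would be unrealistic.

Inbreeding is implemented as partial selfing at rate sigma = 2f/(1+f),
whose equilibrium inbreeding coefficient is F = sigma/(2-sigma) = f.
"""

from __future__ import annotations

import numpy as np

from .genotypes import GenotypeMatrix
from .model import DemographicModel, EffectDFE

__all__ = [
    "WrightFisherEngine",
    "simulate_im",
    "simulate_load_cohort",
    "simulate_windows",
    "load_cohort_model",
    "selfing_rate",
]

MAX_SWEEP_ATTEMPTS = 1000
SWEEP_SAMPLE_REDRAWS = 20


def selfing_rate(f: float) -> float:
    """Selfing rate giving equilibrium inbreeding coefficient ``f``."""
    return 2.0 * f / (1.0 + f)


class _NeutralSampler:
    """Labels every site 'intergenic' with no fitness effect."""

    def __call__(self, rng: np.random.Generator, k: int):
        eff = np.full(k, "intergenic", dtype=object)
        ones = np.ones(k)
        return eff, ones.copy(), ones.copy()


class _DFESampler:
    """Draws site categories from an :class:`EffectDFE` and maps them to
    heterozygote/homozygote fitness factors (1-h*s, 1-s)."""

    def __init__(self, dfe: EffectDFE):
        self.cats = np.array(dfe.categories, dtype=object)
        self.props = np.array([dfe.proportions[c] for c in self.cats], float)
        self.w_het = np.array(
            [1.0 - dfe.h_del[c] * dfe.s_del[c] for c in self.cats]
        )
        self.w_hom = np.array([1.0 - dfe.s_del[c] for c in self.cats])

    def __call__(self, rng: np.random.Generator, k: int):
        idx = rng.choice(len(self.cats), size=k, p=self.props)
        return self.cats[idx], self.w_het[idx].copy(), self.w_hom[idx].copy()


class WrightFisherEngine:
    """Multi-deme forward Wright-Fisher engine on a single window.

    State is a dict of haplotype matrices (rows = haplotypes, two
    consecutive rows per diploid; columns = segregating sites) plus
    per-site position, effect category and fitness factors shared across
    demes.  Sites fixed or lost in the union of demes are pruned each
    generation (a protected focal site is kept while segregating).
    """

    def __init__(
        self,
        window_length: int,
        mu: float,
        rng: np.random.Generator,
        linked: bool = True,
        category_sampler=None,
    ):
        self.L = int(window_length)
        self.mu_per_gamete = mu * window_length
        self.rng = rng
        self.linked = linked
        self.category_sampler = category_sampler or _NeutralSampler()
        self.haps: dict[str, np.ndarray] = {}
        self.sigma: dict[str, float] = {}
        self.pos = np.empty(0, dtype=np.int64)
        self.effect = np.empty(0, dtype=object)
        self.w_het = np.empty(0)
        self.w_hom = np.empty(0)
        self._used: set[int] = set()
        self.focal_col: int | None = None
        self.focal_deme: str | None = None

    # ---------------------------------------------------------------- setup

    @property
    def n_sites(self) -> int:
        return self.pos.size

    def add_population(
        self, name: str, haplotypes: np.ndarray, selfing: float = 0.0
    ) -> None:
        haplotypes = np.ascontiguousarray(haplotypes, dtype=np.uint8)
        if haplotypes.ndim != 2 or haplotypes.shape[0] % 2:
            raise ValueError("haplotypes must be (2N, S)")
        if self.n_sites == 0 and haplotypes.shape[1] > 0:
            raise ValueError("initialise sites before adding carriers")
        if haplotypes.shape[1] != self.n_sites:
            raise ValueError("haplotype column count != engine site count")
        self.haps[name] = haplotypes
        self.sigma[name] = float(selfing)

    def init_sites(
        self,
        positions: np.ndarray,
        effects: np.ndarray | None = None,
        w_het: np.ndarray | None = None,
        w_hom: np.ndarray | None = None,
    ) -> None:
        """Register initial segregating sites.  Categories and fitness
        factors are drawn from the engine's category sampler unless
        supplied explicitly."""
        positions = np.asarray(positions, dtype=np.int64)
        if effects is None:
            eff, wh, wo = self.category_sampler(self.rng, positions.size)
        else:
            eff = np.asarray(effects, dtype=object)
            wh = np.asarray(w_het, dtype=float)
            wo = np.asarray(w_hom, dtype=float)
        self.pos = positions
        self.effect, self.w_het, self.w_hom = eff, wh, wo
        self._used = set(int(p) for p in positions)

    def introduce_focal(
        self, deme: str, s: float, h: float, effect: str = "intergenic"
    ) -> None:
        """Add a focal mutation on one random haplotype of ``deme``,
        beneficial in that deme only (neutral elsewhere)."""
        pos = self._draw_positions(1)
        col = {
            name: np.zeros((H.shape[0], 1), dtype=np.uint8)
            for name, H in self.haps.items()
        }
        row = int(self.rng.integers(0, self.haps[deme].shape[0]))
        col[deme][row, 0] = 1
        for name in self.haps:
            self.haps[name] = np.hstack([self.haps[name], col[name]])
        self.pos = np.append(self.pos, pos)
        self.effect = np.append(self.effect, np.array([effect], dtype=object))
        self.w_het = np.append(self.w_het, 1.0 + h * s)
        self.w_hom = np.append(self.w_hom, 1.0 + s)
        self.focal_col = self.n_sites - 1
        self.focal_deme = deme

    # ------------------------------------------------------------ generation

    def _fitness(self, name: str) -> np.ndarray | None:
        selected = (self.w_het != 1.0) | (self.w_hom != 1.0)
        if self.focal_col is not None and name != self.focal_deme:
            selected = selected.copy()
            selected[self.focal_col] = False
        sel = np.flatnonzero(selected)
        if sel.size == 0:
            return None
        H = self.haps[name]
        G = H[0::2][:, sel].astype(np.int8) + H[1::2][:, sel]
        W = np.where(
            G == 1, self.w_het[sel], np.where(G == 2, self.w_hom[sel], 1.0)
        )
        return W.prod(axis=1)

    def _gametes(self, H: np.ndarray, parents: np.ndarray) -> np.ndarray:
        if self.linked:
            which = self.rng.integers(0, 2, size=parents.size)
            return H[2 * parents + which]
        a = H[2 * parents]
        b = H[2 * parents + 1]
        mask = self.rng.integers(0, 2, size=a.shape, dtype=np.uint8)
        return np.where(mask.astype(bool), a, b)

    def _offspring_from(self, source: str, k: int) -> tuple[np.ndarray, np.ndarray]:
        """k offspring (pairs of gametes) drawn from `source` parents with
        fitness-weighted mating and partial selfing."""
        H = self.haps[source]
        n_par = H.shape[0] // 2
        w = self._fitness(source)
        if w is not None:
            tot = w.sum()
            if tot <= 0:
                raise RuntimeError(f"all fitnesses zero in deme {source!r}")
            p = w / tot
        else:
            p = None
        par1 = self.rng.choice(n_par, size=k, p=p)
        par2 = self.rng.choice(n_par, size=k, p=p)
        selfed = self.rng.random(k) < self.sigma[source]
        par2 = np.where(selfed, par1, par2)
        return self._gametes(H, par1), self._gametes(H, par2)

    def generation(self, plan: dict[str, tuple[int, list[tuple[str, float]]]]) -> None:
        """Advance one generation.

        ``plan`` maps each next-generation deme name to
        ``(n_offspring, [(source_deme, fraction), ...])``; fractions give
        the probability that an offspring's parents come from each
        source deme (migration = probability mass on the other deme).
        """
        new_haps: dict[str, np.ndarray] = {}
        new_sigma: dict[str, float] = {}
        for name, (n_off, sources) in plan.items():
            fracs = np.array([f for _, f in sources], float)
            fracs = fracs / fracs.sum()
            src_of = self.rng.choice(len(sources), size=n_off, p=fracs)
            H_new = np.empty((2 * n_off, self.n_sites), dtype=np.uint8)
            for s_idx, (src, _) in enumerate(sources):
                offs = np.flatnonzero(src_of == s_idx)
                if offs.size == 0:
                    continue
                g1, g2 = self._offspring_from(src, offs.size)
                H_new[2 * offs] = g1
                H_new[2 * offs + 1] = g2
            new_haps[name] = H_new
            # a deme keeps its own mating system; a newly founded deme
            # inherits the selfing rate registered under its name, else 0
            new_sigma[name] = self.sigma.get(name, 0.0)
        self.haps = new_haps
        self.sigma = new_sigma
        self._mutate()
        self._prune()

    def set_selfing(self, name: str, selfing: float) -> None:
        self.sigma[name] = float(selfing)

    # ------------------------------------------------------------- mutation

    def _draw_positions(self, m: int) -> np.ndarray:
        out: list[int] = []
        guard = 0
        while len(out) < m:
            cand = self.rng.integers(0, self.L, size=2 * (m - len(out)) + 4)
            for c in cand:
                c = int(c)
                if c not in self._used:
                    self._used.add(c)
                    out.append(c)
                    if len(out) == m:
                        break
            guard += 1
            if guard > 1000:
                raise RuntimeError(
                    "cannot place new mutations: window saturated "
                    "(increase window_length or lower mu)"
                )
        return np.array(out, dtype=np.int64)

    def _mutate(self) -> None:
        if self.mu_per_gamete == 0:
            return
        counts = {
            name: int(self.rng.poisson(H.shape[0] * self.mu_per_gamete))
            for name, H in self.haps.items()
        }
        m_tot = sum(counts.values())
        if m_tot == 0:
            return
        pos = self._draw_positions(m_tot)
        eff, wh, wo = self.category_sampler(self.rng, m_tot)
        offset = 0
        blocks: dict[str, np.ndarray] = {}
        for name, H in self.haps.items():
            Z = np.zeros((H.shape[0], m_tot), dtype=np.uint8)
            m = counts[name]
            if m:
                rows = self.rng.integers(0, H.shape[0], size=m)
                Z[rows, offset + np.arange(m)] = 1
            blocks[name] = Z
            offset += m
        for name in self.haps:
            self.haps[name] = np.hstack([self.haps[name], blocks[name]])
        self.pos = np.concatenate([self.pos, pos])
        self.effect = np.concatenate([self.effect, eff])
        self.w_het = np.concatenate([self.w_het, wh])
        self.w_hom = np.concatenate([self.w_hom, wo])

    def _prune(self) -> None:
        if self.n_sites == 0:
            return
        tot = sum(H.sum(axis=0, dtype=np.int64) for H in self.haps.values())
        n_alleles = sum(H.shape[0] for H in self.haps.values())
        keep = (tot > 0) & (tot < n_alleles)
        if self.focal_col is not None:
            keep[self.focal_col] = tot[self.focal_col] > 0
        if keep.all():
            return
        dropped = self.pos[~keep]
        self._used.difference_update(int(p) for p in dropped)
        if self.focal_col is not None:
            if not keep[self.focal_col]:
                self.focal_col = None
            else:
                self.focal_col = int(keep[: self.focal_col].sum())
        for name in self.haps:
            self.haps[name] = np.ascontiguousarray(self.haps[name][:, keep])
        self.pos = self.pos[keep]
        self.effect = self.effect[keep]
        self.w_het = self.w_het[keep]
        self.w_hom = self.w_hom[keep]

    # ------------------------------------------------------------- queries

    def focal_count(self, deme: str) -> int:
        if self.focal_col is None:
            return 0
        return int(self.haps[deme][:, self.focal_col].sum())

    def total_focal_count(self) -> int:
        if self.focal_col is None:
            return 0
        return sum(int(H[:, self.focal_col].sum()) for H in self.haps.values())

    def observed_heterozygosity(self, deme: str) -> float:
        """Mean per-site heterozygote frequency over current sites."""
        H = self.haps[deme]
        if H.shape[1] == 0:
            return 0.0
        het = (H[0::2] != H[1::2]).mean(axis=0)
        return float(het.mean())

    def site_frequencies(self, deme: str) -> np.ndarray:
        H = self.haps[deme]
        return H.mean(axis=0)

    # ------------------------------------------------------------- sampling

    def sample(
        self,
        groups: list[tuple[str, int, str]],
        chrom: str = "chr1",
        keep_monomorphic: bool = False,
    ) -> GenotypeMatrix:
        """Sample diploid individuals into a :class:`GenotypeMatrix`.

        ``groups`` is a list of ``(deme, n_individuals, pop_label)``.  By
        default only sites polymorphic in the pooled sample are kept.
        Repeated entries for one deme draw disjoint individuals.
        """
        cols = []
        labels = []
        taken: dict[str, set[int]] = {}
        for deme, n_ind, label in groups:
            H = self.haps[deme]
            n_avail = H.shape[0] // 2
            pool = np.array(
                sorted(set(range(n_avail)) - taken.setdefault(deme, set()))
            )
            if n_ind > pool.size:
                raise ValueError(
                    f"requested {n_ind} individuals from deme {deme!r} "
                    f"with only {pool.size} available"
                )
            ids = self.rng.choice(pool, size=n_ind, replace=False)
            taken[deme].update(int(i) for i in ids)
            G = H[2 * ids].astype(np.int8) + H[2 * ids + 1]
            cols.append(G)  # (n_ind, S)
            labels.extend([label] * n_ind)
        geno = np.vstack(cols).T  # (S, n_total)
        order = np.argsort(self.pos, kind="stable")
        geno = geno[order]
        pos = self.pos[order]
        eff = self.effect[order]
        if not keep_monomorphic and geno.shape[0]:
            tot = geno.sum(axis=1)
            poly = (tot > 0) & (tot < 2 * geno.shape[1])
            geno, pos, eff = geno[poly], pos[poly], eff[poly]
        return GenotypeMatrix(
            genotypes=geno,
            chrom=np.full(pos.size, chrom, dtype=object),
            pos=pos,
            effect=eff,
            pop=np.array(labels, dtype=object),
            ploidy=2,
            chrom_lengths={chrom: self.L},
        )


# ---------------------------------------------------------------------------
# equilibrium initial conditions


def _init_linked(model: DemographicModel, rng: np.random.Generator):
    """Neutral equilibrium state of the whole ancestral population (fully
    linked window) via msprime's discrete-time Wright-Fisher model,
    which stays exact when the sample is the entire population (the
    standard coalescent distorts genealogies once n approaches 2N)."""
    import msprime

    seed = int(rng.integers(1, 2**31 - 1))
    ts = msprime.sim_ancestry(
        samples=model.n_anc,
        population_size=model.n_anc,
        sequence_length=model.window_length,
        ploidy=2,
        model="dtwf",
        random_seed=seed,
    )
    ts = msprime.sim_mutations(
        ts,
        rate=model.mu,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
        random_seed=seed + 1,
    )
    haps = ts.genotype_matrix().T.astype(np.uint8)  # (2N, S)
    haps = np.minimum(haps, 1)
    raw = np.floor(ts.sites_position).astype(np.int64)
    # de-duplicate integer positions (continuous-position collisions)
    pos = np.empty_like(raw)
    used: set[int] = set()
    for k, p in enumerate(raw):
        p = int(p)
        while p in used:
            p = (p + 1) % model.window_length
        used.add(p)
        pos[k] = p
    return haps, pos


def _init_free(
    model: DemographicModel,
    rng: np.random.Generator,
    dfe: EffectDFE | None = None,
):
    """Exchangeable stationary spectrum for unlinked sites.

    Neutral categories follow the Watterson spectrum (expected number of
    sites at derived count i in 2N haplotypes is theta_L/i); selected
    categories are thinned by the Wright stationary density,
    ``f(q) ~ (1/q) exp(-2Ns(2hq + (1-2h)q^2))``.  ``n_containment`` is
    the effective size used inside the selection term (default: the
    engine's own size); a larger value restores the real-scale rarity of
    strongly deleterious variants that theta-rescaling would otherwise
    inflate.  Returns (haplotypes, positions, effects); effects is None
    when no DFE is given.
    """
    two_n = 2 * model.n_anc
    n_sel = model.n_containment if model.n_containment is not None else model.n_anc
    theta_l = 4.0 * model.n_anc * model.mu * model.window_length
    i_vals = np.arange(1, two_n)
    q = i_vals / two_n
    cats = dfe.categories if dfe is not None else ["intergenic"]
    counts_per_cat = {}
    for c in cats:
        prop = dfe.proportions[c] if dfe is not None else 1.0
        s = dfe.s_del[c] if dfe is not None else 0.0
        h = dfe.h_del[c] if dfe is not None else 0.5
        dens = (theta_l * prop / i_vals) * np.exp(
            -2.0 * n_sel * s * (2 * h * q + (1 - 2 * h) * q**2)
        )
        counts_per_cat[c] = rng.poisson(dens)
    total = int(sum(v.sum() for v in counts_per_cat.values()))
    haps = np.zeros((two_n, total), dtype=np.uint8)
    effects = np.empty(total, dtype=object)
    col = 0
    for c in cats:
        for i, cnt in zip(i_vals, counts_per_cat[c]):
            for _ in range(cnt):
                rows = rng.choice(two_n, size=i, replace=False)
                haps[rows, col] = 1
                effects[col] = c
                col += 1
    # unique integer positions by rejection (window >> site count)
    pos: set[int] = set()
    while len(pos) < total:
        draw = rng.integers(0, model.window_length, size=2 * (total - len(pos)))
        for p in draw:
            pos.add(int(p))
            if len(pos) == total:
                break
    positions = np.fromiter(pos, dtype=np.int64, count=total)
    return haps, positions, (effects if dfe is not None else None)


# ---------------------------------------------------------------------------
# high-level cohort simulators


def _build_engine(
    model: DemographicModel, rng: np.random.Generator, category_sampler=None
) -> WrightFisherEngine:
    linked = model.recombination == "none"
    eng = WrightFisherEngine(
        model.window_length,
        model.mu,
        rng,
        linked=linked,
        category_sampler=category_sampler,
    )
    if linked:
        haps, pos = _init_linked(model, rng)
    else:
        haps, pos, _ = _init_free(model, rng)
    eng.init_sites(pos)
    eng.add_population("anc", haps, selfing=selfing_rate(model.f_rural))
    return eng


def _run_im(model: DemographicModel, n_su: int, n_sr: int, rng):
    """One forward realisation; returns (GenotypeMatrix, focal urban
    sample frequency or None)."""
    if n_su > model.n_urban:
        raise ValueError("urban sample size exceeds deme size")
    if n_sr > model.n_rural and model.t_split > 0:
        raise ValueError("rural sample size exceeds deme size")
    eng = _build_engine(model, rng)
    for _ in range(model.burn_in):
        eng.generation({"anc": (model.n_anc, [("anc", 1.0)])})
    eng.mu_per_gamete = model.mu_post_split * model.window_length
    if model.t_split == 0:
        if n_su + n_sr > model.n_anc:
            raise ValueError("sample sizes exceed panmictic population size")
        gm = eng.sample([("anc", n_su, "urban"), ("anc", n_sr, "rural")])
        # disjointness: re-draw as one pool split in two
        return gm, None
    # found the demes (first post-split generation)
    eng.set_selfing("urban", selfing_rate(model.f_urban))
    eng.set_selfing("rural", selfing_rate(model.f_rural))
    eng.generation(
        {
            "urban": (model.n_urban, [("anc", 1.0)]),
            "rural": (model.n_rural, [("anc", 1.0)]),
        }
    )
    if model.s_focal > 0:
        eng.introduce_focal("urban", model.s_focal, model.h_focal)
    plan = {
        "urban": (model.n_urban, [("urban", 1.0 - model.m_ur), ("rural", model.m_ur)]),
        "rural": (model.n_rural, [("rural", 1.0 - model.m_ru), ("urban", model.m_ru)]),
    }
    for _ in range(model.t_split - 1):
        eng.generation(plan)
        if model.s_focal > 0 and eng.total_focal_count() == 0:
            return None, 0.0  # focal lost: caller may resample
    if model.s_focal <= 0:
        return eng.sample([("urban", n_su, "urban"), ("rural", n_sr, "rural")]), None
    # sweep conditioning targets the sampled urban cohort: redraw the
    # sample a few times before discarding the whole replicate, since
    # fresh migrants make any single draw unlikely to be carrier-pure
    focal_pos = None if eng.focal_col is None else int(eng.pos[eng.focal_col])
    gm = focal_freq = None
    for _ in range(SWEEP_SAMPLE_REDRAWS):
        gm = eng.sample([("urban", n_su, "urban"), ("rural", n_sr, "rural")])
        if focal_pos is None:
            focal_freq = 0.0
            break
        urban_idx = np.flatnonzero(gm.pop == "urban")
        at = np.flatnonzero(gm.pos == focal_pos)
        if at.size == 0:
            # monomorphic in the pooled sample: fixed (derived) or lost
            focal_freq = 1.0 if eng.focal_count("urban") > 0 else 0.0
        else:
            g = gm.genotypes[at[0], urban_idx]
            focal_freq = float(g.sum()) / (2 * urban_idx.size)
        if focal_freq == 1.0:
            break
    return gm, focal_freq


def simulate_im(
    model: DemographicModel,
    n_sample_urban: int = 32,
    n_sample_rural: int = 12,
    seed: int | None = None,
    chrom: str = "chr1",
) -> GenotypeMatrix:
    """Simulate one window under the isolation-with-migration model.

    Returns diploid genotypes for ``n_sample_urban`` urban and
    ``n_sample_rural`` rural individuals (defaults matching the study's
    64/24 haplotype projection targets).  Allele 0 is ancestral.  When
    ``model.s_focal > 0`` the replicate is rejection-resampled until the
    focal beneficial allele is fixed among the sampled urban individuals
    (at most ``MAX_SWEEP_ATTEMPTS`` attempts); the returned matrix then
    carries ``focal_freq_urban == 1.0``.
    """
    base_seed = model.seed if seed is None else seed
    if model.s_focal <= 0:
        rng = np.random.default_rng([base_seed, 0])
        gm, _ = _run_im(model, n_sample_urban, n_sample_rural, rng)
        gm.focal_freq_urban = None
        _relabel_chrom(gm, chrom)
        return gm
    for attempt in range(MAX_SWEEP_ATTEMPTS):
        rng = np.random.default_rng([base_seed, attempt])
        gm, freq = _run_im(model, n_sample_urban, n_sample_rural, rng)
        if gm is not None and freq == 1.0:
            gm.focal_freq_urban = 1.0
            _relabel_chrom(gm, chrom)
            return gm
    raise RuntimeError(
        f"sweep conditioning failed: focal allele not fixed in the urban "
        f"sample after {MAX_SWEEP_ATTEMPTS} attempts"
    )


def _relabel_chrom(gm: GenotypeMatrix, chrom: str) -> None:
    old = next(iter(gm.chrom_lengths))
    if old != chrom:
        gm.chrom_lengths = {chrom: gm.chrom_lengths[old]}
        gm.chrom = np.full(gm.pos.size, chrom, dtype=object)


def load_cohort_model(**overrides) -> DemographicModel:
    """Default demographic model for genome-wide load cohorts: the same
    two-deme IM history, but with unlinked sites spread over a 2 Mb
    mutational target, a compact source population (theta matched to the
    window model) and a selective ancestral burn-in so deleterious
    variants start near selection-drift equilibrium."""
    kw = dict(
        n_anc=200,
        n_rural=200,
        m_ru=0.02,
        window_length=20_000_000,
        mu=5e-7,
        recombination="free",
        burn_in=10,
        # containment intermediate between the engine size (200) and the
        # real-scale size implied by theta and the real mutation rate
        # (~6e4): keeps per-individual exposed high-effect load realistic
        # (~2 homozygotes) while retaining enough segregating high-effect
        # sites for a stable R'XY
        n_containment=20_000,
    )
    kw.update(overrides)
    return DemographicModel(**kw)


def simulate_load_cohort(
    model: DemographicModel,
    dfe: EffectDFE | None = None,
    n_sample_urban: int = 64,
    n_sample_rural: int = 16,
    seed: int | None = None,
) -> GenotypeMatrix:
    """Simulate a cohort whose sites carry effect categories under a DFE.

    Each mutation (and each initial site) is assigned a category by the
    DFE proportions; per-site fitnesses are 1, 1-h*s, 1-s for genotypes
    0/1/2, multiplicative across sites.  With a recessive high-effect
    category, the more inbred deme purges those variants faster — the
    signal quantified downstream by R'XY.  See
    ``DemographicModel.n_containment`` for how the initial frequencies
    of selected sites are kept realistically rare.  Default sample sizes
    mirror the study cohort (more individuals than the 64/24 projection
    targets, which absorb the excess).
    """
    dfe = dfe or EffectDFE()
    base_seed = model.seed if seed is None else seed
    rng = np.random.default_rng([base_seed, 0])
    sampler = _DFESampler(dfe)
    if n_sample_urban > model.n_urban:
        raise ValueError("urban sample size exceeds deme size")
    eng = WrightFisherEngine(
        model.window_length,
        model.mu,
        rng,
        linked=(model.recombination == "none"),
        category_sampler=sampler,
    )
    if model.recombination == "none":
        haps, pos = _init_linked(model, rng)
        eng.init_sites(pos)
    else:
        haps, pos, eff = _init_free(model, rng, dfe)
        w_het = np.array([1.0 - dfe.h_del[c] * dfe.s_del[c] for c in eff])
        w_hom = np.array([1.0 - dfe.s_del[c] for c in eff])
        eng.init_sites(pos, eff, w_het, w_hom)
    eng.add_population("anc", haps, selfing=selfing_rate(model.f_rural))
    for _ in range(model.burn_in):
        eng.generation({"anc": (model.n_anc, [("anc", 1.0)])})
    eng.mu_per_gamete = model.mu_post_split * model.window_length
    if model.t_split == 0:
        return eng.sample([("anc", n_sample_urban, "urban"), ("anc", n_sample_rural, "rural")])
    eng.set_selfing("urban", selfing_rate(model.f_urban))
    eng.set_selfing("rural", selfing_rate(model.f_rural))
    eng.generation(
        {
            "urban": (model.n_urban, [("anc", 1.0)]),
            "rural": (model.n_rural, [("anc", 1.0)]),
        }
    )
    plan = {
        "urban": (model.n_urban, [("urban", 1.0 - model.m_ur), ("rural", model.m_ur)]),
        "rural": (model.n_rural, [("rural", 1.0 - model.m_ru), ("urban", model.m_ru)]),
    }
    for _ in range(model.t_split - 1):
        eng.generation(plan)
    return eng.sample(
        [("urban", n_sample_urban, "urban"), ("rural", n_sample_rural, "rural")]
    )


def simulate_windows(
    model: DemographicModel,
    n_windows: int,
    n_sample_urban: int = 32,
    n_sample_rural: int = 12,
    seed: int | None = None,
) -> list[GenotypeMatrix]:
    """Independent window replicates (one chromosome label per window)."""
    base_seed = model.seed if seed is None else seed
    out = []
    for w in range(n_windows):
        m = model.replace(seed=0)
        gm = simulate_im(
            m,
            n_sample_urban,
            n_sample_rural,
            seed=int(np.random.default_rng([base_seed, w, 7]).integers(0, 2**31 - 1)),
            chrom=f"w{w:04d}",
        )
        out.append(gm)
    return out
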