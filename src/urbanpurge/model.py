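"""Demographic model and distribution of fitness effects for the simulator.

The default :class:`DemographicModel` describes the study system: a small
urban deme (78 diploids) that split from a large source population ~32
generations ago and still exchanges migrants with it, with elevated
inbreeding in the urban deme.  The engine works in theta-rescaled units:
population sizes are kept small and the mutation rate is inflated so that
ancestral diversity (4*N*mu per site) matches the nucleotide diversity
observed in real non-urban populations of this system (~5.5e-4/bp); see
docs/methods.md.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class DemographicModel:
    """Parameters of the two-deme isolation-with-migration model.

    Attributes
    ----------
    n_anc, n_urban, n_rural
        Diploid population sizes of the ancestral population and of the
        urban (U) and rural (R) demes.
    t_split
        Generations since the split.
    m_ur
        Per-generation fraction of the urban deme replaced by rural
        migrants (and ``m_ru`` the converse).  Defaults are
        migrant-count balanced: the small urban deme receives 5% of its
        individuals per generation, and exports the same *number* of
        migrants to the much larger rural deme
        (m_ru = m_ur * n_urban / n_rural ~= 0.004).
    f_urban, f_rural
        Target equilibrium inbreeding coefficients, realised through
        partial selfing at rate sigma = 2f/(1+f).
    mu
        Per-base per-generation mutation rate (theta-rescaled; see module
        docstring).
    mu_post_split
        Mutation rate applied after the split.  The post-split epoch runs
        at the *real* population sizes and time scale (78 urban diploids,
        32 generations), where the real mutational input is negligible
        next to standing variation; the default 0 avoids flooding the
        short post-split epoch with theta-rescaled (inflated-rate) young
        mutations.
    window_length
        Simulated sequence length in bp.
    s_focal, h_focal
        Selection and dominance coefficients of a focal beneficial allele
        in the urban deme (s_focal=0: no focal allele).
    bgs_scale
        Multiplier recorded for the background-selection approximation
        (applied to sizes by :func:`make_scenario`).
    burn_in
        Forward generations run in the ancestral population before the
        split (used to build inbreeding structure and inject young
        mutations in load cohorts).
    n_containment
        Effective size used in the selection term of the stationary
        spectrum that initialises selected sites in unlinked (load)
        cohorts; ``None`` means the engine's own ``n_anc``.  Setting it
        to the real-scale size implied by theta and the real mutation
        rate keeps strongly deleterious variants realistically rare,
        avoiding the saturation of purging through identity
        disequilibrium that theta-rescaled frequencies would cause.
    recombination
        ``"none"`` — the window is fully linked (scan/calibration
        windows); ``"free"`` — every site segregates independently
        (genome-wide load cohorts).
    seed
        RNG seed; identical (model, seed) gives identical output.
    """

    n_anc: int = 1000
    n_urban: int = 78
    n_rural: int = 1000
    t_split: int = 32
    m_ur: float = 0.05
    m_ru: float = 0.004
    f_urban: float = 0.3
    f_rural: float = 0.05
    mu: float = 1.4e-7
    mu_post_split: float = 0.0
    window_length: int = 50_000
    s_focal: float = 0.0
    h_focal: float = 0.5
    bgs_scale: float = 0.1
    burn_in: int = 0
    n_containment: int | None = None
    recombination: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_anc", "n_urban", "n_rural"):
            v = getattr(self, name)
            if not (isinstance(v, (int,)) and v >= 2):
                raise ValueError(f"{name} must be an integer >= 2, got {v!r}")
        if self.t_split < 0:
            raise ValueError("t_split must be >= 0")
        for name in ("m_ur", "m_ru"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0) or not math.isfinite(v):
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        for name in ("f_urban", "f_rural"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1), got {v!r}")
        if not (self.mu > 0 and math.isfinite(self.mu)):
            raise ValueError("mu must be positive and finite")
        if self.mu_post_split < 0 or not math.isfinite(self.mu_post_split):
            raise ValueError("mu_post_split must be >= 0 and finite")
        if self.window_length < 1:
            raise ValueError("window_length must be >= 1")
        if self.s_focal < 0 or not math.isfinite(self.s_focal):
            raise ValueError("s_focal must be >= 0")
        if not (0.0 <= self.h_focal <= 1.0):
            raise ValueError("h_focal must be in [0, 1]")
        if self.bgs_scale <= 0:
            raise ValueError("bgs_scale must be > 0")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.n_containment is not None and self.n_containment < 2:
            raise ValueError("n_containment must be >= 2")
        if self.recombination not in ("none", "free"):
            raise ValueError("recombination must be 'none' or 'free'")

    def replace(self, **kw) -> "DemographicModel":
        return dataclasses.replace(self, **kw)

    def rescaled(self, lam: float) -> "DemographicModel":
        """Classic population-size rescaling: N' = N/lam, mu' = mu*lam,
        t' = t/lam.  Selection coefficients are left to the caller (the
        focal s rescales as s' = s*lam when s is small)."""
        if lam <= 0:
            raise ValueError("rescaling factor must be > 0")
        return self.replace(
            n_anc=max(2, round(self.n_anc / lam)),
            n_urban=max(2, round(self.n_urban / lam)),
            n_rural=max(2, round(self.n_rural / lam)),
            t_split=max(0, round(self.t_split / lam)),
            burn_in=max(0, round(self.burn_in / lam)),
            mu=self.mu * lam,
        )


SCENARIOS = ("neutral", "bgs", "sweep")


def make_scenario(base: DemographicModel, kind: str) -> DemographicModel:
    """Derive one of the three calibration scenarios from a base model.

    ``neutral`` returns a copy; ``bgs`` multiplies every diploid size by
    ``bgs_scale`` (default 0.1), approximating strong background selection
    and inbreeding by reduced effective size; ``sweep`` sets ``s_focal=1``
    (a beneficial mutation introduced in the urban deme at the split and
    conditioned on fixation there).
    """
    if kind == "neutral":
        return base.replace()
    if kind == "bgs":
        return base.replace(
            n_anc=max(2, round(base.n_anc * base.bgs_scale)),
            n_urban=max(2, round(base.n_urban * base.bgs_scale)),
            n_rural=max(2, round(base.n_rural * base.bgs_scale)),
        )
    if kind == "sweep":
        return base.replace(s_focal=1.0)
    raise ValueError(f"unknown scenario kind {kind!r}; expected one of {SCENARIOS}")


@dataclass(frozen=True)
class EffectDFE:
    """Per-category site proportions and selection/dominance coefficients.

    The high-effect category is deleterious and fully recessive by
    default, which is the configuration under which inbreeding exposes
    variants as homozygotes and purges them.
    """

    proportions: dict[str, float] = field(
        default_factory=lambda: {
            "intergenic": 0.70,
            "low": 0.15,
            "moderate": 0.10,
            "high": 0.05,
        }
    )
    s_del: dict[str, float] = field(
        default_factory=lambda: {
            "intergenic": 0.0,
            "low": 0.0,
            "moderate": 0.01,
            "high": 0.1,
        }
    )
    h_del: dict[str, float] = field(
        default_factory=lambda: {
            "intergenic": 0.5,
            "low": 0.5,
            "moderate": 0.2,
            "high": 0.0,
        }
    )

    def __post_init__(self) -> None:
        cats = set(self.proportions)
        if cats != set(self.s_del) or cats != set(self.h_del):
            raise ValueError("proportions, s_del and h_del must share categories")
        total = sum(self.proportions.values())
        if any(p < 0 for p in self.proportions.values()) or abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions must be >= 0 and sum to 1 (got {total})")
        for c in cats:
            if self.s_del[c] < 0:
                raise ValueError(f"s_del[{c!r}] must be >= 0")
            if not (0.0 <= self.h_del[c] <= 1.0):
                raise ValueError(f"h_del[{c!r}] must be in [0, 1]")

    @property
    def categories(self) -> list[str]:
        return list(self.proportions)

    def neutral(self) -> "EffectDFE":
        """Same category proportions with all selection switched off."""
        zeros = {c: 0.0 for c in self.proportions}
        return EffectDFE(
            proportions=dict(self.proportions),
            s_del=zeros,
            h_del={c: 0.5 for c in self.proportions},
        )
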