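"""Genotype matrix container shared by all pipeline stages.

Genotypes are stored as counts of the derived (ALT) allele per site and
individual: 0, 1, 2 for diploids, 0, 1 for haploids, and ``MISSING`` (-1)
for uncalled genotypes.  Coordinates are 0-based internally; VCF I/O
converts to/from 1-based at the format boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

MISSING: int = -1

#: effect categories recognised throughout the package, mildest first
EFFECT_CATEGORIES = ("intergenic", "low", "moderate", "high")


@dataclass
class GenotypeMatrix:
    """Sites x individuals derived-allele counts with site/sample metadata.

    Parameters
    ----------
    genotypes
        ``(n_sites, n_individuals)`` int8 array with values in
        ``{0..ploidy, MISSING}``.
    chrom
        Chromosome identifier per site.
    pos
        0-based position per site, strictly increasing within a chromosome.
    effect
        Effect category per site (one of :data:`EFFECT_CATEGORIES`).
    pop
        Population label per individual (e.g. ``urban`` / ``rural``).
    samples
        Individual identifiers; autogenerated if omitted.
    ancestral_is_ref
        Per-site flag: True where allele 0 is the ancestral allele.
    ploidy
        1 or 2.
    """

    genotypes: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    effect: np.ndarray
    pop: np.ndarray
    samples: np.ndarray | None = None
    ancestral_is_ref: np.ndarray | None = None
    ploidy: int = 2
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.effect = np.asarray(self.effect, dtype=object)
        self.pop = np.asarray(self.pop, dtype=object)
        if self.samples is None:
            self.samples = np.array(
                [f"ind{k}" for k in range(self.genotypes.shape[1])], dtype=object
            )
        else:
            self.samples = np.asarray(self.samples, dtype=object)
        if self.ancestral_is_ref is None:
            self.ancestral_is_ref = np.ones(self.genotypes.shape[0], dtype=bool)
        else:
            self.ancestral_is_ref = np.asarray(self.ancestral_is_ref, dtype=bool)
        self._validate()

    def _validate(self) -> None:
        n_sites, n_ind = self.genotypes.shape
        if self.ploidy not in (1, 2):
            raise ValueError(f"ploidy must be 1 or 2, got {self.ploidy}")
        for name, arr, n in [
            ("chrom", self.chrom, n_sites),
            ("pos", self.pos, n_sites),
            ("effect", self.effect, n_sites),
            ("ancestral_is_ref", self.ancestral_is_ref, n_sites),
            ("pop", self.pop, n_ind),
            ("samples", self.samples, n_ind),
        ]:
            if len(arr) != n:
                raise ValueError(f"{name} has length {len(arr)}, expected {n}")
        g = self.genotypes
        bad = (g != MISSING) & ((g < 0) | (g > self.ploidy))
        if bad.any():
            raise ValueError("genotype values outside {0..ploidy, MISSING}")
        # positions strictly increasing within each chromosome
        for c in dict.fromkeys(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[1]

    def pop_indices(self, label: str) -> np.ndarray:
        idx = np.flatnonzero(self.pop == label)
        if idx.size == 0:
            raise ValueError(f"no individuals with population label {label!r}")
        return idx

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset sites, preserving order of `index`."""
        return replace(
            self,
            genotypes=self.genotypes[index],
            chrom=self.chrom[index],
            pos=self.pos[index],
            effect=self.effect[index],
            ancestral_is_ref=self.ancestral_is_ref[index],
        )

    def take_individuals(self, index: np.ndarray) -> "GenotypeMatrix":
        return replace(
            self,
            genotypes=self.genotypes[:, index],
            pop=self.pop[index],
            samples=self.samples[index],
        )

    def derived_counts(self, individuals: np.ndarray | None = None):
        """Per-site (derived allele count, called allele count) over a set
        of individuals (default: all), ignoring missing genotypes."""
        g = self.genotypes if individuals is None else self.genotypes[:, individuals]
        called = g != MISSING
        derived = np.where(called, g, 0).sum(axis=1)
        n_called = called.sum(axis=1) * self.ploidy
        return derived.astype(np.int64), n_called.astype(np.int64)


def concatenate(matrices: list[GenotypeMatrix]) -> GenotypeMatrix:
    """Stack per-chromosome/window matrices sharing the same individuals."""
    if not matrices:
        raise ValueError("nothing to concatenate")
    first = matrices[0]
    for m in matrices[1:]:
        if m.n_individuals != first.n_individuals or m.ploidy != first.ploidy:
            raise ValueError("incompatible matrices")
    lengths: dict[str, int] = {}
    for m in matrices:
        lengths.update(m.chrom_lengths)
    return GenotypeMatrix(
        genotypes=np.vstack([m.genotypes for m in matrices]),
        chrom=np.concatenate([m.chrom for m in matrices]),
        pos=np.concatenate([m.pos for m in matrices]),
        effect=np.concatenate([m.effect for m in matrices]),
        pop=first.pop,
        samples=first.samples,
        ancestral_is_ref=np.concatenate([m.ancestral_is_ref for m in matrices]),
        ploidy=first.ploidy,
        chrom_lengths=lengths,
    )
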