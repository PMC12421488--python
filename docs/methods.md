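# Methods

This note documents the models, estimators and numerical choices behind
`urbanpurge`, in the spirit of the methods sections that simulation and
statistics packages ship alongside their API docs.

## The study system and the default model

The package targets the analysis of a small urban population that
diverged very recently from a large surrounding source population and
still exchanges migrants with it.  The default `DemographicModel`
encodes that system:

| parameter | default | meaning |
|---|---|---|
| `n_urban` | 78 | urban diploid effective size |
| `n_rural`, `n_anc` | 1000 | rescaled source/ancestral diploid size |
| `t_split` | 32 | generations since divergence |
| `m_ur` | 0.05 | fraction of the urban deme replaced by rural migrants per generation |
| `m_ru` | 0.004 | the converse (migrant-count balanced, see below) |
| `f_urban`, `f_rural` | 0.3, 0.05 | target equilibrium inbreeding coefficients |
| `mu` | 1.4e-7 | per-bp mutation rate in rescaled units |
| `window_length` | 50 kb | simulated window |

**θ-rescaling.**  The real source population is far too large to
simulate forward at desk scale, so the engine works in rescaled units:
`n_rural = n_anc = 1000` stand in for a much larger population, with
the mutation rate inflated so that ancestral diversity
`4·n_anc·mu ≈ 5.6e-4/bp` matches the nucleotide diversity observed in
real non-urban populations of this system (≈ 5.5e-4/bp).  The urban
deme's size and the split time are *not* rescaled — 78 diploids and 32
generations are the real-scale values, and the post-split drift they
produce is the signal of interest.  A consequence: the post-split epoch
runs at real time scale, where real mutational input is negligible
relative to standing variation, so `mu_post_split` defaults to 0.
Carrying the inflated rescaled rate into the 32 post-split generations
would flood samples with young variants at ~300× their realistic
abundance and dilute every urban/rural contrast.

**Migration defaults.**  Migration fractions are migrant-count
balanced: the urban deme receives `m_ur = 0.05` of its individuals per
generation, and exports the same *number* of individuals to the much
larger rural deme (`m_ru ≈ m_ur · n_urban/n_rural ≈ 0.004`).  A
symmetric fraction would imply the 78-diploid deme replacing 5% of a
1000-diploid deme every generation, which is physically impossible and,
in simulation, spreads any urban sweep into the rural deme within a few
generations.  `m_ur = 0.05` itself was chosen so that neutral
genome-wide differentiation lands in the weakly structured regime the
system shows in reality; the realized neutral window F_ST distribution
has median ≈ 0.03 and mean ≈ 0.05.  Neither migration value is a
measured quantity; both are model choices.

**Inbreeding.**  Inbreeding is implemented mechanistically as partial
selfing at rate σ = 2f/(1+f), whose equilibrium inbreeding coefficient
is F = σ/(2−σ) = f, reached within ~5 generations.  Realized F̂ in an
isolated deme matches the target within ±0.05 (validated in the test
suite).  In the two-deme model the urban deme's realized F̂ sits below
the mating-system equilibrium (≈ 0.22 at f = 0.3) because outbred
migrants enter every generation; this is a property of the model, not
an estimator artifact.

## The forward engine and its initial conditions

The engine (`WrightFisherEngine`) is a discrete-generation forward
Wright–Fisher simulator: fitness-weighted parent sampling,
partial selfing, migration as a per-offspring probability that both
parents come from the other deme, multiplicative fitness across sites
(1, 1−hs, 1−s per genotype), and infinite-sites mutation with integer
positions de-duplicated by rejection.  Two linkage modes exist:

- `"none"`: a gamete is one parental haplotype — used for 50 kb scan
  and calibration windows, which are independent replicates;
- `"free"`: every site segregates independently — used for genome-wide
  load cohorts, whose sites come from across the genome.

Running a forward burn-in to mutation–drift equilibrium (~4N
generations) would dominate the compute budget, so the ancestral
population is initialised *at* equilibrium and the forward engine takes
over from there:

- linked windows: a whole-population sample from msprime's
  discrete-time Wright–Fisher model (`dtwf`).  The standard coalescent
  distorts genealogies when the sample size approaches 2N — measurably
  so: it pushed the null mean of Tajima's D from ≈ −0.10 (the true
  finite-sample null mean at these parameters, cross-checked against
  tskit) to ≈ −0.25;
- unlinked cohorts: sites drawn independently from the stationary
  spectrum.  Neutral categories follow Watterson's θL/i; selected
  categories are thinned by the Wright stationary density
  `f(q) ∝ (1/q)·exp(−2Ns(2hq + (1−2h)q²))`.

**Containment of deleterious variants.**  At the engine's rescaled
size, strongly deleterious recessives equilibrate at unrealistically
high frequencies, giving each individual ~16 exposed homozygotes.
Selection then acts mostly on aggregate individual fitness and per-site
purging saturates (identity disequilibrium): in controlled experiments
the purging contrast matches the deterministic single-locus recursion
with ~50 selected sites per genome and shrinks steadily as the exposed
load grows.  The load-cohort initialisation therefore uses a larger
"containment" size (`n_containment = 20,000`, intermediate between the
engine size and the ≈ 6×10⁴ implied by θ and the real mutation rate) in
the selection term, keeping high-effect variants rare (~2 exposed
homozygotes per individual) while retaining enough segregating sites
for a stable R′XY.  A 10-generation burn-in then builds inbreeding
structure and injects young mutations.

**Sweep conditioning.**  The sweep scenario introduces one beneficial
copy (s = 1, h = 0.5) in the urban deme at the split and accepts a
replicate when the focal allele is fixed among the sampled urban
individuals.  Because fresh migrants contaminate most single draws
(acceptance ≈ 0.5%), up to 20 sample redraws are attempted per
simulated replicate before the whole replicate is discarded (cap 1000
replicates).  This slightly over-weights replicates with more migrant
non-carriers relative to strict whole-replicate rejection; the effect
on the window-F_ST distribution is far smaller than its
replicate-to-replicate spread.

## Estimators

- **Projection**: hypergeometric down-sampling of each site's called
  alleles to fixed targets (64 urban / 24 rural by default — two times
  the minimum number of individuals with complete data under the 33%
  missingness rule).  Projection is linear, mass-conserving and
  composable; sites with fewer called alleles than the target are
  skipped and counted, matching dadi's semantics.
- **R_XY** is evaluated as the 2D-SFS expectation of the
  pairwise-genome definition (the two agree in expectation).  R′XY
  normalises by a seeded subsample of polymorphic intergenic sites
  (default 20,000, or all available).  The reciprocal identity
  R_XY(X,Y)·R_XY(Y,X) = 1 holds exactly on a transposed spectrum.
- **Block bootstrap**: 100 contiguous blocks of near-equal SNP count
  (chromosome boundaries may be crossed); the neutral normalisation
  subsample is drawn once and resampled with the blocks; 100 replicates
  by default; percentile CIs.  Block spectra are additive, so the fast
  path sums precomputed per-block 2D spectra.
- **Window scan**: π divides the summed per-site heterozygosity by all
  called sites in the window (monomorphic included — the window length
  for fully called simulated data), never by the SNP count.  Window
  F_ST is a ratio of sums; per-site ratios are never averaged.
  Tajima's D uses the standard constants and returns NaN (never 0) for
  windows without SNPs.  For PBS, negative pairwise window F_ST is
  clamped to 0 and F_ST to 1−10⁻⁹ before the log.  Haploid mode treats
  each individual as one allele.
- **Inbreeding F̂** = 1 − observed/expected heterozygosity.  When
  frequencies are estimated from the cohort itself, expected
  heterozygosity uses the unbiased `2p̂(1−p̂)·n/(n−1)`; without the
  correction, sampled singletons (always heterozygous) bias F̂ downward
  by ~1/(n−1), which is material for small cohorts.
- **Relative pruning** is greedy: flags (Θ and R both above threshold)
  are re-evaluated against the currently kept set after each removal of
  the lower-coverage member; coverage ties break by id order.  The
  alternative single threshold Θ > 0.0884 (lower confidence bound for
  second-degree relatives) is exposed as a configuration.
- **Circular permutation**: one shared uniform bp offset per
  chromosome (preserving candidate clustering and lengths),
  origin-crossing intervals split into two arcs, add-one p-values
  (never 0); a per-interval rotation mode is available behind a flag.
  The summary over overlapping windows is the mean (median by option).

## Calibration and outlier calling

`run_calibration` simulates window replicates under the three scenarios
and reports F_ST quantiles (50/95/99/99.9%) so users can derive their
own thresholds; the default pair (0.2 moderate, 0.35 strict) is carried
as metadata, not hard-coded into the distributions.  At a reduced 120-
replicate scale the quantiles are, for the default model: neutral
median ≈ 0.01 with q99 ≈ 0.22; background selection (sizes ×0.1) q99 ≈
0.6; sweep median ≈ 0.44.  A candidate window must exceed the moderate
F_ST threshold *and* sit at or above the genome-wide 95th PBS
percentile (ties included).  Under the ×0.1 scaling the urban deme
shrinks below the default sample size, so calibration clamps samples to
the deme size.

## Problem sizes in the test suite

The statistical tests run at sizes chosen to make each claim decisive
on one CPU in minutes: 1000 neutral panmictic windows for the
π/Tajima's-D/zero-split-F_ST validity checks (the null mean of D is
≈ −0.10, so a stable mean needs many windows); 150 replicates per
scenario for the calibration shifts (the sweep/neutral separation is
enormous, so a KS test is decisive far below 10⁴ replicates); 25
purging cohorts of ~20 Mb mutational target; 500 synthetic datasets for
permutation type-I error; 30 neutral cohorts for bootstrap coverage.
`scripts/acceptance.py` uses the same designs at slightly smaller
replicate counts.

## What the synthetic data do and do not show

The generator reproduces the *structure* of the real system — weak
neutral differentiation with strong gene flow, elevated urban
inbreeding, category-labelled variants with recessive high-effect load,
sweep and background-selection window classes — but not sequencing
error, genotype-likelihood uncertainty (estimators here take hard
genotypes, where the original analyses worked from genotype
likelihoods), linked selection within windows, or real gene annotation.
Passing tests therefore validate the estimators and the qualitative
phenomenology (purging detectable as R′XY(high) < 1; sweeps separable
from drift by window F_ST), not the exact numbers a full-scale field
dataset yields, which depend on genome-scale site counts.

One quantitative limit is documented deliberately: with cohorts of a
few hundred high-effect sites, the per-replicate 100-block bootstrap CI
of R′XY(high) is ~0.2 wide while identity disequilibrium caps the
purging contrast near 0.85–0.9, so a *single* desk-scale replicate
usually cannot exclude R′XY = 1 even though the effect is real and the
replicate mean is robustly below 1 (the pooled-replicate CI excludes 1
comfortably).  Real genome-wide data escape this by having ~100× more
high-effect sites.  The corresponding strict per-replicate test in the
suite is expected to fail at desk scale and is retained as an explicit
statement of that limit.

## Known limitations

- Hard-genotype estimators only; no genotype-likelihood machinery.
- No recombination within windows (linked mode) and no linkage at all
  in load cohorts; intermediate maps are not modelled.
- The coalescent/stationary initialisations are neutral; selected sites
  in load cohorts start from a single-locus stationary approximation
  rather than a fully equilibrated multilocus state.
- VCF support covers biallelic SNPs with GT fields; multiallelic
  records are skipped (and counted), not decomposed.
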