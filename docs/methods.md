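# Methods

This note documents the models and procedures `ovinecnv` implements, the
defaults and why, what the synthetic-data generator does and does not
emulate, and the numerical choices a maintainer would want recorded.

## Signal model

Raw per-SNP allele intensities X (A) and Y (B) are transformed as

- θ = arctan(Y/X)/(π/2), in [0, 1]; X = 0 maps to θ = 1 and a marker with
  X = Y = 0 is masked (NaN), never raised as an error.
- BAF: piecewise-linear rescaling of θ against the canonical cluster angles
  — 0 below θ_AA, 0.5(θ−θ_AA)/(θ_AB−θ_AA) on [θ_AA, θ_AB],
  0.5 + 0.5(θ−θ_AB)/(θ_BB−θ_AB) on [θ_AB, θ_BB], 1 at or above θ_BB.
- LRR = log₂(R_obs/R_exp); R_exp is interpolated linearly through the
  cluster (θ, R) nodes with **clamped** (constant) extrapolation outside
  [θ_AA, θ_BB]. Zero observed intensity floors the LRR at −5 rather than
  −∞; non-positive expected intensity masks the marker.

Canonical clusters are per-genotype **medians** of θ and R over reference
samples — medians because a reference panel drawn from the cohort itself
inevitably contains CNV carriers, and the median resists them. By default
the cohort is its own reference (an external HapMap-like panel can be
substituted by passing different reference matrices). A SNP missing one
outer genotype class is imputed by mirroring around θ_AB (θ_BB = 2θ_AB −
θ_AA clamped to ≤ 1, R from the opposite class); `fallback="drop"` flags
such SNPs unusable instead. Non-monotone or zero-width cluster geometry
always flags the SNP unusable, and unusable SNPs yield NaN BAF/expected-R.

The per-SNP population B-allele frequency (PFB) is the mean reference BAF
clipped to [0.01, 0.99]; clipping keeps the HMM's binomial mixture weights
away from point masses. All-missing SNPs get PFB 0.5 and a flag.

## Quality control

Sample gates (all must hold): LRR SD < 0.3, BAF drift < 0.01, waviness
< 0.05, genotype call rate ≥ 0.90. Two of these statistics are named in the
array-QC tradition without a published closed form, so they are
operationalised here and are config-overridable:

- **BAF drift** = fraction of markers with BAF in (0.15, 0.35) ∪
  (0.65, 0.85), i.e. drifted away from the three canonical bands. Note that
  genuine CN3 segments place heterozygous BAF at 1/3 and 2/3 — inside the
  drifted bands — so animals carrying very large duplication burdens can
  fail this gate. That is faithful to how the statistic behaves on real
  arrays; the recovery tests therefore measure calling performance on all
  samples, while the pipeline applies the gate as specified.
- **Waviness** = SD of per-1-Mb-bin median LRR within chromosomes.

Samples with fewer than 100 usable markers are flagged low-confidence.

Marker gates: missingness ≤ 0.05, MAF ≥ 0.02, exact Hardy–Weinberg p ≥
10⁻⁶, autosomal, positioned. The HWE test is the exact conditional test:
given the observed allele counts it enumerates every heterozygote count of
the right parity, computes each outcome's conditional probability (via
log-gamma, normalised in place), and sums those no more probable than the
observed outcome (with a 1 + 10⁻¹² relative tolerance absorbing float
round-off at ties). In multi-breed cohorts the test runs **within each
breed** and the minimum p faces the threshold — pooling differentiated
breeds would manufacture Wahlund disequilibrium and discard good markers.

## Copy-number HMM

Six states: CN0, CN1, CN2, CN2-LOH, CN3, CN4. Default emission parameters
(all overridable): LRR means (−3.5, −0.66, 0, 0, 0.40, 0.68), LRR SDs
(1.3, 0.28, 0.16, 0.16, 0.21, 0.24), BAF cluster SD 0.04 — the parameter
family of the published SNP-array CNV HMMs this model follows. Stationary
vector π = (10⁻⁴, 5·10⁻⁴, 0.9983, 5·10⁻⁴, 5·10⁻⁴, 10⁻⁴) (the diploid entry
absorbs the remainder so π is exactly stochastic); decay distance D =
100 kb; minimum run length 3 SNPs.

Transitions: A_ij(d) = e^(−d/D)[i=j] + (1 − e^(−d/D))π_j — identity at
d = 0, the stationary distribution as d → ∞, rows exactly stochastic for
any d.

Emissions: Normal(LRR; μ_s, σ_s) times a BAF mixture. For copy number
c ≥ 1 the mixture has components at k/c (k = 0..c) weighted
Binomial(c, PFB); each component is a Gaussian whose tail mass beyond
[0, 1] is re-assigned to the clipped boundary values, so BAF exactly 0 or 1
is scored with the boundary point mass. CN2-LOH keeps only the homozygous
k ∈ {0, 2} components (renormalised); CN0 emits Uniform(0, 1) BAF — with
no alleles there is no genotype signal. A missing LRR or BAF contributes
zero from its term; densities are floored at 10⁻³⁰⁰ before the log.

Decoding is exact Viterbi in log space with ties broken toward the lower
state index (deterministic; verified against exhaustive path enumeration).
Maximal runs of one non-CN2, non-LOH state with ≥ 3 markers become calls
spanning the first to last supporting SNP (1-based inclusive); call
confidence is the summed per-marker log-likelihood advantage of the called
state over CN2. LOH runs are reported separately and never counted as
CNVs: copy number 2 is not a copy-number change. No Baum–Welch
re-estimation is performed — the model is used pre-parameterised, matching
how these callers are used in practice. An optional gap-merge step
(bridge same-state calls separated by < 20% of their combined span) exists
but is OFF by default; the conservative un-merged calls are the reported
unit.

## CNV regions

Calls that share ≥ 1 base (1-based inclusive coordinates throughout) merge
transitively within a chromosome; the region spans the union. Status: Loss
if every supporting copy number is < 2, Gain if every one is > 2, Both
otherwise. The default reporting scope is **per-breed** merging (regions
from different breeds are never merged into one), because per-breed region
counts that sum exactly to the study-wide total are the convention in
multi-breed CNVR maps; cohort-scope merging is also computed. Venn sharing
assigns each region to the combination of breeds with ≥ 1 overlapping
region (optionally at a reciprocal-overlap fraction), partitioning every
breed's set.

Summaries report counts, total/mean/median lengths in kb, size classes
[20, 100) kb, [100, 500] kb, (500, ∞) kb (chosen so the classes partition;
events under 20 kb would land in the first class but are unreachable at
50k-array resolution), percentages rounded **half-up** to integers as
printed tables round, and the genome-proportion line
total_length/(n_samples × 2,500,000 kb) as a percentage (2.5 Gb is the
conventional sheep genome length).

## Selection scan

Per SNP, the Weir–Cockerham (1984) variance components a (among
populations), b (among individuals within populations), c (within
individuals) are computed from per-population sample sizes, B-allele
frequencies and observed heterozygote frequencies; θ̂ = a/(a+b+c). θ̂ is 1
exactly at fixed differences, may be slightly negative at undifferentiated
loci (the estimator is unbiased and deliberately **not** truncated at 0 —
truncation is available via flag but biases window averages upward), and
is NaN at globally monomorphic loci, which are excluded from windows.

Windows are consecutive **non-overlapping** blocks of 5 adjacent SNPs per
chromosome (sliding mode available); the windowed value is the arithmetic
mean of defined θ̂, and a terminal block shorter than 5 is kept and
flagged. Outliers are windows at or above the empirical (1−q) quantile
(quantile method "higher", ties at the threshold all included); q defaults
to 0.01. No publication quantifies the cutoff that turns a peak into a
"region under selection", so q is an explicit parameter and downstream
counts should be read as sensitivity-to-q, not as significance. The
genome-wide differentiation summary is the ratio of sums Σa/Σ(a+b+c), the
standard multi-locus estimator, and is what the simulator's F target is
recovered against.

## Annotation

Intervals are 1-based inclusive; overlap = min(ends) − max(starts) + 1 ≥ 1.
Gap distance between disjoint same-chromosome intervals is max(starts) −
min(ends) **without** the ±1 — of the two off-by-one conventions, both
reproduce printed cross-study distance tables after rounding to kb, and
this one is the documented choice. Distances are reported in kb rounded
half-up. Cross-dataset comparison matches each external region to its
nearest same-chromosome region, labels it overlap / proximal / distant
against a proximity threshold (default 1,000 kb — cross-study tables treat
regions within roughly 1 Mb as "located close"), and summarises the matched
fraction as a half-up-rounded percentage. Chromosome names are normalised
by stripping a "chr" prefix before any join.

## Synthetic cohort generator

The generator emulates a multi-breed ovine 50k-array cohort. Defaults are
the stated world: 3 breeds × 15 animals, 26 autosomes of 96 Mb with 2,000
SNPs each (≈ one marker per 48 kb, the 50k-array density), F_ST target
0.10, 9.13 CNV events per animal (the observed per-animal burden in the
livestock CNV literature this design mirrors), event lengths log-uniform on
[20 kb, 2 Mb], deletion probability 0.33 (the observed loss fraction among
CNV regions), LRR noise SD 0.2, BAF noise SD 0.04. Tests and the
acceptance run use a reduced 2-breed × 15, 2-chromosome × 2,500-SNP
configuration (seed 7) for runtime; the reduction is in scale only.

Mechanics: per-breed allele frequencies are Balding–Nichols draws,
Beta(p(1−F)/F, (1−p)(1−F)/F), giving mean p and variance F·p(1−p) — an
analytic F_ST truth for the recovery tests; F = 0 short-circuits to p.
Genotypes are Binomial(2, p_breed) per animal (HWE within breed,
independent loci). Event counts are Poisson per animal; events are clipped
to chromosome bounds, must span ≥ 1 marker, and never overlap within one
animal (collisions are resampled, with a hard failure if the configuration
cannot place events). Deletions are CN1 with probability 0.85 else CN0,
duplications CN3 with probability 0.85 else CN4 — single-copy changes
dominate real array call sets; the split is a package choice, stated here.
Within an event the B-dosage among the c copies is redrawn
Binomial(c, breed frequency). Intensities invert the signal model: target
BAF k/c (uniform for CN0) and target LRR equal to the calling HMM's state
mean for c, plus Gaussian noise in BAF/LRR space, mapped through the true
cluster geometry (θ_AA, θ_AB, θ_BB = 0.05, 0.50, 0.95; R = 2.0, 2.1, 2.0)
back to X, Y ≥ 0. Everything derives from one seeded generator: a fixed
seed reproduces every array and file byte-for-byte.

What the generator does **not** emulate — and therefore what a green
recovery test does not establish robustness against: GC-content waves and
batch effects (no wavy background), linkage disequilibrium (independent
loci, so windowed F_ST peaks are narrower than real sweeps), X-chromosome
dosage, genotyping error in the PED calls, and breed-asymmetric CNV
burdens (real cohorts show severalfold between-breed differences; the
per-breed mean is configurable but symmetric by default).

## Numerical and degenerate-input choices

- Rounding of table-style percentages and kb distances: half-up (ties away
  from zero), matching printed tables; Python's banker's rounding is never
  used for reported statistics.
- Viterbi ties: lower state index wins, making decoding deterministic.
- Emission underflow: densities floored at 10⁻³⁰⁰; missing values
  contribute 0 rather than propagating NaN.
- Empty inputs: empty Viterbi track → empty path; empty event set →
  all-zero summary; empty external CNVR set → 0% matched; a QC step that
  removes every SNP raises.
- The exact-HWE "no more probable than observed" comparison uses a 10⁻¹²
  relative tolerance so float round-off cannot drop exactly-tied outcomes;
  the test suite verifies equality against exact rational enumeration for
  every genotype configuration up to n = 30.
- The desk-scale pipeline run completes in a few seconds on one CPU; the
  full stated-world scale (45 × 52k markers) runs in a couple of minutes.

## Known limitations

- The HMM's parameters are fixed, not re-estimated; badly calibrated
  arrays would need parameter overrides rather than an EM fit.
- The BAF-drift gate penalises genuine large duplications (see above);
  cohorts expected to carry mega-base duplication burdens should relax it
  consciously.
- Confidence scores are likelihood ratios against CN2 only, not calibrated
  probabilities.
- Per-breed HWE filtering assumes breed labels are correct; admixed
  individuals blur the test.
- The selection-overlap count is a function of the outlier quantile q;
  report it together with q.
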