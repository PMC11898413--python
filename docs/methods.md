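# Methods

This note records the models, estimators and numerical conventions the
package implements, the choices made where the design was open, and
what the synthetic-data generator does and does not emulate.

## Data model

Genotypes are diploid alt-allele dosages in {0, 1, 2} with −1 for
missing calls, held dense as samples × variants. Coordinates are
1-based (VCF convention) internally; windows and sweep regions are
half-open `[start, end)` intervals in that 1-based space, and BED
output converts to 0-based half-open. Only biallelic SNPs enter the
model: multi-allelic and indel records are dropped at read time (all
downstream estimators assume two alleles), not split.

## Site filters

A variant is kept iff (strict inequalities throughout): pooled minor
allele frequency > `min_maf` (default 0.01), depth > `min_depth`
(default 3) and missing fraction < `max_missing` (default 0.2). The
MAF is computed over non-missing genotypes pooled across all samples —
the filter acts on one joint callset, not per population. The depth
criterion is ambiguous in common usage between a site-level and a
genotype-level reading; the default interprets it as mean per-genotype
DP at the site (VCFtools-style site filtering), and
`depth_mode="mask_genotypes"` instead sets individual low-depth calls
missing before the other filters run. Matrices without depth satisfy
the depth criterion vacuously. Filtering is idempotent and order
preserving; per-criterion failure counts are reported (a variant may
fail several criteria at once).

## Windowed statistics

Windows tile each chromosome with starts 1, 1+step, 2·step+1, …
(defaults 100 kb / 10 kb); trailing windows are clipped to the
chromosome end and flagged partial.

**π.** Per site, the unbiased heterozygosity 2p̂q̂·n/(n−1) with n the
non-missing allele copies; sites with n < 2 contribute nothing. Window
π divides the summed per-site values by the window length in bp, so
monomorphic and unassayed positions count toward the denominator (the
VCFtools `--window-pi` convention). Both a genome-wide reduction
(summed heterozygosity over total length) and the mean-of-windows
reduction are available, since published per-population π values can
be computed either way.

**F_st.** Weir & Cockerham (1984) variance components a (among
populations), b, c (within), computed per site from the two
populations' sample sizes, allele frequencies and observed
heterozygote frequencies, aggregated ratio-of-sums: Σa / Σ(a+b+c) over
usable sites. Ratio-of-sums is preferred over mean-of-ratios for its
lower bias (and is what VCFtools reports). Sites where either
population has no calls, where the mean sample size is ≤ 1, or where
a+b+c = 0 are skipped. Estimates are symmetric in the population order
and **negative values are never clamped** — for undifferentiated
populations the finite-sample estimator is expected to straddle zero,
and the negative genome-wide values such cohorts produce are a
meaningful observation, not an error. Hudson's estimator
(ratio-of-averages form) is included as a labelled cross-check
alternative, never substituted silently.

**Tajima's D.** D = (π̂ − S/a₁)/√(e₁S + e₂S(S−1)) with the canonical
constants a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂ computed from the allele-copy
count n. S and π̂ (count scale) accumulate over the window's
segregating sites in the analysis population only. With missing data n
varies by site; the constants use the median n over the window's
segregating sites, which equals 2 × sample size for complete data and
is insensitive to sporadic missingness. Windows with S = 0 get NaN;
populations providing fewer than 4 allele copies are rejected.

## Sweep scan

ROD compares each window's π in a scanned population against the same
window in the designated reference population: ROD = |1 − π_pop/π_ref|,
with the signed value 1 − π_pop/π_ref preserved alongside. The absolute
value makes the statistic two-sided (a diversity *gain* also ranks
high); that is the definition implemented by default, and
`side="loss"` ranks the signed value instead for a strictly
sweep-shaped (diversity-loss) screen. ROD is undefined when the
reference window π is 0 or when either window has fewer than
`min_sites` (default 10) usable variants — the ratio of two small
noisy π values is unstable — and such windows are excluded from
ranking. ROD is scale invariant: multiplying all π by a constant
changes nothing.

Outlier calling takes the genome-wide (1 − 0.05) quantile of windowed
F_st (population vs reference) and of ROD separately, over defined
windows, and returns windows at or above **both** thresholds
(intersection; a union mode exists behind a flag). Ties at a threshold
are included, so a degenerate all-equal distribution returns every
window with a logged warning. Quantiles are computed per population
pair across the whole genome, not per chromosome. Adjacent or
overlapping outlier windows merge into regions (`max_gap` defaults to
0: only overlapping/abutting windows merge — no merge rule is implied
by the screening definition itself, so the most conservative one is the
default); region bounds are the min start / max end, with peak ROD and
peak F_st recorded. A gene is attached to a region iff its 1-based
inclusive GFF3 span overlaps the half-open region by ≥ 1 bp, strand
ignored.

## Structure inference

**IBS distance.** d(i,j) = mean over co-genotyped sites of
|dosage_i − dosage_j| / 2, in [0, 1]; a pair sharing no site is an
error naming the pair. The distance feeding the tree is a package
choice (tree-building tools are routinely run on SNP matrices without
a canonical published distance); it is documented as such.

**Neighbor joining.** Saitou–Nei agglomeration on the Q-criterion
(m−2)d_ij − R_i − R_j, ties broken by the lowest (row, column) index
pair, standard branch-length formulas, trifurcating root (unrooted
convention). Negative branch lengths are clamped to 0 with the
pre-clamp value logged — matching the behaviour of classic phylogeny
packages. NJ is exact on additive matrices, which the tests exploit:
trees regenerated from random additive distances are reproduced to
1e-9, and the implementation is cross-checked against scikit-bio's
independent `nj`.

**Admixture model.** Dosages are modelled g_il ~ Binomial(2, x_il),
x_il = Σ_k q_ik p_kl. The log-likelihood Σ g log x + (2−g) log(1−x)
(binomial coefficients constant, missing entries dropped) is maximized
by plain EM: the E-step allocates each of the 2 allele draws to source
populations, the M-step re-estimates P from allocated alt/ref copies
and Q from per-individual allocations. Plain EM shares its fixed
points with the block-relaxation used by dedicated admixture software
while being straightforward to verify; speed is immaterial at the
scales this package targets. Q rows are renormalized to the simplex,
P is kept in [1e-6, 1 − 1e-6], and the likelihood is asserted
non-decreasing every iteration (up to the vanishing perturbation the
clipping can introduce). Initialization is random (Dirichlet rows for
Q, uniform P) with `n_restarts` restarts keeping the best likelihood;
K = 1 is solved in closed form (pooled frequencies). Default
convergence: relative log-likelihood change < 1e-8 or 2000 iterations.

**Choosing K.** Cross-validation masks a random fold of the observed
genotype entries (5 folds by default), refits, and scores the RMS
deviation of predicted dosages 2·Q̂P̂ at masked entries, averaged over
folds. `scan_K` repeats each K with distinct seeds and reports the
minimum CV error per K, mirroring the repeat-and-take-minimum protocol
of standard practice (20 repeats by default at full scale). For CV
scans the EM tolerance can be relaxed (the tests and the acceptance
script use tol 1e-6, max 500 iterations): prediction error at masked
entries is insensitive to the final decimals of the likelihood, while
full-precision convergence on structureless data is slow.

## Synthetic-data generator

The generator emulates the statistical structure the analyses assume —
not a demographic history. Per site: ancestral frequency p ~
Uniform(0.05, 0.95) (keeps most sites polymorphic pre-filter so the MAF
filter has work to do); population frequency from Balding–Nichols
Beta(p(1−F)/F, (1−p)(1−F)/F) (exactly p when F = 0); genotypes
Binomial(2, p_pop). Variant density is set analytically so expected
genome-wide per-site π equals `target_pi`: sites per chromosome =
target_pi · L / [(1 − F̄)·E(2p(1−p))] with the expectation taken under
the uniform spectrum. Sweep footprints push affected populations'
frequencies to fixation: each in-interval site independently fixes
with probability equal to `diversity_reduction` (fixing to the alt
allele with probability p), so expected heterozygosity inside the
interval drops by exactly that fraction — only the footprint matters
to a diversity/differentiation screen, so no explicit selection
dynamics are simulated. With `admixture_spec=(K, α)`, K source
frequency vectors are drawn Balding–Nichols around p and each
individual's ancestry Q ~ Dirichlet(α·1_K), genotypes
Binomial(2, Q·P). Depth is negative binomial per genotype
(overdispersed coverage is the realistic stress case for the depth
filter) and genotypes go missing independently at `missing_rate`. The
truth record stores per-population F, sweep intervals, true Q and all
drawn frequencies.

Defaults describe the cohort the pipeline is aimed at: 6 populations ×
10 diploids, target π = 3.1 × 10⁻³, divergence F = 10⁻³ (differentiation
of ~10⁻³ magnitude — small enough that finite-sample F_st estimates
straddle zero), mean depth 12× with dispersion 5, 5% missingness.
Chromosome count and length default to 2 × 2 Mb so full scans run in
seconds; all sizes scale up by configuration.

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: linkage disequilibrium (sites are
independent; none of the implemented statistics needs LD, but
window-to-window correlation in real genomes is stronger than
simulated), mutation-model detail and sequencing error at base level,
structural variation, non-equilibrium demography (bottlenecks,
expansions — Tajima's D on real data reflects these), and gene flow
between specific population pairs. Recovery rates measured on
synthetic cohorts are therefore upper bounds on real-data performance
in the same parameter regime, not guarantees.

## Numerical conventions and degenerate inputs

NaN is the undefined sentinel throughout (windows with no usable
sites, ROD with zero reference diversity, Tajima's D with S = 0).
Quantiles use numpy's default linear interpolation. The simulator,
the EM, and the CV scan consume a single `numpy.random.Generator`
seeded explicitly; identical configurations produce byte-identical
VCFs and identical statistics. Filtering away every variant yields an
empty matrix with a warning rather than an error; an empty outlier set
merges to zero regions. Fewer than 20 ranked windows triggers a
percentile-instability warning rather than a refusal.

## Problem sizes used by the test suite and acceptance script

Simulated cohorts in the tests use 1–2 chromosomes of 0.06–3 Mb and
10–40 diploids per scenario — large enough that every statistical
property under test (F recovery to Monte-Carlo precision, ≥95% sweep
recovery, CV selection of K, NJ clustering) is measured with decisive
margins, small enough that the full suite runs in about two minutes.
The acceptance script uses the same scenario family with 12–20
replicates per experiment. These sizes are the package's chosen desk
scale; every experiment scales up by raising the configuration values.
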