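# Methods

`autozyg` implements a complete runs-of-homozygosity (ROH) inbreeding
analysis for small, intensively managed populations: windowed ROH calling
with dataset-specific parameter choices, genome-wide and per-chromosome
inbreeding coefficients, concordance between dense (whole-genome, "WGS")
and sparse (reduced-representation, "RRS") SNP panels, and mixed-model
tests of inbreeding depression on female reproductive traits. Because
genotype and phenotype data for endangered species are typically
access-restricted, the package ships a first-class synthetic-data
generator whose ground truth (true identical-by-descent tracts, planted
effect sizes) makes every downstream stage testable.

## ROH detection

The caller reimplements the sliding-window algorithm popularised by PLINK
`--homozyg`:

1. For each individual and chromosome, a window of `window_snp`
   consecutive SNPs slides one SNP at a time. A window *passes* iff it
   contains at most `window_het` heterozygous and `window_missing` missing
   calls. Windows never span chromosomes.
2. Each SNP is scored by the fraction of windows containing it that pass
   (edge SNPs are contained in fewer windows); SNPs scoring at least the
   hit threshold (default 0.05, the PLINK default; not stated by the
   original analyses we mirror) are run-eligible.
3. Maximal stretches of consecutive eligible SNPs form candidates, split
   wherever the gap between neighbouring SNPs exceeds `homozyg_gap` kb,
   and trimmed so segments start and end on homozygous calls.
4. A candidate is emitted iff its SNP count is at least the L-parameter
   (`homozyg_snp`), its span is at least `homozyg_kb` kb, its kb-per-SNP
   ratio is at most `homozyg_density`, and it contains at most
   `homozyg_het` heterozygous calls.

Two presets carry the published parameterisations: WGS (L = 40, 300 kb,
1 SNP/100 kb, 1 Mb gap, 3 het; 50-SNP windows with ≤ 3 het and ≤ 5
missing) and RRS (L = 37, 1 SNP/130 kb, 25-SNP windows; other values
shared). The "window size of 300 kb" wording attached to `homozyg-kb` in
the source pipelines is interpreted by the flag's actual semantics — a
minimum segment length — and "> 50 SNPs" per window as `window_snp = 50`.
No additional minimum ROH length is imposed beyond `homozyg_kb`.

The per-segment length convention is 1-based inclusive (end − start + 1
bp), matching PLINK `.hom` KB fields; internal coordinates are 0-based
half-open, converted only at I/O boundaries.

The test suite pins the caller, segment for segment, to an independent
brute-force oracle that materialises every window and applies the five
steps literally, across fuzzed maps, genotypes and parameter draws.

### L-parameter

L = ln(α / (n_s · n_i)) / ln(1 − het), with α the tolerated false-positive
rate (0.05), n_s the SNP count, n_i the number of individuals and het the
mean per-site heterozygosity. It is the run length at which a purely
random stretch of homozygous calls anywhere in the dataset becomes
improbable at rate α. Rounding is to the nearest integer by default
(floor/ceil available; the choice is not documented in the analyses we
mirror).

### Genome-coverage parameter

To compare parameter combinations and panels, the package computes the
percentage of the autosomal genome lying in *callable territory*: the
union of maximal SNP runs whose adjacent gaps are within `homozyg_gap` and
which satisfy the SNP-count, span and density requirements — exactly the
intervals where a fully homozygous individual could have a segment called.
The exact published formulation of this coverage parameter lives in
supplementary material we do not reproduce; the callable-territory
definition here is this package's stated surrogate, and it provably
coincides with the caller's output on a fully homozygous individual
(tested). `optimize_parameters` evaluates it over a grid and returns the
argmax (ties broken by grid order).

## Inbreeding coefficients

F_ROH = Σ L_ROH / L_Auto, the fraction of the autosomal genome covered by
ROH. The denominator is the *configured* total autosomal length, not the
SNP-spanned length; this changes absolute values and is therefore fixed
and documented. F_ROH_CHR applies the same ratio per chromosome; its
chromosome-length-weighted mean equals genome-wide F_ROH exactly (tested
to 1e-12). Segment size classes use half-open bins [0–2), [2–4), [4–8),
[8–16), ≥16 Mb — boundary lengths go to the upper class. Concordance
between panels is Pearson's r over shared individuals (genome or
per-chromosome level); chromosomes with constant values (e.g.,
micro-chromosomes with no ROH in any individual) report NaN and are
flagged rather than dropped silently.

## Variant filtering

Genotype-level first, then site-level, so site missingness reflects
blanked genotypes. Genotype criteria (WGS preset): depth > 4, genotype
quality > 20, heterozygous allelic balance within [0.2, 0.8] (balance
defined as alt reads / (ref+alt) reads; values outside the band are the
exclusion region), and ≥ 5 supporting reads. The RRS preset relaxes to
depth > 1, ≥ 2 reads and ≤ 20% site missingness (WGS: ≤ 10%). The
read-support rule is implemented on the total of forward+reverse ref+alt
reads by default; a strict flag additionally requires every strand/allele
stratum to be covered, since the source description is ambiguous between
the two readings. "Quality" is taken as per-genotype quality (GQ); site
QUAL is not carried by the matrix container. Criteria whose evidence
fields are absent are skipped with a log note, never errors. There is
deliberately no minor-allele-frequency or linkage pruning — frequency
filters bias homozygosity-based inbreeding estimates in small populations
— so monomorphic sites are retained.

Mendelian errors are genotype combinations where the child cannot receive
one allele from each parent (verified against an exhaustive 27-combination
enumeration); combinations involving missing calls are never flagged.
Removal blanks the trio members' genotypes at flagged sites by default, or
drops the site.

## Synthetic data

**Genome.** 23 autosomes by default with lengths decaying geometrically
from macro- to micro-chromosomes (total 200 Mb for desk-scale runs, 1 Gb
optional) — micro-chromosomes must exist to reproduce the observation that
some are too short to harbour a callable ROH. The real study system's
autosome count/length is not fully specified upstream, so both are
configuration.

**Pedigree.** Founders plus discrete generations under four mating
schemes: random; half-sib-biased; lek (sires drawn from a small pool of
dominant males, the relevant scheme for a lek-breeding parrot); and a
deterministic full-sib line for calibration (its pedigree inbreeding rises
0, 1/4, 3/8, matching Wright's path counting, which the package also
computes via the tabular kinship recursion).

**Gene dropping.** Founder haplotypes are mutually distinct and carry
alleles drawn per site from a founder allele-frequency distribution
(default Uniform(0.05, 0.5)). Transmission draws a Poisson number of
crossovers per chromosome per meiosis at 1 cM/Mb (no interference) and
records ancestry mosaics, so IBD tracts — where an individual's two
haplotypes descend from one founder haplotype — are exact, not inferred.
F_true is the autosomal IBD fraction. Default SNP density is 1000/Mb
(dense-panel scale); site positions are uniform.

**RRS emulation.** Thinning to a target density, either uniformly
(Bernoulli per site) or clustered around random "restriction-site"
anchors. The realistic cluster radius is a few hundred bp (restriction
loci are short and spaced tens of kb apart); a radius of tens of kb
produces widely separated clumps that the gap rule fragments, destroying
ROH detection — a useful negative control but not an emulation of real
libraries. Extra missingness mimics the lower call rate of sparse
libraries.

**Phenotypes.** Repeated female reproductive measures with a log-link
linear predictor: intercepts reproduce the observed trait means (clutch
2.74, hatched 1.06, volume 38.57 mL); the standardized inbreeding effect
on hatching success defaults to −0.44; female and year random intercepts
default to SD 0.3 and 0.2 (plausible moderate repeatability; no upstream
values exist). Predictors are standardized as (x − mean)/(2 SD). Clutch
size is Poisson truncated at ≥ 1 (observed clutches have at least one
egg); eggs hatched is Poisson *conditioned on* not exceeding clutch size —
an exact truncated-Poisson draw, distributionally identical to rejection
redraws but immune to stalling when the rate far exceeds the clutch — with
a Binomial(clutch, logistic) alternative. Egg volume is Gaussian per egg
with female and clutch intercepts; egg length and width are back-generated
from the volume through V = k·L·W² (k = 0.51e-3 mL/mm³, placing a
50×38 mm egg at ~37 mL, inside the observed 14.5–47.8 mL range; the
upstream constant is unpublished, so k is configuration).

What the generator does *not* emulate: coalescent founder ancestry,
selection, mutation during transmission, sex chromosomes, genotyping error
beyond the explicit error-injection operation, or shared environmental
structure beyond year/female/clutch intercepts. Passing tests therefore
demonstrate correctness of the machinery under the stated model, not
robustness to every property of real data.

**A known consequence of the hatching cap.** Because mean eggs hatched
(1.06) is close to mean clutch size (2.74), the cap binds in a sizeable
minority of female-years. Fitting an uncapped Poisson GLMM to capped data
attenuates the planted hatching-success effect (measured: full-model mean
estimate ≈ −0.33 for a planted −0.44; an uncapped control recovers
≈ −0.41), and zero-substitution model averaging shrinks it further when
relative importance is below 1. Confidence-interval coverage of the
planted value is therefore below nominal at study scale. This is a
property of the generator-design/estimator pair, not an implementation
defect; the recovery test on correctly specified data is within 3 SE.

## GLMMs and model averaging

`fit_glmm` is an in-package maximum-likelihood fitter for Poisson
(log-link) and Gaussian responses with crossed random intercepts, because
no installed Python library fits ML Poisson GLMMs. For candidate variance
parameters, the joint penalized log-likelihood is maximised over fixed
effects and random effects by damped Newton iteration; the marginal
likelihood uses the Laplace approximation
ℓ(θ) = ℓ_joint − ½ log det(ZᵀWZ·D + I). For the Gaussian family this
expression is exact. Variance parameters are profiled by L-BFGS-B on the
SD scale with a zero lower bound, so boundary fits collapse exactly to the
plain GLM (tested to 1e-6 against statsmodels). The Laplace approximation
itself differs from an 80-node Gauss–Hermite reference by ~5e-3 on Poisson
toys with moderate counts — the approximation error, asserted within an
honest 0.02 band. Fixed-effect covariances are conditional on the
estimated variance parameters, the usual GLMM convention.

Per trait: clutch size and hatching success are Poisson with female and
year intercepts, one row per female-year-clutch; egg volume is Gaussian
per egg with female, year and clutch intercepts. Age is excluded from
egg-volume models (collinear with generation, per the VIF check the
package also provides). Generation is coded as an ordered numeric
covariate.

Model averaging fits every subset of the fixed predictors (random effects
always retained), ranks by AICc = AIC + 2k(k+1)/(n−k−1) with k counting
fixed effects plus free variance parameters, and averages the four
best-supported models with Akaike weights w ∝ exp(−Δ/2) renormalised over
that set. The upstream phrase "the four models with the highest AICc"
would select the *worst* models under the information-theoretic framework
it cites; this package treats it as best-supported (lowest AICc), with a
`literal_highest` audit switch. Averaging is full-model
(zero-substitution) by default, conditional averaging by flag; the
adjusted SE is √(Σ w_i (var_i + (β_i − β̄)²)); relative importance is the
summed weight of averaged models containing the predictor; a predictor is
"strongly supported" when its 95% CI excludes zero.

## Chromosome-partitioned model

A Bayesian multi-membership model asks whether inbreeding depression is
localised: g(μ) = β₀ + β_F·std(mean chromosome inbreeding) + Σ_c w_ic u_c
+ a_i, where w_ic is individual i's standardized F_ROH_CHR on chromosome c
(every observation belongs to all chromosomes at once), u_c ~ N(0, σ_chr)
and a_i ~ N(0, σ_ind). Priors are weakly informative — N(0, 2.5) on
coefficients, half-N(0, 1) on SDs — chosen by this package (none are
published) and configurable.

The posterior is sampled by coordinate-wise slice sampling (stepping-out
plus shrinkage), with two model-specific accelerations: random effects are
parameterised non-centrally (unit latents times their SD) to avoid the
small-σ funnel, and an extra slice move travels along the β_F/chromosome
ridge (every chromosome's inbreeding tracks genome-wide inbreeding, so
these directions are nearly collinear; the move shifts β_F with a
compensating least-squares adjustment of the chromosome latents). Defaults
are 4 chains × 3000 iterations with 1500 warmup. Convergence (split-R̂,
bulk ESS) and PSIS-LOO predictive comparison run through ArviZ; a fit is
flagged non-converged whenever any parameter's split-R̂ reaches 1.01.
Δelpd is reported as (model with chromosome term) − (without), with the SE
of the pointwise difference; when Pareto-k diagnostics fail, an exact
k-fold cross-validation fallback refits on training folds.

## Numerical and reproducibility choices

- Missing genotypes are coded −1 in an int8 matrix; all randomness flows
  from explicit integer seeds through `numpy.random.default_rng`.
- Problem sizes used by the shipped end-to-end run: 120 individuals on a
  200 Mb / 23-autosome genome at 1000 SNPs/Mb (dense) and 12.5 SNPs/Mb
  (thinned), 49 females × 3 clutch-years for the fitness models — the
  desk-scale configuration the generator defaults to; all sizes are
  parameters.
- Tie-breaks: parameter-grid optimisation returns the first argmax in grid
  order; `.hom` output is sorted by (individual, chromosome, start).
- Degenerate inputs fail loudly: constant predictors cannot be
  standardized, rank-deficient designs and single-level grouping factors
  are rejected, segments beyond chromosome ends raise, non-convergence is
  flagged in results rather than silently returned.
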