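# Methods

## Statistic and filtering

The unit of analysis is the ancestry dosage of a recombinant hybrid at a
*diagnostic* marker: a locus at which the two founder (F0) lineages of a
cross share no alleles.  A marker enters the panel only if (a) the union
of side-A founder alleles is disjoint from the union of side-B founder
alleles (for multi-founder designs the unions are taken across all
founders per side — the strictest reading that guarantees every allele
polarizes), (b) every genotyped F1 carries exactly one allele from each
side, and (c) it is autosomal (the sex chromosome, labeled "19" by
default, is excluded).  GBS calls at depth ≤ 20 are treated as missing
before the rules are evaluated (a strict "> 20×" rule).  The fraction of
F1 calls at side-disjoint markers that are cross-side heterozygous is
reported as an empirical genotyping-quality check; on clean data it is
1.0.  After polarization, recombinant individuals with fewer than 20
genotyped loci and markers genotyped in fewer than 20 recombinants are
dropped, iterating the two rules to a fixed point so the result is
order-independent.  Founder and F1 rows are carried as controls but
never counted or summarized.

Excess ancestry heterozygosity is observed heterozygosity minus
2·p_A·p_B computed from the *individual's own* (or the locus's own)
ancestry frequencies.  Using own-genome frequencies makes the statistic
insensitive to hybrid-index variance and to directional selection on
ancestry.  One finite-sample subtlety matters for calibration: with
dosage counted over n loci, E[2·h·(1−h)] = 0.5 − 1/(4n) under neutral
segregation, so the uncorrected excess has expectation +1/(4n) (≈ 0.0025
at 100 loci), not exactly zero.  The optional `small_sample` correction
multiplies the expectation by 2n/(2n−1), which removes the offset;
the default is the uncorrected statistic, matching the main analysis
convention, and environment *contrasts* are unaffected either way
because the offset is common to both groups.  Tests that assert a
zero-centered null use the corrected option for that reason.

## Environment model

Individual excess values are modeled as

    value ~ C(environment) + C(cross_type) + C(environment):C(cross_type) + C(lake)

with a random intercept per data source, fitted by REML (statsmodels
MixedLM) with Wald z inference.  Lake applies only to the benthic ×
limnetic stratum; marine × freshwater rows carry the reference level
"none", and any factor observed at a single level is dropped from the
formula.  When the random-intercept variance is estimated at the
boundary (or the optimizer fails) the fit degrades to the ordinary
fixed-effects model, with a note recorded on the result — on small
simulated bundles with no true between-dataset variance this is the
expected path.  The quantity of interest, the pond − lab contrast within
each cross, is a linear combination of fixed effects and is recomputable
from the reported coefficients.

Bootstrap comparison of the pond and lab hybrid-index-deviation
correlations resamples individuals within group and uses the
(k+1)/(B+1) continuity convention for the two-sided P, so P is never
exactly zero.  The single-marker resampling analysis draws one marker
uniformly per chromosome per dataset per replicate, recomputes
individual summaries without re-applying the ≥20-loci filter (a single
marker per chromosome caps loci at the chromosome count), and refits an
additive fixed-effects version of the model; the reported number is the
fraction of replicates whose environment effect has the full-data sign.

## Synthetic data generator

The generator emulates a nine-dataset compilation (two cross types, two
lakes, lab aquaria vs experimental ponds, 23–183 markers and tens to
hundreds of fish per dataset, microsatellite / SNP-array / GBS
platforms; `study_bundle_config()`), or any custom layout.  Ancestry
segregates 1:2:1 independently per marker: the statistic and its null
expectation do not depend on linkage, and chromosome labels exist so the
resampling analysis has groups (an optional shared-dosage-per-chromosome
mode provides crude linkage for sensitivity checks).  Founders carry
their side's full allele pool (microsatellites: two fragment-size-like
integer tokens per side; SNPs: one nucleotide per side) so every
descendant draw is consistent with inheritance.  Missingness applies to
recombinant calls only; GBS depth is negative-binomial (mean 60, shape
3), leaving ~10–15% of calls under the 20× threshold.  Genotyping error
follows the conservative model: each recombinant ancestry-homozygous
call converts to a cross-side heterozygote with probability e; F0/F1
calls and heterozygotes are untouched.  F3 cohorts are formed by random
union of one recombination-free gamete per marker from two distinct
surviving F2 parents.  Standard lengths, when simulated, are
genotype-independent Gaussians with family offsets (a null for the
body-size regression).  Every random draw derives from
(seed, dataset index, family index, stream) so any piece regenerates in
isolation.

Pond F2 family sizes are equal by default; the natural-mating size
distribution in real ponds is unknown and the statistics are insensitive
to it.

## Viability selection

Three architectures span single-locus, pairwise-epistatic and
polygenic-phenotypic mechanisms:

- **heterozygote_advantage** — w = (1−s)^(number of ancestry-homozygous
  loci among k designated markers; k defaults to all).  Because fitness
  factorizes over independent loci, survivor excess per selected locus
  is s/(2(2−s)) at every locus, so the genome-wide mean excess is
  (k/L)·s/(2(2−s)): selection confined to one locus among 100 cannot
  produce a 3% genome-wide excess at any s.
- **pairwise_dmi** — w = (1−s)^(number of designated marker pairs
  homozygous for opposite ancestries), the classic two-locus
  incompatibility.
- **fgm_mismatch** — each marker receives an additive effect vector over
  m traits (default m = 20, effect sd 0.15); w = exp(−σ_scale·d⊥²) with
  d⊥ the perpendicular distance of the additive phenotype from the
  inter-parent axis.  The trait count matters: with m = 2 there is a
  single orthogonal direction, balanced homozygous ancestry can zero it,
  and the attainable excess saturates near 1%; m = 20 makes the 3%
  target reachable at workable survivor yields, which is why it is the
  default.

Survival probability is fitness divided by the cohort maximum.
"Proportional to fitness" leaves the constant free — conditioning on
survival gives the same survivor distribution for any constant — and the
max-normalization keeps yields practical for multiplicative fitnesses
whose raw mean is ~(1−s/2)^L.  Selection acts on true genotypes before
genotyping noise is overlaid, and never alters genotypes, only
membership.  `selection_strength_required` bisects the architecture's
strength parameter on a common simulated cohort with common survival
draws (tolerance 0.002 on the survivor mean excess, automatic interval
expansion, a structured error when the target is unattainable).

## Fisher geometric model

Fitness is w = exp(−σ‖z−o‖²); the selection coefficient of a proposal is
w_mut/w_wt − 1; fixation probability is the diffusion form
π = (1−e^(−2Nsp))/(1−e^(−2Ns)) with the continuous extension π = p when
|2Ns| < 1e−8, evaluated in a factored form that stays finite for
strongly deleterious proposals and clamped to [0,1].  Defaults: m = 2
traits, α = 0.15 mutation-effect sd per trait, σ = 10, N = 1000,
p = 1/N, 1000 mutation proposals ("arise" is read as proposals, not
fixations — fixing 1000 mutations of this size would vastly overshoot
the optimum), optimum [1,1] for m = 2 and 1 on the first trait only for
m > 2.  F2 hybrids (500 by default) draw dosages iid 0.25/0.5/0.25 per
fixed locus and are exactly additive in phenotype.  Mismatch is the
perpendicular distance to the line through the *realized* parent
phenotypes (the walk ends near, not at, the optimum), computed as the
norm of the orthogonal-projection residual vector rather than
√(‖u‖²−proj²), which would lose ~8 digits to cancellation for on-axis
hybrids; fully heterozygous hybrids therefore have mismatch 0 to
~1e−16.  For m > 2 the alternative `nonselected_distance` mode returns
the norm over all non-selected trait components.  `simulate_hybridization`
drives walk and cohort from one seeded stream, so one integer
reproduces a whole run.  The excess-heterozygosity–mismatch Spearman
correlation at the default parameters is about −0.17 on average but has
substantial run-to-run spread at 500 hybrids (roughly 8% of runs miss
P < 0.01); in higher dimensions (m = 10) the relation is much stronger
(ρ ≈ −0.5).

## Problem sizes and numerical choices

Simulation studies default to cohorts of 500 fish × 100 loci with 20
replicates per grid point (error study; Monte-Carlo SE < 0.001 on the
mean excess) and 20,000–40,000 fish for selection-strength bisections;
the test suite's null-calibration study uses 100 bundles of four
datasets (2 lab, 2 pond; 100 fish × 40 markers each), sizes chosen so
each study resolves its target quantity with Monte-Carlo error well
inside the tolerance being checked.  The genotyping-error grid spans
[0, 0.10] in steps of 0.005 with common uniforms across the grid, making
the response monotone within replicate; the analytic small-e response is
mean excess ≈ e/2 + (1−e)/(4L).  The Wright–Fisher check of the fixation
formula uses a haploid forward simulator (Binomial(N, p(1+s)/(1+ps)))
at N = 100 with 1e5 runs per cell; at s = 0.05 the diffusion
approximation itself deviates by ~2.5 Monte-Carlo SEs, so tighter
tolerances would test the approximation, not the code.  Pipeline outputs
are stamped with a hash of the analytic configuration (excluding the
output path), and every seeded procedure is bitwise reproducible.

## What the synthetic data do and do not show

The generator reproduces the *statistical* structure the analysis relies
on — pedigree-consistent allele transmission, 1:2:1 segregation,
platform-specific missingness and depth, environment-linked selection —
but not linkage disequilibrium along real chromosomes, segregation
distortion, genotype-calling error modes beyond hom→het conversion,
population structure among founders, or family-size imbalance from
natural mating.  Passing tests therefore demonstrate that the estimators
are unbiased and calibrated under the stated model, and that the
pipeline recovers planted signals of realistic size; they do not
validate robustness to violations the generator does not model.  The
pipeline accepts real genotype tables (TSV or VCF with a pedigree map)
through exactly the same code path.
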