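# Methods

This note documents the models, algorithms and design choices behind
each stage of the pipeline, what the synthetic-data generator does and
does not emulate, and the numerical conventions that make results
reproducible.

## Colony simulator

The pedigree grows year by year from `n_founders` founders (sex ratio
1:1, founder birth years spread over a 4–16-year age range at start,
lifespans drawn uniform on 18–28 years).  Each year
`births_per_year` infants are born at uniformly distributed dates; the
dam is drawn uniformly from females alive and of reproductive age
(default 4 years) at conception, at most one infant per female per
year.  Conception is placed 200/365.25 years before birth — the same
lead the paternity screen uses, so every simulated true sire is by
construction a demographic candidate.

**Reproductive skew.**  Each male carries a lifetime "quality" drawn
from a Gamma(`male_skew`) distribution and sires are drawn with
probability proportional to quality among eligible males.  Normalized
gamma weights are Dirichlet-distributed paternity shares, so
`male_skew` is a concentration parameter: values below 1 (default 0.5)
give the strong polygynous skew typical of macaque colonies.  A
simulated variance test confirms per-male offspring counts are
over-dispersed relative to the multinomial-uniform null.

**Inbreeding avoidance.**  A proposed mating with pedigree relatedness
r ≥ `inbreeding_avoidance_r` (default 0.25) is rejected and the sire
redrawn from the remaining eligible males; if none remains the
simulation fails naming the year.  A hard threshold was chosen over a
graded penalty because the empirical avoidance function in the source
population is unpublished; the parameter is exposed.

**Genotypes.**  Per-locus allele frequencies are symmetric-Dirichlet
(concentration 1.0 over 7 alleles, giving expected homozygosity
(α+1)/(kα+1) = 0.25, i.e. He = 0.75, matching a well-genotyped colony
database).  Founders draw alleles independently; non-founders inherit
one allele per parent uniformly.  The observed table overlays two
processes: each allele is independently replaced by a uniformly random
*different* allele with probability `typing_error_rate` (default 1%),
and each (individual, locus) is typed independently with probability
`mean_typed_loci / n_loci` (default 14.6/21).  Both true and observed
tables are returned so simulation truth is always available to tests.

**What is not emulated:** spatial/group structure, male migration,
age-specific fertility and mortality, genotyping artifacts beyond the
uniform error model (allelic dropout, stutter), and any phenotype.
Passing tests therefore show the *methods* behave correctly under the
stated statistical structure, not that real colony data meet that
structure.

**Determinism.**  Every generator consumes a single `numpy` Generator
seeded with (seed, stage-constant), drawn in documented order; equal
configs give identical outputs.

## Locus diagnostics

Unbiased expected heterozygosity uses Nei's small-sample correction
He = (2n/(2n−1))(1 − Σp²) (disable with `unbiased_he=False`);
PIC = 1 − Σp² − Σ_{i<j} 2p_i²p_j².  The Hardy-Weinberg test is a
Monte-Carlo exact test: pooled alleles are permuted among genotypes
(sampling the null conditional on allele counts, ≥ 10,000 seedable
permutations by default) and a chi-square distance on genotype counts
is the test statistic, with p = (1 + #{T* ≥ T})/(B + 1).  An exact
test was preferred to the asymptotic chi-square because 7-allele loci
have sparse genotype classes at colony sample sizes; the two agree when
counts are large.  Null-allele screening flags loci whose observed
heterozygote count falls more than 3 SD below its binomial expectation
(no estimator is fitted; the flag is a screen).  The typing-error
diagnostic is the fraction of genotyped dam-offspring pairs sharing no
allele at one or more commonly typed loci.

## Paternity assignment

Candidate sires: males at least `min_age_years` old (default 5 — males
of this species are rarely successful sires earlier; the value is a
parameter because no canonical threshold exists) whose census interval
covers birth − 200 days.

Exclusion works per locus from the set of possible paternal alleles
given mother and offspring; loci where mother and offspring share no
allele fall back to duo logic (candidate must share an offspring
allele) and are flagged rather than aborting the trio, since a small
maternal-mismatch rate is expected from typing error.  Candidates
below the common-locus thresholds (12 trio / 15 duo) are *untestable*:
they are reported but take no part in the comparison — the thresholds
gate testability, not guilt.

The LOD score sums per-locus ln likelihood ratios of "candidate is the
sire" against "the sire is a random population male" with a simple
error mixture: each observed genotype is treated as correct with
probability 1−e and as a random Hardy-Weinberg genotype with
probability e, marginalized over all error patterns of the trio (duo).
With e = 0 this reduces to the classical transmission ratio
T(g_o|g_m,g_c)/P(g_o|g_m).  A locus with zero numerator sends the LOD
to a finite large-negative sentinel (−10⁹) for sorting stability.
Observed alleles with zero recorded frequency are floored at the
smallest positive locus frequency and logged.

The confidence simulation mirrors standard practice: offspring are
simulated from random true sires under the user's sampling settings
(candidate count, proportion of sires sampled, typing completeness,
error rate), and the critical Δ is the smallest LOD gap at which the
proportion of correct assignments among assignments made reaches the
requested level (0.80 or 0.95).  The gap is measured against the
runner-up's LOD floored at zero: otherwise a fully excluded runner-up
at the sentinel LOD would make Δ astronomical and meaningless as a
threshold; when every simulated assignment is correct the critical Δ
is 0 (any positive gap qualifies).

The decision rule: a unique zero-mismatch testable candidate is
accepted on exclusion alone when every testable rival mismatches at
≥ 2 loci; when some rival mismatches at exactly one locus the candidate
must additionally carry the top LOD with Δ above the 95% critical
value; anything else is unresolved.  The grandsire cascade applies the
same candidate filter and rule to each assigned parent, using the
parent's own dam as the trio mother, skipping ungenotyped parents with
a recorded reason.

## Relatedness

Kinship is the standard recursion f(x,y) averaged over the parents of
whichever member lies deeper in the pedigree, f(x,x) = ½(1+f(dam,sire)),
memoized; r = 2f with no inbreeding normalization (the screening
thresholds 0.5 and 0.063 are stated on that scale).  Unknown parents
are unique unrelated founders, so every r is a lower bound with respect
to unrecorded ancestry — this is stated here because it bounds decoy
screening from below.  Reported r values round half-up (0.0625 prints
as 0.063; Python's default banker's rounding would print 0.062).

Two-generation unrelatedness requires demonstrably disjoint
{self, parents, grandparents} sets.  Founders count as base
population; a non-founder with an unknown sire is never silently
treated as unrelated — its non-excluded candidate sires stand in for
the missing link, and without candidate information the predicate
returns false so the expected-relatedness path must decide.  Expected
relatedness grafts each candidate sire in turn and averages r with
uniform weights after zeroing candidates whose relatedness to the dam
reaches the avoidance threshold (default 0.25, exposed); candidates
whose grafting would create a cycle are excluded; if every candidate is
zeroed the weights fall back to uniform with a warning.  Both members
of a pair may be unresolved (independent choices, product weights).

## Triad and session design

KD triads are filled by randomized greedy matching with restarts:
candidate parent-offspring dyads per condition, a reuse plan that
selects exactly `target_reuses` fathers (default 5) to serve as targets
in both paternal conditions, then decoy selection per triad (same sex
as the match, age gap ≤ 2 years at photo date, lighting class equal to
the match image, two-generation unrelated to target and match or
expected r < 0.063), ties broken by smallest age gap then lexicographic
id.  With 8 triads per condition and 5 single reuses the design spans
96 − 5 = 91 distinct animals.  Infeasible inventories raise an error
naming the unfillable condition.  ID triads balance 6 male / 6 female
with 3 left- and 3 right-facing three-quarter pairs per sex.

"Interleaved evenly" is formalized as a quarter-quota scheme — the
paper-style session of 32 KD + 12 ID trials is partitioned into four
quarters of 11, each holding two triads of every KD condition and three
ID trials with ID conditions rotated — because no algorithm is given in
the source description; the scheme is deterministic given the seed and
satisfies the printed counts.  The correct side is counterbalanced
exactly 22 left / 22 right (4/4 within each KD condition, rotated 2/1
quotas over ID conditions) rather than coin-flipped, making the balance
testable.  A break marker sits after trial 22, the midpoint of the
44-trial session.  A validator re-checks every triad and schedule
invariant and runs in the test suite on all generated designs.

## Response model and analysis

The generator's latent score is the fixed-effect linear predictor
(treatment coding: maternal/mixed-sex/inexperienced/female/left as
reference levels; trial position z-transformed to mean 0, SD 1 within
session) plus five crossed random intercepts — participant, triad, and
the identities of the target, left and right images, an image receiving
independent effects per role — plus Gaussian residual noise.  Latent
values snap to the nearest grid point and clamp at ±3.5; exact ties
(including 0, equidistant from ±0.5) break upward, so an all-zero
configuration scores +0.5 everywhere.  The scale has no zero point, so
a deterministic tie rule keeps tests reproducible.  Default
coefficients mirror the kin-discrimination fixed-effect table of the
study design this package emulates; default random SDs (0.2–0.3) and
residual SD 1.5 were set once to reproduce rater-level score spread on
the 8-point scale and are documented, not tuned.

`CrossedLMM` maximizes the Gaussian ML log-likelihood with the fixed
effects and residual variance profiled out via the Woodbury identity;
all linear algebra runs on q × q cross-product matrices (q = total
random levels).  The free parameters are relative standard deviations
σ_k/σ on a linear scale with a bound at zero (for the optional
per-participant random slope with correlation, a scaled 2 × 2 Cholesky
factor), optimized derivative-free (Nelder-Mead, objective tolerance
1e−8) from two starts; boundary (zero-variance) solutions are legal,
and at the boundary the estimates coincide with OLS.  A linear-scale,
derivative-free search was chosen after a log-scale quasi-Newton
parametrization proved able to strand variance parameters in the flat
region near zero.  The engine is cross-checked in the tests against
statsmodels MixedLM log-likelihoods and against closed-form balanced
one-way ANOVA ML estimators.

Inference: likelihood-ratio tests between nested ML fits (χ² clamped
at 0, df = parameter difference); Wald intervals from the profiled-ML
covariance; and seeded parametric-bootstrap percentile intervals
(default 1000 draws, warm-started refits) with sign-based p-values —
the package's stand-in for the MCMC-derived intervals that mixed-model
software reports for Gaussian fits.  This is the one intentional
methodological substitution: same estimand, different uncertainty
machinery, approximate equivalence by design.

The staged reduction mirrors the published procedure: test the random
intercept-slope correlation, then the random slope (df = 1 LRTs);
establish overall significance of the full fixed model against a
control-only null; drop nonsignificant interactions highest order
first, then nonsignificant control main effects, retaining primary
effects and any term with p < 0.10 (the "nonsignificant trend"
threshold is fixed at 0.10 because no cutoff is stated); finally refit
with nonsignificant fixed effects excluded to estimate the intercept —
separately per level of a significant grouping factor (e.g. rater
experience), keeping whichever within-group covariates remain
significant.  The trace records, for every dropped term, its estimate
from the last model containing it.  Everything is deterministic given
the data and the bootstrap seed.

Descriptive statistics use scipy: per-participant one-sample t-tests on
the 12 ID scores (zero-variance participants flagged, p undefined),
paired KD-vs-ID and pooled-variance expert-vs-inexperienced t-tests on
per-participant means, Pearson and Spearman correlations.  A paired
test whose differences are identically zero reports t = 0, p = 1
rather than scipy's NaN.

## Problem sizes and tolerances in the test suite

The suite exercises the pipeline at sizes chosen to make each check
informative while keeping a full run in minutes: the shared synthetic
colony has ~870 individuals; gene-dropping oracles use 5–10 × 10⁴
drops and 3-SE bands; paternity recovery uses 500 offspring × 50
candidates at 21 loci with 1% error and a 1000-replicate confidence
simulation; mixed-model parameter recovery uses 20 replicates of 200
participants with Wald 95% intervals (asymptotically equivalent to the
bootstrap at that size, and an order of magnitude cheaper); calibration
checks use 200–1000 null replicates with 3-SE binomial bands.
Bootstrap-based reduction tests use reduced draw counts (60–300); the
1000-draw default is exercised through the API.

## Known limitations

* Pedigree kinship ignores genotype data; no marker-based relatedness
  estimator is provided.
* The likelihood error model is the simple genotype-replacement
  mixture; it is not the allele-level error process the simulator uses,
  which is deliberate (the analysis should not be told the generator's
  truth) but means LOD values are approximations under allele-level
  error.
* The triad builder is randomized greedy with restarts, not a complete
  constraint solver; a satisfiable but extremely tight inventory can
  exhaust its attempts.
* Mixed-model p-values for fixed effects come from LRT/bootstrap, not
  MCMC; exact agreement with MCMC-derived values is not expected.
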