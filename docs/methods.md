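# Methods

## Scope and data model

bcrisk analyses two-stage case-control studies of a small biallelic SNP
panel plus categorical clinical risk factors. Subject data live in a
pandas DataFrame (one row per subject, one minor-allele-dosage column per
SNP, NaN = missing); the panel fixes each marker's minor and risk allele
at definition time so dosage orientation cannot drift between the testing
and validation stages. Clinical categories partition their axes with
half-open intervals — menarche [<15), [15,17), [17,∞) years; first live
birth [<25), [25,∞) — so the groups tile without overlap. All analyses
are complete-case: a subject missing any required variable is dropped
from that analysis (with a logged count), which is why denominators
shrink across downstream tables.

## Exact tests

*Hardy–Weinberg.* The exact conditional test enumerates every attainable
heterozygote count given the sample's allele counts; the two-sided
p-value sums the conditional probabilities of all counts no more probable
than the observed one, capped at 1. It is computed for controls and
reported, not used as an exclusion filter (the threshold is configurable).

*Genotype-by-status tables.* The Fisher–Freeman–Halton test enumerates
all 2×k tables with the observed margins (vectorised over the last two
cells) and sums hypergeometric probabilities no larger than the observed
table's. "No larger" uses a relative tie tolerance of 1e-7 so
floating-point noise cannot split exactly tied tables. Full enumeration
is quadratic in the margins; the ~1,800-subject 2×3 tables here enumerate
in well under a second, which is the intended regime (no network
algorithm is implemented). Pearson's 2-df chi-square is provided as an
alternative; on dense tables the two agree to two significant figures,
and they diverge exactly where expected — sparse minor-homozygote cells.

## Association models

Logistic regression is fitted by IRLS via statsmodels GLM (binomial
family) behind the package's `fit_logistic` surface; the test suite
cross-checks coefficients against an independent hand-rolled IRLS to
1e-6. Separation is flagged when any non-intercept coefficient passes
|β| = 15. CIs are Wald with fixed z = 1.96, matching the 95% convention;
profile-likelihood intervals are not offered. Genetic codings: additive
(dosage), dominant (carrier), recessive (homozygote), genotype (two
indicators vs the major homozygote). The standard adjustment set is age
(continuous), menarche (two indicators, late = reference), menopausal
status (postmenopausal indicator) and first live birth (late indicator).

Stage-1 screening keeps markers with testing-set exact p < α (default
0.05). Stage-2 validation is deliberately the weakest rule consistent
with a verbal "consistent association" criterion: the validation-stage
effect must lie on the same side of OR = 1 as the testing stage, and the
combined-stage adjusted p must be below α. Combined analyses do not
adjust for stage by default (the stages are samples of the same
population here); a stage covariate can be added by the caller. No
multiple-testing correction is applied across the panel, matching the
screening design it reproduces.

## Risk models

The counting model adds risk-allele dosages (0–10 over five SNPs) plus
binary points for early menarche and late first birth (0–12). An ordinal
menarche variant (2/1/0 points) exists behind a flag; the binary coding
is the default because adding at most two clinical points is the reading
that reproduces the published bin structure (0–1…≥6 alleles shifting to
0–2…≥7 factors). The weighted score uses log combined-stage additive ORs
as SNP weights and log adjusted category ORs for clinical factors;
reference categories weigh 0. Quartile grouping uses the
linear-interpolation percentile definition on control scores, with
boundary values assigned upward — fixed and documented since any
convention changes group membership of tied discrete scores. Grouped-OR
analyses adjust for age and menopausal status by default and add
menarche/first-birth only when those factors are *not* already inside the
score, avoiding double adjustment; the full covariate list can be forced.
Empty groups are collapsed into their lower neighbour and logged. The
trend test refits with the group index as one ordinal covariate.

## Absolute risk

Genotype relative risks follow the multiplicative model (1, OR, OR²).
Each factor's risks are renormalised against level frequencies so that
Σ f·r = 1 (asserted to 1e-10); frequencies come from pooled controls,
the only population stand-in a case-control study offers, and can be
overridden with external frequencies. Because every factor averages to 1,
the population-average projected hazard equals the schedule's incidence —
no additional attributable-risk deflation is applied. The combined
relative risk multiplies the per-factor values (independence assumption;
the generator simulates linkage equilibrium, and markers are chosen for
low LD). Relative risk is age-constant. Projection uses the exact
piecewise-constant-hazard closed form over 20–85 by default (per-subject
start ages are an option) and is verified against adaptive quadrature of
the survival integral to 1e-8. High-risk classification thresholds at
k × the cohort median absolute risk.

The bundled hazard schedule is **synthetic**: thirteen 5-year bands with
incidence rising from 3 to ~120 per 100,000 person-years (peaking at ages
55–70) and competing mortality growing roughly exponentially from 40 to
3,400 per 100,000. It has the right shape and scale for an urban
East-Asian registry but fabricated values; absolute-risk outputs under it
are demonstrations, not estimates.

## Discrimination

AUC is computed from midranks (ties count one half), with variance and
the paired comparison from DeLong placement values — the formulation that
handles heavily tied discrete scores correctly. Operating points maximise
Youden's J (sensitivity + specificity − 1), ties broken toward higher
specificity; this is an assumption, since published
sensitivity/specificity pairs rarely state their criterion.
Cross-validated AUC uses stratified folds and pools held-out scores into
a single AUC (lower variance than averaging per-fold AUCs); fold weights
are refit on each training split.

## Synthetic-data generator

The generator draws per-SNP genotypes independently under HWE at
configured MAFs, clinical categories from configured frequencies, and
disease status from a logistic model additive in dosage·log(OR) and
category log-ORs; the intercept is solved by bisection so the marginal
prevalence matches configuration to ~1e-9. Defaults are the published
study conditions: MAFs (0.12, 0.40, 0.26, 0.34, 0.31), per-allele ORs
(1.25, 1.14, 1.08, 1.33, 1.27), control clinical-category frequencies,
and crude clinical ORs derived by cross-product from the published
combined counts (≈3.12 early and ≈1.62 normal menarche vs late; ≈1.87
late first birth) — crude because adjusted clinical ORs were never
printed; all are overridable. Baseline prevalence defaults to 0.05, a
deliberately low documented knob (no population prevalence is stated by
the source study); at low prevalence ORs approximate RRs, consistent with
the multiplicative absolute-risk combination. Case-control ascertainment
samples 878/900 and 914/967 subjects without replacement from disjoint
pools; missingness is injected genotype-wise at a configurable call rate.
Every stochastic operation takes an explicit seed; composite operations
split one seed via `SeedSequence`.

What the generator does *not* emulate: linkage disequilibrium, age- or
cohort-dependent incidence (status is cross-sectional), correlation
between clinical factors and age, family history, and genotyping error
beyond missingness. Tests passing on synthetic data therefore establish
internal consistency of the statistical machinery — parameter recovery,
orderings, calibration — not the field performance of any marker panel.

## Problem sizes and numerical choices

The test suite simulates studies at the published sample sizes (~3,659
subjects) and cohorts of 60,000–200,000 for ordering and AUC checks;
parameter-recovery coverage uses 200 replicate studies. Logistic
convergence follows statsmodels defaults (max 100 IRLS iterations);
exact-test tie tolerance is relative 1e-7; quartile cutpoints use
linear-interpolation percentiles; absolute-risk normalisation is asserted
to 1e-10 and projection to 1e-8 against quadrature. Degenerate inputs
fail loudly: monomorphic SNPs under any genetic coding, all-equal control
scores for quartiles, empty groups, uncovered projection spans,
unattainable prevalence.

## Known limitations

Exact-test enumeration is not margin-scalable beyond a few thousand
subjects per 2×3 table. Wald CIs undercover for very sparse genotype
cells (the published sparse-cell CIs would need profile likelihood or
exact logistic methods). The absolute-risk model inherits the Gail
independence and age-constant-RR assumptions, and control-based
normalisation frequencies approximate the population only when controls
are representative. Validation of markers uses a fixed rule where
published practice is often verbal and judgement-based.
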