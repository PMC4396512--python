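# Methods

## Forward pathway model

The model maps a nine-gene genotype (MYB28, MYB29, MAM1, GSOX1, GSOX3,
AOP2, AOP3, GSOH, ESP; AOP2/AOP3 are alternate alleles of the single AOP
locus, at most one functional) to a deterministic mean leaf GSL profile
in pmol/mm².  It is a rule-based pool model, not a kinetic one: we track
three aliphatic chain-length class pools and let the modification
enzymes redistribute mass within a class.

Parameters (`PathwayParams`), with defaults and rationale:

| parameter | default | meaning |
| --- | --- | --- |
| `base_short3C`, `base_short4C` | 3, 17 | wild-type short-chain pool; their ratio (15:85) is the minor:dominant chain-class split applied whichever class MAM1 makes dominant.  Chosen so the dominant class exceeds the minor by well over the caller's dominance ratio of 2; the source material states only "more 4C than 3C". |
| `base_long` | 2 | wild-type 5–8C pool, split 0.1/0.1/0.2/0.6 over 5MSO–8MSO.  8MSO dominates (the only long structure quantified anywhere); the pool is kept small relative to 4MSO, as in wild-type chromatograms. |
| `myb28_short_mult`, `myb28_long_mult` | 0.55, 0 | fraction retained after myb28 loss.  Calibrated so the myb28 total is 50% of Col-0 and long-chain GSL vanishes entirely. |
| `myb29_short_mult`, `myb29_long_mult` | 0.725, 1 | calibrated so the myb29 total is 75% of Col-0 with no long-chain reduction. |
| `aop_conversion` | 1.0 | AOP2/AOP3 convert their substrate MSO completely; converted-class chromatograms show essentially no precursor left. |
| `gsoh_conversion` | 0.8 | partial: lines with functional AOP2 and GSOH show both but-3-enyl and OH-but-3-enyl, so the hydroxylation is deliberately incomplete. |
| `gsox_conversion` | 0.7 | chamber mode only: a gsox knockout leaves 30% of each short class as MT.  In field mode (`field_mode=True`, the default) MT never accumulates — redundant GSOX family members take over outdoors — which makes the GSOX locus phenotypically invisible in field material. |
| `indole_base` | I3M 3, 4MI3M 0.5, NMI3M 0.5 | passive indole pool; no aliphatic gene touches it. |

Two quantitative statements about the MYB knockouts conflict in the
source literature (a 25–40% short-chain reduction for myb29 versus a 75%
total; 60% short-chain for myb28 versus 50% total).  The totals (50% /
75% / 0) are adopted as the binding calibration because they define the
amount classes used for haplotype calling; the class-level statements
are treated as qualitative.  ESP acts on GSL activation products only
and is carried through the genotype without ever altering the intact
profile.

Conservation property: AOP, GSOH and GSOX conversions move mass within a
chain class, so the total aliphatic amount depends only on the MYB
states — tested explicitly per class.

## Haplotype caller

The caller inverts the forward rules into seven locus calls
(+/−/NA), with the AOP locus carrying a sub-state (AOP2/AOP3/null/NA).
NA means *unobservable due to epistasis*, not missing data:

* a myb28 myb29 double null makes no aliphatic GSL, hiding MAM1, GSOX,
  AOP and GSOH;
* GSOH needs but-3-enyl, which exists only behind a functional AOP2 in a
  4C-dominant (functional MAM1) background — in a 3C background AOP2
  yields allyl, so GSOH stays NA there too;
* ESP is never observable from intact GSL and is reported NA always (it
  is retained in the seven-locus output so frequency code can
  marginalize uniformly);
* GSOX is only observable in chamber-grown material (see above).

Numeric thresholds are artifact choices, since the source describes the
calls only qualitatively: detection limit 0.5 pmol/mm², chain-class
dominance ratio 2, and amount breaks {0.05, 0.625, 0.875} × reference
total — midpoints between the calibrated 0/50%/75%/100% classes.  The
MYB pair is disambiguated by long-chain presence first (absence with
short-chain presence forces myb28−), total-amount class second;
conflicting evidence yields NA rather than a guess.  When no reference
total is supplied the panel's upper-quartile total aliphatic is a
reasonable stand-in (field totals vary by environment); the bundled
default uses the calibrated Col-0 total (22 pmol/mm²).

Round-trip validation runs every laboratory genotype through
`predict_profile` → `call_haplotype` and scores each locus against the
*expected observable state*; all 17 genotypes agree exactly on noise-free
profiles, and ≥95% of locus states survive multiplicative lognormal
noise of CV 0.2 (chamber mode, where GSOX is informative).

## Haplotype frequency test

Single-locus frequencies are estimated from non-NA calls only.  The
linkage-equilibrium null assigns each full multi-locus state the product
of its marginal frequencies; full states are then collapsed through the
epistasis rules onto observable haplotype keys, so NA-keyed haplotypes
receive the summed mass of their expansions and the observable cells
partition the state space (expected counts sum to the panel size).

The global statistic is Pearson's Σ(O−E)²/E over all cells with E > 0,
unobserved cells entering with O = 0.  Because a 144-accession panel
spreads over ~50 observable cells, many expectations are far below 5 and
the asymptotic chi-squared reference (df = cells − 1 − estimated
frequencies) is unreliable; the default mode is therefore Monte-Carlo
(10 000 multinomial resamples, seed required).  Each resample re-fits
the allele frequencies and the induced expectations before computing its
statistic — a parametric bootstrap of the fitted null.  Holding the
frequencies fixed instead (available via a flag) is conservative because
the estimation degrees of freedom are not absorbed; the refit version
calibrates at the nominal level (type-I 0.05 ± 0.02 in the acceptance
suite).  Observed cells that are impossible under the null (E = 0,
O > 0 — typically caller artifacts under noise) are flagged
`infinite_cells` and force rejection in asymptotic mode.

Per-haplotype deviations use a two-sided binomial test per cell against
its null probability, reported raw (used for the over/under
classification, matching how single-haplotype deviations are usually
displayed) and Bonferroni-adjusted.

Power note: a single enriched haplotype is detected far more efficiently
by its own cell's binomial flag than by the omnibus statistic, which
dilutes a one-cell excess over ~50 cells.  Against the known generating
null at n = 144, doubling the commonest haplotype (mass 0.11) is flagged
"over" in >80% of panels, while the omnibus test needs roughly a
four-fold enrichment for comparable power.  Re-fitting marginals from an
enriched panel absorbs part of the excess into the single-locus
frequencies, which is the correct behaviour of the test but lowers its
apparent power against this particular alternative.

## Fitness pipeline

Absolute fitness per plant is TFC × mean silique length × survival
(TFC = fruits + flowers + buds; silique length proxies seeds per fruit).
Including survivorship scores non-survivors 0; excluding it leaves them
missing — the with-survivorship genotype mean can therefore never exceed
the without-survivorship mean.  Relative fitness divides genotype means
by the unweighted mean of genotype means within the environment
(default; values average exactly 1 per environment) or by the Col-0 mean
(reference convention; Col-0 is 1 everywhere).  Both conventions exist
in the literature for this design; the population-mean one is the
default because the rank-fluctuation displays are built on it.  The
"population mean" is the mean over genotype means, not over plants; on
the balanced design the two are nearly identical, and genotype means are
unweighted with missing plants dropped, not imputed.  Mean normalization
multiplies each within-environment genotype mean by (grand mean /
environment mean), is idempotent, and leaves every environment averaging
to the grand mean.  Genetic correlations are Pearson and Spearman over
genotype means within an environment, p from the standard
t-approximation with n = number of genotypes.

## Split-plot mixed model

The trial design nests plots in treatment × environment and randomizes
every genotype once per block, 10 blocks per plot.  The model is

    trait ~ Genotype * Environment * Treatment + (1 | Plot)

with a single plot variance component.  The REML criterion is profiled
over the variance ratio θ = σ²_plot/σ²_resid: given θ, V = I + θZZ′, and
all GLS quantities come from cached cross-products via Woodbury
identities (a q×q solve for q = 12 plots per evaluation), so the
one-dimensional bounded optimization is effectively free.  The fit
matches statsmodels MixedLM to four decimals and is asserted against it
in the test suite.

Fixed terms are tested with Type II sums of squares by full-vs-reduced
GLS comparisons at the estimated θ̂: each term against the model holding
every term that does not contain it (marginality respected).  At θ = 0
the whole table reproduces ordinary Type II OLS ANOVA exactly (oracle
test).  Denominator df follow the containment rule by default:
whole-plot terms (Environment, Treatment, their interaction) are tested
with the plot-stratum df (12 plots − 6 whole-plot parameters = 6), all
others with the residual df; a pure-residual convention is available
because the original analysis does not state its choice.  The random
plot effect is tested by REML likelihood ratio against the plot-free
model on the ½χ²₀ + ½χ²₁ boundary mixture.

LSMeans are equal-weight marginal predictions over the other fixed
factors (equal to arithmetic means on balanced data), with SEs from the
GLS coefficient covariance.  Dunnett many-to-one comparisons get
family-wise p values by simulating the joint normal distribution of the
standardized contrasts (default 10⁵ draws, seeded; Bonferroni fallback);
Tukey all-pairs comparisons use the studentized range with a standard
insert-and-absorb compact letter display.  Survival (0/1) and the 0–10
ordinal damage score are analyzed as numeric responses, as the original
model formula implies; this is a documented approximation, not an
endorsement — a GLMM would be the cleaner choice for survival.

Precision limit: with only 12 plots the plot-variance ratio carries ~6
degrees of freedom, so a single trial estimates it with ~40% median
relative error no matter the estimator.  The parameter-recovery check
therefore verifies the estimator's centering (the median estimate across
~200 simulated trials lands within ±30% of planted ratios 0.1/0.5/1.0,
measured errors 3–12%), not single-replicate precision.

## PCA concordance

Covariance (centered, unscaled) PCA on the reference environment's
genotype-mean profiles — all structures share pmol/mm² units, so scaling
is off by default but available.  Four components are retained by
default (the published table reports four; a three-component option
exists).  Signs are fixed by making each loading's largest-magnitude
element positive, making results bit-stable across runs and row
orderings.  Projection centers each dataset by its own column means —
scores are generated independently per environment, so an
environment-wide level shift does not move the scores; concordance is
the per-component Pearson correlation between reference and environment
scores.  On the calibrated noise-free field-mode means of the 17
genotypes the top four components carry 99.90% of the variance; chamber
mode adds MT structure columns for the gsox knockouts and drops this to
~97%, which is the honest price of the extra dimension.

## Synthetic data

`generate_trial` builds the full 2 040-plant layout and simulates:
log-scale TFC (fitness is non-negative and right-skewed) with additive
genotype/environment/treatment/G×E/plot/residual effects, normal silique
length, Bernoulli survival with per-G×E logit offsets, leaf damage from
a latent normal rounded into the 11 ordinal bins, flowering time, and
GSL columns = forward-model means × per-environment scale × lognormal
noise (CV 0.2).  Non-survivors carry missing TFC/silique/GSL.  Default
effect SDs (e.g. leaf damage: genotype 0.5, environment 0.8, G×E 0.6,
plot 0.3, residual 1.2) are assumptions chosen so that the qualitative
pattern of the real trials emerges — strong genotype and
genotype-by-environment effects, weak treatment effect — not estimates
of the original data, which are unavailable.  `generate_accession_panel`
draws haplotypes from per-locus frequencies (AOP three-state), optionally
enriched for chosen haplotypes before renormalization, and expands them
through the forward model; a truth table is emitted alongside.  All
randomness flows from one integer seed; identical seeds give
byte-identical tables.

What the generators do *not* emulate: spatial autocorrelation within
plots, herbivore dynamics, climate covariates, measurement error in
silique images, and any linkage disequilibrium between loci.  Passing
tests therefore demonstrate correctness of the estimators under the
stated generating model, and calibrated behaviour at the stated design
sizes — not that real field data would satisfy the same effect sizes.

## Problem sizes used in the checks

Type-I calibration: 500 pure-noise trials at the full design for the
fixed-effect F test; 1 000 panels of n = 144 with 400-resample
Monte-Carlo p values for the frequency test.  Parameter recovery: ~200
trials (67 per planted ratio).  Caller robustness: 500 noisy profiles.
Power demonstrations: 40–50 replicates each, with planted effects stated
in the test docstrings.  The full suite runs in a few minutes on one
CPU.
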