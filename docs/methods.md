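# Methods

## The problem

Whole-blood qPCR miRNA panels quantify expression as a quantification cycle
(Cq): the PCR cycle at which fluorescence crosses threshold, so *lower* Cq
means *higher* expression. Nano-volume instruments cannot call expression
below a detection limit — here 27 cycles — and in population panels many
miRNAs are undetected in a large share of participants. Associating such
left-truncated-by-design measurements with a quantitative phenotype (hand
grip strength, kg, a standard healthy-aging measure) therefore needs a model
that uses both the detected values and the detection pattern itself, while
respecting the family clustering of community cohorts.

## The two-part adaptive test

For each miRNA, define the undetected indicator

    X = 1 if Cq > 27 (or the reaction never crossed threshold), 0 otherwise.

The boundary is deliberately strict: a Cq of exactly 27.0 counts as
detected. (Assay documentation often phrases the limit as "27 or higher";
the indicator above follows the explicit formula convention, and the
threshold is a parameter — `CqMatrix.threshold` and the `--threshold` CLI
flag — so the other convention is one number away.)

Two linear mixed models are fitted, each with a random intercept per family:

* **model 1** (everyone assayed):      grip ~ X + covariates
* **model 2** (detected subset, X=0):  grip ~ Cq + covariates

with covariates sex, age, height, BMI and the technical assay variables
(RNA concentration, 260/280 ratio, RNA quality), all entered untransformed.
The focal Cq is centred within the detected subset — a pure numerical
conditioning step that changes neither the coefficient nor its p-value.

Each miRNA is routed by its detected fraction d among assayed samples:

| detected fraction          | branch          | adaptive p              |
|----------------------------|-----------------|-------------------------|
| detected count < 5% of cohort | ineligible   | none (excluded)         |
| d < 0.10                   | binary_only     | p from model 1          |
| 0.10 <= d < 0.90           | combined        | chi2(2) tail of W1 + W2 |
| d >= 0.90                  | continuous_only | p from model 2          |

where W_i = (beta_i / se_i)^2 is each model's Wald chi-square. In the
combined branch the statistics are recovered from the reported p-values by
inverting the chi-square(1) upper tail, summed, and referred to the
chi-square(2) upper tail. The eligibility floor is an absolute detected
count, ceil(0.05 x full cohort size), so partially assayed miRNAs are held
to the same evidence standard as fully assayed ones. The 90% boundary is
inclusive (d = 0.90 exactly uses the continuous model alone).

Wald statistics are used as the per-model component because beta, SE and p
are the quantities the per-model fits report; a likelihood-ratio variant
would need each model refitted under the null and was not adopted. When a
combined-branch miRNA has only one fittable model (e.g. the detected subset
is too small for a stable continuous fit), the available single-model p is
used and a warning logged, rather than discarding the miRNA.

Because higher Cq means lower expression, a *negative* beta — on Cq or on
the undetected indicator — denotes a *positive* association between miRNA
expression and grip strength.

### Sex-stratified and cell-count-adjusted runs

miRNAs detected in >= 90% of samples are additionally analysed separately in
men and women, with sex removed from the covariate list (a constant column
would make the stratified design singular); strata below 50 participants are
skipped with a warning. Secondary analyses adjust for blood cell counts
(RBC, WBC, platelets, differential percentages) through the identical code
path with an extended covariate list; counts measured in only part of a
cohort are completed by partial least squares regression on the expression
matrix, with the number of latent components chosen to minimise 10-fold
cross-validated RMSE and measured values passed through unchanged.

## Mixed-model estimation

The random-intercept model y = Xb + Zu + e, u_g ~ N(0, s_f^2),
e ~ N(0, s_e^2 I) is fitted by restricted maximum likelihood with the
variance ratio lambda = s_f^2/s_e^2 profiled out: for fixed lambda, GLS
reduces to per-family partial demeaning (y - c_g * mean_g with
c_g = 1 - (1 + lambda n_g)^(-1/2)), and both b and s_e^2 have closed forms.
The one-dimensional REML criterion is minimised over log(lambda) in
[-15, 10] by bounded scalar search (absolute tolerance 1e-10); the lower
bound doubles as the lambda -> 0 (OLS) boundary. This solver is exact for
the single-random-intercept structure and fast enough for the tens of
thousands of fits the permutation calibration needs; the test suite verifies
it against statsmodels' general MixedLM to ~1e-3 relative on coefficients,
SEs and variance components. Degenerate inputs are handled explicitly: a
constant response or a non-positive SE returns a non-converged fit (excluded
from FDR with a warning); a rank-deficient design raises.

The family random intercept stands in for full pedigree/kinship structure:
at the cohort sizes simulated here a shared intercept captures the dominant
within-family correlation, and kinship matrices are out of scope.

## Multiple testing and permutation calibration

q-values are Benjamini-Hochberg step-up, computed in the literal form
q_(i) = min_{j>=i} p_(j) m / j over the ascending order statistics, across
all eligible miRNAs jointly regardless of branch. Threshold summaries
("N (x%) had FDR q value < t") use strict inequality at t in
{0.10, 0.05, 0.01, 0.001}.

The calibration separates the miRNA matrix from the clinical block — grip,
all covariates *and the family ID* travel under one shared permutation, so
the random-effect grouping stays attached to the phenotype — and reruns the
entire two-part analysis on each permuted replicate (default 100). Pooled
adaptive p-values are summarised by the empirical fraction below 0.05 and
0.01 and a Kolmogorov-Smirnov test against Uniform(0,1). Replicates that
fail are skipped and logged; more than 10% failures aborts the run.

## Coexpression and enrichment

For a selected miRNA list (default: the 15 with smallest q, ties broken by
adaptive p then name), each gene's expression is regressed on centred
detected Cq with the same covariates and family intercept; q-values are
computed across all pairs of the run and pairs with q < 0.05 are selected.
Selected pairs are annotated against a two-column (miRNA, gene)
target-prediction table and against gene signatures (overlapping pairs and
unique gene counts). A complementary selector returns significant miRNAs
whose governing beta is strictly positive, i.e. expression *negatively*
associated with grip.

Over-representation of the selected unique genes in gene sets (GMT) uses the
one-sided hypergeometric upper tail at the observed overlap, with

    ratio_of_enrichment = observed overlap / (|selected| x |set ∩ universe| / |universe|),

BH across sets, and results sorted by p. The universe defaults to all genes
on the expression matrix; sets are intersected with the universe first and
selected genes outside it are dropped with a warning. The same machinery
serves user-supplied pathway lists (deduplicated before counting).

## The synthetic cohort generator

Individual-level data of the target kind are access-restricted, so the
pipeline ships a generator whose defaults emulate the published marginals of
a large two-generation community sample:

| parameter | default | unit | rationale |
|---|---|---|---|
| n_participants / n_families | 5668 / 1900 | – | cohort size; ~3 per family |
| prop_women | 0.54 | – | cohort sex split |
| age | N(55.7, 13.2) truncated to [24, 90] | years | cohort age structure |
| height (M/W) | N(69.3, 2.67) / N(63.9, 2.5) | inch | sex-specific marginals |
| BMI (M/W) | N(29.0, 4.9) / N(27.3, 6.1) | kg m^-2 | sex-specific marginals |
| grip intercept (M/W) | 44.7 / 26.5 | kg | sex-stratified means |
| grip age slope (M/W) | -0.35 / -0.18 | kg/yr | decline at mean age, by eye to the published shape |
| grip age quadratic | -0.003 | kg/yr^2 | accelerating decline |
| height / BMI effects | 0.4 / 0.10 | kg/inch, kg per kg m^-2 | modest anthropometric terms |
| family SD | 3.0 | kg | within-family clustering |
| residual SD (M/W) | 7.95 / 4.15 | kg | closes the variance budget (below) |
| detection threshold | 27 | cycles | instrument limit |
| latent Cq | N(mu_m, 2.0) | cycles | per-miRNA location |

Grip is generated as sex intercept + age trend + anthropometric terms +
planted miRNA effects + family intercept + residual, floored at 0 kg. The
age terms are centred at the age mean and corrected for E[(age-mean)^2], and
height/BMI are centred at their sex means, so the intercepts *are* the
expected sex-stratified means. Planted miRNA contributions (continuous
effects on centred detected Cq; binary effects on the centred undetected
indicator) are mean-zero by construction. The residual SDs were set last, by
subtracting every other component's variance (including the default planted
panel's ~6.3 kg^2) from the target totals of 10.0^2 (men) and 6.3^2 (women)
— which is why the slope and residual SD are (men, women) pairs: no shared
scalar can satisfy both sex-specific SD targets at once. Scalar values are
still accepted everywhere a pair is.

Censoring is generative: each miRNA's latent Cq is Gaussian with the mean
location-shifted so P(latent <= 27) equals the spec'd detection fraction
(mu = 27 - sd * Phi^-1(f); at f = 0 or 1 the mean is pushed 8 SD beyond the
limit); latent values above the limit are recorded as undetected ("ND" on
disk, +inf in memory), a distinct state from not-assayed (empty cell / NaN),
which marks a random 1 - assay_fraction share of participants and is
excluded from both models. The default panel has 299 miRNAs with detection
fractions following a right-skewed grid from ~1% to 100%, ~30% non-null
(continuous betas -0.10 to -0.30 kg/Cq, a sparse positive minority, binary
effects of -1 kg on low-detection assays), and every 25th assay covering
only 26% of the cohort.

mRNA blocks are generated per miRNA as gene = r z + sqrt(1-r^2) noise, where
z is the standardised detected Cq (zero elsewhere), so the gene-miRNA
correlation among detected samples equals the declared r; independent null
genes pad the matrix. Fixture builders emit gene sets with one deliberately
enriched set, prediction tables covering half of each block plus decoys, and
a signature list overlapping the blocks.

What the generator does **not** model — and hence what passing tests do not
establish about real data: covariates are mutually independent (no
height-BMI or age-BMI correlation); families are unstructured labels (no
pedigree, kinship or shared environment beyond one intercept); technical
covariates are pure noise unrelated to Cq (they exercise the adjustment code
path, not assay physics); the latent Cq is Gaussian and homoscedastic; and
mRNA blocks are disjoint across miRNAs. Results on real cohorts additionally
depend on all of those features.

## Validation problem sizes

The acceptance-style checks run at sizes chosen to give the binomial and
Monte-Carlo bands stated in each test reasonable width: 1000 random pairs
for the combination oracle (agreement to 1e-10 relative); 100 permutation
replicates of a 50-miRNA, n=1000 cohort with planted effects (pooled
fraction of p < 0.05 within [0.04, 0.06], KS at alpha = 0.01); 200 cohorts
of n=2000 for recovery of a planted -0.20 kg/Cq effect (mean within 0.05,
CI coverage in [0.92, 0.98]); 200 cohorts of 30 miRNAs with 10% non-null at
-0.3 for FDR control (mean realised FDP <= 0.075); one 20-gene
correlation-0.5 block against 500 null genes at n=2000 for coexpression
recovery (>= 16/20 at q < 0.05); 100 seeded fixture collections for
enrichment ranking (planted set first by p in >= 95); and two full demo
pipeline runs for byte-level determinism. The demo pipeline itself uses
n=2000, 40 miRNAs and small coexpression blocks so a complete run finishes
in about two minutes on one core.

## Known limitations

The combined branch assumes the two Wald statistics are independent under
the null; model 1 and model 2 use overlapping participants, so the chi2(2)
reference is an approximation whose adequacy is checked empirically by the
permutation calibration rather than proven. The continuous model requires at
least 30 detected participants; binary fits require both classes present.
Non-converged fits are excluded from FDR, which slightly changes the
interrogated count relative to the eligible count. BH assumes positive
regression dependence across miRNAs; permutation-based FDR and Storey-type
estimators are deliberately out of scope, as are generalized mixed models,
longitudinal designs and kinship-aware covariance.
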