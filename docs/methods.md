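# Methods

## Problem setting

In tumor-informed liquid-biopsy monitoring, a patient's baseline tumor
tissue defines a personal set of somatic mutations (the *tracking set*),
and serial plasma draws are then searched for those mutations in cell-free
DNA. Three questions drive the analysis: is circulating tumor DNA (ctDNA)
present in a given plasma sample at all; is the mutation burden rising over
time (molecular progression) ahead of radiographic progression; and does
ctDNA positivity during treatment stratify progression-free survival (PFS)?
This package implements that full chain for targeted-panel variant-call
tables, with a synthetic cohort generator that supplies ground-truth labels
for every stage.

## Tracking-set construction

Tissue (FFPE) variant calls pass four post-call criteria before seeding the
tracking set:

1. position outside the repetitive-region mask;
2. not predicted germline by the classifier below;
3. ExAC-role population allele frequency < 1% (the ExAC table specifically,
   not the maximum over databases);
4. allele frequency strictly > 5%, relaxed to strictly > 3% for whitelist
   hotspot mutations.

Both AF thresholds are strict: a variant at exactly 5% (or a hotspot at
exactly 3%) fails. All four criteria are evaluated for every variant so the
emitted failure sets are complete rather than short-circuited, which makes
the per-variant report auditable and order-independent. Synonymous variants
are retained by default (`include_synonymous=True`); both synonymous and
non-synonymous somatic variants carry signal for presence testing.

## Germline vs somatic without a matched normal

Plasma-only and tumor-only calling cannot observe the constitutional
genome, so germline polymorphisms are removed by a logistic score over two
feature families: database evidence (maximum population AF across
ExAC/dbSNP/1000G-role tables, number of databases containing the variant,
COSMIC/TCGA-role somatic evidence count) and allele-frequency geometry
(observed AF, |AF - 0.5|, |AF - 1.0|). There is deliberately no hard AF
cut-off: a variant at 25% AF with no database record stays somatic, and a
hotspot (whitelist) variant is never classified germline on AF evidence
alone — the whitelist override precedes scoring. After fitting, the
coefficient on max population AF is clamped non-negative (and the somatic
evidence coefficient non-positive), guaranteeing the monotonicity property
that increasing a variant's population frequency can never flip it from
germline to somatic. The decision threshold defaults to 0.5 on the
germline probability and is configurable.

The score is trained on labeled variants; in the synthetic pipeline the
labels come from the generator's ground truth. Held-out concordance on the
default cohort is >= 0.90 (the documented floor asserted by the test
suite); typical values are higher. The residual errors are the realistic
ones: rare germline variants absent from every database, and somatic
variants whose AF drifts near 0.5.

## ctDNA presence: Monte Carlo empirical p-value

For one plasma sample with tracking set size n, the observed statistic is
the mean AF of the n tracked variants, where a tracked variant not called
in the sample contributes AF 0 — n stays fixed rather than shrinking, so a
patient whose variants fall below callability is pulled toward the null
instead of being evaluated on a cherry-picked subset. The null pool is the
same sample's *background allele alterations*: calls at non-tracked
positions, dominated by sequencing error. Germline-predicted calls are
removed before the test; otherwise constitutional heterozygous sites
(AF ~ 0.5) inflate the null tail and destroy power. Each of 10,000
iterations draws n distinct background alterations and records their mean
AF; the empirical p-value is

    p = (1 + #{iteration means >= observed mean}) / (iterations + 1).

Ties count toward the tail and the add-one smoothing keeps p strictly
positive (finite on log-scale plots). A sample is ctDNA-positive iff
p < alpha with alpha = 0.01, strict. With an empty tracking set or a
background pool smaller than n the result is *indeterminate*, never coerced
to negative; sampling with replacement is available as an explicit opt-in
fallback for tiny pools.

Sampling without replacement is vectorized two ways with identical
semantics: rejection sampling of index tuples when n is small relative to
the pool (the common case: n ~ 6 against hundreds of alterations), and
per-row top-n selection of uniform keys otherwise. `enumerate_tail` /
`exhaustive_pvalue` enumerate every n-subset exactly and serve as the
independent oracle in tests; note the +1/+1 smoothing acts on the subset
count there and on the iteration count in the Monte Carlo version, so the
two smoothed values converge only when the subset count is large — the
oracle comparisons therefore either use the raw tail fraction or instances
with >= ~1000 subsets.

Because the background pool conditions on >= 1 alternate read while absent
tracked variants contribute zeros, the test is conservative under the null:
the measured false-positive rate at alpha = 0.01 is far below 0.01 (the
acceptance run reports it). When tracked AFs are instead drawn from the
alteration pool itself, the p-value is approximately uniform, which the
property suite checks directly.

## Total ctDNA and molecular progression

Total ctDNA level is reported in mutated genome equivalents (mGE): the sum
of detected variant AFs times the number of haploid genome equivalents in
the cfDNA input, using 3.3 pg (0.0033 ng) per haploid genome; e.g. one
variant at 10% AF in 33 ng of input is 0.10 x 33/0.0033 = 1000 mGE. The
constant and formula are config-overridable. The level is additive over
variants and linear in input mass.

Molecular progression is called when a tracked variant's AF rises strictly
in k consecutive inter-sample steps (default k = 2; a single noisy uptick
is not a trend, and the canonical two-rise trajectories motivate the
default), with the run starting at a value no lower than the subject's
baseline — a recovery from a mid-course dip that stays below baseline is
not progression. Ties break the run. The call lands on the day of the
sample completing the k-th rise, so it is invariant to later samples. The
default `any_variant` rule calls on the earliest variant to complete a
qualifying run; a `mean_af` rule applying the same test to the per-sample
mean over tracked variants is provided because the per-variant vs summary
reading of "consecutive increases" is genuinely ambiguous. Lead time is
first radiographic PD day minus call day, reported signed (negative when
radiology saw it first) and None when either side is missing.

## Survival analysis

PFS runs from diagnosis (day 0) to the first RECIST PD or death of any
cause, censored at the last imaging assessment otherwise. The stratifier is
ctDNA status at the first (primary) or last (sensitivity) determinate
post-treatment plasma sample, where post-treatment means strictly after the
recorded treatment start day; indeterminate detections are skipped.
Kaplan-Meier curves, the two-group log-rank test and the univariate Cox
model are delegated to lifelines. Cox uses Efron tie handling (times are at
day resolution, so ties are common) with Wald CIs on the log-HR scale;
categorical covariates with more than two levels are dummy-coded against a
stated reference with per-level HRs and a global likelihood-ratio p-value.
Non-convergence and monotone likelihood (complete separation) return a
flagged result rather than silent numbers. The KM median uses the smallest
t with S(t) <= 0.5 (with a 1e-9 epsilon absorbing log-space round-off in
the product-limit computation).

## Synthetic cohort generator

The generator is first-class, tested code, and its defaults are the study
conditions the rest of the package is validated under: 71 subjects; 2-18
plasma draws per subject (Poisson mean 6, one draw per 21-day cycle with
+/-3-day jitter, baseline at day 0, treatment starting day 1); mean
de-duplicated depth 2779 (plasma) and 1116 (tissue), CV 0.1; on average six
true somatic variants per subject; ~8 germline polymorphisms per subject at
AF near 0.5 (het) or 1.0 (hom), ~95% of them catalogued in at least one
population table at AF >= 0.01.

Specific modeling choices, none of which are claims about any particular
dataset:

- **Panel.** 2000 assayed positions spread over 20 recurrently mutated
  lung-cancer genes with fixed ref/alt alleles; ~2% of positions sit in
  repetitive-region mask blocks. This is a tractable stand-in for a
  ~197-gene hybrid-capture panel: large enough that each plasma sample
  yields hundreds of background alterations for the null pool.
- **Background error.** Per-position error rate ~ Beta(mean 1e-4,
  concentration 2e4), alt count ~ Binomial(depth, rate) — i.e.
  beta-binomial, overdispersed relative to pure binomial as empirical NGS
  background is. The distributional form is a modeling stand-in; nothing
  downstream depends on it beyond overdispersion.
- **Clonality and tissue AFs.** Per-variant clonal fraction c ~
  Beta(1.3, 4.5), mapped affinely onto tissue AF in [0.034, 0.86] (mean
  ~0.22). The same c scales the variant's plasma signal, so tissue AF and
  plasma AF share per-variant structure and tissue-plasma concordance
  emerges rather than being hard-coded.
- **Tumor-fraction trajectories.** Piecewise exponential per arm: 60% of
  subjects are progressors whose tumor fraction declines at 0.03/day until
  a resistance onset day ~ U(30, 150) (recorded as the true molecular
  progression day) and then grows at 0.025/day; responders decline
  throughout. Baseline tumor fraction ~ lognormal(ln 0.01, 1.5), capped at
  0.35. A plasma somatic call's expected AF is c x TF(day) + error, sampled
  binomially in depth; only positions with >= 1 alt read are emitted.
- **Survival link.** A subject is *ctDNA-bearing* when TF at the first
  post-treatment draw is >= 0.003 — about where the detector's power curve
  rises steeply under the default error model, making the label an
  operational definition of "shedding above background" rather than an
  arbitrary dial. PFS is exponential with baseline median 270 days
  (ctDNA-negative), hazard multiplied by hazard_ratio_true = 2.3 for
  bearing subjects. Censoring uses a per-subject censoring hazard
  proportional to the event hazard, giving exactly the configured 35%
  censoring probability per subject (conditionally independent censoring
  given the group, valid for Cox). 10% of events are deaths without
  radiographic PD. Imaging occurs every 63 days with PD appended at the
  event day.
- **FFPE artifacts.** Each subject's tissue table also carries (with
  probability 0.7 each) one masked-region call and one low-AF (3.1-5%)
  call, labeled `background` in the ground truth, so the post-call filters
  are exercised on realistic failures.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: position-specific error profiles and stereotyped
error suppression, GC/coverage bias, clonal evolution (clonal fractions are
constant over time), CNVs/fusions, contamination, inter-assay batch
effects, and informative censoring. Recovery results on synthetic cohorts
demonstrate that the statistical machinery is correct under the stated
model, not that the assay performs at any particular sensitivity in
patients.

## Determinism and numerical conventions

Every stochastic component takes a seed or Generator. The pipeline derives
stage seeds from a master seed via `numpy.random.SeedSequence` children
(stage index, then sorted sample index), so identical configs produce
byte-identical output trees (the run manifest records seeds and SHA-256
checksums, never timestamps). Degenerate inputs have defined behavior:
empty tracking set -> indeterminate; background smaller than n ->
indeterminate (opt-in replacement sampling); zero events in both log-rank
groups -> (0, 1) with a warning; constant Cox covariate -> error. Problem
sizes in the test and acceptance runs (2000 null samples at 2000-10,000
iterations; 100 Cox replicate cohorts; 500 log-rank replicates) are the
package's chosen validation scales, with Monte Carlo tolerances stated as
multiples of the corresponding standard errors.
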