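# Methods

## Model and procedure

`crossdep` quantifies, per gene, the association between two sample-aligned
variables by median dichotomization rather than by correlation. Given a
gene's log2 expression vector and its gene-level efficacy vector (shRNA
knockdown or sgRNA knockout "gene effect" score) over the same samples:

1. Samples missing in either vector are dropped *for that gene only*, so
   each gene uses all samples with complete pairs.
2. **Predictivity** splits the samples at the median expression — strictly
   greater than the median goes to the high group, ties and below go low —
   and reports the difference of mean efficacy, high minus low.
3. **Descriptivity** splits at the median efficacy (numeric ordering of the
   dependency score) and reports the difference of mean expression.
4. Each score gets a two-sided two-sample t-test comparing the same two
   groups. The default is Student's pooled-variance test
   (df = n₁ + n₂ − 2); Welch's unequal-variance test is available via
   `variant="welch"` because some tools default to it.
5. A gene is a **hit** when both p-values pass their thresholds and the two
   scores share a nonzero sign. Dual significance with discordant signs is
   excluded by default and can be reported separately
   (`require_sign_concordance=False`).

Because all inputs are log2-scale, a difference of group means is a log
fold change; no ratio is ever formed. The two scores are deliberately
asymmetric: predictivity asks whether expression strata separate the
phenotype (the biomarker question), descriptivity whether phenotype strata
separate expression (the specificity question).

The patient-cohort variant substitutes relapse-free survival (RFS) days for
efficacy. Predictivity contrasts mean alive days between high/low
expression patients; descriptivity contrasts expression between long- and
short-surviving patients (RFS above vs at/below the median). These scores
use the raw, post-truncation RFS days and deliberately ignore the censoring
indicator — they are mean-difference statistics, not survival-model
estimates. The event-aware complement runs alongside: for every gene, a
Kaplan–Meier estimate and a log-rank test compare the same median-split
expression groups using the event indicator.

## Clinical derivation

RFS days = the earliest of *days to new tumor event* and *days to death*;
if neither is present, the patient is censored at *days to last follow-up*;
rows with none of the three are rejected with a reason. *Vital status* and
*pathologic stage* are parsed and carried as metadata but enter no
computation.

Cohort selection keeps only patients whose five-year status is fully
ascertained, with the window fixed at 1825 days (365 × 5, the conventional
reading of "five years"): events at ≤ 1825 days are kept as events;
patients followed past the window without an event inside it are kept,
administratively censored at day 1825. A patient whose first event falls
*after* the window is event-free at five years and is therefore also kept
as window-censored — the selection rule is about ascertainment, not about
discarding long survivors. Patients censored before the window are dropped
as unascertainable.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `alpha_pred`, `alpha_desc` | 0.01 / 0.01 (cells), 0.01 / 0.05 (survival) | raw per-axis significance thresholds for the hit call |
| `max_missing_frac` | 0.5 | efficacy genes missing in strictly more than this fraction of samples are removed; the boundary is kept |
| `variant` | `student` | t-test flavour; `welch` for unequal variances |
| `window_days` | 1825 | five-year ascertainment window, days |
| top-efficacy cutoff | −1.5 (knockdown), −2 (knockout) | strict thresholds on per-gene mean efficacy for "strongly depleting" summaries |

No multiple-testing correction enters the default hit call — the thresholds
are raw p-values, which is the convention this analysis style uses — but the
output tables carry Benjamini–Hochberg q-value columns (`q_pred`, `q_desc`)
computed over the non-degenerate genes so users can apply FDR control.

## Numerical choices and degenerate inputs

* Median convention: midpoint of the two central order statistics for even
  counts; for odd counts the central value itself, which the "≤ goes low"
  rule assigns to the low group. A consequence worth knowing: negating the
  split variable flips the two groups exactly only for even counts.
* Minimum group size is 2 on both sides of every split; smaller groups give
  `status=insufficient_group` and NaN scores rather than an undefined
  variance. A constant split variable leaves the high group empty:
  `degenerate_expression` / `degenerate_efficacy`.
* If both contrasted groups have zero variance, the t-test degenerates:
  equal means → (t = 0, p = 1); unequal means → (±∞, p = 0). A constant
  *contrast* variable thus yields score 0, p 1.
* Missing values are NaN throughout; generators never emit NaN except as
  the declared missing marker.
* Log-rank ties use the simultaneous-event convention with the standard
  hypergeometric variance; with zero events the test is undefined and
  reported as NaN.
* Output tables are written with pandas' round-tripping float repr, so a
  write/read cycle reproduces values exactly and reruns with the same
  configuration are byte-identical (provenance sidecars record version,
  config hash and seed, never timestamps).

Standard statistical components are delegated: t-tests to
`scipy.stats.ttest_ind`, Kaplan–Meier and log-rank to `lifelines`,
Benjamini–Hochberg to `statsmodels`, Pearson correlation to `scipy`. The
test suite checks each against independently coded closed forms
(pooled-variance formula, hand product-limit, observed-minus-expected
accumulation), keeping implementation and oracle on separate routes.

## Synthetic data

`simulate_paired_panel` draws gene g's log2 expression as
Normal(μ_g, `expr_sd`) with μ_g uniform on `expr_mu_range` (default 2–8, a
plausible log2 abundance range), and efficacy as
Normal(`eff_mu`, `eff_sd`) plus, for planted genes, ± `beta` × the gene's
standardized expression. Missing entries are planted uniformly at
`missing_rate` in the efficacy matrix only, mirroring screens where the
perturbation data, not the RNA-seq, carry the gaps. Defaults (2000 genes ×
40 samples, 25 + 25 planted genes, β = 1.5 per SD against unit noise, 10%
missing) describe a desk-scale screen with moderately strong biomarkers.
Effects are planted on the efficacy side conditional on expression, making
predictivity the "correct-direction" statistic.

`simulate_survival_cohort` reuses the expression model and draws event
times exponentially with patient rate
`baseline_rate · exp(log_hazard_ratio · Σ z_g)` over the planted prognostic
genes, with independent uniform censoring on [0, `censor_window`] days.
Defaults: 200 patients, hazard ratio 2 per SD for one planted gene,
baseline rate 1/2000 per day (median event time ≈ 3.8 years for an average
patient) and a 10-year censoring window, so roughly two-thirds of selected
patients have observed events — a plausible relapse profile for an
aggressive-disease cohort. Each patient is emitted as raw clinical fields
(an observed event becomes a new-tumor-event day or, for 30% of events, a
death day) and re-parsed through the RFS derivation, so the full clinical
path is exercised.

Randomness is counter-based: gene g draws from `default_rng([seed, stream,
g])`, so subsetting genes never reshuffles the remainder.

What the generators do **not** emulate: gene–gene expression covariance
(real co-expression modules inflate the effective number of tests less than
independent genes do), screen-specific artefacts (off-target shRNA effects,
copy-number bias in CRISPR scores), platform batch structure, or
non-exponential hazards. Passing the planted-recovery and calibration tests
therefore demonstrates correctness of the statistics under the stated
model, not robustness to those real-data pathologies.

## Verification scales

The test suite and `scripts/acceptance.py` run at sizes chosen to make the
checks statistically meaningful while staying desk-scale: 100 random
50-gene panels (12–20 samples) for brute-force agreement, a 10,000-gene ×
40-sample null panel for calibration (Kolmogorov–Smirnov uniformity of
predictivity p-values plus a ≤ 1% dual-significance hit rate), 20
replicates of the 2000-gene planted panel for recovery, and 100 cohort
replicates at n = 200 for survival power.

## Known limitations

* Median dichotomization discards within-group ordering; genes with strong
  monotone but range-compressed associations can score low. The package
  intentionally offers no correlation-based alternative ranking beyond the
  diagnostic cross-platform summary.
* The survival scores treat truncated censored times as observed alive
  days; cohorts with heavy early censoring would bias them (the cohort
  selection removes exactly those patients, which is why it precedes the
  scan).
* Gene identity is the full `"SYMBOL (ENTREZID)"` string; cross-release
  symbol drift must be resolved upstream. A symbol-only accessor exists but
  matching on it is the caller's explicit choice.
* Reagent-level inputs are supported only through unweighted mean
  aggregation to gene level (`aggregate_reagents`); no reagent-quality
  weighting is attempted.
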