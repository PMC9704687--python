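# Methods

## The linking problem

Two self-report depression instruments — a six-item legacy subscale (BSI
Depression, 5-point bother ratings coded 0–4, raw sum 0–24) and an anchor
scale from the PROMIS Depression item bank (5-point frequency ratings,
reported as T scores with mean 50 and SD 10 in the US general population) —
measure closely related constructs. A *crosswalk* maps each legacy raw
summed score to the T score most probable for respondents with that raw
score, so that studies using only the legacy scale can be expressed on the
anchor metric. `scorelink` implements the full workflow: fixed-parameter
calibration, crosswalk construction, pattern scoring, and the agreement
battery used to judge whether a crosswalk built in one population can be
applied in another.

## Model

All items follow Samejima's graded response model (GRM). For an item with
K ordered categories, discrimination a > 0 and thresholds
b₁ < … < b_{K−1},

    P(X ≥ k | θ) = 1 / (1 + exp(−D·a·(θ − bₖ))),    k = 1 … K−1,

and category probabilities are adjacent differences of these cumulative
curves. The scaling constant D defaults to 1.0 — the pure logistic metric,
which is the convention for published PROMIS parameters; D = 1.702 is
available for parameter files on the normal-ogive metric. Thresholds are
stored as locations bₖ as they are printed in parameter tables; the
slope-intercept form cₖ = −a·bₖ is available as a conversion utility.
θ lives on the anchor metric, where T = 50 + 10·θ.

Missing responses are skipped in every likelihood (treated as
missing-at-random and ignorable), never imputed.

## Fixed-parameter calibration

The legacy items are placed on the anchor metric by marginal
maximum-likelihood EM in which

* anchor item parameters are frozen at their established values (they define
  the metric and are returned bit-identical),
* the legacy items' slopes and thresholds are free,
* the latent trait distribution is represented by weights on a quadrature
  grid and is itself freely re-estimated every cycle ("multiple weights
  updating, multiple EM cycles") — necessary because the linking sample is
  not assumed to look like the anchor's referent population.

The complete-data log-likelihood separates into a weights term and
independent per-item terms, so the cycle — E-step posteriors, per-item
maximization, weights ← posterior column means — is an exact EM and the
marginal log-likelihood is non-decreasing (enforced in tests at 1e−6).
Per-item maximization uses L-BFGS-B on (log a, b₁, log threshold gaps), so
positivity and strict threshold ordering hold by construction; it is
warm-started at the current parameters and falls back to them if the
optimizer cannot improve, preserving monotone ascent.

Defaults, chosen as conservative common practice (the estimator itself does
not prescribe them):

| setting | default | note |
|---|---|---|
| quadrature | 49 equally spaced points on [−4, 4] | spans T 10–90 |
| initial weights | ∝ standard normal density | renormalized |
| convergence | max abs parameter change < 1e−4 AND relative log-likelihood change < 1e−7 | joint rule |
| cycle cap | 500 | |
| starting values | a = 1.5; bₖ from normal quantiles of observed cumulative endorsement | |

Convergence behaviour worth knowing: with freely updated weights the EM
creeps (hundreds of cycles are normal), and at large n the joint rule can
trigger earlier in cycle count; we verified on simulated data that
tightening the tolerances tenfold does not move the estimates, i.e. the
default rule stops at the MLE, not short of it.

**Standard errors** come from the outer product of per-person score vectors
(OPG / cross-product information) for the free parameters, evaluated at
convergence with the latent weights held at their final values, gradients by
central finite differences of the per-person marginal log-likelihood.
OPG needs no second derivatives; it ignores the sampling variability of the
estimated weights, which is the usual price of this estimator. 95% CIs are
estimate ± 1.96·SE.

**Never-endorsed categories.** A category no one chose cannot anchor its
threshold (the boundary would diverge), so before estimation such categories
of free items are collapsed into the adjacent lower category (category 0
merges upward), the recode is recorded in the result, and a warning is
logged. Raw summed scores must then be recoded through the same mapping
before crosswalk lookup; `CalibrationResult.recode_responses` does this and
the pipeline applies it automatically. In floor-effected samples the top
category of the most severe item is the typical casualty.

**Error contracts.** No fixed item → anchoring error (the metric would be
undefined). No respondent answering both an anchor and a free item →
linkage error. All-missing respondents are dropped and counted.

## Crosswalk construction

The distribution of the legacy summed score S given θ comes from the
Lord–Wingersky recursion, Lⱼ(s|θ) = Σₖ Lⱼ₋₁(s−k|θ)·Pⱼ(k|θ), a dynamic
program that is exact (tested against exhaustive enumeration over all 5⁶
response patterns at 1e−12). Combining it with a prior w(θ) gives, for each
raw score s,

    θ̂(s)  = Σ_q θ_q w_q P(s|θ_q) / Σ_q w_q P(s|θ_q)          (summed-score EAP)
    PSD(s) = posterior SD of θ given S = s,

and the table reports T(s) = 50 + 10·θ̂(s) with SEM(s) = 10·PSD(s).

The default prior is standard normal on the anchor metric, which keeps
crosswalk T scores referenced to the anchor's general population; the
calibration's updated latent weights can be passed instead (`prior
empirical`), and the table records which prior produced it. Which choice a
given published crosswalk used is generally not stated, so neither is
claimed to replicate any published table exactly. A single-point prior is
rejected (its posterior SD is zero, and a crosswalk SEM must be positive).

**Monotonicity.** A crosswalk's T score must increase strictly in the raw
score, and the table constructor enforces this. For real instrument banks —
several items of one format with comparable slopes — summed-score EAP is
strictly increasing in every case we generated. It is, however, not a
theorem: banks mixing a steep short item with a shallow long item whose
thresholds occupy a different range can produce small EAP inversions
(verified by brute-force enumeration, independent of the recursion). Such
tables are rejected rather than silently returned; the property suite
checks exactly this build-or-raise contract.

Output CSVs keep θ columns at four decimals and T columns at one decimal
(the convention of published crosswalk tables); full precision is retained
in memory.

## Observed scores

"Observed" anchor T scores are response-pattern EAPs: posterior mean and SD
of θ given a person's full anchor response pattern, on the same grid and
prior as the crosswalk so both score types share one referencing convention.
EAPs shrink toward the prior mean; the posterior SD never exceeds the prior
SD for informative patterns. Whether a published validation used pattern or
summed-score scoring for its observed T scores is often unstated; pattern
EAP is the default here and summed-score EAP is available through the
crosswalk module.

## Agreement battery

With differences d = derived − observed:

* mean, SD (n−1 denominator) and RMSD (n denominator), so that
  RMSD² = mean² + SD²·(n−1)/n exactly — an identity asserted on every
  computed report;
* Pearson correlation;
* ICC(A,1): two-way, absolute-agreement, single-rater intraclass
  correlation from the ANOVA mean squares, the variant appropriate when the
  question is score *interchangeability* (it penalizes constant shifts,
  unlike consistency ICCs). The variant name is recorded in the report
  because "ICC" alone is ambiguous;
* Bland–Altman bias with limits of agreement bias ± 1.96·SD;
* disattenuated raw-score correlation r/√(rel_x·rel_y) for the
  similar-construct check, with coefficient alpha computed from the same
  sample as the default reliability source (user-supplied reliabilities
  override); values above 1 are reported unclamped with a warning;
* parameter-set comparison: per-parameter 95% CI overlap counts when SEs
  are available on both sides, maximum absolute estimate difference always.

## Synthetic data

The restricted cohort data cannot be shipped, so the generator reproduces
the *design*: one group answers both scales at one sitting; responses are
drawn from the GRM (one uniform per cell, X = #{k : u < P(X ≥ k)}), so
empirical category frequencies converge to the model's (chi-square checked).
Two latent populations are built in:

* development-like — θ ~ N(0, 1), n = 2009;
* validation-like — a floor-effected two-component mixture, 0.7·N(−0.8,
  0.7²) + 0.3·N(0.6, 0.9²), n = 448, emulating a younger, mostly
  asymptomatic cohort (about a third of simulated respondents sit at the
  raw-score floor). The mixture is an emulation target chosen once for
  realism, not an estimate of any real cohort's distribution.

Legacy items are generated from the published 8a-linked parameter set; the
anchor bank is a documented synthetic set of eight (up to eighteen)
5-category items with slopes 1.5–3.5 and spread thresholds — official
anchor-bank parameters are not redistributable, so fixtures define a
realistic anchor metric rather than the PROMIS bank itself. Every fixture
manifest records the seed, population spec and generating truth.

What passing on these fixtures does *not* show: robustness to differential
item functioning between populations (fixture items are invariant by
construction), to non-GRM response styles, or to missingness mechanisms
beyond MAR.

## Problem sizes used in the checks

The recovery simulation calibrates n = 2000 (and 250/1000/4000 for the
sample-size curve); the end-to-end validation fixture uses n = 448; the
recursion oracle enumerates all 15,625 six-item patterns at 49 grid points.
The acceptance script averages the slope-RMSE curve over three replicate
seed families per sample size, because an RMSE over six slopes from a
single draw is noisy enough for one ~2·SE deviation on the steepest item to
mask the 1/√n trend.

## Known limitations

* OPG standard errors understate uncertainty from the estimated latent
  weights and can be optimistic at small n.
* The crosswalk assumes the calibrated GRM holds in the target population;
  it carries no DIF screening of its own.
* Summed-score EAP discards the within-score pattern information that
  pattern EAP uses, which bounds achievable agreement between the two score
  types (visible as RMSD ≈ 5 T points on the floor-effected fixture).
* Equipercentile linking is out of scope by design.
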