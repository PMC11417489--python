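# Methods

This note documents the models, conventions and numerical choices
behind `wearadhere`, in the package's own words. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Day taxonomy and accounting

A protocol day belongs to exactly one of five classes (valid,
participant-controlled non-wear, non-participant-controlled (NPC)
non-wear, changeover, post-withdrawal). Competing classifications
resolve by precedence **changeover > NPC > post-withdrawal >
wear-based**: logistics states are recorded by the study operator and
therefore observer-verified, while wear-based classes are residual.
A changeover day with high wear is still a changeover day — the swap
causes systemic data loss regardless of what the device recorded.

The valid-day threshold is a closed bound: wear ≥ 22 h (within a 24 h
civil day, midnight to midnight in the participant's own clock). The
22 h allowance leaves room for device cleaning or a sauna visit while
still covering day and night behaviour without imputing the missing
hours.

Expected days = protocol days (182) − NPC days − changeover days.
**Post-withdrawal days stay in the denominator by default**: early
withdrawal is treated as participant-controlled, so withdrawers score
near-zero long-term adherence rather than having their missing time
excused. `count_post_withdrawal_in_expected=False` inverts this.
When expected days hit zero, long-term adherence is undefined: it is
reported as missing, excluded from cohort medians, and classified
`low` in group/trajectory tables.

## Adherence scores and groups

* Long-term adherence (LTA) = valid / expected days.
* Daily adherence = mean(wear_hours / 24) over *qualifying* days:
  days that are neither changeover nor NPC and that have positive
  wear. Rationale: a cohort's median daily adherence can greatly
  exceed its LTA only if zero-wear days are excluded from the mean;
  conditioning on "days the device was worn at all" yields the
  interpretable quantity "how much of a worn day is covered". The
  all-expected-days alternative is available
  (`daily_denominator="expected"`).
* Groups: LTA ≥ 0.95 optimal, ≤ 0.75 low, open interval moderate;
  daily adherence uses 0.90 for the optimal cut. Both cut points are
  closed ("95 % or higher", "75 % or lower"); the moderate band is
  the open interval between them. Configurable via `GroupThresholds`.
* Periods: study days [1, 60], [61, 120], [121, 182]. Six months of
  182 days has no exact thirds; the 60/60/62 split keeps the first two
  windows at two 30-day months. A window consisting entirely of
  post-withdrawal days is `dropped_out`.
* Data return = valid days / 182 per participant; cohort-level
  theoretical maximum is 182 × n. Because expected ≤ 182, data return
  never exceeds LTA, with equality exactly when no day was lost to
  logistics.

## Non-wear detection

The detector is intentionally simple and fully documented, standing in
for vendor processing chains whose parameters are rarely published.
Each 60 s epoch carries a movement dispersion (standard-deviation-like
summary of acceleration magnitude, in g) and a near-body temperature.
An epoch is an off-body *candidate* when movement < 13 mg **and**
temperature < 25 °C; a maximal candidate run of at least one detection
window (30 min) becomes off-body, shorter runs stay worn. Ties
therefore resolve toward "worn", deliberately biasing against
over-counting non-wear given the protocol's permissive 2 h/day
allowance. Consequences:

* detected non-wear is resolved at the window scale — the epoch→day
  round trip is exact to ±1 window (30 min);
* removals shorter than the window (cleaning, showering) are absorbed
  into wear, matching the valid-day philosophy.

Daily summaries intersect worn segments with civil days; partial
first/last days carry a coverage flag. Wear conservation (sum over
days = total worn duration) holds to 1e-9 h.

## Synthetic cohort generator

The generator emulates the study conditions: a 182-day protocol,
device changeovers at biweekly (every 14 days → 12 changeover days) or
monthly (28 days → 6) cadence or a mixed schedule switching at day 60
(8), NPC non-wear injected as contiguous multi-day spans (expected 0.8
days per deployment, geometric span lengths, mean 3 days, never
overlapping changeover days), early withdrawal as a per-day hazard
(0.002) confined to the low archetype — matching the observation that
dropping out concentrates among low adherers — and covariates with
realistic frequencies (19 % female, 19 % CRT-D, 35 % AF, smoking
41/14/45 % never/active/previous, ages truncated-normal 64 ± 11 on
[35, 88]).

Adherence propensity is generated on the log scale. Participant *i*
draws an archetype A ∈ {optimal, moderate, low} with default weights
(0.28, 0.429, 0.291) and a valid-day probability

```
log q_i = log b_A + log(1.14)·(age_i − 64)/10 + log(1.24)·1{monthly}
          + log(1.09)·1{both} − |N(0, 0.22)|,    q_i capped at 0.995
```

Valid days then arise Bernoulli(q_i) per non-logistics day (optionally
with AR(1) persistence via `day_autocorrelation`; the default is 0
because no within-person day-to-day correlation target is
established). Valid days draw wear in (22, 24] (24 − 2·Beta(1.5, 4));
invalid days draw 22·Beta(3, 1), concentrating just under the
threshold; changeover days lose an additional 2–8 h swap gap. A
sinusoidal seasonal modifier (`seasonal_amplitude`, default 0) scales
q by calendar month for seasonality-recovery experiments.

**Design choice: estimability over ceiling realism.** The generating
effects (1.14 per age decade, 1.24 monthly, 1.09 mixed) are meant to
be *recoverable* by the package's own regression — OLS on log(LTA) —
so the model must be log-linear in the covariates. With a response
bounded at 1 and a strong age effect over an 11-year age spread, any
archetype baseline near 0.95 puts substantial probability mass at the
cap, censoring the log-linear law and attenuating fitted effects.
The default baselines b = (0.84, 0.70, 0.38) with the one-sided
frailty keep the cap essentially inactive, making the regression
well-specified: over 100 replicates of n = 300 the fitted 95 % CIs
cover the generating effects at roughly the nominal rate (computed by
the acceptance script and test suite). The price is that the default
synthetic cohort's median long-term adherence sits below what a real
high-adherence deployment reports; the archetype labels order
behaviour rather than guarantee group membership. In particular, an
all-optimal cohort scores uniformly high but not universally ≥ 95 %,
because younger participants are mechanically pulled down by the
log-linear age effect. Users who want a near-ceiling cohort can raise
the baselines and shrink the frailty, at the cost of biased effect
recovery.

## Inferential stage

* **Group comparisons** — continuous: Kruskal–Wallis across three
  groups, Wilcoxon rank-sum for the two-group 75 % sensitivity split;
  categorical: Pearson χ² without continuity correction, falling back
  to an exact test when any expected cell < 5 (strict bound). The
  exact test is Fisher's for 2×2; for larger tables a conditional
  Monte-Carlo test with fixed margins (Patefield sampling, 20,000
  draws, +1/+1 correction) — the same construction as R's simulated
  p-values. Two-sided α = 0.05 throughout, no multiplicity
  correction.
* **Repeated-measures ANOVA** — classical split-plot decomposition on
  a complete participants × study-days matrix of daily adherence.
  The between-subject group F is tested on uncorrected df (sphericity
  does not affect it); the day and group × day tests scale their df by
  the Greenhouse–Geisser epsilon, ε = tr(CSC)² / ((k−1)·tr((CSC)²))
  with S the pooled within-group covariance and C the centering
  projector. ε is clipped to [1/(k−1), 1] and is exactly 1 for k = 2.
  Panel completion: days observed by < 80 % of participants are
  dropped, participants observing < 80 % of the remaining days are
  dropped listwise, and a participant's sparse leftover gaps (their
  own changeover/logistics days) are filled with their own mean —
  preserving between-subject contrasts, which carry the group test.
* **Log-linear regression** — OLS of log(LTA) on age per decade, sex,
  HF hospitalization, AF, cardiovascular comorbidity, device type,
  smoking (3-level), KCCQ clinical score and changeover schedule
  (3-level), with references male / no / no / no / ICD / never /
  biweekly. Coefficients and CIs are exponentiated into relative
  effects. Zero-adherence participants are excluded by default (log
  undefined); `offset_epsilon` substitutes a small positive floor
  instead. The design matrix is built explicitly (no formula magic) so
  deliberately duplicated covariates surface as a collinearity error
  naming the offending columns (rank check + pivoted QR). A minimum
  of 10 participants per model term is enforced.
* **Seasonality** — mean daily adherence per calendar month over
  qualifying days; months without qualifying days report missing.

## Pipeline

Stages simulate → detect → account → score → associate → report
exchange plain CSV with documented schemas, so any stage can be fed
real exported wearable data in place of the simulator. A JSON
manifest records config hash, seed and per-stage output checksums;
re-runs skip stages whose outputs are fresh and re-execute anything
missing or stale. Identical config + seed is byte-identical output.
Epoch-level CSVs are emitted only for a configurable sample of
participant-days (`emit_epoch_days`) because a full cohort at 60 s
resolution is ~80 M rows.

## Problem sizes and limitations

The test suite exercises cohorts of 60–1,000 participants and effect
recovery on 100 replicates of n = 300; the acceptance script uses the
same sizes. These are the package's reference problem sizes for a
desk-scale replication of the analysis.

What the synthetic cohort does *not* model: raw tri-axial waveforms
(epoch summaries are generated directly), temperature drift and sensor
noise autocorrelation, covariate-linked withdrawal or NPC rates,
enrolment-volume seasonality, PROM item responses, and any ICD therapy
events. Passing tests therefore demonstrate the correctness and
calibration of the *analysis chain*, not the realism of any particular
cohort's adherence distribution.
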