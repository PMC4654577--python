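# Methods

`triadstress` analyses status emergence in triads of unacquainted men
who watch a relaxing video and then converse, while stress is tracked
in real time from a thumb photoplethysmograph (PPG) and a saliva panel
(testosterone T, cortisol C, alpha-amylase AA) is collected before and
after the session. This note records the models, the numerical
choices, what the synthetic generator does and does not emulate, and
the known limitations.

## Real-time stress measures

The PPG waveform rises and falls with each heartbeat; under sympathetic
stress blood leaves the thumb and the waveform narrows. Two per-beat
quantities are extracted:

* **pulse rate** (BPM), from the spacing of successive waveform peaks;
* **peak-to-peak amplitude** (the thumb-blood-volume proxy, TBV): the
  height of one beat's peak minus the deepest trough before the next
  peak.

Beat detection finds local maxima of the signal after subtracting a
rolling-median baseline (window = two cycles at the minimum plausible
rate), with a refractory spacing of `60/max_bpm` seconds and a
prominence threshold set as a fixed fraction of the detrended signal's
5–95% spread. Both the baseline and the threshold are equivariant
under rescaling, so multiplying a trace by any positive constant (cuff
tightness, sensor gain) leaves every downstream ratio unchanged — this
gain invariance is asserted to 1e-9 in the tests. Defaults
`min_bpm=40`, `max_bpm=180` cover seated adults; beats with
out-of-range instantaneous rates are flagged, not dropped. Raw
amplitudes are never interpreted; only ratios are:

* conversation / video mean peak-to-peak (stress of conversing);
* speaking-turn / listening-turn means for TBV and pulse (stress of
  holding the floor).

A beat belongs to an interval iff its peak time lies in the half-open
interval; each beat counts as one observation in interval means.

**Artifact rules.** Artifact annotations are inputs, not detected.
`excise` removes all beats in an interval from every statistic. `step`
corrects a step-like gain change at time t0 by multiplying all
amplitudes at or after t0 by the ratio of mean amplitudes in the 20 s
windows before and after the break; excisions are applied first, and a
truncated window on either side is an error. Correction acts on the
amplitude series, not the raw samples, which keeps it gain-consistent.

## Turns

A speaking turn is a consistent utterance by one person lasting more
than 4 s, allowing short pauses and brief interjections by others.
Same-speaker utterances separated by gaps of at most `merge_gap_s`
(default 2 s; the source material says only "short pauses", so this is
an exposed parameter) are merged first; merged spans longer than 4 s
become turns. For a given subject, *speaking* intervals are his own
turns and *listening* intervals are the other members' turns minus any
overlap with his own (overlapping speech counts as speaking — stress
attribution follows own vocal effort); silence belongs to neither.
The alternative "listening includes silence" reading is available by
taking the conversation complement, but the default follows the
narrower definition.

## Status ranks

Seven components rank the three members (1 = high): three judges'
gestalt rankings, speaking seconds, topics introduced, turn count, and
the combined peer evaluation. Within a component, tied members share
the better rank ((200, 200, 100) → (1, 1, 3)). A pair is *consistently
differentiated* only if at least 4 of the 7 components strictly order
it the same way; otherwise the pair is tied (with fewer components the
threshold is the same fraction rounded up; a stricter variant that
additionally forbids reversals is available). The three pairwise
outcomes yield the triad pattern: a full order → (1, 2, 3); a tied top
pair over a clear third → (1.5, 1.5, 3); a clear first over a tied
bottom pair → (1, 2.5, 2.5); three ties → (2, 2, 2). Any other
pattern (e.g. a cycle) is classed `unresolved` and receives fallback
ranks from mean component rank, flagged for audit; ranks always sum to
6 per triad.

## Statistical layer

The triad design violates OLS independence (one member's rank
constrains the others'), so fixed effects are estimated in a marginal
model with a **diagonal residual covariance**: one variance per
repeated-measure level (member position; member-by-time for the
three-level analyte models), zero covariances, triad as the grouping
unit. Because the covariance is diagonal this is a heteroscedastic
regression with jointly estimated weights.

Numerical choices:

* **Estimation** is REML by default (the convention of the standard
  mixed-model software for such designs), via a profile fixed-point
  iteration started at the ML solution; plain ML is available. The
  homoscedastic case is closed-form, and with a single level and REML
  the fit reduces exactly to OLS (asserted to 1e-6).
* **Standard errors** carry a Kackar–Harville/Kenward–Roger-type
  correction for the sampling variability of the estimated residual
  variances. For a covariance linear in its parameters the adjustment
  is closed-form and vanishes exactly when the weights cannot move the
  estimator (homoscedastic or saturated designs — the two-group case
  reproduces Welch's t-test exactly, including its df). Without the
  correction the null rejection rate of the rank test at 15 triads is
  ~0.08–0.10 instead of 0.05.
* **Degrees of freedom** are Satterthwaite-type: for a contrast c,
  df = 2 g² / Var(g) with g = c'Cov(b)c and Var(g) from the delta
  method through the inverse Fisher information of the variance
  parameters.
* **Centering**: predictors are mean-centered on the analysis sample
  before interaction products are formed. **Missingness**: listwise
  within a model, pairwise-complete for correlations; a subject
  missing the post saliva keeps a prior-only mean level, flagged.
* **Simple slopes**: the conditional effect of a predictor at
  moderator values mean ± 1 SD, with variance from the full
  coefficient covariance; equal to a re-centered refit to 1e-6 (an
  exact reparameterization, asserted in the tests).
* **Singular designs** raise an error naming the collinear columns;
  non-convergence raises with the iteration trace attached.

**Post-hoc power** of the joint F-test of a k-predictor regression
uses Cohen's f² = R²/(1−R²), noncentrality λ = f²·N (the alternative
λ = f²·(df1+df2+1) is available), df1 = k, df2 = N−k−1, and the upper
tail of the noncentral F beyond the central critical value. At
R² = 0, power equals α exactly; power is strictly increasing in N and
R²; a 20,000-replication Monte-Carlo OLS simulation agrees with the
analytic value within 0.01.

**One-tailed paired t-tests** are the classical statistic with
df = n−1 and the tail chosen by the stated direction.

## The synthetic generator

Every stage is testable without the original recordings because the
generator emits complete sessions — waveforms, utterance tracks,
saliva panels, status components — with the ground truth stored next
to them. Identical seeds give bit-identical sessions (all randomness
flows through one `SeedSequence`).

Defaults are the study conditions: 15 triads (10 with nothing at
stake, 5 with a $20 leader reward), a 200 s video then 600 s of
conversation, 100 Hz sampling (adequate peak localisation at ≤200 BPM
with small files). The waveform is an asymmetric pulse template (fast
upstroke, slow decay) laid down cycle by cycle — pulse morphology is
deliberately crude because only peak/trough structure matters to
peak-to-peak statistics. State parameters were calibrated once,
analytically, to the group statistics the study reports, and are not
tuning knobs:

* video pulse 77 ± 7 BPM between subjects; a +5 BPM listening
  increment (SD 6.5) and a 1.09 speaking/listening pulse ratio put the
  conversation mean near 84 BPM;
* conversation (listening) amplitude 0.80 × video on average (log-SD
  0.25) and a 0.88 speaking/listening amplitude ratio (SD 0.15) put
  the beat-weighted conversation TBV near 0.77 of video;
* both speak/listen ratios are modulated by status rank (−0.05 and
  +0.03 per rank unit) — lower-ranked men find speaking more
  stressful;
* the between-subject SDs were back-solved from the reported
  proportions of subjects showing each effect (79%, 93%, 73%).

The floor is allocated by a near-alternating speaker process (softmax
of latent status scores, flattened for selection) in which status
mostly lengthens turns; this keeps per-subject turn counts in the
narrow 3–13 range seen in real triad conversations while the expected
floor share rises with latent score (exactly 1/3 under equal scores).
Turns are emitted as utterances with sub-merge-gap pauses plus
occasional brief interjections, so the turn builder sees realistic
input.

Saliva analytes are drawn on the analysis scales (lnT, C, lnAA) as
prior/post bivariate normals with the reported prior↔post
correlations, truncated to assay bounds (T ∈ [1, 600] pg/mL,
C ∈ [0.007, 3] µg/dL), with mean lnAA rising 0.29 per rank unit and
0.63 lower in the reward study. The lnAA *residual* correlation is
0.28: once the rank and study structure contributes shared variance
the marginal prior/post correlation is ≈0.44, which is the quantity
reported from data. An optional triad-level random effect on the
analytes defaults to 0 (no within-triad hormone covariance is
documented). Missingness is emulated (AA absent for the first five
no-reward triads; one subject without post saliva).

Status components are noisy copies of the latent score ranked with a
finite rater resolution: scores within `tie_width = 0.9` of each other
tie. With `judge_noise = 0.5` this reproduces the observed tie
frequency (≈8 of 45 pairs) and judge agreement; with zero noise every
component reproduces the latent order exactly, which is what the
zero-noise recovery tests rely on. Artifact injection (step-gain and
noise-burst events at the empirically observed per-subject rates)
writes the matching annotations into the ground truth, exercising the
correction path end to end.

**What the generator does not emulate:** pulse morphology and
heart-rate variability structure, respiration coupling, speech
acoustics, judge-specific biases, diffuse status characteristics, and
any within-triad hormone covariance beyond the optional random
effect. Passing tests therefore demonstrate that the pipeline
recovers programmed effects under realistic magnitudes and noise — not
that the substantive findings would replicate in new human data.

## Problem sizes used in the test and acceptance runs

Study-scale checks run the full pipeline at 15 triads; statistical
recovery uses the saliva-only fast path at 500 triads (24 replicates
for the bias check); null calibration uses 1,000 simulated 15-triad
studies; the power Monte-Carlo uses 20,000 replicates. The type-I
calibration experiment generates data with the lnAA residual
correlation set to 0 so that the generating process satisfies the
diagonal model's independence assumption: it is a test of the
estimator's calibration. Under the default residual correlation of
0.28 the diagonal model over-rejects (~0.12 at nominal 0.05) because
it ignores the within-subject prior/post covariance — a genuine
property of the diagonal-covariance specification that users should
keep in mind when interpreting p-values near threshold.

## Known limitations

* The diagonal covariance ignores within-subject correlation across
  the two saliva samplings (see above).
* Satterthwaite df combined with the adjusted covariance is a hybrid,
  not the full Kenward-Roger df; exact agreement with other software's
  fractional df is not promised.
* The beat detector assumes annotated artifacts; it does not
  auto-detect motion noise.
* Status aggregation follows the ≥4-of-7 majority reading of
  "consistently differentiated"; the stricter no-reversals reading is
  available but changes tie frequency.
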