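# Methods

This note records the models and procedures the package implements, the
parameters that matter, the choices made where the design was genuinely
open, and what the synthetic-data generators do and do not establish.

## Device model and trace handling

The tension meter samples at a nominal 10 Hz over a 0–100 kgf range with
0.1 kgf resolution; its accelerometer is reduced upstream to one signed
scalar per sample in [−1, +1] (+ toward the dog, − toward the handler).
How the physical device encodes or thresholds that direction signal is not
documented anywhere we could rely on, so the signed-scalar contract is an
interface assumption of this package, not a device fact.

Traces are plain CSV (`time_s,force_kgf,dir`), chosen for inspectability;
`write_trace` quantises force to the device resolution, so a read–write
round trip is lossless only up to that rounding.  Strict parsing rejects
non-monotone timestamps; lenient parsing drops the offending rows and logs
the count.

The pre-walk protocol is located by finding maximal runs with force ≥
`min_force` lasting ≥ `min_duration`.  Defaults: `min_force = 5` kgf,
`min_duration = 2.0` s, `guard_gap = 1.0` s.  The protocol specifies 3 s
holds but no amplitude, so the force default is a deliberately loose bound
well above calibration-hold readings and well below a deliberate two-handed
pull; the duration default leaves 1 s of slack against sloppy counting.
Exactly three qualifying pulses are required; any other count raises an
error carrying the candidates found.  The walk begins one guard gap after
the final pulse.  The calibration hold's median force is logged as a
device-offset diagnostic, but baseline removal is done by taring (below),
which is the authoritative rule.

## Signal conditioning

* **Interpolation**: linear, onto the grid `t[0] + k/rate` (default
  10 Hz), never extrapolating past either endpoint.  Linearity is a choice;
  nothing in the source protocol names an interpolant.
* **Taring**: subtract the trace minimum so slack leash reads zero.
  Idempotent and offset-invariant.  It is applied to the walk segment
  only, since the minimum of the full recording could be depressed by the
  unloaded calibration phase.
* **Smoothing**: centred moving average with edge truncation, default
  window 3 samples (0.3 s).  The upstream analysis refers to a "filtered"
  tension without naming the filter; the moving average is the simplest
  defensible reading and `window=1` disables it.  Order: tare, then
  smooth.  Smoothing a tarred trace can lift the minimum slightly off
  zero, so the zero-minimum invariant is only enforced on unsmoothed
  traces; re-taring after smoothing was rejected because it would shift
  event peaks relative to the documented edge-truncation arithmetic.

## Pull-event detection

Threshold: `0.001 × body weight` (kgf) — for a 20 kg dog, 0.02 kgf; note
that for a 100 kg dog this equals the device resolution, so detection at
that size operates at the quantisation floor.

State machine on the tarred, smoothed series: an event opens at a sample
strictly above the threshold; it closes exclusively at the first sample
strictly below the threshold, or at the first sample whose first
difference is strictly positive after an earlier strictly negative
difference within the event (that sample opens the next event).  Ties at
the threshold extend the event; zero differences carry no sign.  These
strictness conventions are deliberate: "exceeded" is read as >, "returned
to less than" as <.  Events still open at the last sample are closed there
and flagged truncated.  Peak force is read from the detection (smoothed)
series for internal consistency.

Direction is the signed channel at `start − 1` (at the onset sample, with
a logged warning, if the event starts the trace): dog if > δ, handler if
< −δ, both if within the dead band; δ defaults to 0.1.

Metrics: NT_max/NT_mean over all event peaks; DT_*/HT_* over dog-/
handler-attributed events; DPF/HPF are attributed counts over walk
duration (n samples / rate).  Events attributed "both" count toward NT
metrics and the event total but not toward DT/HT or the frequencies —
frequencies are defined per party, and double-counting a shared pull into
both parties would bias both.  This is configurable territory; the
exclusion is the package's documented choice.  NT_mean is the mean of
event peaks (the operational definition), not the samplewise mean of the
trace; the latter is exposed as `samplewise_mean`, a diagnostic only.

## Behaviour logs and agreement

Point behaviours → events/s; state behaviours → % of walk time with
overlapping same-behaviour intervals merged first; grouped totals sum the
member point rates for verbal cues and body language.  Cohen's κ between
two codings of one walk is computed on fixed-width time bins (default
1 s): κ on continuous records requires some discretisation, and a fixed
bin is the most transparent; the bin width is a reported parameter, and
per-session κ plus the mean over sessions are both available since it is
unknowable whether a published average κ was pooled or averaged.  Bins are
half-open; a point event on a boundary belongs to the later bin; within a
bin the state behaviour with the largest overlap wins, ties breaking by
catalog order.  When both sequences are one identical constant label,
chance agreement is 1 and κ is returned as 1.0 by convention.

## Questionnaire scales

Reverse scoring is `6 − x` on the 1–5 scale; factor scores are means of
member items after reversal.  **The item→factor assignment is not
published**: the shipped default (H = items {2,3,4,5,6,10,11}, reversing
{2,4,6,10}; D = items {1,7,8,9,12,13}, reversing {7,8,12}) was derived by
reading the item wordings, is labelled non-authoritative in the API docs,
and is fully configurable.  Whether "half" of 13 items means 6 or 7
reversed is ambiguous; the default reverses 7 (the negatively worded
readings).  Cronbach's α uses sample variances (ddof = 1);
zero total variance raises rather than returning a sentinel.  NEO domain
scores enter as numbers in [0, 48]; values outside the typically observed
[3, 48] envelope are flagged, not rejected.

## Association protocol

All outcomes are fitted as linear mixed models on transformed outcomes
(log₁₀ or a power), matching a transform-to-normality strategy rather than
non-Gaussian links.  Random intercepts for volunteer and dog are
**crossed**, not nested — dogs and volunteers re-pair across walks — and
implemented as two variance components over a single all-ones group in
statsmodels `MixedLM`, estimated by maximum likelihood so the reported BIC
is on the ML fit.  Fixed-effect p-values are large-sample Wald z.

Optimisation detail: the likelihood is maximised with Powell's method
first, because on null-ish data a variance component sits on the zero
boundary where the default gradient chain stalls or stops at a visibly
worse optimum; if Powell fails (its line search can enter a singular
covariance region) the default chain is used.  The procedure is
deterministic either way.

The protocol is: bivariate screen (per-candidate OLS on the transformed
outcome, keep p < 0.2; constant candidates dropped with a warning), forced
predictors (five personality domains + dog behavioural level) always
retained, then backward elimination removing the non-forced predictor with
the largest p ≥ 0.05, refitting until all remaining non-forced predictors
are significant.  "The model became consistent" is operationalised as that
stopping rule, with the BIC recorded at every step so a user can audit
whether a removal worsened it; the elimination trace is deterministic.
The bivariate screen's model family is unspecified upstream; plain OLS on
the transformed outcome is used.  VIF_j = 1/(1 − R²_j) with an intercept
in each auxiliary regression; values ≥ 2 are flagged, perfect collinearity
reports `inf`.  Residual normality is reported as a Shapiro–Wilk statistic,
a diagnostic only, never a gate.  No multiple-testing correction is applied
across outcomes, mirroring the modelling tradition this follows; users
screening many outcomes should correct downstream.

## Synthetic data: what it emulates, and what a green test shows

`simulate_walk` builds 10 Hz traces with a baseline offset (default
0.3 kgf), Gaussian sensor noise, optional timestamp jitter, optionally the
full pre-walk protocol (10 s hold at 0.5 kgf, three 3 s pulls at 8 kgf),
and planted bursts shaped as triangles, raised-cosine humps, or
double-humps — the last exists precisely to exercise the gradient-split
rule and counts as two detectable pulls in ground truth.  The direction
channel takes the planted sign from 0.5 s before burst onset so that
pre-onset attribution stays correct when smoothing advances the detected
onset by a sample.  Defaults (300 s walks, 20 kg dog, pulls of 0.5–4 kgf
lasting 1–3 s) are what a field recording of a moderately pully shelter
dog plausibly looks like.

`simulate_cohort` defaults to the study geometry (74 volunteers, 111
dogs, 370 walks, dogs walkable only by volunteers at the same or higher
level) and draws personality from the published volunteer distribution
(e.g. neuroticism 24.97 ± 8.80).  Outcomes are built on the transformed
scale from planted fixed effects (default magnitudes of order 0.01 per
NEO point on a log₁₀ outcome, matching the scale of reported
coefficients), crossed random intercepts (SD 0.05 each) and residual noise
(SD 0.15), then back-transformed.

What green tests establish: the detector equals its independent reference
implementation exactly; planted events, directions and effect signs are
recovered at the stated noise levels; the statistics match their closed
forms.  What they do not establish: that real leash traces look like the
parametric bursts (no gait dynamics, no leash elasticity, no drift), that
real coders behave like the binned agreement model, or that the published
coefficient tables are reproduced — the raw study data are not public, so
numerical agreement with them is out of reach by design.

## Known limitations

* Dropouts longer than one sample interval are not gap-filled; the
  dropout simulator exists for robustness testing only.
* The detector is offline; no streaming mode.
* A 100 kg dog's threshold coincides with the device resolution, making
  small pulls undetectable in principle at that size.
* Walking-level assignment in the cohort generator cycles volunteers
  uniformly; it does not model the over-walking of long-stay dogs.
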