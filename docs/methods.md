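# Methods

This note documents the models and procedures implemented in `ppvkit`,
their assumptions, the parameters that matter, and the numerical and
design choices made where the design was genuinely open.

## Beat extraction and exclusion rules

Beats are characterised by their diastolic onset time (seconds) and pulse
pressure PP = systolic − diastolic (mmHg); units are fixed, never
inferred. When starting from a raw arterial waveform, systolic peaks are
found with a refractory period (`min_interval_s`, default 0.3 s — a
200 bpm ceiling) and a prominence gate of 25% of the signal's range; each
beat's onset is the minimum between successive peaks. No claim is made
that this matches any particular monitor's proprietary detector; all
downstream analyses can equally start from pre-extracted beat tables.

Exclusion rules, applied to the continuous series before windowing:

- *Extrasystole*: a beat whose inter-beat interval is **strictly** less
  than 0.9 × the median of the up-to-ten preceding intervals. At least
  three preceding intervals are required before a call is made (windows
  start mid-recording, so shorter histories occur only at the very start
  of a recording). The beat following an extrasystole is also excluded:
  post-extrasystolic potentiation inflates its PP.
- *Outlier*: PP deviating **strictly** more than ±25% from the median PP
  of the ten nearest other beats, taken by index (5 before / 5 after,
  window shifted — not shrunk — at the edges). For a regular rhythm,
  index- and time-neighbourhoods coincide.
- *Window QC*: a 30-s window with more than two extrasystoles is invalid.
  Post-ectopic beats do not count toward this tally.

Both rules are scale-invariant (in time and PP respectively), which the
property tests exercise.

## The classic PPV estimator

Included beats are scanned for alternating PP extrema: each extremum is
the best beat within one respiratory cycle length (T_resp = 60/RR, from
the *set* rate) after the previously committed extremum, so every maximum
lies within one T_resp of the previous minimum and vice versa. The chain
starts with whichever extremum the data present first (decided by the
first strict PP change; a flat series defaults to seeking a maximum), and
ties go to the earliest beat. An extremum whose confirmation window is
cut off by the end of the data is discarded — the part-cycle at the
window edge cannot be trusted to contain a genuine crest or trough, and
keeping it systematically corrupts the final pair.

Committed extrema are paired non-overlappingly from the most recent
backwards; each pair contributes
`100·(PP_max − PP_min)/((PP_max + PP_min)/2)`, and the estimate is the
mean of the last three pairs. Fewer than three pairs leaves the estimate
*unavailable* (never zero — zero is a valid measurement).

With n beats per respiratory cycle, the sampled extremum of a sinusoidal
modulation is attenuated by cos(δ) with δ up to π/n, so the estimator is
biased low by construction at low HR/RR; this is the phenomenon the
package exists to quantify, not a defect to fix.

## The GAM PPV estimator

The beat-wise PP series of one window is decomposed as

    PP(t) = β₀ + f_trend(t) + f_cyc(φ(t)) + ε,   φ(t) = (t − t_ref) mod T_resp

- `f_cyc`: cyclic cubic P-spline in respiratory phase, 10 coefficients,
  periodic by construction (wrapped B-spline basis), cyclic second-order
  difference penalty. Its basis columns are centred over a dense uniform
  phase grid, which enforces a zero mean over one cycle and keeps the
  term identifiable against the intercept.
- `f_trend`: clamped cubic P-spline in time, 6 coefficients, second-order
  difference penalty, columns centred over the data.
- Smoothing: the two penalties are chosen by generalized cross-validation
  over a 7×7 log-spaced grid (λ ∈ 10⁻⁴…10⁴). The grid is searched from
  large to small λ so that GCV ties (e.g. an exactly-interpolable series)
  resolve to the smoother fit. A 10⁻⁹ ridge guards rank deficiency.
- Phase reference `t_ref` is the window start (synthetic data generates
  phase directly; with ventilator timing available, inspiration onset
  should be used). The *set* respiratory rate is used, never an estimate.

`PPV_GAM = 100 · (max f_cyc − min f_cyc) / mean(PP)`, with the extrema
read off a 512-point phase grid (amplitude error < 0.01% for smooth
components; by construction never below the peak-to-peak at observed
phases). The estimator requires ≥ 10 included beats spanning ≥ 3
respiratory cycles, else it is flagged unavailable.

The implementation is validated against R `mgcv` (cyclic cubic spline +
time smooth, REML) on identical data; the two agree to well under one
percentage point of PPV.

## Fluid responsiveness and ROC

ΔSV = 100·(SV_post − SV_pre)/SV_pre, with SV_pre/post the medians of six
stroke-volume samples per two-minute phase; a responder has ΔSV
strictly > 10%. Discrimination is summarised by the Mann–Whitney AUC
(ties one half) with DeLong's structural-components variance, computed
via mid-ranks. The 95% CI uses the normal approximation; if that leaves
[0, 1] the interval is recomputed on the logit scale by the delta method.
The reported threshold maximizes Youden's J, ties resolved to the lower
threshold (the criterion is configurable in principle; Youden is the
field's default).

## Agreement analysis

Bland–Altman on (PPV_GAM, PPV_Classic) pairs: bias = mean difference,
95% limits of agreement = bias ± 1.96·SD (SD with n−1). Confidence
intervals are percentile bootstrap over case resamples, 4000 resamples by
default, seeded. Pair-level resampling ignores within-patient clustering
deliberately: the per-setting analyses involve one pair per
patient-setting. Stratification splits pairs at HR/RR = 3.6 (strictly
below vs at-or-above), dropping pairs with a missing estimate and
reporting the count.

## Hierarchical effects model

For PPV measurements y (one per patient × setting × method):

    log y_i ~ StudentT(ν = 4, η_i, σ_{s(i)})
    η_i = a_{m(i)} + b_vt[m(i), vt(i)] + b_rr[m(i), rr(i)] + u_{p(i)}
    u_p = τ·z_p,  z_p ~ Normal(0, 1)

- Treatment coding against the reference setting V_T = 10 ml/kg,
  RR = 10/min; `exp(b)` are multiplicative relative effects, and every
  fixed effect is method-specific (the two estimators may respond
  differently to the ventilator), while the patient intercept is shared.
- ν is fixed at 4, not estimated: the heavy tail buys robustness to
  outlying windows.
- σ is indexed by ventilator setting and, by default, also by method
  (`sigma_per_method=False` pools methods), since the estimators'
  precision differs most exactly where their sampling behaviour differs.
- The t-residual is placed on the **log** scale, matching the synthetic
  cohort generator. Consequently σ_s is already a *relative* dispersion,
  and the per-setting coefficient of variation is reported as the SD of
  the t(ν) log residual, `CV_s = sqrt(ν/(ν−2))·σ_s` (≈ σ·√2 for ν = 4),
  in percent. CV contrasts between settings/methods are computed draw by
  draw and summarised as median and 2.5–97.5 percentiles, like every
  other posterior quantity.
- Priors (all overridable): a ~ Normal(log 10, 1) — centred on a PPV of
  10% with a generous spread; b ~ Normal(0, 1) on the log scale (±1 unit
  covers effects from ×0.37 to ×2.7); τ, σ ~ half-Normal(0, 1).

### Sampling

The posterior is smooth and unconstrained after log-transforming τ and
σ, so it is sampled with Hamiltonian Monte Carlo using exact analytic
gradients: leapfrog integration, trajectory lengths jittered uniformly
over 8–32 steps, dual-averaging step-size adaptation to 80% acceptance,
and a diagonal mass matrix estimated from the second quarter of warm-up
(dual averaging restarts when the metric changes). Default: 4 chains ×
2000 iterations, first half warm-up. Convergence is assessed with
split-R-hat and bulk ESS (arviz); a fit with max R-hat ≥ 1.05 is flagged
unreliable and can be made to raise. Patient intercepts are non-centred,
which avoids the funnel pathology at small τ.

On 20-patient simulated cohorts, 900 iterations × 3 chains give max
R-hat ≲ 1.05 and 95% interval coverage of the generating relative
effects of ~96% across 20 replicates; reported results in the test suite
use those sizes. Posterior medians between independent seeds agree within
about one percentage point of relative effect at these budgets.

## Synthetic data: what it emulates, and what not

**Beat level** (`gen_beats`): beat times from a nominal heart rate with
optional multiplicative timing jitter, or exact intervals anchored at a
fixed respiratory phase (`phase_lock`) for integer-HR/RR aliasing
experiments; PP = mean + polynomial trend + cyclic modulation + Gaussian
noise. The modulation shape has peak-to-peak 2 and is scaled by
`pp_mean·ppv_true/200`, so the injected PPV is exact by construction.
Shapes: sine (default) and a skewed variant whose rise occupies the first
third of the cycle (inspiration:expiration 1:2). Programmed extrasystoles
pull a beat early by a configurable prematurity (< 0.9, so the exclusion
rule must fire) and attenuate its PP by 40%; the truth record retains
their indices, and the filter tests require exact recovery.

**Cohort level** (`gen_cohort`): the generative structure of the effects
model above, over the ten-setting protocol grid — all four tidal volumes
(4, 6, 8, 10 ml/kg pbw) at RR = 10/min and V_T ∈ {6, 8} at RR ∈ {17, 24,
31}/min (high V_T at high RR is excluded by airway-pressure limits; a
configurable fraction of patients can also drop the (8, 31) setting).
Truth defaults are study-like: reference-setting median PPV 10%,
between-patient log-sd τ = 0.4, relative effects e_vt = {0.49, 0.64,
0.81}, e_rr(GAM) = {0.95, 0.87, 0.81}, e_rr(Classic) = {0.93, 0.80,
0.56}, log-scale residual σ = 0.15 (doubled for Classic at RR = 31 —
the sparse-sampling noise penalty). Fluid challenges draw responder
status (20%), ΔSV ~ Normal(17, 3) for responders and Normal(3, 3)
otherwise (truncated at −20), and six SV samples per phase with 3 mL
noise around the phase means; responders also carry a 1.8× higher PPV
intercept so that discrimination analyses have signal.

What the generators deliberately do **not** emulate: arterial waveform
morphology (dicrotic notch, reflection waves), respiratory sinus
arrhythmia, correlated measurement error between the two estimators
computed on the same window, drifting ventilator timing, or any
physiological coupling between PPV and ΔSV beyond the responder intercept
shift. Passing recovery tests therefore demonstrates correctness of the
estimators and inference machinery under the stated generative
assumptions — not clinical performance on real recordings.

## Numerical and degenerate-input conventions

- All comparisons in exclusion rules and thresholds are strict, exactly
  as worded; boundary cases are pinned by tests.
- Estimates that cannot be computed (QC failure, too few beats or pairs,
  non-convergent fit) are NaN with `available=False` and a reason string;
  they are never silently zero.
- Every stochastic routine takes an explicit seed (or Generator); same
  seed ⇒ bit-identical output, which the tests enforce.
- The ten-setting grid, the 30-s window length, the 0.9/±25%/two-
  extrasystole rules, ν = 4 and the 3.6 HR/RR cut are study constants,
  not tuning knobs.

## Known limitations

- The beat detector is a generic local-extremum segmenter; it is not a
  validated clinical algorithm.
- GCV occasionally undersmooths very noisy windows compared with mgcv's
  REML; the cross-check tolerance (1 pp of PPV) reflects this.
- The HMC sampler has no divergence-based treedepth control (it is not
  NUTS); heavily unbalanced cohorts may need more iterations, which the
  R-hat gate will signal.
- Bland–Altman intervals assume independent pairs; repeated-measures
  (mixed-effects) limits of agreement are out of scope.
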