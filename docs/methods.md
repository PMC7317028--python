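# Methods

## The signal and the statistic

Skin microcirculation exhibits spontaneous rhythmic blood-flow oscillations
(flowmotion).  Skin fluorescence recorded from the forearm tracks these
oscillations indirectly: tissue NADH fluorescence rises when oxygen delivery
falls, so the recorded intensity oscillates with perfusion.  The absolute
fluorescence level is dominated by nuisance factors (pigmentation, optical
coupling), so a recording is first **normalized** by its mean over a central
resting window (default 60–120 s): all analysis happens on the resulting
unitless trace, which makes the statistics comparable across subjects and
invariant to any rescaling of the raw intensities.

The slow baseline around which the signal oscillates is not reliably flat —
across subjects it can be ascending, descending, ascending to a plateau, or
parabolic, and during reperfusion it is always a rising saturating curve.  A
**second-order polynomial fitted by least squares** is flexible enough to
capture all of these shapes while leaving the oscillations of interest in
the residuals.  The flowmotion parameter is the per-point residual power:

FM = (SSE / n) × 10⁶

where SSE is the residual sum of squares of the quadratic fit and n the
number of samples.  Dividing by n (not n − 3) makes windows of different
lengths comparable; the 10⁶ factor brings values into the range of units to
hundreds.  Computed on a resting window the statistic is called FM; on a
150 s window of post-occlusive reperfusion, FM(R).

Numerical details: time is centered and scaled to [−1, 1] before solving the
least-squares system (condition number stays O(1) even for 10-minute
windows at 25 Hz); coefficients are mapped back to centered seconds.  A
constant segment yields FM = 0, not an error.  Fits require ≥ 4 samples.

## Spectral decomposition

Residual power is decomposed with a plain FFT periodogram: rectangular
window, no zero padding, frequency step 1/T.  The normalization is "mean
squared amplitude": the one-sided periodogram sums to the mean squared
residual, so a bin-centered sinusoid of amplitude A carries A²/2 in its bin
and **FM = 10⁶ × total periodogram power exactly** (Parseval).  The spectral
summary is therefore literally a partition of FM across frequency.

Band attribution follows the standard intervals for skin blood-flow
oscillations — endothelial (0, 0.021] Hz, neurogenic (0.021, 0.052] Hz,
myogenic (0.052, 0.15] Hz, cardiac (0.6, 2] Hz — with left-open,
right-closed intervals (a bin at exactly 0.021 Hz counts as endothelial;
membership uses a 10⁻⁹ Hz tolerance against float rounding).  The DC bin is
excluded; respiratory and other unclassified power (0.15–0.6 Hz) is
collected in a remainder term rather than reported as a band.  Two
normalizations are emitted: fractions of total residual power, and "pie"
fractions over the three sub-cardiac bands (these sum to 1 and are the
natural display for the three-component decomposition).

The periodogram is computed on the quadratic-fit residuals, not the raw
signal.  This is what turns the FM–total-power relationship into an
identity and keeps slow baseline drift out of the endothelial band.

## Protocol segmentation

The occlusion protocol records ≥ 3 min of baseline, 3 min of arterial
occlusion (cuff at 60 mm Hg above systolic pressure) and ≥ 3 min of
reperfusion.  Defaults (all configurable):

| parameter | default | rationale |
|---|---|---|
| normalization window | [60, 120) s | central resting period |
| rest discard | 60 s | subject settles during the first 30–60 s |
| rest window | 150 s, ending at occlusion start when marks exist | equal-duration comparison of FM and FM(R) |
| reperfusion window | 150 s from the hyperemia minimum | reperfusion only lasts ~3 min |
| hyperemia search | 60 s after release | the minimum is reached within ~20–30 s |

The reperfusion window is anchored at the post-release fluorescence
**minimum** (maximal hyperemia) rather than at cuff release: the minimum is
operator-independent, and a config switch (`reperfusion_anchor="release"`)
restores release anchoring.  The minimum is located on a 1 s moving-average
copy so a single noise spike cannot claim it; ties break to the earliest
time; smoothing affects localization only, never the analyzed values.  All
windows are half-open `[start, end)` with sample counts derived by index
arithmetic on the uniform grid.  Non-uniform sampling is an error, never
silently resampled — both the quadratic fit and the periodogram assume a
uniform grid.

The occlusion interval is analyzed as a quality check: no flowmotion should
survive under an inflated cuff, so the occlusion-segment FM should be a
small fraction (< 1% in the simulations below) of resting FM; the ischemic
fluorescence rise itself is absorbed by the quadratic baseline.

## Cohort procedures

* **Within-subject CV** — sample SD (n − 1 denominator) over the mean, per
  subject; the cohort value is the arithmetic mean of per-subject CVs.
* **Normality-gated correlation** — Shapiro–Wilk on *both* variables at
  α = 0.05; Pearson only if neither rejects, Spearman otherwise.  (Whether
  one or both variables should be gated was an open choice; gating both is
  the conservative reading.)
* **Paired Wilcoxon signed-rank** — exact null distribution when there are
  ≤ 25 untied nonzero differences, normal approximation with mid-ranks
  otherwise; zero differences dropped by default (Pratt handling by flag).
  All p-values two-tailed.
* **Prediction bands** — OLS with the t-based pointwise prediction interval
  ŷ ± t₁₋α/₂,ₙ₋₂ · s · √(1 + 1/n + (x−x̄)²/Sxx); an observation outside its
  own-x interval is an outlier (e.g. unusually strong flowmotion for its
  age).
* **Disturbed-response flag** — subjects with *both* FM(R) and the myogenic
  share myo(R) at or below the cohort's lower quartile (linear-interpolation
  quantile; boundary values included).  Requiring the conjunction keeps
  subjects with merely modest total reperfusion power out of the flag.
* Repeated measurements are aggregated per subject by the mean
  (configurable) before cross-subject analyses.

These procedures are standard; they are implemented on scipy/numpy and
verified in the test suite against independent oracles (full 2ⁿ enumeration
of the signed-rank null for n ≤ 12, closed-form vs statsmodels prediction
intervals, coverage simulation).

## The synthetic-data generator

No public recordings of this kind exist, so the package ships a simulator
whose defaults define the study conditions used throughout the tests.

**Trace model.**  Oscillators are fixed-frequency sinusoids with seeded
random phases — chosen over filtered noise so the expected statistics are
analytic: expected FM = Σ (A/m)²/2 × 10⁶ over the sub-cardiac oscillators,
where m is the noise-free signal mean over the normalization window (m = 1
for the default flat baseline).  Defaults: endothelial 0.02 Hz / amplitude
0.008, neurogenic 0.04 Hz / 0.006, myogenic 0.10 Hz / 0.008, cardiac
1.0 Hz / 0.002 (the heartbeat is visible but weak), Gaussian noise
SD 5×10⁻⁴ (the recordings this emulates have a very low noise-to-signal
ratio).  These give resting FM = 82, mid-range for healthy adults.  All
frequencies are bin-aligned on the 150 s analysis windows.

For the full protocol (600 s: occlusion at 180 s, release at 360 s) the
generator adds a saturating-exponential ischemic rise (amplitude 0.2, time
constant 150 s — the rise is still far from saturation when the cuff opens,
as in real recordings) with oscillators suppressed; at release, a smooth
half-cosine drop over 25 s to an undershoot of −0.15 (maximal hyperemia),
then exponential recovery with a 90 s time constant and oscillators restored
at a per-band gain, default endo 1.0 / neuro 1.0 / myo 2.0 — the myogenic
activation that drives the hypoxia response.  A scalar gain g is also
accepted and multiplies expected FM(R) by g².

The exponential time constants were chosen so the deterministic ischemia
and recovery shapes lie within the quadratic baseline's capacity (residual
< 1% of amplitude), consistent with the premise that a second-order
polynomial fits all observed baselines.  Quadratic detrending necessarily
absorbs part of very slow tones: ≈ 0.3% of power at 0.1 Hz over 150 s but
up to ≈ 7% at 0.02 Hz, so the analytic ground truth is accurate to ~2% for
oscillators at or above 0.04 Hz and is a mild overestimate below.  With the
default amplitude mix the end-to-end error in FM stays within ~2% and in
FM(R) within ~4%.

**Cohort model.**  Covariates echo the two study-group profiles (ages
50.5 ± 12.9 clipped to 31–72, or 38.4 ± 6.4 clipped to 30–50; SBP ≈
125 ± 12–15 mm Hg; BMI ≈ 25 ± 3–4).  Resting flowmotion is linear in age
(default slope −1.6 per year, intercept 155, residual SD 30 — yielding a
moderate correlation, r ≈ −0.5, similar to what is observed in healthy
adults).  The reperfusion response is mechanistic: the myogenic band power
surges to a tight, near-saturating level (140 ± 12), while the carried-over
endothelial+neurogenic power varies widely across subjects and declines
with systolic pressure (−2.5 per mm Hg).  Two consequences match the
observed phenomenology: FM(R) > FM for every healthy subject with
myo(R) ≫ myo, and FM(R) is strongly inversely correlated with blood
pressure.  A third is a design point: because the myogenic surge is tight
while the carried-over power varies, FM(R) and myo(R) are *negatively*
associated among healthy responders — subjects with low total FM(R) have a
high myogenic share — so the joint lowest-quartile flag isolates genuinely
disturbed responders instead of sweeping in the low tail of healthy ones.
Planted disturbed subjects (no myogenic activation) have FM(R) and myo(R)
drawn uniformly in (0.4–0.8) × the healthy lower quartile.  Repeated
measurements apply a multiplicative within-subject scatter (default 20%).

**What the simulator does not emulate** — and hence what passing tests do
not demonstrate about real data: motion artifacts, nonstationary oscillator
amplitude/frequency drift, 1/f background, inter-band coupling, skin-optics
effects, or realistic joint distributions of covariates beyond first
moments.  Parameter-recovery results certify the pipeline's correctness on
its own generative model, not clinical validity.

## Problem sizes

Simulation-based checks use 600 s traces at 25 Hz (15 000 samples), cohorts
of 35–40 subjects, 200 seeds for recovery rates, and 1000 replicates for
prediction-band coverage — sizes at which the full test suite and the
acceptance script each run in a few seconds.

## Known limitations

* The exact FM–periodogram identity holds because both operate on the same
  detrended residuals; device software computing a PSD on the raw signal
  would show a strong correlation rather than an identity.
* Whether device software divides SSE by n or n − 3, and how repeated
  measurements are aggregated, is not externally specified; n and the mean
  are used, both exposed in configuration.
* Band-edge membership at exactly 0.021/0.052/0.15 Hz follows the
  right-closed convention; other implementations may differ at bin-boundary
  frequencies.
* The generator's amplitude ranges are plausible rather than fitted to any
  measured population; absolute FM values from simulations should not be
  read as normative.
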