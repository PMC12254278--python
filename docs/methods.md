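# Methods

This note documents the models, parameters, and numerical choices behind
whisktask, and what the synthetic-data tests do and do not establish about
recorded data.

## Task model and trial scoring

The task is a go/no-go aperture discrimination on a linear track. A trial
opens at an outer IR-beam crossing, the animal palpates a motorized
aperture (wide 45 mm, neutral 35 mm, narrow 25 mm) with its whiskers, and
responds by licking or by withholding and crossing the middle beam. Scoring
follows the stage rule: in the initial rule, wide+lick = hit (reward),
narrow+lick = false alarm (punishment), withholding gives miss / correct
rejection; the reversed rule swaps contingencies; neutral-aperture trials
and all extinction trials are unscored, extinction outcomes being fair coin
flips independent of the aperture. `behavior.score_trials` assembles trials
from a raw `(t_s, device, value)` event stream; lick events with no open
trial are dropped and counted.

## Signal-detection statistics

d′ = Φ⁻¹(hit rate) − Φ⁻¹(FA rate). Rates of 0 and 1 are replaced by 1/(2n)
and 1 − 1/(2n), n being the count of the relevant trial class, which bounds
|d′| by Φ⁻¹(1 − 1/(2n_go)) + Φ⁻¹(1 − 1/(2n_nogo)). The expert criterion
Φ⁻¹(0.95) is reported as 1.65, the conventionally tabulated two-decimal
critical value (half-up rounding of 1.645); Φ⁻¹(0.975) reports as 1.96
unchanged. Running d′ at trial *i* uses the half-open window of the
preceding 200 scored trials (i − 200, i]; windows missing either class are
gaps. "Trials to expert" is the first *sustained* crossing of the running
d′ — sustained meaning the series stays at or above threshold for the next
window/2 scored trials or to the end of the data; a per-session variant is
selectable. The session-level expert criterion requires ≥ 4 sessions and
≥ 200 trials above d′ = 1.65.

The moment of insight is the first session whose no-go success rate is ≥ 5×
the previous session's (zero previous rates cannot qualify); the population
moment maps each animal's insight session onto a [0, 1] stage-progression
axis before averaging. Learning curves are 4-parameter logistic
least-squares fits with 20 random multistarts; lick-latency trends fit
y = a + b·e^(−c·x) the same way, with `a` free by default (initialized at
the median latency) or pinned to the median behind a flag. Retraction
metrics take the turning point as the global post-touch maximum of the
approach coordinate, earliest time on ties.

## Kinematic conditioning

Whisker angle traces are filtered with a 4th-order Butterworth band-pass
(2–30 Hz) applied forward-backward (zero phase, order and band
configurable). Whisking phase is the analytic-signal angle shifted so that
0 = full retraction and π = full protraction, in [0, 2π). Whisking
amplitude is peak-to-peak angle in a centered 100 ms window (a
Hilbert-envelope variant is selectable); frames whose window is truncated
at the trace edges are flagged. Whisking requires amplitude > 5°,
quiescence < 3°; the 3–5° dead band joins neither state, and frames within
100 ms of a touch are excluded from both. Whisk cycles are full 2π
progressions of the unwrapped phase inside a window (floor count).
Velocity is a centered 3-point finite difference; before locomotion
thresholding it passes a 50 ms median filter to suppress single-frame
tracking jitter. Locomotion needs |v| > 100 mm/s and rest |v| < 10 mm/s,
each sustained ≥ 200 ms, optionally restricted to a region of interest away
from the lick ports. Occupancy maps count frames in 10 × 1 mm half-open
cells and attach a mean ± SD speed profile per longitudinal bin.

## Per-unit statistics and the shuffle null

Units pass QC with isolation distance strictly > 15 and ISI-violation
fraction strictly < 3% at a 1.5 ms threshold; units lacking an isolation
distance are dropped with a warning. RS/FS classification thresholds
trough-to-peak at 350 µs (BC, ZIv) or 300 µs (VPM, POm), FS below the
threshold; RS are retained for BC/VPM/POm and FS for ZIv.

Response-onset latency uses a Poisson baseline model: spike counts summed
over trials in 1 ms bins, baseline rate from (−800, −600) ms pre-touch,
per-bin upper-tail Poisson probability, and the first bin with p ≤ 0.05 in
the 200 ms search window as the onset. Following the per-bin rule there is
no multiple-comparison correction by default (a Bonferroni flag exists);
with ~200 bins a homogeneous unit will occasionally produce a spurious
onset — the recovery tests therefore check the *median* latency across
units, and the no-change test uses the corrected variant. A silent baseline
is floored at 0.1 Hz and flagged.

Touch modulation compares paired per-trial spike counts in 200 ms response
vs baseline windows with a two-sided Wilcoxon signed-rank test per
aperture, requiring a positive median paired difference (the baseline
window length is set equal to the response window). The calcium variant
sums ΔF/F over 400 ms (12 frames at 30 Hz; converted by time at other
frame rates) before vs after touch with a paired t-test.

The shuffle null rotates all spike times by one Uniform(0, duration) offset
with wrap-around, preserving the spike count and all but one interval, 100
times per unit. Null 95th percentiles use the `higher` order statistic, the
standard conservative convention for finite permutation nulls (interpolated
percentiles measured anti-conservative: 8.5% vs 7.0% empirical type-I on
200 homogeneous units for the angle test). State modulation compares
|rate_A − rate_B| to the shuffled distribution of the same quantity, with
enhanced/suppressed labels by sign. Angle (and head-azimuth) tuning bins
angles at 5°, excludes touch-adjacent spikes and bins occupied < 0.5 s, and
tests the modulation depth (r_max − r_min)/r_mean against the null.

Phase tuning bins phase into 32 bins and fits
λ(φ) = ⟨λ⟩ + Amp·cos(φ − φ_pref) by linear regression on
(1, cos φ, sin φ); the solution equals the first circular Fourier
coefficient of the binned profile. SNR = 2·Amp·√(T/⟨λ⟩) with T = 111 ms,
the average whisk-cycle window. Significance uses a one-sample Kuiper test
of the spike phases against circular uniformity (V statistic with the
Stephens finite-n corrected asymptotic tail); a binned-rate variant is
selectable. The Kuiper test ignores occupancy non-uniformity of the phase
trace; for strongly non-sinusoidal whisking this can inflate significance,
which is why the fitted amplitude, not the test alone, carries the effect
size.

Spatial tuning averages 100 ms-bin firing rates into 20 mm position bins
and fits rate(x, v) = A·exp(−(x − μ)²/(2σ²)) + β·v + c by weighted least
squares (Poisson occupancy weights), profiling the linear parameters over a
(μ, σ) grid (μ at bin centers, σ ∈ {20, 40, 80} mm) and polishing with a
bounded nonlinear fit. Because μ is free, the covariance-based CI of A is
structurally anti-conservative (selection over candidate field locations;
measured 35–42% false positives on homogeneous units), so significance of
the amplitude is instead referred to the 95th percentile of |A| refit on
100 circular-shift shuffles — the same calibration logic as the other
tuning tests (measured 4–6.5% false positives). The speed coefficient keeps
its covariance CI: a unit is spatially tuned iff |A| beats its shuffle null
*and* zero lies inside the speed coefficient's 95% CI. This veto is
conservative: a genuine place field on the running path can correlate with
speed and be rejected; time-bin autocorrelation also makes the speed CI
slightly narrow.

## Decoding

Spike decoding trains a linear-kernel SVM per 50 ms count bin under 10-fold
stratified cross-validation, scaling features on training folds only; the
headline number is the mean accuracy from touch onset to +400 ms. Per-bin
retraining (rather than cumulative windows) is the default. Whisker-angle
decoding expands each per-frame angle (−20 to +100 frames at 240 fps) in a
cubic B-spline basis with knots at training-set quantiles and fits a
logistic regression over the concatenated expansions — a smooth additive
classifier — reporting the held-out (20%) ROC with pointwise 95% CIs and an
AUC CI from 100 bootstrap resamples. Calcium decoding uses a compact
convolutional network on neurons × 24-frame snippets: two blocks of 3×3
same-padding convolution, batch normalization, ReLU, and 2×2 max pooling,
then a fully connected layer with two outputs and softmax, trained 100
epochs with SGD momentum 0.9 at learning rate 0.01 (momentum coefficient
chosen as the standard default), implemented directly on numpy with full
seeding. Chance-level controls permute labels before training; calibration
fixtures use `balance_classes` so chance is exactly 0.5 (with imbalanced
labels a classifier's majority bias shifts apparent chance to the majority
fraction).

## Synthetic experiments

The generator emulates the study conditions: stage-ruled trials with
equal-probability aperture draws; a parametric learner whose lick
probabilities follow logistic trajectories (defaults: go 0.85→0.95, no-go
0.80→0.05, midpoint 400 trials, rate 0.01/trial) with an optional ≥5-fold
insight step; 240 Hz whisker angles with 14.5 Hz whisking bouts (sinusoid
amplitude 15°, alternating 0.5–2 s bouts, sub-3° quiescent jitter,
touch-locked deflections); 60 Hz run–pause locomotion at 200 mm/s on the
±410 mm track; inhomogeneous-Poisson spikes thinned at 1 ms (0.5 ms in the
orchestrated pipeline, whose randomly stacked gains can exceed 100 Hz) with
rate = baseline × touch gain (rectangular 200 ms) × locomotion gain ×
von-Mises angle factor (the 0–180° range mapped onto a full circle) ×
(1 + (Amp/baseline)·cos(φ − φ_pref)) × (1 + place Gaussian), clipped at 0;
and calcium ΔF/F as spikes convolved with a double-exponential kernel
(rise 50 ms, decay 500 ms) plus Gaussian noise at 30 Hz. Every stream draws
an independent sub-seed from the master seed, so identical configurations
reproduce bit-identically. Trial timing statistics are not constrained by
the task design beyond ordering; inter-trial intervals default to
Uniform(5, 15) s with touch 0.5 s after the beam, configurable.

What the synthetic data do not emulate: non-Poisson spike-train structure
(bursting, refractoriness beyond thinning resolution), whisker
biomechanics and multi-whisker asynchrony, tracking noise and dropped
frames beyond simple jitter, calcium indicator nonlinearity and neuropil
contamination, and electrode drift. Passing recovery and calibration tests
therefore establishes correctness of the estimators under their stated
assumptions, not robustness to every artifact of recorded data.

## Problem sizes and numerical choices

Calibration suites use 200 simulated homogeneous units with 100 shuffles
each on a ~300 s session; recovery runs use ~600 s sessions at 10 Hz
baseline; decoding checks use 200 trials with 8–10 units. The orchestrated
demonstration run uses 60 trials, 5 ephys and 10 calcium units — sizes
chosen so a complete run finishes in seconds while every statistic remains
well-estimated. Curve fits use multistart (20 random starts for the
behavioral fits; a (μ, σ) grid for the place field) with non-convergence
reported as flagged results rather than exceptions. All times are seconds
internally (ms only in reports), positions mm with 0 at the middle beam,
spatial bins half-open [lo, hi).

## Known limitations

The event-list dialect is a documented stand-in (the acquisition system's
exact schema is not public); a `touch` device token carries video-derived
contact times. The uncorrected latency scan admits ~5% of bins under the
null by construction. The Kuiper test and the speed-coefficient veto have
the caveats noted above. The CNN is intentionally minimal and CPU-bound; it
is suitable for the few-hundred-trial regime, not large imaging datasets.
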