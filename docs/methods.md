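# Methods

This note records the models implemented, the defaults and why they were
chosen, the numerical decisions that affect results, and the limits of
what the synthetic-data validation demonstrates.

## Standing: stabilogram diffusion analysis

The COP trajectory is low-passed (Butterworth, design cutoff 15 Hz,
order 2) before analysis.  The filter is applied forward–backward
(zero-phase), the posturography norm, so sway geometry is not phase
distorted; the quoted order/cutoff describe the single pass and the
effective attenuation order doubles.

The mean square displacement is computed for *every* integer sample
interval m up to `sda_max_dt_s` (default 2 s): for interval m the
average runs over all N − m ordered sample pairs.  Per-axis and planar
curves are returned; the planar curve equals the sum of the axis curves
by construction, and this identity (and its consequence
D_rs = D_xs + D_ys under a shared fit window, by linearity of least
squares) is asserted to 1e-9 throughout the test-suite.

Short-term coefficients are half the ordinary least-squares slope of the
MSD-vs-Δt line inside the fit window.  The fit is in linear space (slope
of the displacement-squared-versus-interval plot).  The window default
is **0.02–0.5 s**: the short-term (persistent) regime of quiet standing
ends below one second, and the first sample interval (0.01 s at 100 Hz)
is excluded as the most filter-affected point.  This window is the
largest analytic choice the method leaves open, so it is exposed in
configuration, and when the two-regime changepoint falls inside the
window the fit is truncated at it.  Negative fitted slopes (possible on
short, heavily saturated trials) are reported as-is with a flag and
excluded from the log transform — clamping would distort the estimator
distribution that the recovery tests check.

The critical point between regimes is the breakpoint of a continuous
two-segment linear fit (`msd ~ b0 + b1·Δt + b2·max(Δt − b, 0)`) scanned
over every interior grid point; it is reported only when the two-segment
model reduces the residual sum of squares of the single line by at least
5 %.  An exactly linear curve (residuals at numerical zero) reports no
breakpoint.

Sway ranges are per-axis max − min; SRD = ML − AP.  Diffusion
coefficients are additionally reported as natural logs (`ln_*`) because
their sampling distribution is strongly right-skewed; non-positive
values are logged as missing.

## Walking: events, step metrics, divergence exponents

### Heel-strike detection

All detection operates on 10-point moving-average-smoothed channels
(centered windows, shrinking at the edges so length is preserved; for
even windows the span is left-heavy by one sample).  Candidate events
are contiguous excursions of smoothed Fz above body weight with peak
prominence ≥ 10 % of body weight.  Body weight comes from metadata when
present, otherwise from the median of Fz across the trial — over many
gait cycles the net vertical impulse balances weight.

A surge qualifies only when a rapid COPX change precedes it: the robust
rate criterion is |dCOPX/dt| > 3 × MAD(dCOPX/dt) within a look-back
window of 0.4 × (median step period) before the surge onset.  The step
period is estimated spectrally (dominant COPX stride frequency between
0.2 and 2 Hz, halved), which is robust before any events exist.  The
event sample is the maximum of the smoothed *centred* derivative of Fz
between surge onset (preceding local minimum) and surge peak — centred
differentiation with an odd smoothing window avoids the half-sample bias
of one-sided differences.  The COPX shift direction at its fastest point
labels the side (+X rightward ⇒ right heel-strike; the sign convention
is arbitrary and documented in `io_config`).  Side-alternation
violations are flagged, never silently repaired.  A record whose Fz
never exceeds body weight (quiet standing) raises a detection error.

### Step metrics

Step time is the interval between consecutive heel-strikes; step width
is the absolute COPX difference at consecutive strike instants.  Because
a single treadmill plate records only the net COP, this width is a proxy
for lateral foot placement biased by the double-support blend; it is
accurate when sampled at weight acceptance, which the event convention
guarantees.  The first and last 10 steps of each trial are excluded, and
centre/spread are median and MAD — a single missed or spurious event
produces one gross outlier step, which these statistics ignore.

### Divergence exponent λ\*

Each channel is processed separately:

1. smooth (10-point moving average, same series as detection);
2. stride segmentation by same-side (default right) heel-strikes;
3. cubic-spline time-normalization to 200 points per stride on an
   endpoint-exclusive grid (concatenated strides tile normalized time
   without duplicating boundary samples); natural spline boundaries;
4. central 150 strides (ties toward the trial start);
5. delay from the first minimum of lagged mutual information;
6. delay embedding at fixed dimension 5 (false-nearest-neighbour
   diagnostics are provided to check sufficiency, but the pipeline
   dimension is fixed by configuration);
7. Rosenstein average-log-divergence curve: exact nearest neighbour per
   state (k-d tree) outside a Theiler window of one stride (200
   samples), mean natural-log pair distance tracked over forward lags
   (default 10 strides), pairs truncated at the series end;
8. least-squares slope over the curve's 10–90 % magnitude range,
   converted to per-stride units (slope per sample × 200).

**Mutual information estimator.**  Histogram MI with ⌈√(N/5)⌉
equal-width bins.  Equal-width (not equiprobable/rank) binning matters:
rank binning makes the estimate a pure copula functional, which for
deterministic signals is dominated by discretisation artifacts (for a
noiseless sine it produces a local *maximum* at quarter period), and it
scatters tied values of flat-topped signals across bins.  The MI profile
is smoothed (11-lag moving average) and the first strict local minimum
that persists below the following 10 lags and dips below MI(lag 1) by
more than the histogram bias scale (B−1)²/2N is taken.  Fallbacks, in
order: first drop below MI(1)/e; the smoothed profile's global minimum
(deterministic signals whose MI never collapses); lag 1.  With this
estimator the sine first minimum lands within 10 % of quarter period and
white noise falls through to the fallbacks.

**Fit region.**  The curve is min–max normalized only to locate the fit
region — first attainment of 10 % up to first attainment of 90 % of the
range — and the slope is fitted on the raw curve, so λ\* keeps absolute
units and is invariant to positive channel rescaling (log distances
shift by a constant) and to curve offsets.  Anchoring the upper bound at
first attainment avoids the fluctuation-chasing that plagues
fixed-time-window fits of these curves.

**Degenerate inputs.**  Pairwise distances are floored at 1e-6 × RMS of
the state matrix: separations below that scale are floating-point and
interpolation texture, not dynamics.  A curve that never rises above
100 × that floor carries no resolvable divergence and is reported flat
(λ\* = 0, flagged); likewise an exactly constant curve.  In
false-nearest-neighbour searches, neighbours below the floor (duplicate
states, common in noiseless periodic signals sampled commensurately) are
skipped, with the neighbour list widened adaptively.

**Units.**  λ\* is reported per stride: time-normalization fixes 200
samples per stride, making the stride the natural unit, and it is the
gait-literature convention.  For signals sampled in physical time, pass
`samples_per_unit = round(1/dt)` to obtain per-second units (this is how
the Lorenz anchor is evaluated).

### Known-system anchor

The divergence chain is validated on the Lorenz system
(σ=10, ρ=28, β=8/3; x-coordinate at dt = 0.01): the Rosenstein slope is
compared against a fully independent Benettin tangent-space integration
(fixed-step RK4, renormalized every 0.1 time units), which reproduces
the canonical λ₁ ≈ 0.906 nats per unit time for these parameters.  The
two routes agree within ~5 % at the default sizes.

### Sensitivity of λ\* to additive sensor noise

Because the divergence curve is a mean of *log* distances, a noise floor
enters as an additive constant: pure rescaling cannot change the slope.
What additive measurement noise does change is the mixture between the
fast noise-decorrelation rise at the bottom of the curve and the slower
intrinsic divergence above it.  With the magnitude-anchored 10–90 % fit,
raising the floor compresses the climb from below, and the measured λ\*
*decreases* monotonically with the noise level (measured on the default
gait conditions, medians over 10 seeds at 1/2/4/8 % of signal range:
0.50, 0.48, 0.47, 0.47 per stride).  An *increase* with noise — often
assumed from fixed-time-window fits over the first stride — does not
occur under the magnitude rule.  Interpretation for practice: λ\*
differences between recording setups with different noise floors are
biased toward zero, not inflated.

## Synthetic data: what it emulates, what it does not

`gen_sway` draws per-axis increments of variance 2D/fs (pure Brownian)
or filters them through a discrete Ornstein–Uhlenbeck recursion.  For a
requested regime-switch interval, the OU relaxation timescale is
calibrated (root-finding) so that the two-segment breakpoint of the
*analytic* MSD curve 2Dτ(1 − e^(−Δt/τ)) falls at the requested interval;
the generated trials then scatter around that truth.  The axes are
independent: ML–AP coupling, drift, and non-stationarity of real stance
are not modelled.

`gen_gait` constructs the **net** (whole-body) vertical GRF directly as
BW·(1 + g_i·p(φ)) with a zero-mean per-step profile p: a steep
weight-acceptance rise just after the strike, an M-shaped top peaking
near 1.19 BW, and a trough near 0.89 BW, so each cycle integrates to
body weight (within 2 %) and crosses body weight exactly once.  Summing
per-foot stance profiles with double-support overlap — the obvious
alternative — cannot satisfy impulse balance with a single
body-weight crossing per step; since the instrument records only the
net force, the net profile is modelled directly and per-foot force is
not represented.  COPX alternates between ±width/2 with a smooth
anticipatory transition ending just before each strike, plus a 2 mm
phase-locked ripple (real COP is never piecewise-constant, and exactly
flat segments are degenerate under delay embedding); per-step width and
duration are drawn around their programmed means.  COPY sweeps forward
each step with a cosine flyback (treadmill butterfly).  Cycle amplitudes
of Fz and COPY are optionally modulated by 1 + chaos_gain·z_i with z
from a logistic map at r = 3.9 — a deterministic, seeded source of
genuinely diverging cycle dynamics, far cheaper than integrating a
continuous chaotic system.  Sensor noise is Gaussian, scaled to channel
range.

Ground-truth strike times use the same convention as the detector — the
maximal-inclination instant of the noiseless net Fz, an analytic phase
of the profile — so detection scores measure noise-induced jitter, not
convention mismatch.

Defaults are steady adult treadmill walking: 700 N body weight, cadence
110 steps/min, step width 100 ± 6 mm, step-time SD 12 ms, sensor noise
2 % of channel range, chaos gain 0.2.  The chaos default is deliberately
non-zero: human gait exhibits λ\*_Fz of roughly 0.5–1.5 per stride, and
a strictly periodic default would make divergence analyses of "typical"
synthetic trials degenerate.

What passing recovery tests do **not** show: the generator has no
musculoskeletal content (no double-support force sharing, no kinematic
variability structure, no drift or non-stationarity), so validation here
demonstrates correctness of the estimators on signals with known
structure, not fidelity of any biomechanical model.  Real-data effect
sizes cannot be reproduced synthetically; condition effects in
`gen_experiment` illustrate orderings, they do not emulate human
condition contrasts.

## Exactly periodic inputs and sampling

A subtlety worth recording: "noiseless periodic" gait is only periodic
*after sampling* when the step duration is an integer number of samples.
At incommensurate cadences, ±1-sample rounding of stride boundaries
injects a small (~1 % amplitude) stride-to-stride texture that the
divergence estimator correctly reports as divergence.  Periodicity
anchors therefore use a commensurate cadence (112.5 steps/min at 300 Hz,
160 samples per step) and generator-truth strike indices; with those,
all three channels report λ\* = 0 exactly (flat curves at the numerical
floor).

## Scaled problem sizes

Full-scale analyses use 150 strides and a 10-stride divergence window.
The test-suite and the acceptance script run some replicated experiments
at reduced sizes chosen once for desk-scale iteration — 30–60 strides
with a 5-stride window for λ\* replicates, 10-second sway trials for I/O
and batch tests — while the single-trial checks (detection, periodic
anchor, condition ordering, SDA recovery) run at full scale.  Reduced
sizes raise estimator variance but change no estimator definition.

## Limitations

- Step width from net COP underestimates true foot-placement width and
  blends double-support dynamics; treat absolute widths with caution.
- The SDA fit window and the MSD changepoint interact on strongly
  saturating trials; inspect `critical_point` and `r2_r` before pooling.
- λ\* from 150 strides is a finite-time estimate with seed-level
  variance of order ±0.05 per stride at the default conditions; compare
  conditions within, not across, processing configurations.
- The MI-based delay is estimated per channel and per trial; delays for
  the same channel can differ across trials, which is intended (the
  embedding adapts), but makes λ\* values comparable only through the
  shared fit convention.
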