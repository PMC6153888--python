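# Methods

This note records the scientific and numerical choices behind `distaniso`:
what each component models, which assumptions it makes, and what the
simulation studies in the test suite do and do not establish.

## Motion profiles

The *target* translation uses a raised-cosine velocity profile,
v(t) = (D/T)·(1 − cos 2πt/T), so acceleration is sinusoidal with peak
2πD/T² and the motion is rest-to-rest by construction. With the task's fixed
T = 3 s, the peak ranges from 0.35 m/s² (D = 0.5 m) to 1.05 m/s²
(D = 1.5 m).

The *test* translation accelerates along the first half of a sinusoid
(a(t) = A sin πt/t1, peak A) and then decelerates at a constant rate d until
it halts. Rest-to-rest closure fixes two identities — the peak velocity
v1 = 2·A·t1/π must equal d·(T − t1), and the total distance is
S = A·t1²/π + v1·(T − t1)/2, which simplifies to **S = A·t1·T/π**. The
acceleration-phase duration t1 is therefore available in closed form from
any two of (A, d, S) plus T; both solvers (`solve_test_profile` from
(A, T, S), `solve_test_profile_from_decel` from (A, d, T)) are exact to
machine precision. With A = 1.55 m/s², T = 5 s, S = 2.5 m this gives
t1 ≈ 1.013 s and d ≈ 0.251 m/s².

Profiles are sampled on a uniform grid (default 1000 Hz) with analytic
velocity and position series; the trapezoid-rule integral of the sampled
acceleration reproduces the stored velocity with error shrinking as
1/rate². Translation direction is a label, never a signed kinematic
quantity: the same profile serves every direction.

## Synthetic cohorts

The generator emulates the experiment's structure: 24 participants × 2 body
orientations (upright, 30° backward pitch) × 12 sagittal directions (−150°
to 180° in 30° steps) × 6 distances (0.5–1.5 m), organised in 12 blocks of
12 trials with the orientations in separate halves and counterbalanced
order. The block structure is reproduced for realism but carries no
generative effect.

**Error structure.** Each participant's expected absolute error follows one
of the five model variants, scaled by a single multiplicative log-normal
random effect exp(participant_sd · z_i) applied to all weights (median 1).
Defaults: horizontal–vertical anisotropy with w_h = 0.36 m, w_v = 0.40 m
(the magnitudes this paradigm is designed to resolve) and
participant_sd = 0.2 — a ±20% between-participant spread in overall error
level, typical of psychophysical cohorts and still identifiable from 20
participants. The anisotropy is **body-fixed** by default: in the pitched
orientation the generative error curve follows body-frame directions
(earth direction − 30°).

**Noise calibration.** The analysis models expected *absolute* error, so
the generator draws a zero-centered signed error whose absolute value has
exactly that mean. For an unbounded normal this is the folded-normal
identity σ = μ·√(π/2). Responses, however, live on the test translation's
path [0, 2.5 m]; a hard clip would push mean absolute errors below μ at
short target distances (by up to ~0.04 m at D = 0.5 m) and propagate into
every downstream estimate. Signed errors are therefore drawn from a normal
truncated to [−D, 2.5−D] with the scale solved per trial (vectorised
bisection, exact to ~1e-12) so that E|error| = μ(α) holds on the bounded
support as well. When μ exceeds ~99% of the truncation-limited supremum
(lo²+hi²)/(2(hi−lo)) — extreme random-effect draws, well under 1% of trials
— the scale is capped and the achieved mean falls slightly short. The
signed-error distribution is an assumption: the paradigm constrains only
the mean absolute error, not the shape.

**Duration-strategy participants** (default 4 of 24) press at a
participant-specific anchor time (uniform 2–4 s into the test translation)
with 0.15 s Gaussian jitter; the press time is converted to distance through
the test profile's position curve, yielding responses unrelated to the
target distance.

What the generator does *not* model: vestibular transduction (otolith
dynamics, detection deadbands), response biases (signed error is
mean-calibrated, not bias-calibrated), learning or fatigue across blocks,
and any direction-dependence of the *response* noise beyond what the error
model implies. Passing recovery tests therefore show that the pipeline is
consistent under its own assumptions — not that real data satisfy them.

## Exclusion rules

Participants are screened first, then trials; the order is part of the
contract because outlier bounds computed before screening would be polluted
by duration-strategy participants. The screen tests the Pearson correlation
between target and reproduced distances per participant (two-sided, n−2 df)
and excludes when p ≥ .05 or r ≤ 0; requiring a *positive* correlation is
this package's reading (an inverse responder has not reproduced distance).
Constant response vectors have no defined correlation and are excluded with
a logged reason. The trial rule then removes trials whose absolute error
deviates more than two sample standard deviations from the participant's
overall mean — pooled over both orientations and all directions, applied
once (not iterated). For zero-mean Gaussian signed errors the folded-normal
two-SD tail holds ~4.5% of trials, matching the ~4–5% removal rate the rule
produces on simulated cohorts.

## Mixed-effects fitting and model comparison

Direction enters continuously through sin/cos projections. The working
model is y_ij = exp(b_i)·μ(α_ij; w) + ε_ij with b_i ~ N(0, τ²) and Gaussian
ε. The single multiplicative random effect (rather than per-weight random
effects) is deliberate: per-weight effects are not identifiable from ~20
participants × 72 trials. The Gaussian residual on a non-negative response
is a known support mismatch, retained because it is the standard
nonlinear-mixed-effects practice this analysis replicates; two alternative
Gaussian variance structures (residual sd scaled by exp(b_i), or by
exp(b_i)·μ_ij) are available via `residual_scaling` and give practically
identical weight estimates on simulated cohorts. The isotropy null uses the
same multiplicative structure on a constant intercept, i.e. a log-normally
scaled random intercept.

For fixed parameters the conditional sum of squares is quadratic in
exp(±b), so each participant contributes three sufficient statistics and
the marginal likelihood is integrated by **adaptive Gauss–Hermite
quadrature** (15 nodes) around the per-participant mode, found by
safeguarded Newton iterations. Estimation is ML (not REML) so AICc
comparisons across fixed-effect structures remain valid. The optimiser is
multi-start L-BFGS-B (5 starts: a moment-based start, one start at the
no-random-effect boundary to handle degenerate data, and jittered
restarts), weights kept non-negative by absolute-value reparameterisation
and variances by log-parameterisation with sd bounds [1e-6, ~150];
best-likelihood wins and non-convergence is flagged, never silent.

k counts fixed weights + random-effect variance + residual variance
(isotropy 3, hv 4, ud/fb 5, fbud 6). Comparisons refuse fits whose
observation count or data checksum differ. Fitting is done separately per
body-orientation condition (upright; pitched coded earth-centered; pitched
coded body-centered), mirroring how such designs are reported.

**Finite-sample behaviour.** ML variance-component estimation is biased
downward in small samples, and the skewed generative residuals interact
with the multiplicative random effect, so at the design's scale (20
participants, 72 trials each) replicate means of the fitted weights can sit
slightly below truth — a sub-percent effect that the recovery tests bound
at 3 Monte-Carlo standard errors of the replicate mean.

## Reference frames

Body angle = earth angle − pitch, wrapped to (−180°, 180°] so the
12-direction grid maps onto itself for pitch multiples of 30°; the wrap
convention matters because −180°/180° aliasing would silently mispair one
bin. Error patterns are participant-averaged per direction bin before
correlating (12 pairs), and the two codings of the pitched pattern use
identical data re-indexed, which the tests assert directly. The p-value
uses the t distribution with n_pairs − 2 = 10 df; results are reported as
r(12) with the pair count exposed, following the field's habit of indexing
r by the number of pairs rather than df.

At the experiment's scale the frame test is strongly attenuated: the
anisotropy signal (≈0.04 m between axes) is comparable to direction-bin
noise, so single-cohort correlations scatter widely, and discrimination
(body > earth) emerges reliably only in replicate means — consistent with
modest empirical correlations in this paradigm.

## Stimulus-noise audit

Recorded traces are low-passed with a 4th-order Butterworth at 80 Hz
applied forward–backward (zero phase; only the cutoff is prescribed by the
procedure, order and realisation are this package's choice) and
gravity-corrected by subtracting each axis's mean over the recording. SNR
is the squared ratio of the rms commanded-vector norm to the rms norm of
the commanded-minus-recorded difference; repeats are averaged on the SNR
scale, not in dB. Perfect recordings yield an `inf` sentinel, all-zero
commands yield 0.

Differential thresholds: ΔI = 0.05·I + 0.03 (horizontal),
0.19·I^0.60 (upward), 0.17·I^0.42 (downward); oblique directions combine
the terms in quadrature weighted by cos α / sin α with the opposite
vertical term zeroed. As printed, the combined formula does not reduce to
the pure-vertical functions at ±90° (the 0.03 horizontal offset persists
inside the root) and makes the horizontal term (−0.05·I + 0.03)² at pure
backward; the default mode therefore routes pure-axis angles through the
single-axis functions with unsigned intensity (the physically coherent
reading), while `mode="literal"` evaluates the combined formula exactly as
printed everywhere. The audit takes each target stimulus's noise rms as the
intensity I, takes the lowest threshold across a direction's stimuli, and
flags the |target − test| noise-rms difference as sub-threshold when it
falls below that minimum. Synthetic IMU recordings (commanded = profile
acceleration projected on the sagittal unit vector; recorded = commanded +
iid per-axis Gaussian noise) validate the procedure end to end; real
hardware effects (vibration spectra, axis cross-talk, drift) are out of
scope.

## Problem sizes in the test suite

The simulation studies use 100 replicates per condition at the design's own
scale (20–24 participants, 144 trials each): parameter recovery and
model-selection power under horizontal–vertical truth, model selection
under isotropic truth, and frame discrimination with body-fixed anisotropy.
SNR and calibration checks use 10⁴-sample recordings and ~2000-trial cells.
The full suite runs in a few minutes on one CPU.

## Known limitations

- The Gaussian-on-absolute-error working model mismatches the response's
  support and skew; weight estimates inherit a sub-percent finite-sample
  bias at n = 20 participants.
- The generator injects noise at the level of reproduced distance; it is
  silent about mechanism (sensory vs memory vs decision noise).
- The frame-correlation test assumes the head follows the trunk (body =
  head frame), appropriate when the head is restrained.
- AICc-based selection at this signal-to-noise level has modest power;
  refined variants (ud/fb/fbud) are frequently indistinguishable from their
  parent by the dAICc < 4 rule, which is itself a convention.
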