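# distaniso

Tools for studying **anisotropy in human traveled-distance estimation**: do
people encode how far they moved with equal accuracy along every spatial
axis, or are horizontal translations represented more faithfully than
vertical ones — and is that pattern anchored to the body or to gravity?

The package targets the distance-reproduction paradigm used with motion
simulators: a blindfolded observer is translated over a *target* distance
(0.5–1.5 m) along one of 12 directions in the sagittal plane, then presses a
button during a standardised *test* translation when they feel the same
distance has been covered. It provides, as a plain Python library:

- **Motion profiles** (`distaniso.motion`) — the raised-cosine-velocity
  target translation and the half-sinusoid-plus-constant-deceleration test
  translation, with closed-form rest-to-rest solvers and CSV export.
- **Synthetic cohorts** (`distaniso.cohort`) — trial tables with the full
  within-participant design (2 body orientations × 12 directions × 6
  distances), a multiplicative participant random effect, calibrated
  direction-dependent noise, and a minority of "duration-strategy"
  participants whose responses ignore distance.
- **Exclusion rules** (`distaniso.preprocess`) — the participant correlation
  screen and the per-participant ±2 SD trial-outlier rule, plus
  per-direction error patterns.
- **Error models** (`distaniso.models`) — the isotropy null and four
  anisotropy models fitted as nonlinear mixed-effects models and compared by
  AICc.
- **Reference frames** (`distaniso.frames`) — earth↔body direction
  relabeling and the correlation test that separates body- from
  earth-centered anisotropy.
- **Stimulus-noise audit** (`distaniso.noise`) — signal-to-noise ratios of
  commanded vs recorded accelerations, Weber-type differential thresholds,
  and the sub-threshold check, validated on synthetic IMU traces.
- **Pipeline & CLI** (`distaniso.pipeline`, console script `distaniso`) —
  simulate → screen → clean → fit → compare → frame correlations, fully
  reproducible from a config and one seed.

## The model

For a translation at angle α in the sagittal plane (0° = forward,
90° = up), the expected absolute reproduction error under the
horizontal–vertical anisotropy model is

    E|error|(α) = sqrt( (w_h · cos α)² + (w_v · sin α)² )

with non-negative weights `w_h`, `w_v` (meters): the expected error on a pure
horizontal / vertical translation. Refinements split the horizontal weight by
travel sense (`w_f`, `w_b`), the vertical weight by sense (`w_u`, `w_d`), or
both; the quadrature form makes equal weights collapse each refinement onto
its parent, and the isotropy null is a constant intercept. Each model is
fitted by maximum marginal likelihood with a participant-level multiplicative
random effect,

    y_ij = exp(b_i) · E|error|(α_ij) + ε_ij,   b_i ~ N(0, τ²),

integrated by adaptive Gauss–Hermite quadrature, and candidates are ranked by
the small-sample Akaike criterion AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1), with
dAICc < 4 treated as indistinguishable.

## Worked example

```python
import distaniso as da

table = da.simulate_cohort(da.CohortConfig(seed=2))   # 24 participants, 144 trials each
kept, report = da.screen_participants(table)          # drops the 4 duration-strategy members
upright = kept[kept["orientation"] == "upright"]

fits = [da.fit_mixed_model(upright, v, seed=2) for v in da.VARIANTS]
print(da.compare_models(fits)[["variant", "aicc", "daicc", "best"]])
```

prints

```
 variant       aicc    daicc  best
      hv 656.904997 0.000000  True
      ud 658.019807 1.114810 False
      fb 658.835132 1.930135 False
isotropy 659.451746 2.546750 False
    fbud 659.950133 3.045136 False
```

The horizontal–vertical model wins, and its fitted weights
(`w_h` ≈ 0.371 m, `w_v` ≈ 0.416 m) recover the generative anisotropy
(0.36 / 0.40 m): vertical translations carry the larger expected error. The
same cohort's reference-frame test (`examples/04_reference_frame.py`) gives
a body-centered correlation r(12) = +0.54 against an earth-centered
r(12) = +0.06 — the accuracy pattern rotated with the pitched body.

Each script in `examples/` demonstrates one capability end to end and prints
a short interpretation: motion profiles, simulation + screening, model
comparison, reference frames, and the noise audit.

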