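# Methods

## Signal model and geometry

The package analyses multichannel unipolar electrograms u_ij(t) recorded
on a regular rows × cols electrode array (default 8 × 16 at 1 mm pitch,
128 electrodes; 1000 Hz sampling). Rows are lettered from the top, so
the vertical bipole u_A1 − u_B1 points along +y; x grows with the column
number; the origin is the bottom-left electrode. All amplitudes are
handled internally in µV and all distances in mm.

A *clique* is a square 2×2 cell of electrodes at side k·pitch
(k = 1…4 by default, realised by index subsampling of one fixed array;
all overlapping cells are kept). Within a cell the corner roles
A1/A2/B1/B2 are the cell's own, independent of the global labels. The
five configurations build one orthogonal bipole pair each: the four
triangles subtract along two adjacent edges; the cross subtracts along
the diagonals and rotates the result by +π/4 counter-clockwise into the
Cartesian frame. The rotation is orthonormal: per-sample norm and total
energy of the pair are preserved, while the *electrode separation*
underlying the cross bipoles is √2 times the cell side — the package
reports this separation per row so the √2 spacing penalty is visible in
outputs.

## Omnipole estimation

The omnipole ô(t) is the projection of the bipole pair along the
wavefront, found by maximising the ratio of the signed peak of the
projected signal to the peak absolute value of the orthogonal
projection. The objective is evaluated on one activation window at a
time. Numerical choices:

- **Search**: coarse 1° grid over [−π, π), then a 0.01° fine grid spanning
  ±1° around the coarse optimum, then bounded scalar maximisation inside
  the best 0.02° bracket. The objective is piecewise smooth (the argmax
  sample switches discontinuously), so grid-first is safer than gradient
  descent; the returned angle never scores below the fine grid's best
  point, which is how the exhaustive-search equivalence is guaranteed.
- **Degenerate inputs**: a pair identically zero in the window raises a
  degenerate-input error. A residual below 10⁻⁹ × the bipole amplitude
  scale (perfectly aligned noiseless input) is floored, so the ratio is
  reported as a large capped value with a `capped` flag instead of a
  division crash. Capped ratios are flags, not measurements, and are
  excluded from aggregated ORR statistics.
- **Direction convention**: rotating the frame by θ_o aligns +x with the
  wavefront, so the propagation direction is −θ_o, reported in degrees
  in [0, 360). Because the numerator is a *signed* maximum, antiparallel
  directions are distinguished: flipping the waveform polarity flips the
  recovered direction by exactly 180°.

## Reliability metrics

- **ORR** = max(ô)/max|r| over the activation window (signed numerator,
  absolute denominator), with the same epsilon guard as above.
- **NLA**: the bipoles are normalised by the peak omnipole amplitude and
  the loop they trace in the b_x–b_y plane is integrated as
  ½ Σ |xₙ·Δyₙ − yₙ·Δxₙ| with the endpoint closed — a trapezoidal rule on
  the magnitude of the surface element, i.e. the area swept by the
  electric-field vector about the origin. Taking the magnitude per
  element is deliberate: an ideal planar wave seen by a cross clique
  traces a curve that is swept out and retraced, whose *net* signed area
  cancels identically, which would make the metric blind exactly where
  it is needed. The magnitude form returns 0 for trajectories collinear
  through the origin, the enclosed area for origin-interior star-shaped
  loops (where it equals the shoelace formula), and needs no
  triangulation of the interior. NLA is invariant to joint positive
  rescaling of (b_x, b_y, ô).
- **PW**: time between the first and last crossings of
  threshold × peak(ô) inside the window (threshold 0.5, i.e. FWHM, by
  default; exposed as a parameter), with linear sub-sample interpolation
  at both edges. Using first/last rather than nearest-to-peak crossings
  makes the widening caused by delayed-subtraction notching and pulse
  splitting measurable.
- **MD**: per-electrode reference derivatives o_ij = −du_ij/dt (central
  differences scaled to µV/ms, no smoothing by default) are aligned to
  the first corner by integer-lag cross-correlation (lags above half the
  window flag an alignment failure) and averaged; averaging four
  independent channels roughly halves the noise floor. The estimate and
  the reference are then each normalised by their own peak absolute
  amplitude, aligned at their dominant peaks, and compared by RMSE over
  the overlapping samples. MD is dimensionless (both inputs are
  normalised first); overlap-only RMSE keeps it symmetric under argument
  swap. Peak alignment (rather than a second cross-correlation) is used
  for this final comparison because the reference construction already
  consumed a cross-correlation; both modes are exposed.

Metrics are computed per activation window and aggregated as
mean/SD/median/IQR per (configuration, spacing, metric). Statistical
modelling across recordings (mixed models, post-hoc contrasts) is
intentionally not implemented; the tidy table carries recording, angle,
clique and beat identifiers so an external statistics environment can
fit such models directly.

## Synthetic generator

`generate_planar_wave` emulates a paced, healthy-tissue epicardial
recording: a planar wavefront with direction Ψ_w and conduction velocity
v sweeps the array, and every electrode sees one identical biphasic
template per beat, delayed by τ(x, y) = (x cos Ψ_w + y sin Ψ_w)/v.
Delays are applied in continuous time (the template is a closed-form
function), so sub-sample delays are exact. Defaults, chosen once as the
package's study conditions:

| parameter | default | rationale |
|---|---|---|
| template | Gaussian-derivative, σ = 2 ms, 1 mV peak | biphasic single-deflection morphology; −dw/dt is a positive Ricker pulse, matching the monophasic omnipole the metrics assume; the resulting pulse widths (≈2.6–6 ms FWHM) are in the physiological range |
| velocity | 0.5 m/s | typical epicardial conduction velocity |
| pacing | 4 Hz, 3 beats, no jitter | ventricular pacing rates used experimentally; beats at exact period multiples |
| noise | white Gaussian, sd 20 µV per channel | a clean but not ideal recording (≈34 dB vs the unipolar peak); an optional common-mode sinusoid exercises the averaging noise rejection |
| fs | 1000 Hz | matches the acquisition rate emulated |

A circular wavefront from a point source is available
(τ = ‖(x, y) − source‖/v) and converges to the planar delays as the
source recedes. `noise_sd_for_snr_db` converts an SNR target to a noise
sd using the standard power-ratio definition, with the signal RMS taken
over the template support (±5σ).

What the generator deliberately does *not* model: reaction–diffusion or
ionic tissue dynamics, wavefront curvature or collision within the
array, fibrosis/scar, electrode contact variation, baseline wander.
Consequently the synthetic benchmark is *more* favourable than real
recordings in specific, known ways: ideal planar propagation gives the
cross clique near-line loops (NLA far below experimentally observed
values) and very high ORR at 1 mm, and direction recovery is limited
only by finite-difference geometry and noise. Passing trend tests here
demonstrates the algorithmic machinery, not clinical performance.

## Known limitations and measured behaviour

- **Finite-difference direction bias.** With the default template width
  (σ = 2 ms) and velocity (0.5 m/s), corner-to-corner delays at 1 mm
  spacing are 2–2.8 ms — comparable to σ. Difference pulses then scale
  sublinearly with delay, which tilts the electric-field loop's major
  axis by up to ≈4° at intermediate wavefront angles. This is a property
  of the physics, not the estimator: the identical code recovers every
  angle to within 0.4° (the 1 kHz peak-sampling floor) when delays are
  small relative to the template width. The bias shrinks with faster
  conduction, wider deflections or finer pitch.
- **Angle-averaged NLA saturation.** Triangular-clique NLA grows with
  spacing up to ≈3 mm and then flattens or dips: once activation pulses
  split, the normalising ô peak keeps growing while the loop excursion
  does not. The cross clique's four metrics degrade monotonically over
  1–4 mm.
- **ORR noise floor.** At 1 mm the residual of well-aligned
  configurations is noise-dominated, so with the default noise level the
  angle-averaged triangle ORR can peak at 2 mm rather than 1 mm; the
  noiseless geometry gives strictly decreasing ORR for every
  configuration.
- Problem sizes used by the default sweep: 24 wavefront angles (15°
  steps), spacings 1–4 mm, all five configurations, a deterministic even
  subsample of 12 cliques per spacing, 3 beats. These sizes give stable
  angle-averaged means while keeping a full sweep under a minute on one
  CPU; all of them are parameters.
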