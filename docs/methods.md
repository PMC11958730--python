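# Methods

`stoscan` is a virtual 4D cone-beam CT (4DCBCT) scanner. It closes the
acquisition loop in software: a breathing thorax phantom produces a
chest-height surrogate signal, a streaming predictor estimates the
respiratory phase a latency ahead, and a gantry controller modulates
rotation speed and gates projections so that the acquired data realizes a
prescribed spatiotemporal structure. The reconstruction chain and the
metrics then quantify what that structure buys. This note records the
models, the parameters that matter, and the design decisions taken where
the design was genuinely open.

## The acquisition model

A scan acquires `N_p` projections over a `theta_arc = 200°` short-scan
arc. The *conventional* protocol (1320 projections, 240 s) spaces
projections evenly in angle and time with no reference to the patient;
at a 4 s breath this guarantees heavy oversampling of every respiratory
bin and projection pairs less than 0.2° apart within a bin.

The *spatiotemporally optimized* (STO) protocols instead target the
interleaved ideal structure: projection `k` at angle
`S_k = k * theta_arc / N_p` with respiratory bin
`j_k = ((k-1) mod N_b) + 1`. Consecutive projections then step through
the breathing cycle, and projections of one bin are spread exactly
`N_b * theta_arc / N_p` apart — 3.3° for the 600-projection arm, 10° for
the 200-projection arm. An STO scan lasts `N_p / N_b` breaths (60 and 20
respectively), and the projection count itself is the leading-order dose
proxy: 55% and 85% fewer projections than the conventional arm.

### Hardware constraint set

The controller respects the constraint set of a clinical linac gantry:
unidirectional rotation, speed at most 6°/s, acceleration at most
2°/s², projections only on the 5.5 Hz trigger grid, and an abort
condition when the speed stays below 0.3°/s. The abort dwell (5 s) is a
package choice: the threshold is a hardware property, the dwell is not
specified anywhere, and a dwell avoids spurious aborts at bin
boundaries. While a scan is in progress the controller never *commands*
less than the abort speed; when a target becomes unreachable (a skipped
breath) the gantry drifts past the ideal angle and the excess appears as
schedule error rather than as an abort — which also reproduces the
empirical signature of irregular breathing: isolated same-bin gaps well
above the target separation.

## Surrogate signal and phantom

The surrogate is an anterior chest-height proxy: per breath,
`y(t) = baseline + drift·t + A_i · ((1 + cos 2πφ)/2)^p` with `φ` the
normalized time since the breath's peak inhale, plus Gaussian sensor
noise. Per-breath periods are drawn from a truncated normal and
amplitudes jittered. Defaults: 4 s ± 0.2 s period, 10 mm excursion with
5% jitter, 0.5 mm/min drift, 0.1 mm noise, 30 Hz sampling. The waveform
exponent `p` defaults to 1 (a plain raised cosine); `p > 1` produces an
exhale dwell but makes the lag-plot phase (below) deviate from
time-normalized phase by up to ±1.5 bins, so the dwell shape is opt-in.
An optional irregular episode (default 20 s) rescales periods by
0.55–1.9× and amplitudes by 0.4–1.3× per breath, emulating stretches of
coughing-like breathing.

Three presets name the study conditions: `REGULAR_BREATHER` (fixed 4 s
period, noise and drift retained) — the reference condition for
closed-loop schedule fidelity, because with breath-to-breath period
variability the time-normalized phase bins of the *current* breath
depend on a period that is unknowable in real time (measured: an
unbiased, ±1-bin, σ ≈ 0.4 bin prediction floor); `VARIABLE_BREATHER`
(the defaults above); and `IRREGULAR_BREATHER` (adds the episode).

Ground-truth phase is defined peak-inhale to peak-inhale, bin 1 starting
at peak inhale, uniformly in time within each breath. The generator
labels analytically; `retrospective_phase_bins` recovers the same
labeling from the signal by peak detection (the scoring reference).

The phantom is a geometric thorax: an elliptical body (230 × 180 ×
240 mm), two lung ellipsoids, a 20 mm tumor (15 mm superior–inferior
motion), a spherical-cap diaphragm dome (25 mm motion), and ~28
vessel-like spheres whose motion amplitude grades from near zero at the
apex to 80% of the diaphragm excursion at the base. The vessels matter:
without intrapulmonary texture, deformable registration has nothing to
carry motion through uniform lung and silently under-recovers it.
Structures are composited with ~4 mm partial-volume (antialiased) edges;
razor-sharp edges at 4 mm voxels would dominate the reconstruction error
budget with ringing that no real scan exhibits. Motion is
superior–inferior by default (the dominant clinical axis), configurable
as a 3-vector; anatomy sits at its reference position at exhale and
descends toward peak inhale (`u = 1`). Attenuations are in 1/mm (body
0.02, lung 0.004, tumor 0.03, diaphragm 0.025); no HU conversion.

## Phase estimation and prediction

Plotting `y(t)` against `y(t - ω)` (lag `ω = 0.5 s`) traces an ellipse
for quasi-sinusoidal breathing, centred at the signal baseline — so
baseline drift moves the ellipse, not the phase. The ellipse is fitted
with a normalized direct least-squares conic fit constrained to
ellipses (an in-package implementation; the scikit-image fitter proved
numerically unstable on exactly periodic windows). The ellipse is
divided into `N_b` equal *angular* sectors measured from the major axis
in the traversal direction; the sector being traced is the phase.

Two details make the predictor line up with time-defined phase:

* the lag-plot point `(y(t-ω), y(t))` represents the respiratory state
  at `t - ω/2`, so predictions advance the elliptical angle by
  `(horizon + ω/2) · angular_speed`;
* the angular speed is a median of finite differences of the unwrapped
  angle over the trailing second, and the instantaneous angle is a
  short trailing average, which suppresses sensor noise at bin
  boundaries.

For a pure sinusoid this construction is exact (bin accuracy ≥ 95%,
limited only by sampling quantization), and accuracy degrades
monotonically with sensor noise. The fitting window is 10 s, refit at
the sample rate; a degenerate fit (flat or collinear lag plot) flags low
confidence and the predictor holds its last bin. The predictor is
strictly streaming: queries use only samples already pushed.

The system latency `τ` defaults to 0.4 s and is always configurable.

## The closed-loop controller

The control problem could be posed as a mixed-integer program over the
remaining schedule; this package solves it with a receding-horizon
greedy rule instead. The objective (absolute angular deviation from the
ideal schedule) and the constraint set are the same, and the
schedule-MAE surface is what defines success, so the solver choice is an
implementation decision. Each 30 Hz control tick, the controller:

1. targets the next ideal projection `k*` and its bin `j_{k*}`;
2. asks the predictor when that bin next becomes active and picks the
   first trigger tick at least 80 ms (the gate guard) inside the
   predicted occupancy — the guard absorbs small early-prediction
   errors that would otherwise fire the x-ray one bin early;
3. tracks the *ideal pace line*: it commands the speed that arrives at
   `S_{k*}` at the chosen tick while moving at the steady ideal pace
   (one angular step per bin dwell), so consecutive projections need no
   speed transients. The command saturates at `v_max` (flagged as an
   unavoidable schedule error) and is floored at the abort speed while
   the scan is live.

The gate for each trigger tick is fixed one trigger period ahead from
the predictor's extrapolation. The plant is first-order speed tracking
saturated at `a_max`. Acquired projections record the *ground-truth*
bin from the trace, so prediction errors surface as data-structure
errors, never as label noise — mirroring a system that sorts
retrospectively from the recorded signal.

Measured behaviour at the defaults: noiseless periodic breather — MAE
≈ 0.09° with the exact interleaved bin sequence; regular breather with
sensor noise — MAE ≈ 0.13–0.18°, exact sequence; variable and irregular
breathers — MAE grows and isolated same-bin gaps exceed the target
separation, the same failure signature reported for coughing patients.

## Projection and reconstruction

The cone-beam geometry is a conventional linac: 1000 mm source–axis,
1536 mm source–detector, a 96×96 flat panel at 4 mm pitch, 200° arc.
Desk-scale defaults are a 64³ volume at 4 mm; everything is
configurable. Forward projection is ray-driven with trilinear sampling
at half-voxel steps (numba kernels; verified against a fine independent
line integrator to <0.01% and against the analytic sphere chord-length
oracle). FDK reconstruction applies per-pixel cosine weights, Parker
short-scan weights with the effective half-fan `(arc - 180°)/2`, a
band-limited ramp filter with Hann apodization (zero-padded FFT), and
voxel-driven distance-weighted backprojection. A ray-driven splatting
adjoint (the exact numerical transpose of the forward kernel) exists for
adjoint-consistency testing.

Respiratory-correlated (4DFDK) frames are scaled by the *global*
angular step, which makes the decomposition exact: the frames sum to
the full FDK volume to floating-point precision. The consequence — each
frame carries `1/N_b` of the intensity scale — is deliberate and
documented below.

## McKinnon-Bates and adaptive reconstruction

The MKB step estimates each frame as a perturbation of the blurred
volume: simulate each bin's projections from the blurred FDK volume,
reconstruct them with the same per-bin operator, affine-scale onto the
per-bin frames (closed-form least squares over the whole volume, with a
flagged unit-gain fallback for constant inputs), and subtract the
difference from the blurred volume.

Two scale/stabilization choices were genuinely open and are resolved as
follows:

* **Per-bin normalization of the MKB intermediates.** If the per-bin
  images enter at `1/N_b` scale (the sum-identity convention), the
  fitted gain is ~1 and the perturbation removes only `1/N_b` of the
  motion blur; the frames stay blurred and motion estimation on them
  under-recovers badly (measured). The MKB chain therefore reconstructs
  its intermediates with each bin's own angular step (full anatomical
  scale, the classical construction), while the public
  respiratory-correlated frames keep the global convention and their
  exact sum identity.
* **Cross-bin centering of the perturbations.** Reprojecting a
  short-scan cone-beam FDK volume does not reproduce the data (measured
  ~17% at desk scale, dominated by smooth cone/short-scan systematics),
  and that self-inconsistency enters every bin's perturbation almost
  identically. Each perturbation is therefore centered on the cross-bin
  mean: the bin-independent systematic cancels exactly, the
  phase-specific motion term survives at full strength, and the MKB
  frames average exactly back to the blurred volume. Perturbations are
  also masked to the scanned cylindrical field of view (with an 8 mm
  cosine taper); outside it the per-bin backprojections hold unmeasured
  junk.

Motion is then estimated by registering each MKB frame to the reference
(peak-inhale) frame. The default engine is multiresolution
symmetric-forces demons with fluid-like regularization (update-field
smoothing σ=3.0 voxels, total-field smoothing σ=1.5, max step 2 voxels,
300/150/50 iterations at shrink 4/2/1). Both inputs are pre-smoothed by
a 1-voxel Gaussian before either engine runs (fields are applied to the
unsmoothed images), which damps the tendency to register residual
streaks instead of anatomy. The engine is fully deterministic, takes a
few seconds per 64³ registration on one core, recovers a 6 mm rigid
shift to ~1.1 mm mean error and ~90% of a 14 mm tumor excursion. Pure diffusion-like demons
regularization systematically under-recovers displacements larger than
the structures carrying them, hence the fluid term. A B-spline
free-form engine with a 16 mm control-point grid and Mattes mutual
information is selectable (`RegConfig(engine="bspline")`) but is two
orders of magnitude slower per registration in this single-threaded
setting and is not the default. Registrations whose field is below 0.3
voxel at the 95th percentile snap to zero (sub-resolution fields are
noise, and motionless frames should pass through unwarped).

The reference adaptive frame is the *mean* of the warped MKB frames
(the equations admit a bare sum, but the mean preserves the attenuation
scale and matches the apply-and-average description of the pipeline);
the other frames are produced by warping the reference through the
inverted fields. DVF inversion is a damped fixed-point iteration
(`V⁻¹(x) = -V(x + V⁻¹(x))`, damping 0.5, tolerance 0.1 voxel); a
non-invertible field raises, and the adaptive chain degrades to the
negated field with a logged warning. A failed registration degrades to
an identity field — that frame then contributes blur, not an error.
Warping uses cubic B-spline interpolation: linear interpolation visibly
blurs edges when ten warped frames are averaged.

## Metrics

* **Schedule MAE** — mean absolute angular deviation from the ideal
  schedule, matched by projection index.
* **Interbin separation** — sorted consecutive angular gaps within each
  bin's projections.
* **CNR** — `(mu_lung - mu_diaphragm) / sigma` with `sigma` the standard
  deviation of the *pooled* voxels of both ROIs (the most common reading
  of a joint standard deviation); the sign is preserved, so attenuation
  images give negative values.
* **TIW** — an axis-aligned probe box extracts parallel runs across a
  tissue interface; a 4-parameter logistic is fitted to each run and
  the 10–90% width (`ln 81 · scale`) averaged over successful fits, in
  mm. Runs fail on fit error, R² < 0.5, amplitude below 25% of the run
  range, or width beyond the run; more than half failing raises "no
  coherent interface". The 90/10 levels are measured on the fitted
  asymptotes, not the raw data range.
* **Dose reduction** — `100 · (1 - N_p / N_p_ref)`.
* **Motion-model robustness** — registers a motion-compensated image to
  a non-compensated reference with the same engine and reports per-axis
  and total displacement statistics over a tumor mask.

## What the synthetic data does and does not show

The generator reproduces the *structure* of the problem — surrogate
periodicity, drift, irregular episodes, latency, trigger quantization,
gantry dynamics, photon noise, motion blur versus streak trade-offs —
but not patient realism: no anatomical texture beyond the vessel
spheres, no hysteresis between surrogate and internal motion, no
cardiac motion, no scatter or beam hardening, and breathing statistics
chosen as plausible rather than fitted to any cohort. Passing tests
demonstrate that the control loop and reconstruction chain behave as
designed under these idealized conditions; they do not certify clinical
image quality.

One acceptance-level property deliberately does not hold at desk scale:
the expectation that motion-compensated frames have a *smaller* tumor
interface width than the per-bin frames of the same 200-projection
scan. That ordering belongs to the clinical regime, where ~20
projections per bin meet ~512-pixel resolution and per-bin frames are
unusably streaky. At 64³ with evenly spread STO projections, a 20-view
frame already resolves the tumor edge near the grid floor (~3.8 mm
median TIW), while frame averaging through registration carries ~1–2 mm
of residual misalignment (measured: even ground-truth-aligned averaging
of the MKB frames yields ~7.6 mm, because each 20-view frame's streak
pattern scatters its apparent edge position). The adaptive chain still
wins where its mechanism predicts it should: streak level in uniform
tissue, trajectory fidelity (tumor center within ~0.2–0.8 voxel RMS of
the motion law), and robustness of tumor position.

## Problem sizes

The shipped defaults — 64³ volumes at 4 mm, 96² detector at 4 mm, 200
projections, 10 bins — were chosen so that a complete virtual trial arm
(trace → closed-loop scan → rendering → adaptive reconstruction →
metrics) runs in minutes on a single core. All sizes are configurable,
and the scaling is the obvious one: forward/backprojection linear in
rays × samples, registration roughly linear in voxels.
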