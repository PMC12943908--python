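# Methods

## Problem and model

A foot-mounted IMU samples tri-axial acceleration at 50 Hz
(Δt = 0.02 s). Stride cycles are delimited by pre-detected gait-event
sample indices; consecutive indices bound one stride, interpreted as the
half-open interval [start, end) so strides tile the record without
overlap. The task is to estimate each stride's length from one
acceleration channel (default `az`; the channel is configurable because
recording conventions differ between sensors and mounting orientations).

The estimator is a linear-Gaussian state-space model over
x = [p, v, a]ᵀ — displacement (m), velocity (m/s) and acceleration
(m/s²) accumulated within the current stride:

    x_k = A x_{k-1} + w_k,   z_k = H x_k + v_k
    A = [[1, Δt, 0], [0, 1, Δt], [0, 0, 1]],  H = [0, 0, 1]
    w ~ N(0, Q),  v ~ N(0, R)

The transition deliberately omits the ½Δt² coupling of acceleration into
displacement; the package treats this first-order kinematic form as the
reference formulation and offers the full constant-acceleration
discretisation behind `FilterConfig(full_ca_transition=True)` for
comparison (on 50 Hz gait signals the difference is below 0.2% of stride
length). A formal control term B·u is carried for dimensional
completeness with u ≡ 0: gait has no measurable external control input.
Because A and H are constant, the filter is the constant-Jacobian special
case of an extended Kalman filter — numerically a linear Kalman filter —
and the package's plain `ekf` mode is exactly that.

Stride length is read off as |p_end − p_start| of the filtered
displacement over the stride, times a calibration factor (default 1.0)
that absorbs any mapping from the measured axis to forward progression;
with synthetic data the factor is exactly 1.

### Per-stride reinitialisation

Each stride is filtered from a fresh state x₀ = [0, 0, z₀] (z₀ the
stride's first preprocessed sample) with covariance P₀ = I. Resetting p
makes per-stride lengths independent of accumulated drift; resetting v as
well follows from the cyclic-gait assumption (the foot's velocity
returns to its initial value at each gait event, which the synthetic
generator reproduces exactly). Without the velocity reset,
double-integration drift grows without bound across a multi-minute
record and per-stride errors inflate with stride index.

### Gain regulation at acceleration zero crossings

The filter's only nonstandard mechanics are transient. When the measured
acceleration strictly changes sign (z_{k-1}·z_k < 0; exact zeros do not
trigger), the next `boost_samples` (default 3) measurement updates use an
effective measurement variance R/`boost_factor` (default 10), which
provably raises the Kalman gain toward the measurement. Two effects
follow. First, the filter reconverges faster through the signal's
fast-turning regions, undoing most of the amplitude attenuation (lag
bias) a fixed-gain filter exhibits on quasi-periodic signals. Second —
and quantitatively more important for stride length — a heel-strike
transient injects a spurious velocity impulse; a linear time-invariant
filter preserves that impulse in full (its DC gain is 1, only spreading
it in time), whereas the boost triggered by the first post-transient zero
crossing snaps the acceleration state back to the measurement and
truncates the transient's exponential tail, removing part of its
impulse. This is why the modified route beats both the plain filter and
raw integration on the synthetic benchmark.

### Sign-flip consistency rule

Measurement noise can make the small early-stride displacement cross
zero non-physically. The rule: if adjacent displacements have strictly
negative product, the current one's sign is flipped to match its
predecessor, magnitude preserved. It is implemented as a logical check on
the *emitted* displacement sequence only — chained against the
previously emitted value — and feeds nothing back into the state
recursion, the gain or the covariance. The feedback variant (flipping
the state inside the recursion) is pathological: once noise leaves an
emitted displacement slightly negative while the true displacement grows
positive, the flip re-engages every step and pins p near zero, stalling
the integration for the whole stride; the output-only form preserves
|p_end − p_start| exactly when an entire trajectory is mirrored and
guarantees the emitted sequence carries no adjacent sign reversal.

## Preprocessing front end

`wavelet_denoise` performs a multilevel discrete db4 decomposition,
thresholds the detail coefficients and reconstructs. Defaults: 2 levels,
universal soft threshold σ·√(2 ln n) with σ = MAD(finest details)/0.6745,
symmetric boundary extension. The depth default is a frequency-band
decision: at 50 Hz, levels 1–2 cover 6.25–25 Hz, comfortably above the
≤3–4 Hz band holding walking's fundamental and low harmonics, so
thresholding removes broadband noise and sharpens heel-strike transients
without biasing the gait waveform. Deeper decompositions reach into the
gait band and the soft threshold then shrinks genuine harmonic content —
measurably worsening stride-length recovery — so depth should only be
raised for sensors with low-frequency noise. With thresholding disabled
the transform is an identity (perfect reconstruction), which the tests
exploit.

`cubic_smooth` is the five-point local cubic least-squares smoother: a
cubic p(k) = a₀ + a₁k + a₂k² + a₃k³ is fitted to each sliding
five-sample window and evaluated at the window centre. All stencils are
*derived* at import time from the least-squares normal equations rather
than hard-coded: the interior stencil comes out as the classical
[−3, 12, 17, 12, −3]/35, and the last two samples use the one-sided
five-point fit evaluated at offsets 3 and 4, with index-mirrored
counterparts at the start. Every stencil's coefficients sum to 1
(constants are preserved), the operator is linear, and it reproduces any
degree-≤3 polynomial exactly — all verified against a brute-force
polynomial-fit oracle.

## Synthetic gait generator

`synthgait` generates records whose ground truth is known in closed
form. Each stride's acceleration is a scaled sinusoid pair

    a(t) = A [sin(ωt) − ½ sin(2ωt)],  ω = 2π/T,  A = 8πL/(3T²)

whose velocity (A/ω)[¾ − cos ωt + ¼ cos 2ωt] = (A/2ω)(1 − cos ωt)² is
non-negative and cyclic (zero at both stride ends) and whose double
integral over [0, T] is exactly L. The vanishing boundary slope keeps
the trapezoidal double-integration discretisation error of the sampled
profile below 10⁻⁵ m at 50 Hz. Stride lengths and durations are drawn
from configurable normals (defaults 1.2 ± 0.1 m and 1.0 ± 0.05 s,
self-selected-pace adult treadmill walking; lengths truncated at 0.2 m),
an impact-like decaying transient (default 2 m/s², 3-sample e-folding)
marks each stride start, and i.i.d. Gaussian noise (default σ = 0.3
m/s²) is added to the measurement channel. The record carries one
trailing rest sample so the terminal event index is itself a valid
sample index and the final half-open segment covers the whole last
stride. The other two channels carry low-amplitude filler so file
formats and channel selection are exercised.

What the generator does *not* emulate: gravity orientation and attitude,
joint kinematics, soft-tissue artifact, speed drift, or correlated
sensor noise. Passing the synthetic benchmarks therefore demonstrates
the pipeline's statistical behaviour under its own model assumptions —
not clinical accuracy on human data, for which the calibration factor
and noise covariances would need re-estimation.

## Filter tuning

Defaults: Q = diag(10⁻⁶, 10⁻⁴, 10⁻²), R = 0.05, P₀ = I, chosen for
stable behaviour on the synthetic generator's signal scale (≈10 m/s²
amplitude, ≈0.25 m/s² residual noise after preprocessing) and all
settable from config files or CLI flags. On the default benchmark
(100 strides, noise 0.3 m/s², seed 1) the three routes give mean
relative errors of 0.0331 (raw integration), 0.0457 (plain filter) and
0.0285 (modified filter): the plain filter's fixed gain trades noise
suppression for lag bias and loses to raw integration, while the
zero-crossing boost recovers that loss and additionally clips part of
the heel-strike impulse. Raising R (or lowering Q₃₃) increases both
smoothing and lag; the boost mitigates the lag but the trade-off should
be re-examined for sensors with different noise floors.

## LSTM regressor

A single LSTM layer (default 50 hidden units) plus a linear head maps a
fixed-length one-channel stride signal to a scalar length. Variable-
length strides are linearly resampled to 50 samples (≈ one stride at
50 Hz); resampling rather than padding keeps the model minimal, at the
documented cost of discarding stride-duration information (on the
synthetic benchmark this caps attainable R² well below 1, since duration
enters the length–amplitude relation). Inputs and labels are z-scored
with statistics fitted on the training split only; the seeded split is
70/15/15 per stride. Training minimises MSE with Adam (lr 10⁻³, batch
16), inverted dropout 0.2 on the final hidden state, and early stopping
on validation MSE with patience 25 (best weights restored). The network
(forward pass, backpropagation through time, Adam) is implemented
directly in numpy, which keeps training exactly reproducible under a
fixed seed on one CPU; gradients are verified against numerical
differentiation in the test suite.

## Numerical choices

- Covariances are re-symmetrised ((P + Pᵀ)/2) after every update;
  symmetry and a −10⁻⁸ eigenvalue floor are asserted in tests.
- Zero crossings use the strict product rule z_{k-1}·z_k < 0, so exact
  zeros never trigger a boost; the sign-flip product rule is strict in
  the same way.
- The innovation variance HP̄Hᵀ + R_eff must be positive; a violation
  signals a broken configuration and raises.
- The smoother requires ≥ 5 samples, segments ≥ 3 samples, and filtering
  ≥ 2; degenerate inputs raise with explicit messages rather than
  truncating.
- Stride-event files are 0-based by default; `--one-based` converts on
  read. Unit conversion to m/s² uses a configurable scale factor
  (default 1.0; 9.81 for logs recorded in g).
- Relative-error summaries use the sample (n−1) SD by default with a
  population-SD toggle.

## Problem sizes

The bundled benchmark sizes — 100 strides for the filter comparison,
400 strides / 120 epochs / 3 seeds for the LSTM comparison, 5 seeds for
the mode-ordering check — were chosen so the full suite and the
acceptance script each complete in minutes on one CPU while keeping the
compared effects several standard errors apart.

## Known limitations

- The mapping from the measured axis to forward stride length is a
  single calibration constant; real deployments need a per-subject or
  per-sensor calibration against a reference system.
- The filter assumes gait events are given; event detection is out of
  scope.
- Only the Daubechies wavelet family is exercised; other bases run but
  are not guaranteed.
- The LSTM is an exploratory single-layer model; no subject-independent
  validation is built in (the dataset splitter accepts grouping keys so
  one can be added).
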