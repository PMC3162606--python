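# Methods

`scnwave` has two halves: a measurement pipeline that turns a
bioluminescence movie of a cultured SCN slice into phase-wave statistics,
and a coupled phase-oscillator lattice model whose simulations interpret
those statistics.  This note records the models, the parameter choices
that matter, and the numerical decisions, in enough detail to reproduce
or challenge any of them.

## 1. Envelope phase and amplitude

Each pixel of a movie carries a damped, baseline-shifted circadian
oscillation x(t).  The pipeline is deliberately model-free:

1. **Smoothing.** Centered moving average, window 6 h (13 samples at the
   default 0.5 h sampling).  At the trace ends the window shrinks
   one-sidedly; this keeps the full trace length so early/late extrema
   can anchor envelopes, at the cost of slightly attenuated boundary
   anchors (the phase error this induces is confined to the first/last
   cycle and is below 5e-3 rad on a noiseless cosine).
2. **Extrema.** Local maxima/minima of the smoothed trace
   (`scipy.signal.find_peaks`), plateaus resolved to their midpoint,
   alternation enforced by keeping the more extreme of same-type
   neighbors.  Two guards suppress noise-born spurious extrema, which
   would otherwise each inject a full spurious cycle into the phase:
   a minimum separation of 40% of the nominal period and a minimum
   prominence of 5% of the smoothed trace's range.  A boundary sample
   may serve as an extra anchor when the observation window cuts an
   extremum in half.
3. **Envelopes.** Piecewise-linear interpolation through the peak values
   (upper envelope h) and trough values (lower envelope l), each defined
   only between its first and last anchor; no extrapolation.
4. **Amplitude** A = (h - l)/2 and **phase** theta from
   y = (2 x_s - h - l)/(h - l), clipped to [-1, 1] (chord error of the
   linear envelopes can push |y| marginally above 1 near extrema);
   theta = arccos(y) on descending segments, accumulated so that
   theta = 0 (mod 2 pi) at peaks, pi at troughs, and exactly 2 pi is
   gained per cycle.
5. **Quality.** A pixel is non-oscillatory — masked, never imputed — if
   it yields fewer than two peaks or troughs, a non-positive amplitude,
   or a median amplitude below the high-frequency residual SD of the
   trace (SNR guard: a dead pixel's smoothed noise still wiggles, but
   only at the noise scale).

The Hilbert transform of the midline-subtracted trace provides an
independent phase/amplitude estimate used purely as a cross-check; on
damped-cosine fixtures the two phases agree to < 0.05 rad/2pi (circular
RMS), which is the package's justification for the specific envelope
formulas.

## 2. Synchronization and fluctuation statistics

* **Order parameter** R e^{i Phi} = mean of e^{i theta_j} over valid
  pixels; R = 1 is perfect synchrony.
* **Spatial fluctuation Delta** = SD of the locally detrended phase, in
  rad/2pi.  Imaging default: circular mean over a 7x7-pixel window
  (~3x3 cells), center included, only pixels with a fully valid window
  (unbiased, and exactly zero on a linear phase ramp — the traveling
  wave does not contaminate Delta).  Both choices are options
  (`exclude_center`, `boundary`) because the lattice model uses the
  complementary convention (section 4).
* **Wave velocity** from the space-time plot: per line and frame the
  spatially unwrapped phase (cycles) is regressed on distance (mm); the
  mean gradient g gives v = 1/(|g| T).  Averaging over a band of
  parallel lines suppresses the cell-jitter contribution to the slope,
  which a single line cannot (the jitter is static, so more frames do
  not help).  |g| below 1e-4 cycles/mm is reported as undefined.

## 3. Synthetic movies

The generator emulates the structure of the recordings: a phase-offset
map (travel delay from a wave origin at 0.2 mm/h, default period 24 h)
plus per-cell jitter (2x2-pixel cells, N(0, 0.017) cycles, constant in
time — the experimental fluctuation pattern is stable), an amplitude
bump placed away from the wave origin, exponential damping (72 h),
baseline, linear trend, Gaussian measurement noise, and optional dead
cells.  Defaults (60x60 px at 10 um/px, 0.5 h sampling, 120 h) are
chosen so that a single movie supports the recovery tolerances: the
phase gradient is ~0.002 cycles/px against jitter of 0.017 cycles, so a
12-row band average recovers v to a few percent, and the 7x7 detrended
SD recovers the jitter within the extraction-noise budget (~+15%).
Ground truth reports the *realized* detrended SD of the generated map,
not the nominal jitter, so recovery tests do not conflate sampling
variation with pipeline bias.

What the generator does not emulate: anatomical subregions, non-Gaussian
photon statistics, cell-size heterogeneity, and amplitude-phase
coupling.  Passing recovery tests therefore demonstrates correctness of
the pipeline's geometry and statistics, not robustness to every
real-data artifact.

## 4. Lattice model

N1 x N2 x NL = 20 x 20 x 10 phase oscillators, 6-connected with open
boundaries (a slice has free surfaces):

    dtheta_i/dt = omega_i + K sum_{j ~ i} sin(theta_j - theta_i) + xi_i

* omega_i ~ N(1, sigma_omega); one model cycle (2 pi time units) maps to
  24 h.
* Pacemaker: the x = 0 plane runs 4% faster (each drawn omega_i
  multiplied by 1.04), launching the traveling wave.
* Defects: surface (z = 0) sites deleted with probability gamma; a
  defect pixel displays the phase of the live site directly beneath it,
  as interior cells shine through in the recordings.
* The coupling term is the plain sum over live nearest neighbors.  A
  per-site normalized variant (K/n_i) is available
  (`normalize_by_degree=True`); with normalization the critical coupling
  shifts to ~6x larger values, far from the reference K_c ~ 0.05, which
  is why the unnormalized sum is the default.
* Noise: see section 6.

Integration: classical RK4, dt = 0.02, from the fully synchronized state
theta = 0.  The drift needs one sin and one cos per oscillator per stage
(sin(theta_j - theta_i) expanded via neighbor sums of sin and cos);
batches of runs integrate in one array, in float32 by default.  Phases
are wrapped into [0, 2 pi) every 50 steps — the drift is invariant under
per-site 2 pi shifts — keeping float32 trigonometry accurate
indefinitely; the removed multiples are book-kept exactly so observed
surface phases remain unwrapped.  Float32 rounding acts like a
random-walk phase perturbation of ~5e-3 rad over 25 000 steps, two
orders of magnitude below the smallest Delta plateaus of interest;
float64 is available (`dtype="float64"`) and is used for the
integrator-order convergence test, where O(dt^4) differences sit below
float32 resolution.

**Surface Delta.** The model's Delta(t) is computed on the *unwrapped*
surface phases: theta_i is a real-valued dynamical variable, and below
the critical coupling repeated phase slips accumulate without bound —
that unbounded growth is the defining signature of desynchronization.
(On wrapped phases Delta saturates near the uniform-distribution value
~0.25 within ~150 time units, hiding the transition entirely.)  The
local mean is arithmetic over the 3x3 neighborhood of each site — one
lattice site is one cell — *excluding* the center site and *truncated*
at the lattice boundary, so all 400 surface sites contribute.  On a
20x20 surface the boundary sites are a fifth of the total and carry the
largest locking lags; including them raises the steady-state Delta(K)
curve by 20-40% at intermediate K, and this convention is what
quantitatively reproduces the reference coupling bracket (section 7).
For locked states the convention differences are second order; for the
imaging path (large fields, edges negligible) the stricter full-window
convention of section 2 remains the default.

## 5. Trajectory classification and sweeps

A Delta(t) trajectory is *bounded* (synchronized) if it plateaus after
the transient (250 time units of the 500-unit horizon) and *growing*
otherwise.  Operationally, growing requires both:

* least-squares slope of Delta over the post-transient window
  > `slope_tol` (2e-5 rad/2pi per time unit), and
* mean Delta over the last tenth > `growth_factor` (1.25) x the median
  over the first post-transient quarter.

Far-from-critical controls separate by orders of magnitude (locked runs:
slope < 5e-6, late/early ratio ~1.00; unlocked: slope > 1e-4, ratio
> 1.4); the defaults sit at the geometric midpoints of those gaps and
were fixed from such controls, not from near-critical runs.  Non-finite
trajectories count as growing, and trajectories below 1e-4 rad/2pi are
always bounded (exact synchrony).  Every sweep point uses five
replicates (fresh frequency draws, defect placements, noise paths) and a
majority vote; K_c is the smallest grid coupling with a bounded
majority, with one round of grid refinement (step 0.005 in K) across the
transition.  Near the transition the vote is genuinely stochastic — the
same protocol with different replicate seeds can move K_c or a
robustness threshold by one grid step; the sweep tables report the
per-point bounded fraction so this margin is visible.

The coupling bracket interpolates where steady-state Delta(K) (mean over
the post-transient window and replicates) crosses the experimentally
measured fluctuation level 0.02 rad/2pi, linearly in log K (Delta(K)
decays roughly geometrically; a linear-in-K variant is a function
argument).  The bracket is read off the defect-free curve (lower end)
and the gamma = 0.5 curve (upper end).

## 6. Dynamical noise conventions

`noise_intensity` D parametrizes independent white Gaussian forcing.
Two discretizations are implemented:

* `"forcing"` (default): the noise is sampled once per step with
  amplitude sqrt(2D) and carried through the RK4 update, giving the
  per-step increment sqrt(2D) * dt * N(0,1).  This is the convention
  under which the robustness thresholds of this model family are quoted
  (synchrony up to D of order 1-10 at K ~ 0.1-0.2); its equivalent
  continuous-time intensity is D * dt.
* `"em"`: exact Euler-Maruyama increment sqrt(2 D dt) * N(0,1) after the
  deterministic RK4 step, realizing <xi_i(t) xi_j(s)> =
  2 D delta_ij delta(t-s) literally; the noise-only control (K = 0,
  sigma_omega = 0) then shows per-oscillator phase variance 2 D t, which
  is the property test for this mode.

The two differ only in the meaning of the D axis (a factor dt in
intensity); classification machinery is identical.

## 7. Reference values and problem sizes

All quantitative anchors are recomputed at the full protocol
(20x20x10, dt = 0.02, t_end = 500, 5 replicates) by
`scripts/acceptance.py` and `tests/test_acceptance.py`; nothing is
hard-coded.  Under this protocol the model reproduces K_c ~ 0.05
(gamma = 0, within one 0.005 grid step across replicate sets), K_c ~
0.10-0.11 (gamma = 0.5; the majority vote at K = 0.10 sits right at the
replicate margin), the coupling bracket ~[0.12, 0.22] at the 0.02
rad/2pi level (2-4x K_c), and noise robustness up to D ~ 8 at K = 0.22
vs ~0.7 at K = 0.06.  The largest tolerated frequency heterogeneity at
K = 0.22 lands at sigma_omega ~ 0.2-0.25 depending on the replicate set:
the sigma transition is broad (bounded fractions 0.8 at 0.2 and 0.6 at
0.25 in a typical run), and plateau Delta values there are already large
(~0.2-0.6 rad/2pi), so a one-grid-step overestimate relative to the
0.2 reference is within this model's replicate variability, not a
resolvable disagreement.

Known limitations: no non-local or diffusible coupling (the lattice is
strictly nearest-neighbor); no spatial gradient in natural frequencies
beyond the pacemaker plane; defects only on the display surface; the
imaging pipeline assumes uniform sampling and a single dominant
oscillation per pixel.
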