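# scnwave

Quantitative analysis and modeling of circadian **phase waves** in the
suprachiasmatic nucleus (SCN), the mammalian master clock.

Time-lapse bioluminescence of a cultured SCN slice shows every pixel
oscillating with a ~24 h period, but not in unison: a spatial phase
gradient sweeps across the tissue once per cycle (a traveling wave of
~0.2 mm/h), riding on top of stable cell-scale phase jitter.  `scnwave`
provides both halves of the quantitative story:

* **Measurement.** Per-pixel amplitude A(t) and phase θ(t) extracted
  from peak/trough envelopes of the smoothed signal (cross-checked
  against the Hilbert transform), the synchronization index
  R·e^{iΦ} = N⁻¹ Σ_j e^{iθ_j} (Kuramoto order parameter), the spatial
  phase fluctuation Δ = SD of the locally detrended phase in rad/2π
  (fractions of a cycle), and the wave velocity from space–time plots.
* **Model.** A 20×20×10 lattice of locally coupled phase oscillators,

      dθ_i/dt = ω_i + K Σ_{⟨j⟩} sin(θ_j − θ_i) + ξ_i(t),

  with heterogeneous frequencies ω_i ~ N(1, σ_ω), a 4%-faster pacemaker
  plane at x = 0 that launches the wave, random surface defects
  (probability γ, displayed as the phase of the cell beneath), and white
  dynamical noise of intensity D.  Experiments built on it estimate the
  critical coupling K_c below which Δ grows without bound, bracket the
  biological coupling strength by matching the measured Δ ≈ 0.02 rad/2π,
  and map robustness against σ_ω and D.

Because no SCN recordings ship with the package, a synthetic-movie
generator with exact ground truth (wave velocity, realized cell jitter,
defect map) makes the entire pipeline testable end to end.

## Worked example

```python
import numpy as np
from scnwave import (SyntheticMovieSpec, generate_movie, extract_movie,
                     order_parameter, delta_from_field, wave_velocity,
                     phase_to_time)

# 60x60 px, 10 um/px, 0.5 h sampling for 120 h; 0.2 mm/h wave,
# 0.017 cycles of stable cell jitter
movie, truth = generate_movie(SyntheticMovieSpec(seed=3))
field = extract_movie(movie)                      # per-pixel theta(t), A(t)

frame = field.phase_field(np.searchsorted(movie.time_axis, 60.0))
print(f"R = {order_parameter(frame).R:.3f}")
print(f"Delta = {delta_from_field(frame, window=7):.4f} rad/2pi "
      f"(ground truth {truth.true_delta:.4f})")
print(f"= {60 * phase_to_time(delta_from_field(frame, 7), 24.0):.1f} min of a 24 h cycle")

lines = [(np.full(60, r), np.arange(60)) for r in range(24, 36)]
frames = [field.phase_field(np.searchsorted(movie.time_axis, t))
          for t in (48.0, 60.0, 72.0)]
print(f"wave velocity = {wave_velocity(frames, lines).velocity:.3f} mm/h")
```

prints

```
R = 0.968
Delta = 0.0194 rad/2pi (ground truth 0.0164)
= 27.9 min of a 24 h cycle
wave velocity = 0.204 mm/h
```

i.e. the slice is strongly synchronized (R close to 1), the cell-scale
phase scatter is ~2% of a cycle (about half an hour), and the wave moves
at the construction speed within a few percent.

On the model side:

```python
from scnwave import SimConfig
from scnwave.experiments import estimate_Kc

sweep = estimate_Kc(SimConfig(seed=1, gamma=0.0),
                    [0.0, 0.02, 0.04, 0.045, 0.05, 0.07, 0.09],
                    n_replicates=5)
print(sweep.to_frame())          # per-K steady Delta and bounded/growing vote
print("K_c =", sweep.critical_value)
```

A command-line interface mirrors the library:
`scnwave synth | extract | metrics` for the movie pipeline and
`scnwave simulate | kc | robustness | couple` for the model experiments;
every command takes `--seed`, writes CSV/JSON with units in the headers,
and drops a manifest recording config, seeds and output checksums.

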