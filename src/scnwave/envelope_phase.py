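"""Envelope-based amplitude and phase extraction for oscillatory traces.

Bioluminescence of a circadian reporter in a single pixel is a damped,
noisy, baseline-shifted oscillation x(t).  Rather than fitting a model,
amplitude and phase are read off the signal geometry:

1. x(t) is smoothed with a centered 6 h moving average.
2. Local maxima (peaks) and minima (troughs) of the smoothed trace are
   detected.
3. The upper envelope h(t) interpolates linearly between successive peak
   values, the lower envelope l(t) between successive trough values.
4. Amplitude:  A(t) = (h(t) - l(t)) / 2.
5. Phase: the signal is normalized to y(t) = (2 x_s - h - l)/(h - l),
   which runs from +1 at a peak to -1 at the following trough;
   theta = arccos(y) on descending segments and increases through
   2pi - arccos(y) on ascending segments, accumulated so that theta
   advances by exactly 2pi per cycle, with theta = 0 at every peak.

The Hilbert-transform phase/amplitude (``hilbert_phase``) is provided as
an independent cross-check; on well-behaved oscillatory traces the two
extractions agree closely, which is the internal consistency test for
the envelope definitions.

Pixels whose smoothed trace yields fewer than two peaks or two troughs
(monotone drift, dead pixels, pure noise) are flagged non-oscillatory
and are excluded from downstream statistics rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks
from scipy.signal import hilbert as _hilbert

__all__ = [
    "MovieGrid",
    "EnvelopePair",
    "PhaseAmplitudeField",
    "PixelExtraction",
    "smooth_series",
    "detect_extrema",
    "enforce_alternation",
    "build_envelopes",
    "amplitude",
    "phase",
    "hilbert_phase",
    "extract_pixel",
    "extract_movie",
]

TWO_PI = 2.0 * np.pi


@dataclass
class MovieGrid:
    """Per-pixel intensity time series of a bioluminescence movie.

    intensities has shape (H, W, T); time_axis is uniform, in hours.
    """

    intensities: np.ndarray
    time_axis: np.ndarray
    pixel_size: float
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must have shape (H, W, T)")
        if self.time_axis.ndim != 1 or self.time_axis.size != self.intensities.shape[2]:
            raise ValueError("time_axis length must match the trailing axis")
        dt = np.diff(self.time_axis)
        if dt.size and (np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6)):
            raise ValueError("time_axis must be strictly increasing and uniform")
        if self.mask is None:
            self.mask = np.all(np.isfinite(self.intensities), axis=2)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def sampling_interval(self) -> float:
        return float(self.time_axis[1] - self.time_axis[0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass
class EnvelopePair:
    """Piecewise-linear peak/trough envelopes of one trace.

    h and l are sampled on the trace's own time grid; outside their
    interpolation domain (before the first / after the last extremum of
    the respective kind) they are NaN.
    """

    h: np.ndarray
    l: np.ndarray
    peak_times: np.ndarray
    trough_times: np.ndarray
    peak_values: np.ndarray
    trough_values: np.ndarray
    peak_indices: np.ndarray
    trough_indices: np.ndarray


@dataclass
class PixelExtraction:
    """Full extraction result for a single trace."""

    theta: np.ndarray            # rad, NaN outside the inter-extremum domain
    amplitude: np.ndarray        # counts, NaN outside the envelope domain
    envelopes: EnvelopePair | None
    oscillatory: bool
    smoothed: np.ndarray


@dataclass
class PhaseAmplitudeField:
    theta: np.ndarray            # (H, W, T) rad, unwrapped, NaN outside domain
    amplitude: np.ndarray        # (H, W, T) counts
    oscillatory: np.ndarray      # (H, W) bool quality flag
    time_axis: np.ndarray
    pixel_size: float
    period_hint: float = 24.0

    def phase_field(self, t_index: int):
        """Single-frame :class:`~scnwave.sync_metrics.PhaseField` view."""
        from .sync_metrics import PhaseField

        theta = self.theta[:, :, t_index]
        mask = self.oscillatory & np.isfinite(theta)
        return PhaseField(theta=theta, mask=mask, pixel_size=self.pixel_size,
                          period=self.period_hint)


def smooth_series(x: np.ndarray, sampling_interval: float, window: float = 6.0) -> np.ndarray:
    """Centered moving average with a window of ``window`` hours.

    At the trace boundaries the window shrinks one-sidedly so the output
    has the same length as the input (needed so envelopes can anchor on
    early/late extrema).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    half = int(round(window / (2.0 * sampling_interval)))
    if 2 * half + 1 < 2:
        raise ValueError("smoothing window must span at least 2 samples")
    if 2 * half + 1 > n:
        raise ValueError("smoothing window longer than the trace")
    csum = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def detect_extrema(
    xs: np.ndarray,
    min_separation: int | None = None,
    min_prominence: float | None = None,
    include_boundaries: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima (peaks) and local minima (troughs).

    Plateaus (runs of equal consecutive samples) count as a single
    extremum located at the plateau midpoint.  ``min_separation``
    (samples) and ``min_prominence`` (intensity units) suppress the
    spurious peak/trough pairs that residual measurement noise leaves
    on a smoothed trace -- without them, each spurious pair silently
    adds a full cycle to the accumulated phase.  A boundary sample can
    anchor an envelope too: when the trace starts (ends) on the falling
    or rising shoulder of an extremum cut off by the observation window,
    the segment before the first (after the last) interior extremum
    contributes its own extreme point, if prominent enough.  Fewer than
    two peaks or two troughs means the trace is non-oscillatory; that
    decision is left to the caller (no exception is raised here).
    """
    xs = np.asarray(xs, dtype=float)
    if xs.size < 3 or np.ptp(xs) == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    kw = {}
    if min_separation is not None and min_separation >= 1:
        kw["distance"] = min_separation
    if min_prominence is not None and min_prominence > 0:
        kw["prominence"] = min_prominence
    peaks, _ = find_peaks(xs, **kw)
    troughs, _ = find_peaks(-xs, **kw)

    if include_boundaries:
        prom = min_prominence if min_prominence else 0.0
        interior = np.sort(np.concatenate([peaks, troughs]))
        if interior.size:
            first, last = int(interior[0]), int(interior[-1])
            first_is_peak = first in peaks
            # leading segment: opposite-type extremum before the first one
            seg = xs[: first + 1]
            cand = int(np.argmin(seg) if first_is_peak else np.argmax(seg))
            if cand != first and abs(xs[cand] - xs[first]) > prom:
                if first_is_peak:
                    troughs = np.concatenate([[cand], troughs])
                else:
                    peaks = np.concatenate([[cand], peaks])
            last_is_peak = last in peaks
            seg = xs[last:]
            cand = last + int(np.argmin(seg) if last_is_peak else np.argmax(seg))
            if cand != last and abs(xs[cand] - xs[last]) > prom:
                if last_is_peak:
                    troughs = np.concatenate([troughs, [cand]])
                else:
                    peaks = np.concatenate([peaks, [cand]])
    return np.asarray(np.sort(peaks), dtype=int), np.asarray(np.sort(troughs), dtype=int)


def enforce_alternation(
    xs: np.ndarray, peaks: np.ndarray, troughs: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Drop the weaker of two same-type neighbors so extrema alternate.

    ``detect_extrema`` already produces alternating lists; this guard
    exists for extrema supplied from elsewhere (e.g. hand annotations).
    """
    events = sorted(
        [(int(i), +1) for i in peaks] + [(int(i), -1) for i in troughs]
    )
    kept: list[tuple[int, int]] = []
    for i, kind in events:
        if kept and kept[-1][1] == kind:
            prev_i, _ = kept[-1]
            better = xs[i] > xs[prev_i] if kind > 0 else xs[i] < xs[prev_i]
            if better:
                kept[-1] = (i, kind)
        else:
            kept.append((i, kind))
    p = np.asarray([i for i, k in kept if k > 0], dtype=int)
    t = np.asarray([i for i, k in kept if k < 0], dtype=int)
    return p, t


def build_envelopes(
    times: np.ndarray, xs: np.ndarray, peaks: np.ndarray, troughs: np.ndarray
) -> EnvelopePair:
    """Linear interpolation through peak and trough samples of ``xs``.

    Envelope values come from the smoothed trace itself; each envelope is
    defined only between its first and last anchoring extremum.
    """
    if peaks.size < 2 or troughs.size < 2:
        raise ValueError("need at least 2 peaks and 2 troughs to build envelopes")
    times = np.asarray(times, dtype=float)
    xs = np.asarray(xs, dtype=float)

    def interp(idx: np.ndarray) -> np.ndarray:
        env = np.interp(times, times[idx], xs[idx])
        env[(times < times[idx[0]]) | (times > times[idx[-1]])] = np.nan
        return env

    return EnvelopePair(
        h=interp(peaks),
        l=interp(troughs),
        peak_times=times[peaks],
        trough_times=times[troughs],
        peak_values=xs[peaks],
        trough_values=xs[troughs],
        peak_indices=peaks,
        trough_indices=troughs,
    )


def amplitude(env: EnvelopePair) -> np.ndarray:
    """A(t) = (h(t) - l(t)) / 2 on the common envelope domain (else NaN)."""
    a = (env.h - env.l) / 2.0
    return a


def phase(xs: np.ndarray, times: np.ndarray, env: EnvelopePair) -> np.ndarray:
    """Unwrapped envelope phase theta(t) in radians.

    The normalized signal y = (2 x_s - h - l)/(h - l) is clipped to
    [-1, 1] (linear-interpolation chord error can push it slightly
    outside near extrema).  theta = 0 (mod 2pi) at every detected peak
    and pi at every trough, increasing monotonically by 2pi per cycle.
    NaN outside the span of detected extrema or where A(t) = 0.
    """
    a = amplitude(env)
    with np.errstate(invalid="ignore", divide="ignore"):
        y = (2.0 * xs - env.h - env.l) / (env.h - env.l)
    y = np.clip(y, -1.0, 1.0)

    events = sorted(
        [(t, +1) for t in env.peak_times] + [(t, -1) for t in env.trough_times]
    )
    theta = np.full_like(xs, np.nan, dtype=float)
    first_peak_pos = next(j for j, (_, k) in enumerate(events) if k > 0)
    for j in range(len(events) - 1):
        t0, kind0 = events[j]
        t1, _ = events[j + 1]
        seg = (times >= t0) & (times <= t1)
        base = np.pi * (j - first_peak_pos)  # phase at extremum j
        if kind0 > 0:   # descending: peak -> trough
            theta[seg] = base + np.arccos(y[seg])
        else:           # ascending: trough -> next peak
            theta[seg] = base + np.pi - np.arccos(y[seg])
    bad = ~np.isfinite(a) | (a <= 0)
    theta[bad] = np.nan
    return theta


def hilbert_phase(
    xs: np.ndarray, env: EnvelopePair | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous phase and amplitude from the analytic signal.

    The trace is detrended by subtracting the envelope midline
    (h + l)/2 before the transform (a Hilbert phase is only meaningful
    for a zero-mean oscillation).  Where the midline is undefined the
    nearest defined value is used.  Returns (theta_H unwrapped, A_H).
    Used as an independent cross-check of the envelope extraction, not
    in the main pipeline.
    """
    xs = np.asarray(xs, dtype=float)
    if env is not None:
        mid = (env.h + env.l) / 2.0
        good = np.isfinite(mid)
        if good.any():
            idx = np.arange(xs.size)
            mid = np.interp(idx, idx[good], mid[good])
        else:
            mid = np.full_like(xs, xs.mean())
    else:
        mid = np.full_like(xs, xs.mean())
    analytic = _hilbert(xs - mid)
    theta_h = np.unwrap(np.angle(analytic))
    return theta_h, np.abs(analytic)


def extract_pixel(
    x: np.ndarray,
    times: np.ndarray,
    window: float = 6.0,
    period_hint: float = 24.0,
    prominence_frac: float = 0.05,
    snr_min: float = 1.0,
) -> PixelExtraction:
    """Run the full envelope extraction on a single intensity trace.

    ``period_hint`` (h) sets the minimum extremum separation (40% of a
    period) and ``prominence_frac`` the minimum extremum prominence as a
    fraction of the smoothed trace's range; both only guard against
    noise-induced spurious extrema and are far below genuine circadian
    peak spacing/amplitude.  ``snr_min`` rejects pixels whose envelope
    amplitude does not exceed ``snr_min`` times the high-frequency
    residual (raw minus smoothed trace): a dead pixel emitting pure
    measurement noise still shows slow wiggles after smoothing, but
    their amplitude stays at the noise scale.
    """
    times = np.asarray(times, dtype=float)
    dt = float(times[1] - times[0])
    xs = smooth_series(x, dt, window)
    peaks, troughs = detect_extrema(
        xs,
        min_separation=max(1, int(round(0.4 * period_hint / dt))),
        min_prominence=prominence_frac * float(np.ptp(xs)),
    )
    peaks, troughs = enforce_alternation(xs, peaks, troughs)
    nan = np.full_like(xs, np.nan)
    if peaks.size < 2 or troughs.size < 2:
        return PixelExtraction(nan, nan.copy(), None, False, xs)
    env = build_envelopes(times, xs, peaks, troughs)
    a = amplitude(env)
    finite_a = a[np.isfinite(a)]
    if finite_a.size == 0 or np.any(finite_a <= 0):
        return PixelExtraction(nan, nan.copy(), env, False, xs)
    resid_sd = float(np.std(np.asarray(x, dtype=float) - xs))
    if float(np.median(finite_a)) < snr_min * resid_sd:
        return PixelExtraction(nan, nan.copy(), env, False, xs)
    th = phase(xs, times, env)
    return PixelExtraction(th, a, env, True, xs)


def extract_movie(
    movie: MovieGrid,
    window: float = 6.0,
    period_hint: float = 24.0,
) -> PhaseAmplitudeField:
    """Per-pixel envelope extraction over a whole movie."""
    h, w, t = movie.shape
    theta = np.full((h, w, t), np.nan)
    amp = np.full((h, w, t), np.nan)
    osc = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            if not movie.mask[i, j]:
                continue
            res = extract_pixel(movie.intensities[i, j], movie.time_axis, window,
                                period_hint=period_hint)
            if res.oscillatory:
                theta[i, j] = res.theta
                amp[i, j] = res.amplitude
                osc[i, j] = True
    return PhaseAmplitudeField(
        theta=theta,
        amplitude=amp,
        oscillatory=osc,
        time_axis=movie.time_axis,
        pixel_size=movie.pixel_size,
    )
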