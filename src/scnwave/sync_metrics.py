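"""Synchronization and spatial-fluctuation statistics for phase fields.

Two scalar summaries are used throughout: the Kuramoto order parameter

    R e^{i Phi} = (1/N) sum_j e^{i theta_j}

over the valid pixels of a single-time-point phase field, and the spatial
phase fluctuation Delta, defined as the standard deviation of the phase
field after subtracting, at every pixel, the circular mean of the
surrounding ``window x window`` neighborhood (7x7 pixels for imaging data,
3x3 for the oscillator lattice, where one lattice site is one cell).
Delta is reported in rad/2pi, i.e. fractions of a cycle; multiplying by
the oscillation period converts it to a time.

A traveling phase wave appears as a near-linear spatial ramp in theta.
Both statistics are designed to be insensitive to it: R measures global
coherence, and the local detrending in Delta removes any linear ramp
exactly, isolating cell-scale jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "PhaseField",
    "SyncResult",
    "FluctuationResult",
    "WaveVelocityResult",
    "order_parameter",
    "spatial_detrend",
    "spatial_fluctuation",
    "delta_from_field",
    "phase_to_time",
    "wave_velocity",
]

TWO_PI = 2.0 * np.pi


@dataclass
class PhaseField:
    """A single-time-point phase image.

    Parameters
    ----------
    theta:
        Phase in radians, shape (H, W). Values outside ``mask`` are ignored.
    mask:
        Boolean validity flags, shape (H, W). Defaults to all-valid.
    pixel_size:
        Physical pixel pitch in mm (needed only for wave-velocity estimates).
    period:
        Oscillation period in hours (needed only for unit conversions).
    """

    theta: np.ndarray
    mask: np.ndarray | None = None
    pixel_size: float = 1.0
    period: float = 24.0

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.ndim != 2:
            raise ValueError("theta must be a 2-D array")
        if self.mask is None:
            self.mask = np.isfinite(self.theta)
        else:
            self.mask = np.asarray(self.mask, dtype=bool) & np.isfinite(self.theta)
        if self.mask.shape != self.theta.shape:
            raise ValueError("mask shape must match theta shape")


@dataclass
class SyncResult:
    R: float
    Phi: float
    n_valid: int


@dataclass
class FluctuationResult:
    delta: float
    detrended: np.ndarray
    window: int
    n_valid: int


@dataclass
class WaveVelocityResult:
    velocity: float          # mm/h, NaN when undefined
    gradient: float          # cycles/mm (signed mean spatial gradient)
    defined: bool
    n_lines: int = 1
    slopes: np.ndarray = field(default_factory=lambda: np.empty(0))


def wrap_phase(x: np.ndarray | float) -> np.ndarray | float:
    """Wrap phase difference(s) to the interval (-pi, pi]."""
    return -np.remainder(np.pi - np.asarray(x), TWO_PI) + np.pi


def order_parameter(fld: PhaseField) -> SyncResult:
    """Kuramoto order parameter of a phase field.

    R is the magnitude of the population mean of unit phase vectors and
    Phi its angle; R = 1 means every valid pixel carries the same phase
    (mod 2pi) and R = 0 complete incoherence.
    """
    theta = fld.theta[fld.mask]
    if theta.size == 0:
        raise ValueError("order_parameter: no valid pixels")
    z = np.exp(1j * theta).mean()
    return SyncResult(R=float(np.abs(z)), Phi=float(np.angle(z)), n_valid=int(theta.size))


def _window_sums(arr: np.ndarray, window: int) -> np.ndarray:
    """Sum over the window x window neighborhood of every pixel (zero pad)."""
    return ndimage.uniform_filter(arr, size=window, mode="constant", cval=0.0) * window**2


def spatial_detrend(
    fld: PhaseField,
    window: int = 7,
    exclude_center: bool = False,
    boundary: str = "exclude",
) -> np.ndarray:
    """Remove the local circular-mean phase from every pixel.

    The local mean is taken over the centered ``window x window``
    neighborhood using the resultant-vector (circular) mean.  For a
    strongly synchronized field (window spread well below a radian)
    this coincides with the arithmetic mean, but it remains correct
    across phase wraps.

    Parameters
    ----------
    exclude_center:
        Leave the pixel itself out of its local mean.  The default keeps
        it in (for i.i.d. cell jitter this shrinks the detrended SD by
        the factor sqrt(1 - 1/window**2), a ~1% effect for 7x7).
    boundary:
        ``"exclude"`` (default): only pixels whose full window lies
        inside the valid mask get a value (unbiased SD, and a linear
        phase ramp detrends to exactly zero).  ``"truncate"``: every
        valid pixel gets a value, averaging over whatever part of the
        window is valid; near edges a steep ramp then leaves a residual.

    Returns the detrended field delta-theta in radians, wrapped to
    (-pi, pi].
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    if boundary not in ("exclude", "truncate"):
        raise ValueError("boundary must be 'exclude' or 'truncate'")
    h, w = fld.theta.shape
    if h < window or w < window:
        raise ValueError("field smaller than the detrending window")

    m = fld.mask.astype(float)
    s = np.where(fld.mask, np.sin(fld.theta), 0.0)
    c = np.where(fld.mask, np.cos(fld.theta), 0.0)
    counts = _window_sums(m, window)
    ssum = _window_sums(s, window)
    csum = _window_sums(c, window)
    if exclude_center:
        ssum = ssum - s
        csum = csum - c
        counts = counts - m
    if boundary == "exclude":
        ok = (counts > window**2 - (1.5 if exclude_center else 0.5)) & fld.mask
    else:
        ok = (counts > 0.5) & fld.mask
    local_mean = np.arctan2(ssum, csum)

    out = np.full_like(fld.theta, np.nan)
    out[ok] = wrap_phase(fld.theta[ok] - local_mean[ok])
    if not np.any(ok):
        raise ValueError("spatial_detrend: no pixel has a valid window")
    return out


def spatial_fluctuation(detrended: np.ndarray, window: int = 7) -> FluctuationResult:
    """Delta: standard deviation of a detrended phase field, in rad/2pi."""
    vals = detrended[np.isfinite(detrended)]
    if vals.size < 2:
        raise ValueError("spatial_fluctuation: need at least 2 valid pixels")
    return FluctuationResult(
        delta=float(np.std(vals) / TWO_PI),
        detrended=detrended,
        window=window,
        n_valid=int(vals.size),
    )


def delta_from_field(fld: PhaseField, window: int = 7) -> float:
    """Convenience: detrend then take the fluctuation statistic."""
    return spatial_fluctuation(spatial_detrend(fld, window), window).delta


def phase_to_time(value: float, period: float) -> float:
    """Convert a phase quantity in rad/2pi (cycles) to a duration in hours.

    E.g. a fluctuation of 0.017 rad/2pi on a 24 h rhythm corresponds to
    0.017 * 24 h = 0.41 h, about 25 min.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    return value * period


def _line_slope(theta_line: np.ndarray, positions_mm: np.ndarray) -> float:
    """Least-squares slope (cycles/mm) of unwrapped phase along one line."""
    good = np.isfinite(theta_line)
    if good.sum() < 2:
        return np.nan
    phi = np.unwrap(theta_line[good]) / TWO_PI
    x = positions_mm[good]
    return float(np.polyfit(x, phi, 1)[0])


def wave_velocity(
    fields: Sequence[PhaseField],
    lines: Sequence[tuple[np.ndarray, np.ndarray]] | tuple[np.ndarray, np.ndarray],
    gradient_tol: float = 1e-4,
) -> WaveVelocityResult:
    """Estimate the phase-wave propagation speed along one or more lines.

    Each line is a (rows, cols) pair of pixel indices ordered along the
    propagation axis.  For every frame and every line the phase is
    unwrapped spatially and a least-squares slope of the space-time plot
    is taken; the mean slope g (cycles/mm) gives the speed

        v = 1 / (|g| * period)   [mm/h]

    since a wave of speed v and period T carries a spatial phase gradient
    of 1/(v*T) cycles per mm.  A near-flat mean gradient (|g| below
    ``gradient_tol`` cycles/mm) yields an undefined-velocity flag.
    """
    if len(fields) == 0:
        raise ValueError("wave_velocity: need at least one field")
    if isinstance(lines, tuple) and not isinstance(lines[0], tuple):
        lines = [lines]  # single (rows, cols) pair

    period = fields[0].period
    pixel_size = fields[0].pixel_size
    slopes = []
    for rows, cols in lines:
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        steps = np.hypot(np.diff(rows.astype(float)), np.diff(cols.astype(float)))
        pos = np.concatenate([[0.0], np.cumsum(steps)]) * pixel_size
        for fld in fields:
            theta = np.where(fld.mask, fld.theta, np.nan)[rows, cols]
            slopes.append(_line_slope(theta, pos))
    slopes = np.asarray(slopes)
    slopes = slopes[np.isfinite(slopes)]
    if slopes.size == 0:
        return WaveVelocityResult(np.nan, np.nan, False, len(lines))
    g = float(slopes.mean())
    if abs(g) < gradient_tol:
        return WaveVelocityResult(np.nan, g, False, len(lines), slopes)
    return WaveVelocityResult(
        velocity=float(1.0 / (abs(g) * period)),
        gradient=g,
        defined=True,
        n_lines=len(lines),
        slopes=slopes,
    )
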