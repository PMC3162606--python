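"""Locally coupled phase-oscillator lattice model of the SCN slice.

The dorsal SCN is modeled as an N1 x N2 x NL cuboid of phase oscillators
with nearest-neighbor (6-connected, open-boundary) sinusoidal coupling:

    dtheta_i/dt = omega_i + K * sum_{j ~ i} sin(theta_j - theta_i) + xi_i(t)

* omega_i ~ N(<omega>, sigma_omega) i.i.d., with <omega> = 1 so one model
  cycle (2pi time units) maps onto 24 h of biology;
* the x = 0 plane is the pacemaker: its oscillators run a fixed factor
  (default 1.04) faster, which launches a traveling phase wave across
  the lattice, as the dmSCN does across the slice;
* the surface layer z = 0 (what the camera sees) loses each site
  independently with probability gamma ("extinct" cells); dead sites
  carry no dynamical state, and the displayed surface phase at a defect
  is that of the live oscillator directly beneath it;
* xi_i is independent white Gaussian noise with
  <xi_i(t) xi_j(s)> = 2 D delta_ij delta(t - s).

Integration is fourth-order Runge-Kutta with dt = 0.02 on the
deterministic part; the noise increment is added after each step.  Two
noise conventions are supported:

* ``noise_mode="forcing"`` (default): the noise is treated as a forcing
  of amplitude sqrt(2 D) sampled once per time step and carried through
  the Runge-Kutta update, i.e. the per-step increment is
  sqrt(2 D) * dt * N(0,1).  This is how such lattice simulations are
  commonly coded, and the robustness thresholds quoted for this model
  family (synchrony up to D of order 1-10) are on this D scale.  Its
  equivalent continuous-time intensity is D * dt.
* ``noise_mode="em"``: exact Euler-Maruyama increment
  sqrt(2 D dt) * N(0,1), realizing the covariance
  <xi_i(t) xi_j(s)> = 2 D delta_ij delta(t - s) literally; use this when
  D must be a true white-noise intensity (per-oscillator phase variance
  grows as 2 D t when K = 0).

Both reduce to plain RK4 when D = 0.  All runs start fully synchronized
(theta_i = 0).

The coupling sum is evaluated via sin(theta_j - theta_i) =
cos(theta_i) * sum_j sin(theta_j) - sin(theta_i) * sum_j cos(theta_j),
so each Runge-Kutta stage needs one sin and one cos per oscillator;
many runs (replicates, sweep points) are integrated in one batched
array, and phases are wrapped periodically so single precision (the
default) keeps full trigonometric accuracy.  See docs/methods.md for
the numerical error budget.

The coupling term is the plain sum over live nearest neighbors (the
convention under which the reference critical couplings K_c ~ 0.05-0.11
arise); a variant normalized by the live-neighbor count n_i, which keeps
the per-site coupling comparable between bulk, boundary and
defect-adjacent oscillators but rescales K_c by roughly the mean degree,
is available via ``SimConfig.normalize_by_degree = True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Any, Sequence

import numpy as np

from .sync_metrics import PhaseField

__all__ = [
    "SimConfig",
    "LatticeState",
    "SurfaceTrace",
    "EnsembleResult",
    "build_lattice",
    "step",
    "simulate",
    "run_ensemble",
    "surface_phase",
    "model_delta",
]

TWO_PI = 2.0 * np.pi


@dataclass
class SimConfig:
    """All parameters of one lattice simulation."""

    coupling: float = 0.1             # K
    n1: int = 20                      # lattice width  (x: pacemaker axis)
    n2: int = 20                      # lattice length (y)
    nl: int = 10                      # layers         (z: z=0 is the imaged surface)
    omega_mean: float = 1.0
    sigma_omega: float = 0.05
    gamma: float = 0.0                # surface defect probability
    noise_intensity: float = 0.0      # D
    noise_mode: str = "forcing"       # "forcing" | "em", see class docstring
    pacemaker_boost: float = 1.04     # factor applied to omega_i on the x=0 plane
    dt: float = 0.02
    t_end: float = 500.0
    transient: float = 250.0          # discarded before steady-state statistics
    obs_stride: float = 1.0           # time units between surface observations
    normalize_by_degree: bool = False  # True: coupling K/n_i per site
    seed: int = 0
    dtype: str = "float32"            # integration precision ("float32"|"float64")

    def validate(self) -> None:
        if min(self.n1, self.n2, self.nl) < 1:
            raise ValueError("lattice dimensions must be >= 1")
        if self.dt <= 0 or self.t_end <= 0:
            raise ValueError("dt and t_end must be positive")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.coupling < 0 or self.noise_intensity < 0 or self.sigma_omega < 0:
            raise ValueError("coupling, noise_intensity, sigma_omega must be >= 0")
        if self.pacemaker_boost <= 0:
            raise ValueError("pacemaker_boost must be positive")
        if self.noise_mode not in ("forcing", "em"):
            raise ValueError("noise_mode must be 'forcing' or 'em'")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class LatticeState:
    """Phases, frequencies and structure of one lattice realization.

    All arrays have shape (n1, n2, nl).  ``live`` is False at surface
    defects; dead sites have omega = 0 and never influence the dynamics.
    """

    theta: np.ndarray
    omega: np.ndarray
    live: np.ndarray
    pacemaker: np.ndarray
    n_neighbors: np.ndarray
    time: float = 0.0

    @property
    def n_live(self) -> int:
        return int(self.live.sum())


@dataclass
class SurfaceTrace:
    """Observed surface dynamics of one simulation."""

    times: np.ndarray
    delta: np.ndarray                 # rad/2pi
    order_param: np.ndarray           # R(t) over the displayed surface
    final_surface: np.ndarray         # wrapped phases, (n1, n2)
    surface_mask: np.ndarray          # False where a whole column is dead
    config: SimConfig

    def steady_delta(self) -> float:
        """Mean Delta over post-transient observations."""
        keep = self.times >= self.config.transient
        return float(np.mean(self.delta[keep]))


@dataclass
class EnsembleResult:
    """Batched simulation output: one row per ensemble member."""

    times: np.ndarray
    delta: np.ndarray                 # (B, n_obs)
    order_param: np.ndarray           # (B, n_obs)
    final_surface: np.ndarray         # (B, n1, n2), wrapped to [0, 2pi)
    final_surface_unwrapped: np.ndarray  # (B, n1, n2), accumulated phase
    surface_mask: np.ndarray          # (B, n1, n2)
    configs: list


def _structure_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))


def _noise_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))


def _neighbor_count(live: np.ndarray) -> np.ndarray:
    n = np.zeros(live.shape, dtype=float)
    lv = live.astype(float)
    for ax in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(None, -1)
        sl_hi[ax] = slice(1, None)
        n[tuple(sl_lo)] += lv[tuple(sl_hi)]
        n[tuple(sl_hi)] += lv[tuple(sl_lo)]
    return n


def build_lattice(config: SimConfig) -> LatticeState:
    """Draw frequencies and defects and assemble the initial state.

    Natural frequencies are drawn i.i.d. N(omega_mean, sigma_omega); the
    pacemaker boost multiplies each drawn omega_i on the x = 0 plane (it
    scales the individual frequency, not the plane mean).  Surface
    (z = 0) sites are deleted with probability gamma.  The initial
    condition is complete synchrony, theta_i = 0.
    """
    config.validate()
    rng = _structure_rng(config.seed)
    shape = (config.n1, config.n2, config.nl)
    omega = rng.normal(config.omega_mean, config.sigma_omega, shape)
    omega[0, :, :] *= config.pacemaker_boost
    live = np.ones(shape, dtype=bool)
    if config.gamma > 0:
        live[:, :, 0] = rng.random((config.n1, config.n2)) >= config.gamma
    omega = np.where(live, omega, 0.0)
    pacemaker = np.zeros(shape, dtype=bool)
    pacemaker[0, :, :] = live[0, :, :]
    return LatticeState(
        theta=np.zeros(shape),
        omega=omega,
        live=live,
        pacemaker=pacemaker,
        n_neighbors=_neighbor_count(live),
        time=0.0,
    )


try:  # fused neighbor-sum/drift kernel; trig stays in numpy (SIMD)
    import numba as _nb

    # fastmath stays OFF: reassociation licenses alignment-dependent SIMD
    # reductions, which coupled (chaotic) dynamics amplify into run-to-run
    # differences; strict IEEE ops keep results bit-reproducible.
    @_nb.njit(cache=True)
    def _drift_kernel(s, c, kdivn, omega, o1, o2, out):  # pragma: no cover - jit
        b, m = s.shape
        for ib in range(b):
            sb = s[ib]
            cb = c[ib]
            kb = kdivn[ib]
            ob = omega[ib]
            outb = out[ib]
            for i in range(o1, m - o1):
                ssum = (sb[i - 1] + sb[i + 1] + sb[i - o2] + sb[i + o2]
                        + sb[i - o1] + sb[i + o1])
                csum = (cb[i - 1] + cb[i + 1] + cb[i - o2] + cb[i + o2]
                        + cb[i - o1] + cb[i + o1])
                outb[i] = ob[i] + kb[i] * (cb[i] * ssum - sb[i] * csum)

    @_nb.njit(cache=True)
    def _rk4_combine(th, k1, k2, k3, k4, dt6):  # pragma: no cover - jit
        b, m = th.shape
        for ib in range(b):
            for i in range(m):
                th[ib, i] += dt6 * (
                    k1[ib, i] + 2.0 * (k2[ib, i] + k3[ib, i]) + k4[ib, i]
                )

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


class _BatchEngine:
    """Vectorized RK4(+noise) integrator over a batch of lattice states.

    All batch members must share (n1, n2, nl, dt); coupling, frequencies,
    defects and noise intensity may differ per member.

    Internally each lattice is stored flattened with a one-site ghost
    shell of permanently dead sites on every face, so the six neighbor
    sums become contiguous shifted reads (SIMD-friendly) and open
    boundaries fall out of the ghost zeros.
    """

    def __init__(self, states: Sequence[LatticeState], configs: Sequence[SimConfig]):
        if len(states) != len(configs) or not states:
            raise ValueError("need one config per state")
        c0 = configs[0]
        for c in configs:
            if (c.n1, c.n2, c.nl, c.dt) != (c0.n1, c0.n2, c0.nl, c0.dt):
                raise ValueError("batched runs must share lattice shape and dt")
        self.configs = list(configs)
        self.dtype = np.float32 if c0.dtype == "float32" else np.float64
        self.dt = c0.dt
        b = len(states)
        n1, n2, nl = c0.n1, c0.n2, c0.nl
        self.dims = (n1, n2, nl)
        p1, p2, p3 = n1 + 2, n2 + 2, nl + 2
        self._padded = (b, p1, p2, p3)
        m = p1 * p2 * p3
        self.m = m
        self.o1 = p2 * p3
        self.o2 = p3
        self.shape = (b, n1, n2, nl)

        def flat(per_state_arrays, dtype):
            arr = np.zeros((b, p1, p2, p3), dtype)
            arr[:, 1:-1, 1:-1, 1:-1] = np.stack(per_state_arrays)
            return np.ascontiguousarray(arr.reshape(b, m))

        self.theta = flat([s.theta for s in states], self.dtype)
        self.live = flat([s.live for s in states], self.dtype)
        self.omega = flat([s.omega for s in states], self.dtype)
        kdivn = []
        for s, c in zip(states, configs):
            if c.normalize_by_degree:
                with np.errstate(divide="ignore", invalid="ignore"):
                    kn = np.where(s.n_neighbors > 0, c.coupling / s.n_neighbors, 0.0)
            else:
                kn = np.full(s.theta.shape, c.coupling)
            kdivn.append(np.where(s.live, kn, 0.0))
        self.kdivn = flat(kdivn, self.dtype)
        self.noise_amp = np.array(
            [
                np.sqrt(2.0 * c.noise_intensity) * c.dt
                if c.noise_mode == "forcing"
                else np.sqrt(2.0 * c.noise_intensity * c.dt)
                for c in configs
            ],
            dtype=self.dtype,
        ).reshape(b, 1, 1, 1)
        self.noisy = bool(np.any(self.noise_amp > 0))
        self.noise_rngs = [_noise_rng(c.seed) for c in configs]
        # work buffers
        self._s = np.zeros((b, m), self.dtype)
        self._c = np.zeros((b, m), self.dtype)
        self._ss = np.zeros((b, m), self.dtype)
        self._sc = np.zeros((b, m), self.dtype)
        self._k = [np.zeros((b, m), self.dtype) for _ in range(4)]
        self._tmp = np.zeros((b, m), self.dtype)
        # surface display: at a defect show the live site with the smallest z > 0
        live_cols = np.stack([s.live for s in states])       # (b, n1, n2, nl) bool
        zidx = np.argmax(live_cols, axis=3)                   # first live z per column
        self.surface_mask = live_cols.any(axis=3)
        bi, xi, yi = np.meshgrid(
            np.arange(b), np.arange(n1), np.arange(n2), indexing="ij"
        )
        # flat padded index of the displayed site for every surface pixel
        self._surf_flat = (
            bi * 0 + (xi + 1) * self.o1 + (yi + 1) * self.o2 + (zidx + 1)
        )
        self._bi = bi
        self.surf_offset = np.zeros((b, n1, n2))  # removed 2pi multiples, exact

    def _interior(self, arr: np.ndarray) -> np.ndarray:
        """(B, n1, n2, nl) strided view of a flat padded array."""
        b = arr.shape[0]
        return arr.reshape(self._padded)[:, 1:-1, 1:-1, 1:-1]

    # -- dynamics ----------------------------------------------------------

    def _drift(self, theta: np.ndarray, out: np.ndarray) -> None:
        s, c = self._s, self._c
        np.sin(theta, out=s)
        s *= self.live
        np.cos(theta, out=c)
        c *= self.live
        if _HAVE_NUMBA:
            _drift_kernel(s, c, self.kdivn, self.omega, self.o1, self.o2, out)
            return
        ss, sc, tmp = self._ss, self._sc, self._tmp
        o1, o2, m = self.o1, self.o2, self.m
        for buf, src in ((ss, s), (sc, c)):
            np.add(src[:, : m - 1], src[:, 1:], out=buf[:, : m - 1])
            buf[:, 1:] += src[:, : m - 1]
            buf[:, : m - o2] += src[:, o2:]
            buf[:, o2:] += src[:, : m - o2]
            buf[:, : m - o1] += src[:, o1:]
            buf[:, o1:] += src[:, : m - o1]
        # coupling = cos(theta_i) * S_sin - sin(theta_i) * S_cos
        np.multiply(c, ss, out=out)
        np.multiply(s, sc, out=tmp)
        out -= tmp
        out *= self.kdivn
        out += self.omega

    def rk4_step(self) -> None:
        th, dt = self.theta, self.dt
        k1, k2, k3, k4 = self._k
        tmp = self._tmp
        self._drift(th, k1)
        np.multiply(k1, self.dtype(dt / 2.0), out=tmp)
        tmp += th
        self._drift(tmp, k2)
        np.multiply(k2, self.dtype(dt / 2.0), out=tmp)
        tmp += th
        self._drift(tmp, k3)
        np.multiply(k3, self.dtype(dt), out=tmp)
        tmp += th
        self._drift(tmp, k4)
        if _HAVE_NUMBA:
            _rk4_combine(th, k1, k2, k3, k4, self.dtype(dt / 6.0))
        else:
            k2 += k3
            k2 *= 2.0
            k1 += k4
            k1 += k2
            k1 *= self.dtype(dt / 6.0)
            th += k1

    def add_noise(self, block: np.ndarray) -> None:
        """block: (B, n1, n2, nl) standard normals; dead sites get none."""
        view = self._interior(self.theta)
        view += self.noise_amp * block * self._interior(self.live)

    def wrap(self) -> None:
        """Wrap phases into [0, 2pi), bookkeeping the exact 2pi multiples
        removed from surface pixels so observed phases stay unwrapped.

        The drift depends on theta only through sin/cos, so wrapping
        leaves the dynamics unchanged while keeping single-precision
        trigonometry accurate over arbitrarily long runs.
        """
        pre = self.surface().astype(np.float64)
        np.remainder(self.theta, self.dtype(TWO_PI), out=self.theta)
        post = self.surface().astype(np.float64)
        self.surf_offset += TWO_PI * np.rint((pre - post) / TWO_PI)

    # -- observation -------------------------------------------------------

    def surface(self) -> np.ndarray:
        """Displayed surface phases (defects replaced from beneath)."""
        flat = np.take_along_axis(
            self.theta, self._surf_flat.reshape(self._surf_flat.shape[0], -1), axis=1
        )
        return flat.reshape(self._surf_flat.shape)

    def surface_unwrapped(self) -> np.ndarray:
        """Surface phases with the removed 2pi multiples restored."""
        return self.surface().astype(np.float64) + self.surf_offset

    def observe(self) -> tuple[np.ndarray, np.ndarray]:
        """(Delta, R) per batch member on the displayed surface.

        Delta is the standard deviation, over all surface pixels, of the
        unwrapped phase minus the arithmetic mean of its 3x3 neighbors
        (center excluded, windows truncated at the lattice boundary; one
        lattice site is one cell).  Working on unwrapped phases matters:
        below the critical coupling accumulated phase slips make Delta
        grow without bound, which is the signature the trajectory
        classifier keys on.  R uses the wrapped phases (it is
        2pi-periodic anyway).
        """
        surf = self.surface_unwrapped()
        mask = self.surface_mask
        vals = np.where(mask, surf, 0.0)
        cnt = _box_sum_padded(mask.astype(float))
        tot = _box_sum_padded(vals)
        nbr_cnt = cnt - mask
        with np.errstate(invalid="ignore", divide="ignore"):
            nbr_mean = (tot - vals) / nbr_cnt
        d = surf - nbr_mean
        d = np.where(mask & (nbr_cnt > 0), d, np.nan)
        delta = np.nanstd(d.reshape(d.shape[0], -1), axis=1) / TWO_PI
        s = np.sin(surf)
        c = np.cos(surf)
        z = (np.where(mask, c, 0.0).sum(axis=(1, 2))
             + 1j * np.where(mask, s, 0.0).sum(axis=(1, 2)))
        r = np.abs(z) / np.maximum(mask.sum(axis=(1, 2)), 1)
        return delta, r


def _box_sum_padded(a: np.ndarray) -> np.ndarray:
    """Sum over 3x3 neighborhoods with zero padding; shape-preserving."""
    b, h, w = a.shape
    p = np.zeros((b, h + 2, w + 2), a.dtype)
    p[:, 1:-1, 1:-1] = a
    return (
        p[:, :-2, :-2] + p[:, :-2, 1:-1] + p[:, :-2, 2:]
        + p[:, 1:-1, :-2] + p[:, 1:-1, 1:-1] + p[:, 1:-1, 2:]
        + p[:, 2:, :-2] + p[:, 2:, 1:-1] + p[:, 2:, 2:]
    )


_NOISE_BLOCK = 100  # steps of pre-drawn noise increments per batch member


def run_ensemble(
    configs: Sequence[SimConfig],
    states: Sequence[LatticeState] | None = None,
) -> EnsembleResult:
    """Integrate a batch of lattice simulations and record surface metrics.

    Surface Delta (3x3-detrended, rad/2pi) and the order parameter R are
    sampled every ``obs_stride`` time units, including t = 0.
    """
    configs = list(configs)
    if states is None:
        states = [build_lattice(c) for c in configs]
    eng = _BatchEngine(states, configs)
    c0 = configs[0]
    n_steps = int(round(c0.t_end / c0.dt))
    stride = max(1, int(round(c0.obs_stride / c0.dt)))
    wrap_every = 50

    times, deltas, orders = [], [], []
    d0, r0 = eng.observe()
    times.append(0.0)
    deltas.append(d0)
    orders.append(r0)

    noise_block = None
    for istep in range(1, n_steps + 1):
        eng.rk4_step()
        if eng.noisy:
            j = (istep - 1) % _NOISE_BLOCK
            if j == 0:
                n_draw = min(_NOISE_BLOCK, n_steps - istep + 1)
                noise_block = np.stack(
                    [
                        rng.standard_normal(
                            (n_draw,) + eng.shape[1:], dtype=eng.dtype
                        )
                        for rng in eng.noise_rngs
                    ]
                )
            eng.add_noise(noise_block[:, j])
        if istep % wrap_every == 0:
            eng.wrap()
        if istep % stride == 0:
            if not np.all(np.isfinite(eng.theta)):
                bad = ~np.isfinite(eng.theta)
                raise FloatingPointError(
                    f"non-finite phases at t={istep * c0.dt:.2f} "
                    f"in {int(bad.any(axis=(1, 2, 3)).sum())} batch member(s)"
                )
            d, r = eng.observe()
            times.append(istep * c0.dt)
            deltas.append(d)
            orders.append(r)

    eng.wrap()
    return EnsembleResult(
        times=np.asarray(times),
        delta=np.stack(deltas, axis=1),
        order_param=np.stack(orders, axis=1),
        final_surface=eng.surface().astype(np.float64),
        final_surface_unwrapped=eng.surface_unwrapped(),
        surface_mask=eng.surface_mask,
        configs=configs,
    )


def simulate(config: SimConfig, state: LatticeState | None = None) -> SurfaceTrace:
    """Run one lattice simulation (see :func:`run_ensemble`)."""
    res = run_ensemble([config], None if state is None else [state])
    return SurfaceTrace(
        times=res.times,
        delta=res.delta[0],
        order_param=res.order_param[0],
        final_surface=res.final_surface[0],
        surface_mask=res.surface_mask[0],
        config=config,
    )


def step(state: LatticeState, config: SimConfig,
         rng: np.random.Generator | None = None) -> LatticeState:
    """Advance one RK4 step of length dt (plus a noise increment if D > 0).

    Reference single-step interface built on the same engine as
    :func:`run_ensemble`; intended for unit-scale checks, not for long
    production runs (use :func:`simulate` for those).
    """
    eng = _BatchEngine([state], [config])
    eng.rk4_step()
    if config.noise_intensity > 0:
        rng = rng if rng is not None else _noise_rng(config.seed)
        eng.add_noise(rng.standard_normal(eng.shape, dtype=eng.dtype))
    if not np.all(np.isfinite(eng.theta)):
        raise FloatingPointError("non-finite phase after step")
    state.theta = eng._interior(eng.theta)[0].astype(np.float64)
    state.time += config.dt
    return state


def surface_phase(state: LatticeState, pixel_size: float = 1.0,
                  period: float = TWO_PI) -> PhaseField:
    """Displayed surface (z = 0) phase field of a lattice state.

    At a surface defect the phase of the live oscillator with the
    smallest z beneath that (x, y) column is displayed, emulating the
    bioluminescence of interior cells showing through; columns with no
    live oscillator at any depth are masked.
    """
    live = state.live
    zidx = np.argmax(live, axis=2)
    any_live = live.any(axis=2)
    n1, n2 = live.shape[:2]
    xi, yi = np.meshgrid(np.arange(n1), np.arange(n2), indexing="ij")
    theta = state.theta[xi, yi, zidx]
    return PhaseField(theta=np.where(any_live, theta, np.nan), mask=any_live,
                      pixel_size=pixel_size, period=period)


def model_delta(fld: PhaseField) -> float:
    """Delta of a model surface field, using a 3x3 detrending window.

    In the model one lattice site is one cell, so the cell-scale window
    is 3x3 sites (the imaging counterpart uses 7x7 pixels = 3x3 cells).
    The local mean is over the eight neighboring oscillators (center
    excluded), truncated at the lattice boundary so every surface site
    contributes -- on a 20x20 surface the boundary sites are a fifth of
    the total and carry the largest locking lags, so dropping them would
    understate the fluctuation.  This is the same convention the
    simulation engine applies to its unwrapped Delta(t) series.
    """
    from .sync_metrics import spatial_detrend, spatial_fluctuation

    d = spatial_detrend(fld, window=3, exclude_center=True, boundary="truncate")
    return spatial_fluctuation(d, window=3).delta
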