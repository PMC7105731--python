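"""Monodomain reaction–diffusion on regular 2D sheets and 3D slabs.

Propagation of the membrane potential is governed by the monodomain
equation: the ionic cell model supplies the reaction term and a per-axis
effective diffusion coefficient D (mm^2/ms) — absorbing tissue resistivity,
surface-to-volume ratio and membrane capacitance — supplies conduction.
Boundaries are no-flux. Time stepping is operator-split: an explicit
reaction step per node followed by a second-order central-difference
diffusion step, with the explicit stability bound dt <= h^2 / (2 dim D)
checked up front.

Because the underlying experiment reports only conduction velocities
(20 cm/s during reentry generation, 68.5 cm/s during maintenance) and not
resistivity values, the contract here is CV calibration: ``calibrate_diffusion``
bisects on D until a planar wave on a 1D cable travels at the target speed.

The two-phase protocol is: three S1 stimuli 600 ms apart at one edge, an S2
stimulus over a half/quadrant region fired when the wave tail of the last S1
repolarizes at a mid-line monitor node (reentry generation, low CV), then a
stimulus-free continuation from the saved state at normal CV (reentry
maintenance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from numba import njit

from .cell_models import (
    CellParams, NVAR_DETAILED, NVAR_REDUCED, _Y0_DETAILED, _Y0_REDUCED,
    _tp06_step, _fk_step, FK_V_REST, FK_V_SPAN,
)

__all__ = [
    "TissueGrid", "StimulusProtocol", "VoltageMovie", "PhasePlan",
    "Checkpoint", "S2Region", "CalibrationError", "NoPropagationError",
    "ProtocolFailure",
    "calibrate_diffusion", "measure_cv", "run_s1s2", "run_maintenance",
    "simulate_phase", "diffusion_only_movie",
]

FRAME_DT = 10.0   # ms; output cadence of every voltage movie


class CalibrationError(RuntimeError):
    pass


class NoPropagationError(RuntimeError):
    pass


class ProtocolFailure(RuntimeError):
    pass


class S2Region(str, Enum):
    LEFT_HALF = "LEFT_HALF"
    LOWER_LEFT_QUADRANT = "LOWER_LEFT_QUADRANT"
    RIGHT_HALF = "RIGHT_HALF"
    LOWER_RIGHT_QUADRANT = "LOWER_RIGHT_QUADRANT"


@dataclass
class TissueGrid:
    """Regular grid with spacing ``h`` (mm) and per-axis diffusion (mm^2/ms).

    Node-centered coordinates x = i * h, 0-based indices; ``nz = 1`` makes a
    2D sheet. ``mask`` marks tissue nodes (full rectangle by default).
    """

    nx: int
    ny: int
    nz: int = 1
    h: float = 0.25
    d_x: float = 0.1
    d_y: float = 0.1
    d_z: float = 0.1
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError("spacing h must be positive")
        if min(self.d_x, self.d_y, self.d_z) < 0:
            raise ValueError("diffusion coefficients must be >= 0")
        if self.mask is None:
            self.mask = np.ones(self.shape, dtype=bool)
        if not self.mask.any():
            raise ValueError("tissue mask is empty")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nz, self.ny, self.nx)

    @property
    def n_nodes(self) -> int:
        return self.nz * self.ny * self.nx

    def with_diffusion(self, d: float) -> "TissueGrid":
        return TissueGrid(self.nx, self.ny, self.nz, self.h, d, d, d,
                          self.mask.copy())

    def region_mask(self, region: S2Region) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        hx, hy = self.nx // 2, self.ny // 2
        if region is S2Region.LEFT_HALF:
            m[:, :, :hx] = True
        elif region is S2Region.RIGHT_HALF:
            m[:, :, hx:] = True
        elif region is S2Region.LOWER_LEFT_QUADRANT:
            m[:, :hy, :hx] = True
        elif region is S2Region.LOWER_RIGHT_QUADRANT:
            m[:, :hy, hx:] = True
        return m & self.mask

    def max_stable_dt(self) -> float:
        dsum = (self.d_x * (self.nx > 1) + self.d_y * (self.ny > 1)
                + self.d_z * (self.nz > 1))
        if dsum == 0:
            return np.inf
        return self.h ** 2 / (2.0 * dsum)


@dataclass
class StimulusProtocol:
    """Three S1 pulses at one edge, then a region S2 triggered by the wave
    tail of the last S1 reaching the middle of the stimulated region.

    The monitor node is the part of the S2 region that the S1 wave reaches
    last: when its wave tail repolarizes, the whole region is excitable
    while tissue just beyond it is still refractory, which is the
    unidirectional-block geometry that lets the S2 wavefront break and
    curl into a rotor."""

    s2_region: S2Region = S2Region.LOWER_LEFT_QUADRANT
    s1_interval: float = 600.0        # ms between the three S1 pulses
    s1_width: int = 3                 # columns stimulated at the left edge
    stim_amplitude: float | None = None  # None -> model default
    s2_amplitude: float | None = None    # None -> same as S1
    stim_duration: float = 2.0        # ms
    s2_tail_threshold: float = -80.0  # mV; repolarization level firing S2
                                      # (deep in the tail: the monitor
                                      # region must be fully re-excitable)

    def s1_mask(self, grid: TissueGrid) -> np.ndarray:
        m = np.zeros(grid.shape, dtype=bool)
        m[:, :, :self.s1_width] = True
        return m & grid.mask

    def monitor_index(self, grid: TissueGrid) -> int:
        """Flat index of the node whose repolarization fires S2: the wave
        tail must have cleared the S2 region up to the middle portion of
        the sheet, so refractory tissue still lies beyond the monitor.

        Along the propagation axis this is the region's far edge, clamped
        to the sheet midline (for regions extending to the far boundary
        the tail would otherwise have left the domain entirely and no
        unidirectional block could form)."""
        mask = grid.region_mask(self.s2_region)
        idx = np.argwhere(mask)                     # (iz, iy, ix) rows
        far_x = min(idx[:, 2].max(), grid.nx // 2)
        at_edge = idx[idx[:, 2] == idx[:, 2][idx[:, 2] <= far_x].max()] \
            if (idx[:, 2] <= far_x).any() else idx
        at_edge = at_edge[at_edge[:, 2] == at_edge[:, 2].max()]
        mid_y = (grid.ny - 1) / 2
        best = at_edge[np.argmin(np.abs(at_edge[:, 1] - mid_y))]
        iz, iy, ix = (int(v) for v in best)
        return iz * grid.ny * grid.nx + iy * grid.nx + ix


@dataclass
class PhasePlan:
    """Target conduction velocities and durations of the two phases."""

    generation_cv: float = 20.0       # cm/s
    generation_duration: float = 10_000.0   # ms
    maintenance_cv: float = 68.5      # cm/s
    maintenance_duration: float = 20_000.0  # ms

    def __post_init__(self) -> None:
        if min(self.generation_cv, self.maintenance_cv) <= 0:
            raise ValueError("conduction velocities must be positive")
        if min(self.generation_duration, self.maintenance_duration) <= 0:
            raise ValueError("durations must be positive")


@dataclass
class VoltageMovie:
    """Space–time membrane potential, one frame every 10 ms.

    ``frames`` has shape (n_frames, nz, ny, nx) in mV.
    """

    grid: TissueGrid
    times: np.ndarray
    frames: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        steps = np.diff(self.times)
        if len(steps) and not np.allclose(steps, FRAME_DT):
            raise ValueError("frame cadence must be exactly 10 ms")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def node_trace(self, iz: int, iy: int, ix: int) -> np.ndarray:
        return self.frames[:, iz, iy, ix].astype(np.float64)

    def center_index(self) -> tuple[int, int, int]:
        return (self.grid.nz // 2, self.grid.ny // 2, self.grid.nx // 2)

    def save(self, path) -> None:
        import h5py, json
        with h5py.File(path, "w") as f:
            f.create_dataset("frames", data=self.frames.astype(np.float32),
                             compression="gzip")
            f.create_dataset("times_ms", data=self.times)
            f.attrs["dims"] = (self.grid.nx, self.grid.ny, self.grid.nz)
            f.attrs["spacing_mm"] = self.grid.h
            f.attrs["D"] = (self.grid.d_x, self.grid.d_y, self.grid.d_z)
            f.attrs["provenance"] = json.dumps(self.provenance, default=str)

    @classmethod
    def load(cls, path) -> "VoltageMovie":
        import h5py, json
        with h5py.File(path, "r") as f:
            nx, ny, nz = (int(v) for v in f.attrs["dims"])
            dx, dy, dz = (float(v) for v in f.attrs["D"])
            grid = TissueGrid(nx, ny, nz, float(f.attrs["spacing_mm"]),
                              dx, dy, dz)
            return cls(grid, f["times_ms"][:],
                       f["frames"][:].astype(np.float64),
                       json.loads(f.attrs.get("provenance", "{}")))


@dataclass
class Checkpoint:
    """Every state variable of every node at a moment in time."""

    t: float
    Y: np.ndarray          # (n_nodes, n_state_vars)
    shape: tuple[int, int, int]
    model_kind: str


# ---------------------------------------------------------------------------
# Compiled integration core
# ---------------------------------------------------------------------------

@njit(cache=True)
def _laplacian(v, lap, nz, ny, nx, dx, dy, dz, h2):
    """No-flux finite-volume Laplacian (ghost node = boundary node, so the
    flux across every outer face is exactly zero), scaled by D/h^2."""
    for iz in range(nz):
        zm = iz - 1 if iz > 0 else 0
        zp = iz + 1 if iz < nz - 1 else nz - 1
        for iy in range(ny):
            ym = iy - 1 if iy > 0 else 0
            yp = iy + 1 if iy < ny - 1 else ny - 1
            for ix in range(nx):
                xm = ix - 1 if ix > 0 else 0
                xp = ix + 1 if ix < nx - 1 else nx - 1
                c = v[iz, iy, ix]
                acc = dx * (v[iz, iy, xm] + v[iz, iy, xp] - 2.0 * c)
                acc += dy * (v[iz, ym, ix] + v[iz, yp, ix] - 2.0 * c)
                if nz > 1:
                    acc += dz * (v[zm, iy, ix] + v[zp, iy, ix] - 2.0 * c)
                lap[iz, iy, ix] = acc / h2


@njit(cache=True)
def _advance(Y, model_code, p, dt, n_steps, t0,
             nz, ny, nx, dx, dy, dz, h,
             s1_flat, s1_times, s2_flat, stim_dur, stim_amp, stim_amp_s2,
             monitor_idx, s2_threshold, s2_armed_after, s2_time_inout,
             frames, frame_stride, frame_offset, activation_time):
    """Advance the whole tissue for ``n_steps`` of ``dt`` starting at ``t0``.

    model_code: 0 = detailed ionic model, 1 = reduced model, 2 = diffusion only.
    ``s2_time_inout`` is a 1-element array: negative = not yet fired; the
    trigger logic writes the firing time once the monitor node repolarizes
    below ``s2_threshold`` after ``s2_armed_after``. ``activation_time``
    records each node's first upstroke time (-1 before activation).
    """
    n_nodes = nz * ny * nx
    v = np.empty((nz, ny, nx))
    lap = np.empty((nz, ny, nx))
    h2 = h * h
    n_s1 = len(s1_times)
    monitor_prev = Y[monitor_idx, 0] if model_code == 0 else \
        (FK_V_REST + FK_V_SPAN * Y[monitor_idx, 0]) if model_code == 1 else 0.0
    monitor_was_up = False

    for step in range(n_steps):
        t = t0 + step * dt
        # stimulus currents
        s1_on = False
        for k in range(n_s1):
            if s1_times[k] <= t < s1_times[k] + stim_dur:
                s1_on = True
        s2_fired = s2_time_inout[0]
        s2_on = (s2_fired >= 0.0) and np.isfinite(s2_fired) and \
            (s2_fired <= t) and (t < s2_fired + stim_dur)

        # reaction
        if model_code != 2:
            for i in range(n_nodes):
                istim = 0.0
                if s1_on and s1_flat[i]:
                    istim = stim_amp
                if s2_on and s2_flat[i]:
                    istim = stim_amp_s2
                if model_code == 0:
                    _tp06_step(Y[i], dt, istim, p)
                else:
                    _fk_step(Y[i], dt, istim, p)

        # diffusion on the voltage variable
        idx = 0
        for iz in range(nz):
            for iy in range(ny):
                for ix in range(nx):
                    v[iz, iy, ix] = Y[idx, 0]
                    idx += 1
        _laplacian(v, lap, nz, ny, nx, dx, dy, dz, h2)
        idx = 0
        for iz in range(nz):
            for iy in range(ny):
                for ix in range(nx):
                    Y[idx, 0] = v[iz, iy, ix] + dt * lap[iz, iy, ix]
                    idx += 1

        # activation bookkeeping (voltage in mV)
        up_thr = -40.0 if model_code == 0 else (-40.0 - FK_V_REST) / FK_V_SPAN \
            if model_code == 1 else 1e30
        for i in range(n_nodes):
            if activation_time[i] < 0.0 and Y[i, 0] >= up_thr:
                activation_time[i] = t + dt

        # S2 trigger: monitor repolarizes below threshold after being armed
        if s2_time_inout[0] < 0.0 and t + dt >= s2_armed_after:
            vm_mon = Y[monitor_idx, 0]
            if model_code == 1:
                vm_mon = FK_V_REST + FK_V_SPAN * vm_mon
            if vm_mon > -40.0:
                monitor_was_up = True
            if monitor_was_up and vm_mon < s2_threshold:
                s2_time_inout[0] = t + dt
            monitor_prev = vm_mon

        # frame recording
        if (step + 1) % frame_stride == 0:
            kf = frame_offset + (step + 1) // frame_stride
            idx = 0
            for iz in range(nz):
                for iy in range(ny):
                    for ix in range(nx):
                        vm = Y[idx, 0]
                        if model_code == 1:
                            vm = FK_V_REST + FK_V_SPAN * vm
                        frames[kf, iz, iy, ix] = vm
                        idx += 1


def _model_code(params: CellParams | None) -> int:
    if params is None:
        return 2
    return 0 if params.model_kind == "detailed" else 1


def _initial_Y(params: CellParams | None, n_nodes: int) -> np.ndarray:
    if params is None:
        return np.zeros((n_nodes, 1))
    y0 = _Y0_DETAILED if params.model_kind == "detailed" else _Y0_REDUCED
    return np.tile(y0, (n_nodes, 1))


def _check_stability(grid: TissueGrid, dt: float) -> None:
    lim = grid.max_stable_dt()
    if dt > lim:
        raise ValueError(
            f"dt={dt} ms violates the explicit diffusion stability bound "
            f"h^2/(2*dim*D) = {lim:.4g} ms")


def simulate_phase(grid: TissueGrid, params: CellParams | None,
                   duration: float,
                   protocol: StimulusProtocol | None = None,
                   Y: np.ndarray | None = None,
                   t0: float = 0.0,
                   s2_enabled: bool = True) -> tuple[VoltageMovie, Checkpoint, float]:
    """Low-level driver shared by the S1–S2 and maintenance runs.

    Returns (movie, final checkpoint, s2 firing time or -1).
    """
    code = _model_code(params)
    if params is not None:
        dt = params.default_dt
    else:
        dt_raw = min(0.1, 0.45 * grid.max_stable_dt())
        dt = FRAME_DT / np.ceil(FRAME_DT / dt_raw)   # commensurate with frames
    _check_stability(grid, dt)
    p = params.vector() if params is not None else np.zeros(1)

    if Y is None:
        Y = _initial_Y(params, grid.n_nodes)
    n_steps = int(round(duration / dt))
    frame_stride = int(round(FRAME_DT / dt))
    if abs(frame_stride * dt - FRAME_DT) > 1e-9:
        raise ValueError("dt must divide the 10 ms frame cadence")
    n_frames = n_steps // frame_stride
    nz, ny, nx = grid.shape
    frames = np.empty((n_frames + 1, nz, ny, nx), dtype=np.float64)
    frames[0] = Y[:, 0].reshape(grid.shape)
    if code == 1:
        frames[0] = FK_V_REST + FK_V_SPAN * frames[0]

    if protocol is not None:
        s1_flat = protocol.s1_mask(grid).ravel()
        s1_times = t0 + protocol.s1_interval * np.arange(3)
        s2_flat = grid.region_mask(protocol.s2_region).ravel()
        stim_amp = protocol.stim_amplitude
        if stim_amp is None:
            stim_amp = 52.0 if code == 0 else 3.0
        stim_amp_s2 = protocol.s2_amplitude
        if stim_amp_s2 is None:
            stim_amp_s2 = stim_amp
        armed_after = float(s1_times[-1]) + 5.0
        s2_time = np.array([-1.0]) if s2_enabled else np.array([np.inf])
        s2_threshold = protocol.s2_tail_threshold
        stim_dur = protocol.stim_duration
    else:
        s1_flat = np.zeros(grid.n_nodes, dtype=bool)
        s1_times = np.empty(0)
        s2_flat = np.zeros(grid.n_nodes, dtype=bool)
        stim_amp = 0.0
        stim_amp_s2 = 0.0
        stim_dur = 0.0
        armed_after = np.inf
        s2_time = np.array([np.inf])
        s2_threshold = -70.0

    if protocol is not None:
        monitor = protocol.monitor_index(grid)
    else:
        monitor = (grid.nz // 2) * ny * nx + (ny // 2) * nx + nx // 2
    activation = np.full(grid.n_nodes, -1.0)
    _advance(Y, code, p, dt, n_steps, t0, nz, ny, nx,
             grid.d_x, grid.d_y, grid.d_z, grid.h,
             s1_flat, np.asarray(s1_times, dtype=np.float64), s2_flat,
             stim_dur, float(stim_amp), float(stim_amp_s2), monitor,
             s2_threshold, armed_after, s2_time, frames, frame_stride, 0,
             activation)

    times = t0 + FRAME_DT * np.arange(n_frames + 1)
    movie = VoltageMovie(grid, times, frames)
    ck = Checkpoint(t0 + n_steps * dt, Y.copy(), grid.shape,
                    params.model_kind if params is not None else "none")
    fired = float(s2_time[0]) if np.isfinite(s2_time[0]) else -1.0
    return movie, ck, fired


# ---------------------------------------------------------------------------
# Conduction-velocity calibration
# ---------------------------------------------------------------------------

def _cable_cv(params: CellParams, d: float, h: float,
              n_nodes: int = 80, t_max: float = 250.0) -> float:
    """Planar-wave CV (cm/s) on a 1D cable with diffusion ``d``."""
    grid = TissueGrid(nx=n_nodes, ny=1, nz=1, h=h, d_x=d, d_y=0.0, d_z=0.0)
    code = _model_code(params)
    dt = params.default_dt
    _check_stability(grid, dt)
    Y = _initial_Y(params, n_nodes)
    stim_flat = np.zeros(n_nodes, dtype=bool)
    stim_flat[:4] = True
    activation = np.full(n_nodes, -1.0)
    frames = np.empty((1, 1, 1, n_nodes))
    amp = 52.0 if code == 0 else 3.0
    n_steps = int(round(t_max / dt))
    _advance(Y, code, params.vector(), dt, n_steps, 0.0, 1, 1, n_nodes,
             d, 0.0, 0.0, h,
             stim_flat, np.array([1.0]), np.zeros(n_nodes, dtype=bool),
             2.0, amp, 0.0, n_nodes // 2, -70.0, np.inf, np.array([np.inf]),
             frames, n_steps + 1, 0, activation)
    i1, i2 = int(0.35 * n_nodes), int(0.75 * n_nodes)
    t1, t2 = activation[i1], activation[i2]
    if t1 < 0 or t2 < 0 or t2 <= t1:
        raise NoPropagationError(
            f"wave did not traverse the cable (activation {t1}, {t2})")
    speed_mm_ms = (i2 - i1) * h / (t2 - t1)
    return speed_mm_ms * 100.0   # mm/ms -> cm/s


def calibrate_diffusion(params: CellParams, target_cv: float, h: float,
                        tol: float = 0.02, d_lo: float = 1e-4,
                        d_hi: float | None = None, max_iter: int = 40) -> float:
    """Bisection on D until the planar-wave CV is within ``tol`` of target.

    CV grows monotonically (roughly as sqrt(D)) with the diffusion
    coefficient, so plain bisection on the bracketed interval converges.
    """
    if target_cv <= 0:
        raise ValueError("target_cv must be positive")
    if d_hi is None:
        # largest D the explicit 1D-cable step remains stable for
        d_hi = 0.9 * h ** 2 / (2.0 * params.default_dt)
    t_max = max(250.0, 1.6 * 80 * h * 100.0 / target_cv)

    def cv_of(d):
        try:
            return _cable_cv(params, d, h, t_max=t_max)
        except NoPropagationError:
            return 0.0

    lo, hi = d_lo, d_hi
    cv_lo, cv_hi = cv_of(lo), cv_of(hi)
    if not (cv_lo < target_cv < cv_hi):
        raise CalibrationError(
            f"target {target_cv} cm/s not bracketed: CV({lo})={cv_lo:.2f}, "
            f"CV({hi})={cv_hi:.2f}")
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)   # geometric mean: CV ~ sqrt(D)
        cv_mid = cv_of(mid)
        if abs(cv_mid - target_cv) / target_cv < tol * 0.5:
            return mid
        if cv_mid < target_cv:
            lo = mid
        else:
            hi = mid
    return np.sqrt(lo * hi)


def measure_cv(movie: VoltageMovie, axis: str = "x",
               threshold: float = -40.0) -> float:
    """CV of a planar wave as plane distance / activation-time difference.

    Activation time of a plane is its earliest upward crossing of the
    threshold, with linear interpolation between the 10 ms frames. Result
    in cm/s, independent of wave direction.
    """
    ax = {"x": 3, "y": 2, "z": 1}[axis]
    n = movie.frames.shape[ax]
    i1, i2 = int(0.25 * n), int(0.75 * n)
    if i2 <= i1:
        raise ValueError("grid too small along the measurement axis")

    def plane_activation(i):
        plane = np.take(movie.frames, i, axis=ax)   # (nt, ...)
        v = plane.reshape(plane.shape[0], -1)
        best = np.inf
        for jn in range(v.shape[1]):
            s = v[:, jn]
            above = s >= threshold
            cross = np.flatnonzero(~above[:-1] & above[1:])
            if len(cross):
                k = cross[0]
                frac = (threshold - s[k]) / (s[k + 1] - s[k])
                t = movie.times[k] + frac * FRAME_DT
                best = min(best, t)
        return best

    t1, t2 = plane_activation(i1), plane_activation(i2)
    if not np.isfinite(t1) or not np.isfinite(t2):
        raise NoPropagationError("wave never reached a sampling plane")
    dt_ms = abs(t2 - t1)
    if dt_ms == 0:
        raise NoPropagationError("zero activation-time difference")
    return abs(i2 - i1) * movie.grid.h / dt_ms * 100.0


# ---------------------------------------------------------------------------
# Two-phase protocol
# ---------------------------------------------------------------------------

def run_s1s2(grid: TissueGrid, params: CellParams,
             protocol: StimulusProtocol, plan: PhasePlan,
             seed: int = 0) -> tuple[VoltageMovie, Checkpoint]:
    """Reentry-generation phase: 3 S1 beats, wave-tail-triggered S2.

    The model is deterministic; ``seed`` only stamps provenance. Raises
    :class:`ProtocolFailure` when the S2 trigger condition is never met.
    """
    movie, ck, s2_time = simulate_phase(
        grid, params, plan.generation_duration, protocol)
    if s2_time < 0:
        raise ProtocolFailure(
            "S2 trigger condition (wave-tail repolarization at the monitor "
            "node) was never met within the generation phase")
    movie.provenance = {
        "phase": "generation", "s2_region": protocol.s2_region.value,
        "s2_fired_ms": s2_time, "target_cv_cm_s": plan.generation_cv,
        "seed": seed, "model": params.model_kind,
        "gks_multiplier": params.gks_multiplier,
    }
    return movie, ck


def run_maintenance(checkpoint: Checkpoint, grid: TissueGrid,
                    params: CellParams, plan: PhasePlan,
                    duration: float | None = None) -> VoltageMovie:
    """Stimulus-free continuation from a saved state at maintenance CV."""
    if checkpoint.shape != grid.shape:
        raise ValueError(
            f"checkpoint shape {checkpoint.shape} does not match grid "
            f"{grid.shape}")
    if checkpoint.model_kind != params.model_kind:
        raise ValueError("checkpoint and params disagree on the cell model")
    duration = plan.maintenance_duration if duration is None else duration
    movie, _, _ = simulate_phase(grid, params, duration,
                                 Y=checkpoint.Y.copy(), t0=checkpoint.t)
    movie.provenance = {
        "phase": "maintenance", "target_cv_cm_s": plan.maintenance_cv,
        "model": params.model_kind, "gks_multiplier": params.gks_multiplier,
    }
    return movie


def diffusion_only_movie(grid: TissueGrid, v0: np.ndarray,
                         duration: float) -> VoltageMovie:
    """Pure-diffusion evolution of an initial field (ionic currents off);
    the oracle path for the diffusion operator and its no-flux boundaries."""
    Y = v0.reshape(-1, 1).astype(np.float64).copy()
    movie, _, _ = simulate_phase(grid, None, duration, Y=Y)
    movie.provenance = {"phase": "diffusion-only"}
    return movie
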