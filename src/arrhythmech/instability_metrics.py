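"""Electrical-instability quantifiers for voltage movies.

Four per-case scalars summarize how disorganized the excitation is during
reentry:

* mean reentry APD — APD90 averaged over the activations seen at a probe
  node (the domain center by default);
* dominant frequency (DF) — per node, the frequency of the highest spectral
  power of the membrane-potential signal, zero-padded to 0.01 Hz resolution,
  searched in a 0.5–30 Hz band; the case value is the mean over nodes that
  showed any activity;
* phase singularities (PS) — points where the excitation phase is undefined,
  found as 2x2 plaquettes around which the wrapped phase differences sum to
  +/- 2 pi (topological charge); the case value is the time-averaged count;
* filaments — in 3D, voxels whose interpolated centroid potential sits on
  the V_iso level in two consecutive frames (the discrete dV/dt = 0 +
  iso-potential condition); the case value is the time-averaged element
  count, with 26-connected components as a diagnostic.

The phase is a delay embedding: theta(x, t) = atan2(V(x, t + tau) - Vmean(t),
V(x, t) - Vmean(t)) with tau equal to one 10 ms frame by default and
Vmean(t) the spatial mean at t.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .cell_models import APTrace, apd90, detect_upstrokes, CensoredAPDError
from .tissue_sim import VoltageMovie, FRAME_DT

__all__ = [
    "PhaseParams", "PhaseField", "PSRecord", "FilamentParams",
    "FilamentRecord", "InsufficientActivityError",
    "mean_reentry_apd", "dominant_frequency_map", "compute_phase",
    "phase_difference", "detect_ps", "ps_record", "detect_filaments",
    "filament_record", "case_metrics",
]


class InsufficientActivityError(RuntimeError):
    """Fewer than two activations at the probe node."""


# ---------------------------------------------------------------------------
# Reentry APD
# ---------------------------------------------------------------------------

def mean_reentry_apd(movie: VoltageMovie,
                     probe: tuple[int, int, int] | None = None,
                     min_duration: float = 0.0) -> tuple[float, int]:
    """Mean APD90 over all activations at the probe node (domain center by
    default). Returns (mean APD ms, activation count)."""
    if movie.duration < min_duration:
        raise ValueError("movie shorter than the required analysis window")
    iz, iy, ix = probe if probe is not None else movie.center_index()
    v = movie.node_trace(iz, iy, ix)
    t = movie.times - movie.times[0]
    trace = APTrace(t, v, np.zeros_like(v), bcl=np.inf)
    ups = detect_upstrokes(t, v)
    if len(ups) < 2:
        raise InsufficientActivityError(
            f"only {len(ups)} activation(s) at probe node")
    apds = []
    for b in range(len(ups)):
        try:
            apds.append(apd90(trace, b))
        except CensoredAPDError:
            continue   # unfinished final beat
    if not apds:
        raise InsufficientActivityError("no measurable APDs at probe node")
    return float(np.mean(apds)), len(ups)


# ---------------------------------------------------------------------------
# Dominant frequency
# ---------------------------------------------------------------------------

def dominant_frequency_map(movie: VoltageMovie,
                           band: tuple[float, float] = (0.5, 30.0),
                           resolution: float = 0.01,
                           activity_threshold: float = 1.0):
    """Per-node dominant frequency (Hz) and the tissue-mean DF.

    Signals are mean-detrended and zero-padded so the FFT bin width is at
    most ``resolution`` Hz. Nodes whose peak-to-peak voltage never exceeds
    ``activity_threshold`` mV have undefined DF (NaN) and are excluded from
    the mean; the excluded count is returned.
    """
    if movie.duration < 2000.0:
        raise ValueError("dominant frequency needs at least 2 s of signal")
    fs = 1000.0 / FRAME_DT                     # Hz
    sig = movie.frames.reshape(movie.n_frames, -1).astype(np.float64)
    ptp = sig.max(axis=0) - sig.min(axis=0)
    active = ptp > activity_threshold

    n = sig.shape[0]
    n_fft = int(2 ** np.ceil(np.log2(max(n, fs / resolution))))
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    band_idx = (freqs >= band[0]) & (freqs <= band[1])

    df = np.full(sig.shape[1], np.nan)
    if active.any():
        x = sig[:, active] - sig[:, active].mean(axis=0)
        spectrum = np.fft.rfft(x, n=n_fft, axis=0)[band_idx]
        power = spectrum.real ** 2 + spectrum.imag ** 2
        peak = np.argmax(power, axis=0)
        df[active] = freqs[band_idx][peak]

    mean_df = float(np.nanmean(df)) if active.any() else np.nan
    n_excluded = int((~active).sum())
    df_map = df.reshape(movie.grid.shape)
    return df_map, mean_df, n_excluded


# ---------------------------------------------------------------------------
# Phase mapping and singularities
# ---------------------------------------------------------------------------

@dataclass
class PhaseParams:
    """Delay-embedding parameters: tau must be a whole number of frames."""

    tau: float = FRAME_DT      # ms

    @property
    def tau_frames(self) -> int:
        k = self.tau / FRAME_DT
        if abs(k - round(k)) > 1e-9 or round(k) < 1:
            raise ValueError("tau must be a positive multiple of the 10 ms "
                             "frame step")
        return int(round(k))


@dataclass
class PhaseField:
    """theta(node, t) in [-pi, pi), aligned with the source movie frames."""

    times: np.ndarray
    theta: np.ndarray          # (n_frames, nz, ny, nx)

    def frame(self, k: int) -> np.ndarray:
        return self.theta[k]


@dataclass
class PSRecord:
    """Per-frame singularities and their time-averaged count."""

    frame_times: np.ndarray
    points: list = field(default_factory=list)  # per frame: [(iz, fy, fx, charge)]
    counts: np.ndarray | None = None

    @property
    def mean_count(self) -> float:
        return float(np.mean(self.counts))

    def to_csv(self, path) -> None:
        import pandas as pd
        rows = [(t, fx, fy, iz, q)
                for t, pts in zip(self.frame_times, self.points)
                for (iz, fy, fx, q) in pts]
        pd.DataFrame(rows, columns=["frame_ms", "x", "y", "z",
                                    "charge"]).to_csv(path, index=False)


def compute_phase(movie: VoltageMovie,
                  params: PhaseParams | None = None,
                  origin: float | None = None) -> PhaseField:
    """Delay-embedded excitation phase of every node.

    The final tau's worth of frames is dropped (no future sample exists).
    The per-frame origin is the spatial mean voltage at time t, unless a
    fixed ``origin`` (mV) is supplied.
    """
    params = params or PhaseParams()
    k = params.tau_frames
    if movie.n_frames <= k:
        raise ValueError("movie shorter than the embedding delay")
    v = movie.frames.astype(np.float64)
    if origin is not None:
        vmean = np.full(movie.n_frames, float(origin))
    else:
        vmean = v.reshape(movie.n_frames, -1).mean(axis=1)
    now = v[:-k] - vmean[:-k, None, None, None]
    future = v[k:] - vmean[:-k, None, None, None]
    theta = np.arctan2(future, now)
    theta[theta >= np.pi] = -np.pi          # range contract: [-pi, pi)
    return PhaseField(movie.times[:-k], theta)


def phase_difference(theta1, theta2):
    """Wrapped phase difference in [-pi, pi), elementwise.

    theta1 - theta2, shifted by -2 pi when it reaches +pi or above and by
    +2 pi when it is below -pi (the three-case wrap rule; the +pi boundary
    maps to -pi so the output range is half-open).
    """
    d = np.asarray(theta1, dtype=np.float64) - np.asarray(theta2)
    out = np.where(d >= np.pi, d - 2.0 * np.pi,
                   np.where(d < -np.pi, d + 2.0 * np.pi, d))
    if out.ndim == 0:
        return float(out)
    return out


def detect_ps(phase: PhaseField, frame: int, tol: float = 0.1,
              iz: int = 0):
    """Phase singularities of one 2D frame (or one z-slice of a 3D frame).

    For every 2x2 plaquette the four wrapped phase differences are summed
    counterclockwise; a total within ``tol`` of +/- 2 pi marks a PS of that
    topological charge at the plaquette center. Returns a list of
    (iy + 0.5, ix + 0.5, charge) with charge = +/- 2 pi.
    """
    th = phase.theta[frame, iz]
    a = th[:-1, :-1]
    b = th[:-1, 1:]
    c = th[1:, 1:]
    d = th[1:, :-1]
    winding = (phase_difference(b, a) + phase_difference(c, b)
               + phase_difference(d, c) + phase_difference(a, d))
    two_pi = 2.0 * np.pi
    plus = np.abs(winding - two_pi) < tol
    minus = np.abs(winding + two_pi) < tol
    pts = []
    for iy, ix in zip(*np.nonzero(plus)):
        pts.append((iy + 0.5, ix + 0.5, two_pi))
    for iy, ix in zip(*np.nonzero(minus)):
        pts.append((iy + 0.5, ix + 0.5, -two_pi))
    return pts


def ps_record(phase: PhaseField, tol: float = 0.1) -> PSRecord:
    """PS detection over all frames and slices; fills the time-averaged
    count used as the per-case scalar."""
    nz = phase.theta.shape[1]
    counts = np.zeros(len(phase.times))
    points = []
    for k in range(len(phase.times)):
        frame_pts = []
        for iz in range(nz):
            for (fy, fx, q) in detect_ps(phase, k, tol=tol, iz=iz):
                frame_pts.append((iz, fy, fx, q))
        points.append(frame_pts)
        counts[k] = len(frame_pts)
    return PSRecord(phase.times, points, counts)


# ---------------------------------------------------------------------------
# Filaments
# ---------------------------------------------------------------------------

@dataclass
class FilamentParams:
    """Iso-potential filament detection parameters.

    ``v_iso`` fixed in mV, or None to estimate it per frame as the mean
    voltage over surface-slice PS locations, clamped to [-75, -10] mV with
    a -40 mV fallback when no surface PS exists.

    An element is a filament element when the interpolated potential inside
    it attains V_iso at frames n and n+1 — i.e. the iso-surface intersects
    the element at both times, which is exactly where the surface does not
    move over one frame (the discrete dV/dt = 0 condition) and marks the
    rotation axis. With the 4-corner interpolation this is the corner
    values bracketing V_iso. ``epsilon`` > 0 additionally requires the
    p = q = r = 0.5 centroid value to be within epsilon of V_iso at both
    frames (a stricter, thinner variant).
    """

    v_iso: float | None = None
    epsilon: float | None = None
    v_iso_bounds: tuple[float, float] = (-75.0, -10.0)
    v_iso_fallback: float = -40.0
    p: float = 0.5
    q: float = 0.5
    r: float = 0.5


@dataclass
class FilamentRecord:
    """Per-frame filament voxels, their connected components, and the
    time-averaged counts (elements = the per-case scalar)."""

    frame_times: np.ndarray
    element_counts: np.ndarray
    component_counts: np.ndarray
    elements: list = field(default_factory=list)

    @property
    def mean_elements(self) -> float:
        return float(np.mean(self.element_counts))

    @property
    def mean_components(self) -> float:
        return float(np.mean(self.component_counts))

    def to_csv(self, path) -> None:
        import pandas as pd
        rows = [(t, int(ix), int(iy), int(iz))
                for t, mask in zip(self.frame_times, self.elements)
                for (iz, iy, ix) in np.argwhere(mask)]
        pd.DataFrame(rows, columns=["frame_ms", "x", "y", "z"]).to_csv(
            path, index=False)


def _corner_stack(v: np.ndarray) -> tuple[np.ndarray, ...]:
    """The four interpolation corners of every element:
    V(x,y,z), V(x+1,y,z), V(x,y+1,z), V(x,y,z+1)."""
    return (v[:-1, :-1, :-1], v[:-1, :-1, 1:],
            v[:-1, 1:, :-1], v[1:, :-1, :-1])


def _centroid_values(v: np.ndarray, p: float, q: float, r: float) -> np.ndarray:
    """Interpolated element-centroid potential from four corner nodes:
    V_c = p V(x,y,z) + q V(x+1,y,z) + r V(x,y+1,z) + (1-p-q-r) V(x,y,z+1)."""
    c0, c1, c2, c3 = _corner_stack(v)
    return p * c0 + q * c1 + r * c2 + (1.0 - p - q - r) * c3


def _iso_crossing(v: np.ndarray, v_iso: float) -> np.ndarray:
    """True where the 4-corner interpolation attains V_iso inside the
    element, i.e. the corner values bracket the iso level."""
    c = np.stack(_corner_stack(v))
    return (c.min(axis=0) <= v_iso) & (v_iso <= c.max(axis=0))


def _estimate_v_iso(movie: VoltageMovie, phase: PhaseField, frame: int,
                    params: FilamentParams) -> float:
    """Mean membrane potential at surface-slice PS locations, clamped."""
    pts = []
    for iz in (0, movie.grid.nz - 1):
        pts += [(iz, fy, fx) for (fy, fx, _q) in
                detect_ps(phase, frame, iz=iz)]
    if not pts:
        return params.v_iso_fallback
    vals = [movie.frames[frame, iz, int(fy), int(fx)] for iz, fy, fx in pts]
    lo, hi = params.v_iso_bounds
    return float(np.clip(np.mean(vals), lo, hi))


def detect_filaments(movie: VoltageMovie, frame: int,
                     params: FilamentParams | None = None,
                     phase: PhaseField | None = None):
    """Filament voxels of one frame pair (frame, frame + 1) of a 3D movie.

    A voxel is a filament element iff its centroid potential is within
    epsilon of V_iso at both frames (the discretized dV/dt = 0 iso-potential
    condition). Returns (element mask, element count, component count).
    """
    if movie.grid.nz < 2:
        raise ValueError("filament detection needs a 3D movie; use "
                         "detect_ps for 2D sheets")
    if frame + 1 >= movie.n_frames:
        raise ValueError("need frames n and n+1")
    params = params or FilamentParams()

    v_n = movie.frames[frame].astype(np.float64)
    v_n1 = movie.frames[frame + 1].astype(np.float64)

    if params.v_iso is not None:
        v_iso = params.v_iso
    elif phase is not None and frame < len(phase.times):
        v_iso = _estimate_v_iso(movie, phase, frame, params)
    else:
        v_iso = params.v_iso_fallback

    mask = _iso_crossing(v_n, v_iso) & _iso_crossing(v_n1, v_iso)
    if params.epsilon is not None:
        c_n = _centroid_values(v_n, params.p, params.q, params.r)
        c_n1 = _centroid_values(v_n1, params.p, params.q, params.r)
        mask &= (np.abs(c_n - v_iso) < params.epsilon) \
            & (np.abs(c_n1 - v_iso) < params.epsilon)
    n_elements = int(mask.sum())
    structure = np.ones((3, 3, 3), dtype=bool)   # 26-connectivity
    _, n_components = ndimage.label(mask, structure=structure)
    return mask, n_elements, n_components


def filament_record(movie: VoltageMovie,
                    params: FilamentParams | None = None,
                    phase: PhaseField | None = None) -> FilamentRecord:
    """Filament detection over all frame pairs of a 3D movie."""
    params = params or FilamentParams()
    if phase is None and params.v_iso is None:
        phase = compute_phase(movie)
    n_pairs = movie.n_frames - 1
    elem = np.zeros(n_pairs)
    comp = np.zeros(n_pairs)
    masks = []
    for k in range(n_pairs):
        mask, ne, nc = detect_filaments(movie, k, params, phase)
        elem[k] = ne
        comp[k] = nc
        masks.append(mask)
    return FilamentRecord(movie.times[:-1], elem, comp, masks)


# ---------------------------------------------------------------------------
# Per-case summary
# ---------------------------------------------------------------------------

def case_metrics(movie: VoltageMovie,
                 tension_field=None,
                 vlv: np.ndarray | None = None,
                 vlv_times: np.ndarray | None = None,
                 aortic_flow: np.ndarray | None = None,
                 filament_movie: VoltageMovie | None = None) -> dict:
    """The six per-case scalars: mean APD, mean DF, time-averaged PS count,
    time-averaged filament-element count, SV and ampTens.

    2D cases have no filaments (0 when no 3D movie is supplied). Metrics
    that fail on degenerate input are reported as NaN rather than raising.
    """
    from .excitation_contraction import amp_tens, stroke_volume

    out = {"apd_ms": np.nan, "df_hz": np.nan, "ps_count": np.nan,
           "filament_count": 0.0, "sv_ml": np.nan, "amptens_kpa": np.nan,
           "apd_n_activations": 0, "df_excluded_nodes": 0}
    try:
        out["apd_ms"], out["apd_n_activations"] = mean_reentry_apd(movie)
    except (InsufficientActivityError, ValueError):
        pass
    try:
        _, out["df_hz"], out["df_excluded_nodes"] = \
            dominant_frequency_map(movie)
    except ValueError:
        pass
    try:
        phase = compute_phase(movie)
        out["ps_count"] = ps_record(phase).mean_count
    except ValueError:
        phase = None
    fm = filament_movie if filament_movie is not None else (
        movie if movie.grid.nz > 1 else None)
    if fm is not None:
        out["filament_count"] = filament_record(fm).mean_elements
    if tension_field is not None:
        try:
            out["amptens_kpa"] = amp_tens(tension_field)
        except ValueError:
            pass
    if vlv is not None:
        t = vlv_times if vlv_times is not None else \
            np.arange(len(vlv)) * FRAME_DT
        out["sv_ml"] = stroke_volume(t, vlv, aortic_flow).value
    return out
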