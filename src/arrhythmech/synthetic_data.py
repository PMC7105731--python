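"""Ground-truth generators: analytic spiral/scroll voltage movies, planar
waves with known conduction velocity, and feature tables with a prescribed
correlation structure.

These are first-class fixtures: every generator emits the same
VoltageMovie / table schema as the simulator, so detectors and statistics
can be validated against exact ground truth (vortex core positions,
chirality, rotation period, target correlation matrices) without running
any tissue simulation.

Synthetic "voltage" is a cosine wave mapped into the physiological
[-86, +34] mV range so APD-style thresholds stay meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tissue_sim import TissueGrid, VoltageMovie, FRAME_DT

__all__ = [
    "SpiralSpec", "TableSpec",
    "gen_spiral_movie", "gen_scroll_movie", "gen_plane_wave_movie",
    "gen_correlated_table", "FEATURE_COLUMNS",
]

V_OFFSET = -26.0     # mV; midpoint of the synthetic voltage range
V_AMPLITUDE = 60.0   # mV; cosine amplitude -> [-86, +34] mV

FEATURE_COLUMNS = ["apd_ms", "df_hz", "ps_count", "filament_count",
                   "sv_ml", "amptens_kpa"]


@dataclass
class SpiralSpec:
    """Analytic rotor field specification.

    Each vortex contributes chirality * atan2(y - y0, x - x0) to the total
    phase; the common rotation and an outgoing radial term k * r (distance
    to the nearest core) complete it:
    V = V0 + A cos(sum_i chi_i theta_i - 2 pi t / T + k r).
    """

    nx: int = 50
    ny: int = 50
    h: float = 0.5                       # mm
    cores: list = field(default_factory=lambda: [(12.5, 12.5, +1)])
    period: float = 200.0                # ms
    wavenumber: float = 0.0              # rad/mm
    amplitude: float = V_AMPLITUDE       # mV
    offset: float = V_OFFSET             # mV
    drift: tuple[float, float] = (0.0, 0.0)   # core drift, mm/s

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("rotation period must be positive")
        for (x0, y0, chi) in self.cores:
            if not (0 <= x0 <= (self.nx - 1) * self.h
                    and 0 <= y0 <= (self.ny - 1) * self.h):
                raise ValueError(f"vortex core ({x0}, {y0}) outside domain")
            if chi not in (-1, +1):
                raise ValueError("chirality must be +1 or -1")


def _phase_field(spec: SpiralSpec, t: float) -> np.ndarray:
    x = np.arange(spec.nx) * spec.h
    y = np.arange(spec.ny) * spec.h
    X, Y = np.meshgrid(x, y)
    total = np.zeros_like(X)
    r_min = np.full_like(X, np.inf)
    for (x0, y0, chi) in spec.cores:
        cx = x0 + spec.drift[0] * t / 1000.0
        cy = y0 + spec.drift[1] * t / 1000.0
        total += chi * np.arctan2(Y - cy, X - cx)
        r_min = np.minimum(r_min, np.hypot(X - cx, Y - cy))
    return total - 2.0 * np.pi * t / spec.period + spec.wavenumber * r_min


def gen_spiral_movie(spec: SpiralSpec, duration: float):
    """Analytic spiral-wave movie plus the ground-truth core trajectory.

    Returns (movie, tracks) where tracks is a list per frame of
    (x_mm, y_mm, chirality) for every core.
    """
    if duration < 2 * spec.period:
        raise ValueError("duration must cover at least two rotations")
    times = np.arange(0.0, duration + FRAME_DT / 2, FRAME_DT)
    frames = np.empty((len(times), 1, spec.ny, spec.nx))
    tracks = []
    for k, t in enumerate(times):
        frames[k, 0] = spec.offset + spec.amplitude * np.cos(
            _phase_field(spec, t))
        tracks.append([(x0 + spec.drift[0] * t / 1000.0,
                        y0 + spec.drift[1] * t / 1000.0, chi)
                       for (x0, y0, chi) in spec.cores])
    grid = TissueGrid(nx=spec.nx, ny=spec.ny, nz=1, h=spec.h,
                      d_x=0.0, d_y=0.0, d_z=0.0)
    movie = VoltageMovie(grid, times, frames,
                         {"generator": "spiral", "period_ms": spec.period,
                          "cores": spec.cores})
    return movie, tracks


def gen_scroll_movie(spec: SpiralSpec, nz: int, twist: float = 0.0,
                     duration: float | None = None):
    """Stacked phase-shifted spiral layers = a scroll wave.

    ``twist`` is the added phase per layer (rad); the ground-truth filament
    is the vertical core line (straight when twist = 0). Returns
    (movie, filament ground truth: list of (x, y, chirality))."""
    if nz < 3:
        raise ValueError("a scroll needs nz >= 3 layers")
    duration = duration if duration is not None else 2 * spec.period
    times = np.arange(0.0, duration + FRAME_DT / 2, FRAME_DT)
    frames = np.empty((len(times), nz, spec.ny, spec.nx))
    for k, t in enumerate(times):
        base = _phase_field(spec, t)
        for iz in range(nz):
            frames[k, iz] = spec.offset + spec.amplitude * np.cos(
                base + twist * iz)
    grid = TissueGrid(nx=spec.nx, ny=spec.ny, nz=nz, h=spec.h,
                      d_x=0.0, d_y=0.0, d_z=0.0)
    movie = VoltageMovie(grid, times, frames,
                         {"generator": "scroll", "period_ms": spec.period,
                          "twist": twist, "cores": spec.cores})
    truth = [(x0, y0, chi) for (x0, y0, chi) in spec.cores]
    return movie, truth


def gen_plane_wave_movie(cv: float, nx: int = 100, ny: int = 8,
                         h: float = 0.25, duration: float = 400.0,
                         apd: float = 150.0, rise: float = 30.0) -> VoltageMovie:
    """Traveling pulse with activation time x / cv (cv in cm/s).

    The waveform is piecewise linear in time — an upstroke from -86 to
    +34 mV over ``rise`` ms followed by a linear repolarization over
    ``apd`` ms — so threshold crossings interpolated between the 10 ms
    frames recover the wave kinematics exactly.
    """
    if cv <= 0:
        raise ValueError("cv must be positive")
    speed = cv / 100.0    # mm/ms
    times = np.arange(0.0, duration + FRAME_DT / 2, FRAME_DT)
    x = np.arange(nx) * h
    act = x / speed       # ms
    frames = np.empty((len(times), 1, ny, nx))
    for k, t in enumerate(times):
        elapsed = t - act
        v = np.full(nx, -86.0)
        up = (elapsed >= 0) & (elapsed < rise)
        v[up] = -86.0 + 120.0 * (elapsed[up] / rise)
        falling = (elapsed >= rise) & (elapsed < rise + apd)
        v[falling] = 34.0 - 120.0 * ((elapsed[falling] - rise) / apd)
        frames[k, 0] = v[None, :]
    grid = TissueGrid(nx=nx, ny=ny, nz=1, h=h, d_x=0.0, d_y=0.0, d_z=0.0)
    return VoltageMovie(grid, times, frames,
                        {"generator": "plane_wave", "cv_cm_s": cv})


# ---------------------------------------------------------------------------
# Correlated feature tables
# ---------------------------------------------------------------------------

@dataclass
class TableSpec:
    """Multivariate-normal feature-table target.

    ``correlation`` must be symmetric with unit diagonal; a matrix that is
    marginally indefinite (as printed 3-decimal matrices can be) is
    repaired by clipping negative eigenvalues, and the repair is recorded
    on the instance.
    """

    means: np.ndarray
    sds: np.ndarray
    correlation: np.ndarray
    n: int
    seed: int = 0
    columns: list = field(default_factory=lambda: list(FEATURE_COLUMNS))
    integer_columns: tuple = ("ps_count", "filament_count")
    psd_repaired: bool = field(default=False, init=False)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=np.float64)
        self.sds = np.asarray(self.sds, dtype=np.float64)
        self.correlation = np.asarray(self.correlation, dtype=np.float64)
        k = len(self.means)
        if self.correlation.shape != (k, k) or len(self.sds) != k:
            raise ValueError("inconsistent spec dimensions")
        if not np.allclose(self.correlation, self.correlation.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.correlation), 1.0):
            raise ValueError("correlation diagonal must be 1")
        if np.any(np.abs(self.correlation) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")


def _repair_psd(corr: np.ndarray, floor: float = 1e-8):
    """Eigenvalue clipping + diagonal rescaling; returns (matrix, repaired)."""
    w, v = np.linalg.eigh(corr)
    if w.min() >= floor:
        return corr, False
    w = np.clip(w, floor, None)
    m = (v * w) @ v.T
    d = np.sqrt(np.diag(m))
    m = m / np.outer(d, d)
    np.fill_diagonal(m, 1.0)
    return m, True


def gen_correlated_table(spec: TableSpec) -> pd.DataFrame:
    """Seed-reproducible multivariate-normal table with target moments.

    Built by Cholesky of the (possibly PSD-repaired) correlation matrix,
    scaled and shifted to the target means/SDs. Count-valued columns are
    rounded to nonnegative integers.
    """
    corr, repaired = _repair_psd(spec.correlation)
    spec.psd_repaired = repaired
    try:
        chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(corr)))
    except np.linalg.LinAlgError as e:
        raise ValueError("correlation matrix not PSD after repair") from e
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal((spec.n, len(spec.means)))
    data = spec.means + spec.sds * (z @ chol.T)
    df = pd.DataFrame(data, columns=spec.columns)
    for col in spec.integer_columns:
        if col in df:
            df[col] = np.maximum(np.round(df[col]), 0).astype(int)
    return df
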