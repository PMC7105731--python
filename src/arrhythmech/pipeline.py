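"""Experiment-grid orchestration: the 48-condition desk-scale study.

A case is one (g_Ks multiplier, S2 site) pair. Per case the pipeline
calibrates the tissue diffusion to the generation-phase conduction
velocity, runs the S1-S2 reentry-generation simulation, continues from the
saved state at the maintenance-phase velocity, computes the four
electrical-instability metrics on the voltage movie, drives the
cross-bridge + circulation surrogate for the two mechanical read-outs, and
emits one feature-table row.

The default desk preset runs the reduced cell model on a small 2D sheet
(minutes for the whole grid rather than the weeks a full-resolution
ventricle would take); every size and duration is configurable. Metrics
are computed over the whole case window (S1 pacing, induced reentry and
the maintenance continuation) because at sheet scale induced spirals need
not outlive the phase boundary; the methods note discusses this scaling
choice. 2D sheets have no filaments (the column is zero); the ``slab3d``
preset stacks layers for filament work.

``analyze`` replicates the published decision path: correlations, all
single-predictor models, the full 4-predictor models with collinearity
flags, then — when any variance inflation factor exceeds 10 — refits
without the highest-VIF predictor.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cell_models import CellParams, GKS_GRID
from .tissue_sim import (
    TissueGrid, StimulusProtocol, PhasePlan, S2Region, VoltageMovie,
    calibrate_diffusion, run_s1s2, run_maintenance, ProtocolFailure,
    FRAME_DT,
)
from .instability_metrics import (
    mean_reentry_apd, dominant_frequency_map, compute_phase, ps_record,
    filament_record, InsufficientActivityError,
)
from .excitation_contraction import (
    CrossBridgeParams, CirculationParams, run_crossbridge, amp_tens,
    activation_from_tension, run_circulation, stroke_volume,
)
from .stats_engine import (
    pearson_matrix, ols_fit, fit_from_summary, SummaryStats,
    VIF_PERMISSIBLE_MAX, CollinearityError,
)
from .cell_models import FK_V_REST, FK_V_SPAN

__all__ = [
    "GridSpec", "RunManifest", "run_case", "run_grid", "analyze",
    "calcium_from_voltage", "FEATURE_TABLE_COLUMNS",
]

FEATURE_TABLE_COLUMNS = ["case", "gks_mult", "s2_site", "apd_ms", "df_hz",
                         "ps_count", "filament_count", "sv_ml",
                         "amptens_kpa"]

#: Fixed tension scale (kPa) mapping spatial-mean tension onto the
#: ventricular activation for grid cases; a single absolute reference
#: (on the order of the baseline twitch peak) so that conditions are
#: compared on one scale rather than each being min-max rescaled.
ACTIVATION_TENSION_SCALE_KPA = 10.0

ALL_S2_SITES = (S2Region.LEFT_HALF, S2Region.LOWER_LEFT_QUADRANT,
                S2Region.RIGHT_HALF, S2Region.LOWER_RIGHT_QUADRANT)


@dataclass
class GridSpec:
    """The experiment grid and its tissue-scale preset."""

    multipliers: tuple = GKS_GRID
    s2_sites: tuple = ALL_S2_SITES
    preset: str = "sheet2d"            # "sheet2d" | "slab3d"
    model_kind: str = "reduced"        # cell model for tissue runs
    nx: int = 64
    ny: int = 64
    nz: int = 1                        # used by slab3d
    h: float = 0.5                     # mm
    generation_duration: float = 2600.0
    maintenance_duration: float = 1000.0
    generation_cv: float = 20.0
    maintenance_cv: float = 68.5
    seed: int = 0
    outdir: str | None = None
    save_movies: bool = False

    def __post_init__(self) -> None:
        if self.preset not in ("sheet2d", "slab3d"):
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.preset == "slab3d" and self.nz < 2:
            self.nz = 4
        if self.preset == "sheet2d":
            self.nz = 1

    @property
    def n_cases(self) -> int:
        return len(self.multipliers) * len(self.s2_sites)

    def cases(self):
        for mult in self.multipliers:
            for site in self.s2_sites:
                yield float(mult), S2Region(site)

    def plan(self) -> PhasePlan:
        return PhasePlan(self.generation_cv, self.generation_duration,
                         self.maintenance_cv, self.maintenance_duration)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


@dataclass
class RunManifest:
    """One row per case: status, metrics, timing; failures carry the error
    string rather than leaving silent gaps."""

    config_hash: str
    version: str
    entries: list = field(default_factory=list)

    def add(self, case: str, status: str, wall_s: float,
            row: dict | None = None, error: str = "",
            paths: dict | None = None) -> None:
        self.entries.append({"case": case, "status": status,
                             "wall_clock_s": wall_s, "row": row,
                             "error": error, "paths": paths or {}})

    def to_json(self, **kw) -> str:
        return json.dumps({"config_hash": self.config_hash,
                           "version": self.version,
                           "entries": self.entries}, default=float, **kw)


def calcium_from_voltage(frames: np.ndarray, tau: float = 30.0,
                         frame_dt: float = FRAME_DT) -> np.ndarray:
    """Phenomenological per-node calcium from a voltage movie.

    The same first-order relaxation toward the normalized depolarization
    used by the reduced cell model, evaluated at frame cadence:
    dc/dt = (max(u, 0) - c) / tau with u = (V - V_rest)/span, then
    Ca (mM) = 1e-4 + 1e-3 c.
    """
    nt = frames.shape[0]
    u = np.clip((frames.reshape(nt, -1) - FK_V_REST) / FK_V_SPAN, 0.0, None)
    c = np.zeros_like(u)
    a = frame_dt / tau
    for k in range(1, nt):
        c[k] = c[k - 1] + a * (u[k - 1] - c[k - 1])
    return 1e-4 + 1e-3 * c


# Diffusion calibrations are deterministic in (model, multiplier, h, cv);
# cache them so the 48-case grid does not re-bisect per case.
_CALIBRATION_CACHE: dict = {}


def _calibrated_d(params: CellParams, cv: float, h: float) -> float:
    key = (params.model_kind, round(params.gks_multiplier, 9), h, cv)
    if key not in _CALIBRATION_CACHE:
        _CALIBRATION_CACHE[key] = calibrate_diffusion(params, cv, h)
    return _CALIBRATION_CACHE[key]


def run_case(mult: float, site: S2Region, spec: GridSpec) -> dict:
    """One grid case -> the six-metric feature row (plus bookkeeping)."""
    params = CellParams(model_kind=spec.model_kind, gks_multiplier=mult)
    plan = spec.plan()
    d_gen = _calibrated_d(params, plan.generation_cv, spec.h)
    d_mnt = _calibrated_d(params, plan.maintenance_cv, spec.h)

    grid = TissueGrid(spec.nx, spec.ny, spec.nz, spec.h,
                      d_x=d_gen, d_y=d_gen, d_z=d_gen)
    protocol = StimulusProtocol(s2_region=site)
    gen_movie, ck = run_s1s2(grid, params, protocol, plan, seed=spec.seed)
    mnt_movie = run_maintenance(ck, grid.with_diffusion(d_mnt), params, plan)

    # analysis window: reentry only — from the S2 stimulus through the
    # maintenance continuation (S1 pacing is protocol, not arrhythmia)
    s2_ms = gen_movie.provenance["s2_fired_ms"]
    keep = gen_movie.times >= s2_ms
    frames = np.concatenate([gen_movie.frames[keep], mnt_movie.frames[1:]])
    times = np.concatenate([gen_movie.times[keep], mnt_movie.times[1:]])
    movie = VoltageMovie(grid, times, frames,
                         {**gen_movie.provenance, "window": "post-S2"})

    row = {"gks_mult": mult, "s2_site": site.value, "s2_fired_ms": s2_ms}
    # probe APD during the arrhythmic episode; when the induced activity
    # dies before re-exciting the probe twice, fall back to the final
    # paced beat (the episode's last captured activation)
    try:
        row["apd_ms"], row["apd_n_activations"] = mean_reentry_apd(movie)
    except InsufficientActivityError:
        from .cell_models import APTrace, CensoredAPDError, apd90 as _apd90
        c = gen_movie.center_index()
        paced = gen_movie.times < s2_ms          # exclude the S2 transient
        tr = APTrace(gen_movie.times[paced],
                     gen_movie.node_trace(*c)[paced],
                     np.zeros(int(paced.sum())), np.inf)
        try:
            row["apd_ms"] = _apd90(tr, -1)
        except CensoredAPDError:
            row["apd_ms"] = _apd90(tr, -2)
        row["apd_n_activations"] = 1
    _, row["df_hz"], row["df_excluded_nodes"] = dominant_frequency_map(movie)
    phase = compute_phase(movie)
    row["ps_count"] = ps_record(phase).mean_count
    if spec.nz > 1:
        row["filament_count"] = filament_record(movie).mean_elements
    else:
        row["filament_count"] = 0.0

    # mechanics over the whole case record (pacing + arrhythmic episode)
    full_frames = np.concatenate([gen_movie.frames, mnt_movie.frames[1:]])
    full_times = np.concatenate([gen_movie.times, mnt_movie.times[1:]])
    ca = calcium_from_voltage(full_frames)
    tension = run_crossbridge(full_times, ca, CrossBridgeParams())
    row["amptens_kpa"] = amp_tens(tension)
    y_v = activation_from_tension(tension,
                                  scale=ACTIVATION_TENSION_SCALE_KPA)
    circ = run_circulation(full_times, y_v, CirculationParams())
    svr = stroke_volume(full_times, circ["v_lv"], circ["aortic_flow"])
    row["sv_ml"] = svr.value
    row["sv_no_ejection"] = svr.no_ejection
    if spec.save_movies and spec.outdir:
        from pathlib import Path
        p = Path(spec.outdir)
        p.mkdir(parents=True, exist_ok=True)
        path = p / f"case_gks{mult:g}_{site.value}.h5"
        movie.save(path)
        row["movie_path"] = str(path)
    return row


def run_grid(spec: GridSpec):
    """Run every case; failures are logged in the manifest and the grid
    continues. Returns (feature table, manifest)."""
    from . import __version__
    manifest = RunManifest(spec.config_hash(), __version__)
    rows = []
    for mult, site in spec.cases():
        label = f"gks{mult:g}_{site.value}"
        t0 = time.perf_counter()
        try:
            row = run_case(mult, site, spec)
            row["case"] = label
            rows.append(row)
            manifest.add(label, "ok", time.perf_counter() - t0, row=row)
        except (ProtocolFailure, RuntimeError, ValueError) as e:
            manifest.add(label, "failed", time.perf_counter() - t0,
                         error=f"{type(e).__name__}: {e}")
    table = pd.DataFrame(rows)
    if len(table):
        ordered = [c for c in FEATURE_TABLE_COLUMNS if c in table.columns]
        extra = [c for c in table.columns if c not in ordered]
        table = table[ordered + extra]
    return table, manifest


# ---------------------------------------------------------------------------
# Analysis bundle
# ---------------------------------------------------------------------------

ELECTRICAL_PREDICTORS = ["apd_ms", "df_hz", "ps_count", "filament_count"]
MECHANICAL_RESPONSES = ["sv_ml", "amptens_kpa"]


def analyze(table: pd.DataFrame | None = None,
            summary: SummaryStats | None = None,
            n: int | None = None) -> dict:
    """Full statistical workflow on a feature table (or directly on
    summary statistics): correlation matrix, single-predictor models, the
    4-predictor models with collinearity flags, and — when the flags fire
    — the refits without the highest-VIF predictor.

    Returns a bundle dict: summary, single_models, full_models,
    reduced_models, dropped_predictor (per response).
    """
    if table is None and summary is None:
        raise ValueError("need a feature table or summary statistics")
    if table is not None and len(table) < 10:
        raise ValueError("need at least 10 cases")

    from_raw = table is not None
    if from_raw:
        usable = [c for c in ELECTRICAL_PREDICTORS + MECHANICAL_RESPONSES
                  if c in table.columns
                  and table[c].std(ddof=1) > 1e-12
                  and not table[c].isna().any()]
        summary = pearson_matrix(table, usable)
    predictors = [c for c in ELECTRICAL_PREDICTORS
                  if c in summary.variables]
    responses = [c for c in MECHANICAL_RESPONSES if c in summary.variables]

    def fit(resp, preds):
        if from_raw:
            return ols_fit(table, resp, preds)
        return fit_from_summary(summary, resp, preds, n=n)

    bundle = {"summary": summary, "single_models": {}, "full_models": {},
              "reduced_models": {}, "dropped_predictor": {}}
    for resp in responses:
        for pred in predictors:
            bundle["single_models"][(resp, pred)] = fit(resp, [pred])
        if len(predictors) < 2:
            continue
        try:
            full = fit(resp, predictors)
        except CollinearityError:
            full = None
        bundle["full_models"][resp] = full
        if full is not None and full.collinearity_flagged:
            worst = max(full.vif, key=full.vif.get)
            bundle["dropped_predictor"][resp] = worst
            reduced = fit(resp, [p for p in predictors if p != worst])
            bundle["reduced_models"][resp] = reduced
    return bundle
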