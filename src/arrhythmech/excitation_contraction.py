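"""One-way excitation–contraction coupling and the circulation surrogate.

Per-node intracellular calcium drives a four-state cross-bridge chain

    N_xb <-> P_xb <-> XB_PreR <-> XB_PostR

where the regulatory transitions N->P and P->N carry steep calcium
cooperativity through the troponin-bound calcium fraction TCa_Tot
(forward rate K_np * TCa_Tot^7.5, backward K_pn * TCa_Tot^-7.5). Active
tension is T_max * (XB_PreR + XB_PostR). Troponin binding itself is a
single-site on/off ODE driven by Ca_i.

The whole-organ pumping surrogate is a closed-loop lumped circulation with
time-varying ventricular compliance: P = C(t)^-1 (V - V_rest(t)) with
C = y_v (C_max - C_min) + C_min and rest volumes interpolated between their
diastolic and systolic values by the same activation y_v. y_v is the
min–max-normalized spatial-mean tension of the tissue. Finite-element
passive mechanics is deliberately out of scope: stroke volume comes solely
from this lumped loop, which is the main fidelity gap versus a full
electromechanical ventricle.

Contractility read-outs: stroke volume (end-diastolic minus end-systolic
LV volume over detected ejection cycles) and ampTens (the mean over nodes
of the temporal standard deviation of tension; population SD by
definition, in contrast to the sample SD used by the statistics stage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.signal import find_peaks

__all__ = [
    "CrossBridgeParams", "TensionField", "CirculationParams",
    "CirculationState", "StrokeVolumeResult",
    "run_crossbridge", "amp_tens", "activation_from_tension",
    "step_circulation", "run_circulation", "stroke_volume",
]


# ---------------------------------------------------------------------------
# Cross-bridge tension
# ---------------------------------------------------------------------------

@dataclass
class CrossBridgeParams:
    """Four-state cross-bridge chain parameters (rates in 1/ms).

    The published myofilament rate scale is reduced to a desk-sized chain;
    ``t_max`` is the single tension scale factor mapping total strong-bound
    occupancy to kPa.
    """

    f_aapT: float = 0.05     # P_xb -> XB_PreR attachment
    g_aapT: float = 0.01     # XB_PreR -> P_xb reverse
    h_fT: float = 0.02       # XB_PreR -> XB_PostR rotation
    h_bT: float = 0.004      # XB_PostR -> XB_PreR reverse
    g_xbT: float = 0.012     # XB_PostR -> N ATP-consuming detachment
    k_np: float = 0.6        # N_xb -> P_xb scale, * TCa_Tot^+coop
    k_pn: float = 0.01       # P_xb -> N_xb scale, * TCa_Tot^-coop
    coop: float = 7.5        # calcium cooperativity exponent
    t_max: float = 30.0      # kPa at full strong binding; gives O(10 kPa)
                             # peak twitch tension at 1 Hz pacing
    kon: float = 50.0        # troponin on-rate, 1/(mM*ms)
    koff: float = 0.02       # troponin off-rate, 1/ms
    rate_cap: float = 0.5    # 1/ms cap on the diverging TCa^-coop rate
    dt: float = 0.2          # internal integration step, ms

    def vector(self) -> np.ndarray:
        return np.array([self.f_aapT, self.g_aapT, self.h_fT, self.h_bT,
                         self.g_xbT, self.k_np, self.k_pn, self.coop,
                         self.t_max, self.kon, self.koff, self.rate_cap])


@dataclass
class TensionField:
    """Per-node active tension (kPa), same frame cadence as the driver."""

    times: np.ndarray            # ms
    tension: np.ndarray          # (n_frames, n_nodes), kPa

    def __post_init__(self) -> None:
        if self.tension.shape[0] != len(self.times):
            raise ValueError("tension frame count does not match times")
        if np.any(self.tension < -1e-9):
            raise ValueError("tension must be nonnegative")

    @property
    def n_nodes(self) -> int:
        return self.tension.shape[1]


@njit(cache=True)
def _crossbridge_loop(ca, frame_dt, dt, p, tension_out, states_out,
                      record_states):
    """Integrate troponin + 4-state chain per node; record at frame cadence.

    ca: (n_frames, n_nodes) mM, linearly interpolated between frames.
    """
    n_frames, n_nodes = ca.shape
    sub = int(round(frame_dt / dt))
    f_aap, g_aap, h_f, h_b, g_xb = p[0], p[1], p[2], p[3], p[4]
    k_np, k_pn, coop, t_max = p[5], p[6], p[7], p[8]
    kon, koff, cap = p[9], p[10], p[11]

    for j in range(n_nodes):
        n_s = 1.0
        p_s = 0.0
        pre = 0.0
        post = 0.0
        tca = 0.0
        tension_out[0, j] = 0.0
        if record_states:
            states_out[0, j, 0] = n_s
            states_out[0, j, 1] = p_s
            states_out[0, j, 2] = pre
            states_out[0, j, 3] = post
        for k in range(n_frames - 1):
            c0 = ca[k, j]
            c1 = ca[k + 1, j]
            for s in range(sub):
                cai = c0 + (c1 - c0) * (s + 0.5) / sub
                tca += dt * (kon * cai * (1.0 - tca) - koff * tca)
                if tca < 1e-6:
                    tca = 1e-6
                elif tca > 1.0:
                    tca = 1.0
                fwd = k_np * tca ** coop
                if fwd < 1e-30:      # unactivated troponin: no recruitment
                    fwd = 0.0
                elif fwd > cap:
                    fwd = cap
                bwd = k_pn * tca ** (-coop)
                if bwd > cap:
                    bwd = cap
                dn = bwd * p_s - fwd * n_s + g_xb * post
                dp = fwd * n_s - bwd * p_s - f_aap * p_s + g_aap * pre
                dpre = f_aap * p_s - g_aap * pre - h_f * pre + h_b * post
                dpost = h_f * pre - h_b * post - g_xb * post
                n_s += dt * dn
                p_s += dt * dp
                pre += dt * dpre
                post += dt * dpost
                # renormalize occupancies to machine precision
                tot = n_s + p_s + pre + post
                n_s /= tot
                p_s /= tot
                pre /= tot
                post /= tot
            tension_out[k + 1, j] = t_max * (pre + post)
            if record_states:
                states_out[k + 1, j, 0] = n_s
                states_out[k + 1, j, 1] = p_s
                states_out[k + 1, j, 2] = pre
                states_out[k + 1, j, 3] = post


def run_crossbridge(times: np.ndarray, ca: np.ndarray,
                    params: CrossBridgeParams | None = None,
                    return_states: bool = False):
    """Tension field from a per-node calcium movie.

    ``ca`` is (n_frames, n_nodes) in mM at uniform frame cadence; each node
    is integrated independently (no mechanical coupling). With
    ``return_states`` also returns the four occupancies recorded at frame
    cadence, shape (n_frames, n_nodes, 4) ordered (N, P, PreR, PostR).
    """
    params = params or CrossBridgeParams()
    ca = np.asarray(ca, dtype=np.float64)
    if ca.ndim == 1:
        ca = ca[:, None]
    if np.any(ca < 0):
        raise ValueError("calcium input must be nonnegative")
    if len(times) != ca.shape[0]:
        raise ValueError("times and calcium frame counts differ")
    frame_dt = float(times[1] - times[0])
    out = np.empty_like(ca)
    states = np.empty(ca.shape + (4,)) if return_states \
        else np.empty((1, 1, 4))
    _crossbridge_loop(ca, frame_dt, params.dt, params.vector(), out,
                      states, return_states)
    field = TensionField(np.asarray(times, dtype=np.float64), out)
    return (field, states) if return_states else field


def amp_tens(field: TensionField) -> float:
    """Mean over nodes of the per-node temporal standard deviation of
    tension (population SD, divisor n), in kPa."""
    if field.tension.shape[0] < 2:
        raise ValueError("amp_tens needs at least two frames")
    return float(np.mean(np.std(field.tension, axis=0, ddof=0)))


def activation_from_tension(field: TensionField,
                            scale: float | None = None) -> np.ndarray:
    """Global ventricular activation y_v(t) from the spatial-mean tension.

    Default: min–max normalized to [0, 1] over the run (constant fields
    map to 0) — the natural choice for a single record. For *cross-case*
    comparisons pass a fixed ``scale`` (kPa): y_v = clip(mean T / scale, 1),
    so that weakly contracting cases genuinely activate the ventricle
    less instead of being rescaled to full range.
    """
    if field.tension.size == 0:
        raise ValueError("empty tension field")
    m = field.tension.mean(axis=1)
    if scale is not None:
        return np.clip(m / scale, 0.0, 1.0)
    lo, hi = m.min(), m.max()
    if hi - lo < 1e-12:
        return np.zeros_like(m)
    return (m - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# Lumped circulation
# ---------------------------------------------------------------------------

@dataclass
class CirculationParams:
    """Closed-loop lumped cardiovascular parameters.

    Resistances in mmHg*s/mL, compliances in mL/mmHg, volumes in mL. The
    defaults are a compact working parameterization of the classic
    systemic + pulmonary 8-compartment loop, tuned once to eject a few
    tens of mL per cycle under regular 1 Hz activation.
    """

    # valve and vascular resistances
    r_mi: float = 0.005     # mitral: LA -> LV
    r_ao: float = 0.01      # aortic: LV -> systemic artery
    r_sa: float = 1.0       # systemic artery -> vein
    r_sv: float = 0.05      # systemic vein -> RA
    r_tr: float = 0.005     # tricuspid: RA -> RV
    r_pu: float = 0.01      # pulmonary valve: RV -> pulmonary artery
    r_pa: float = 0.1       # pulmonary artery -> vein
    r_pv: float = 0.05      # pulmonary vein -> LA
    # passive compliances
    c_sa: float = 1.5
    c_sv: float = 50.0
    c_pa: float = 4.0
    c_pv: float = 8.0
    c_la: float = 5.0
    c_ra: float = 5.0
    # ventricular compliance bounds (passive y=0 -> c_min, active y=1 -> c_max)
    c_min_lv: float = 1.0
    c_max_lv: float = 1.2
    c_min_rv: float = 2.0
    c_max_rv: float = 2.4
    # ventricular rest volumes (diastolic / systolic)
    v_rest_lv_d: float = 110.0
    v_rest_lv_s: float = 15.0
    v_rest_rv_d: float = 100.0
    v_rest_rv_s: float = 25.0
    # cross-ventricular compliance coupling (off by default)
    c_lr: float = 0.0
    c_rl: float = 0.0
    #: literal printed-variant flag: use the diastolic right-ventricular
    #: rest volume in the activated-state offset vector (see methods note);
    #: default uses the systolic rest volume for both ventricles.
    literal_rest_vector: bool = False

    def __post_init__(self) -> None:
        for name in ("r_mi", "r_ao", "r_sa", "r_sv", "r_tr", "r_pu",
                     "r_pa", "r_pv", "c_sa", "c_sv", "c_pa", "c_pv",
                     "c_la", "c_ra"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.c_min_lv < self.c_max_lv):
            raise ValueError("need 0 < c_min_lv < c_max_lv")
        if not (0 < self.c_min_rv < self.c_max_rv):
            raise ValueError("need 0 < c_min_rv < c_max_rv")
        if self.v_rest_lv_s > self.v_rest_lv_d or \
                self.v_rest_rv_s > self.v_rest_rv_d:
            raise ValueError("systolic rest volume must not exceed diastolic")


@dataclass
class CirculationState:
    """Volumes (mL) of every compartment plus derived pressures (mmHg)."""

    v_lv: float = 140.0
    v_rv: float = 130.0
    v_la: float = 60.0
    v_ra: float = 60.0
    v_sa: float = 150.0
    v_sv: float = 3000.0
    v_pa: float = 80.0
    v_pv: float = 120.0
    y_v: float = 0.0
    p_lv: float = 0.0
    p_rv: float = 0.0
    aortic_flow: float = 0.0   # mL/s, > 0 only while the aortic valve is open

    def total_volume(self) -> float:
        return (self.v_lv + self.v_rv + self.v_la + self.v_ra
                + self.v_sa + self.v_sv + self.v_pa + self.v_pv)


def _ventricular_pressure(v: float, y: float, c_min: float, c_max: float,
                          v_rest_d: float, v_rest_s: float,
                          offset_diastolic: bool = False) -> float:
    """P = C(y)^-1 (V - V_rest(y)); the rest volume interpolates from its
    diastolic value at y=0 down to the offset (normally the systolic value;
    the literal printed variant uses the diastolic one for the RV)."""
    c = y * (c_max - c_min) + c_min
    offset = v_rest_d if offset_diastolic else v_rest_s
    v_rest = (1.0 - y) * (v_rest_d - v_rest_s) + offset
    return (v - v_rest) / c


def step_circulation(state: CirculationState, params: CirculationParams,
                     y_v: float, dt: float) -> CirculationState:
    """One explicit step of the closed loop (dt in ms, <= 1 ms).

    Valve flows are diodes: flow only when upstream pressure exceeds
    downstream. Raises on negative compartment volumes.
    """
    if dt > 1.0:
        raise ValueError("circulation step requires dt <= 1 ms")
    p = params
    y = float(np.clip(y_v, 0.0, 1.0))

    p_lv = _ventricular_pressure(state.v_lv, y, p.c_min_lv, p.c_max_lv,
                                 p.v_rest_lv_d, p.v_rest_lv_s)
    p_rv = _ventricular_pressure(state.v_rv, y, p.c_min_rv, p.c_max_rv,
                                 p.v_rest_rv_d, p.v_rest_rv_s,
                                 offset_diastolic=p.literal_rest_vector)
    # optional cross-ventricular coupling
    p_lv += p.c_lr * p_rv
    p_rv += p.c_rl * p_lv

    p_la = state.v_la / p.c_la
    p_ra = state.v_ra / p.c_ra
    p_sa = state.v_sa / p.c_sa
    p_sv = state.v_sv / p.c_sv
    p_pa = state.v_pa / p.c_pa
    p_pv = state.v_pv / p.c_pv

    def valve(p_up, p_dn, r):
        return (p_up - p_dn) / r if p_up > p_dn else 0.0

    q_mi = valve(p_la, p_lv, p.r_mi)
    q_ao = valve(p_lv, p_sa, p.r_ao)
    q_sa = (p_sa - p_sv) / p.r_sa
    q_sv = (p_sv - p_ra) / p.r_sv
    q_tr = valve(p_ra, p_rv, p.r_tr)
    q_pu = valve(p_rv, p_pa, p.r_pu)
    q_pa = (p_pa - p_pv) / p.r_pa
    q_pv = (p_pv - p_la) / p.r_pv

    k = dt / 1000.0   # flows are mL/s
    out = CirculationState(
        v_lv=state.v_lv + k * (q_mi - q_ao),
        v_rv=state.v_rv + k * (q_tr - q_pu),
        v_la=state.v_la + k * (q_pv - q_mi),
        v_ra=state.v_ra + k * (q_sv - q_tr),
        v_sa=state.v_sa + k * (q_ao - q_sa),
        v_sv=state.v_sv + k * (q_sa - q_sv),
        v_pa=state.v_pa + k * (q_pu - q_pa),
        v_pv=state.v_pv + k * (q_pa - q_pv),
        y_v=y, p_lv=p_lv, p_rv=p_rv, aortic_flow=q_ao,
    )
    for name in ("v_lv", "v_rv", "v_la", "v_ra", "v_sa", "v_sv",
                 "v_pa", "v_pv"):
        if getattr(out, name) <= 0:
            raise RuntimeError(f"circulation instability: {name} <= 0")
    return out


def run_circulation(times: np.ndarray, y_v: np.ndarray,
                    params: CirculationParams | None = None,
                    state: CirculationState | None = None,
                    dt: float = 0.5,
                    settle_cycles: int = 0):
    """Drive the closed loop with an activation series y_v(t).

    y_v is linearly interpolated onto the integration step. Returns a dict
    of traces sampled at the input cadence: v_lv, p_lv, aortic_flow,
    total_volume. ``settle_cycles`` > 0 repeats the y_v series that many
    times first to let the loop reach a periodic regime.
    """
    params = params or CirculationParams()
    state = state or CirculationState()
    times = np.asarray(times, dtype=np.float64)
    y_v = np.clip(np.asarray(y_v, dtype=np.float64), 0.0, 1.0)
    span = times[-1] - times[0]

    for _ in range(settle_cycles):
        t = 0.0
        while t < span:
            y = np.interp(t, times - times[0], y_v)
            state = step_circulation(state, params, y, dt)
            t += dt

    n = len(times)
    v_lv = np.empty(n)
    p_lv = np.empty(n)
    q_ao = np.empty(n)
    v_tot = np.empty(n)
    t = times[0]
    for i in range(n):
        while t < times[i]:
            y = np.interp(t, times, y_v)
            state = step_circulation(state, params, y, dt)
            t += dt
        v_lv[i] = state.v_lv
        p_lv[i] = state.p_lv
        q_ao[i] = state.aortic_flow
        v_tot[i] = state.total_volume()
    return {"times": times, "v_lv": v_lv, "p_lv": p_lv,
            "aortic_flow": q_ao, "total_volume": v_tot, "state": state}


# ---------------------------------------------------------------------------
# Stroke volume
# ---------------------------------------------------------------------------

@dataclass
class StrokeVolumeResult:
    value: float               # mL, mean EDV - ESV over detected cycles
    cycles: list = field(default_factory=list)   # (edv, esv) pairs
    no_ejection: bool = False

    def __float__(self) -> float:
        return self.value


def stroke_volume(times: np.ndarray, v_lv: np.ndarray,
                  aortic_flow: np.ndarray | None = None,
                  prominence: float = 1.0) -> StrokeVolumeResult:
    """Mean stroke volume over fill–eject cycles of the LV volume trace.

    A cycle is a local volume maximum (end-diastole, the volume right
    before it maximally decreases) followed by the next local minimum
    (end-systole). When an aortic-flow trace is supplied, only cycles whose
    falling limb overlaps a flow > 0 interval count (the meaningful period).
    Degenerate traces return 0 with ``no_ejection`` set.
    """
    v = np.asarray(v_lv, dtype=np.float64)
    if len(v) < 3:
        return StrokeVolumeResult(0.0, [], True)
    peaks, _ = find_peaks(v, prominence=prominence)
    troughs, _ = find_peaks(-v, prominence=prominence)
    cycles = []
    for pk in peaks:
        later = troughs[troughs > pk]
        if len(later) == 0:
            continue
        tr = later[0]
        if aortic_flow is not None:
            if not np.any(np.asarray(aortic_flow)[pk:tr + 1] > 0):
                continue
        cycles.append((float(v[pk]), float(v[tr])))
    if not cycles:
        return StrokeVolumeResult(0.0, [], True)
    sv = float(np.mean([edv - esv for edv, esv in cycles]))
    return StrokeVolumeResult(sv, cycles, False)
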