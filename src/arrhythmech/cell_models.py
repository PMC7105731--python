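"""Ventricular membrane kinetics: detailed human ionic model and a reduced
phenomenological model, plus single-cell pacing and APD90 measurement.

The detailed model is the ten Tusscher–Panfilov (2006) human ventricular
myocyte formulation with epicardial / mid-myocardial / endocardial variants.
Its slow delayed-rectifier conductance g_Ks is parameterized as a baseline
value (0.392 * 1.3 mS/uF) times a dimensionless multiplier; scaling this
multiplier up shortens the action potential duration (APD), which is the
experimental dial used to span a wide range of tachyarrhythmia severities.

The reduced model is a three-current excitable model (fast inward, slow
outward, slow inward) of the Fenton–Karma class with one extra state for a
phenomenological calcium transient, cheap enough for large tissue grids. Its
repolarization time constants are mapped from the same g_Ks multiplier so
that its APD range spans roughly 74-250 ms.

Gating variables are integrated with the Rush–Larsen exponential scheme;
voltage and concentrations with forward Euler. Default steps: 0.02 ms
(detailed), 0.1 ms (reduced).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

__all__ = [
    "CellParams",
    "CellState",
    "APTrace",
    "GKS_BASELINE",
    "GKS_GRID",
    "IntegrationFailure",
    "NoCaptureError",
    "CensoredAPDError",
    "make_state",
    "step_ionic",
    "run_paced",
    "apd90",
    "detect_upstrokes",
    "total_calcium",
]

# ---------------------------------------------------------------------------
# Parameters and containers
# ---------------------------------------------------------------------------

#: Baseline slow delayed-rectifier conductance (mS/uF): published epicardial
#: value 0.392 scaled by 1.3, the reference point of the multiplier grid.
GKS_BASELINE = 0.392 * 1.3

#: The multiplier ladder used for the experiment grid.
GKS_GRID = (1, 2, 4, 6, 8, 10, 20, 30, 40, 60, 80, 100)


class IntegrationFailure(RuntimeError):
    """A state variable became non-finite during integration."""


class NoCaptureError(RuntimeError):
    """A stimulus failed to elicit an upstroke."""


class CensoredAPDError(RuntimeError):
    """A beat never repolarized to 90% within its cycle."""


@dataclass
class CellParams:
    """Membrane-model parameters.

    Conductances are absolute values in mS/uF (detailed model); ``g_ks`` is
    the baseline that ``gks_multiplier`` scales. ``scale`` entries multiply
    the named conductance and let a config tweak any channel without
    restating absolute values.
    """

    model_kind: str = "detailed"          # "detailed" | "reduced"
    variant: str = "epi"                  # "epi" | "M" | "endo"
    cm: float = 0.185                     # effective membrane capacitance (uF)
    g_na: float = 14.838
    g_k1: float = 5.405
    g_to: float = 0.294                   # epi/M; endo uses 0.073
    g_kr: float = 0.153
    g_ks: float = GKS_BASELINE            # epi/endo; M uses 0.098 * 1.3
    g_cal: float = 3.98e-5
    k_naca: float = 1000.0
    p_nak: float = 2.724
    g_pca: float = 0.1238
    g_pk: float = 0.0146
    g_bna: float = 0.00029
    g_bca: float = 0.000592
    gks_multiplier: float = 1.0
    stim_amplitude: float = 52.0          # uA/uF, depolarizing
    stim_duration: float = 1.0            # ms
    dt: float | None = None               # default chosen by model kind
    scale: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model_kind not in ("detailed", "reduced"):
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        if self.variant not in ("epi", "M", "endo"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.gks_multiplier <= 0:
            raise ValueError("gks_multiplier must be positive")
        if self.variant == "endo":
            self.g_to = 0.073
        elif self.variant == "M":
            self.g_ks = 0.098 * 1.3
        for key, fac in self.scale.items():
            setattr(self, key, getattr(self, key) * fac)

    @property
    def default_dt(self) -> float:
        return self.dt if self.dt is not None else (
            0.02 if self.model_kind == "detailed" else 0.1)

    def vector(self) -> np.ndarray:
        """Flat parameter vector consumed by the compiled kernels."""
        if self.model_kind == "detailed":
            return np.array([
                self.g_na, self.g_k1, self.g_to, self.g_kr,
                self.g_ks * self.gks_multiplier, self.g_cal,
                self.k_naca, self.p_nak, self.g_pca, self.g_pk,
                self.g_bna, self.g_bca,
                1.0 if self.variant == "endo" else 0.0,
            ])
        return _fk_param_vector(self.gks_multiplier)


@dataclass
class CellState:
    """Full state of one cell: V_m plus the model's internal variables.

    ``y`` is the raw state vector; named accessors expose the physiologically
    meaningful entries for the detailed model.
    """

    y: np.ndarray
    model_kind: str = "detailed"

    @property
    def vm(self) -> float:
        return float(self.y[0])

    @property
    def cai(self) -> float:
        if self.model_kind == "detailed":
            return float(self.y[I_CAI])
        return 1e-4 + 1e-3 * float(self.y[3])

    def copy(self) -> "CellState":
        return CellState(self.y.copy(), self.model_kind)


@dataclass
class APTrace:
    """Uniformly sampled single-cell recording of V_m and Ca_i."""

    t: np.ndarray       # ms
    vm: np.ndarray      # mV
    cai: np.ndarray     # mM
    bcl: float          # pacing cycle length, ms

    def __post_init__(self) -> None:
        if len(self.t) != len(self.vm) or len(self.t) != len(self.cai):
            raise ValueError("trace series lengths differ")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({"time_ms": self.t, "vm_mV": self.vm,
                      "cai_mM": self.cai}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Detailed model kernel (ten Tusscher–Panfilov 2006 formulation)
# ---------------------------------------------------------------------------

# state vector layout
I_V, I_M, I_H, I_J, I_XR1, I_XR2, I_XS, I_R, I_S, I_D, I_F, I_F2, \
    I_FCASS, I_RQ, I_CAI, I_CASS, I_CASR, I_NAI, I_KI = range(19)
NVAR_DETAILED = 19
NVAR_REDUCED = 4

# physical constants and fixed model parameters
_RGAS = 8314.472
_TEMP = 310.0
_FARADAY = 96485.3415
_RTONF = _RGAS * _TEMP / _FARADAY
_KO, _NAO, _CAO = 5.4, 140.0, 2.0
_VC, _VSR, _VSS = 0.016404, 0.001094, 5.468e-5
_CAPACITANCE = 0.185
_PKNA = 0.03
_KMK, _KMNA = 1.0, 40.0
_KSAT, _ALPHA_NCX, _GAMMA_NCX = 0.1, 2.5, 0.35
_KMNAI, _KMCA = 87.5, 1.38
_KPCA = 0.0005
_VMAXUP, _KUP = 0.006375, 0.00025
_VREL, _K1P, _K2P, _K3, _K4 = 0.102, 0.15, 0.045, 0.060, 0.005
_EC, _MAXSR, _MINSR = 1.5, 2.5, 1.0
_VLEAK, _VXFER = 0.00036, 0.0038
_BUFC, _KBUFC = 0.2, 0.001
_BUFSR, _KBUFSR = 10.0, 0.3
_BUFSS, _KBUFSS = 0.4, 0.00025

#: Resting initial conditions (epicardial, 1 Hz steady-state neighbourhood).
_Y0_DETAILED = np.array([
    -85.23,        # V
    0.00172,       # m
    0.7444,        # h
    0.7045,        # j
    0.00621,       # Xr1
    0.4712,        # Xr2
    0.0095,        # Xs
    2.42e-8,       # r
    0.999998,      # s
    3.373e-5,      # d
    0.7888,        # f
    0.9755,        # f2
    0.9953,        # fCass
    0.9073,        # R' (SR release gate)
    0.000126,      # Cai (mM)
    0.00036,       # CaSS (mM)
    3.64,          # CaSR (mM)
    8.604,         # Nai (mM)
    136.89,        # Ki (mM)
])


@njit(cache=True)
def _tp06_step(y, dt, istim, p):
    """Advance one detailed-model cell by dt.

    ``istim`` is a depolarizing current in uA/uF (positive = inward).
    Rush–Larsen on gates, forward Euler on V and concentrations.
    """
    v = y[I_V]
    cai = y[I_CAI]
    cass = y[I_CASS]
    casr = y[I_CASR]
    nai = y[I_NAI]
    ki = y[I_KI]
    endo = p[12] > 0.5

    ek = _RTONF * np.log(_KO / ki)
    ena = _RTONF * np.log(_NAO / nai)
    eks = _RTONF * np.log((_KO + _PKNA * _NAO) / (ki + _PKNA * nai))
    eca = 0.5 * _RTONF * np.log(_CAO / cai)

    # --- currents -----------------------------------------------------
    ina = p[0] * y[I_M] ** 3 * y[I_H] * y[I_J] * (v - ena)

    ak1 = 0.1 / (1.0 + np.exp(0.06 * (v - ek - 200.0)))
    bk1 = (3.0 * np.exp(0.0002 * (v - ek + 100.0))
           + np.exp(0.1 * (v - ek - 10.0))) / (1.0 + np.exp(-0.5 * (v - ek)))
    ik1 = p[1] * np.sqrt(_KO / 5.4) * ak1 / (ak1 + bk1) * (v - ek)

    ito = p[2] * y[I_R] * y[I_S] * (v - ek)
    ikr = p[3] * np.sqrt(_KO / 5.4) * y[I_XR1] * y[I_XR2] * (v - ek)
    iks = p[4] * y[I_XS] * y[I_XS] * (v - eks)

    vf = (v - 15.0) / _RTONF
    if abs(vf) < 1e-7:
        vf = 1e-7
    e2vf = np.exp(2.0 * vf)
    ical = (p[5] * y[I_D] * y[I_F] * y[I_F2] * y[I_FCASS] * 4.0
            * (v - 15.0) * _FARADAY / _RTONF
            * (0.25 * cass * e2vf - _CAO) / (e2vf - 1.0))

    inaca = (p[6] * (np.exp(_GAMMA_NCX * v / _RTONF) * nai ** 3 * _CAO
                     - np.exp((_GAMMA_NCX - 1.0) * v / _RTONF)
                     * _NAO ** 3 * cai * _ALPHA_NCX)
             / ((_KMNAI ** 3 + _NAO ** 3) * (_KMCA + _CAO)
                * (1.0 + _KSAT * np.exp((_GAMMA_NCX - 1.0) * v / _RTONF))))

    inak = (p[7] * _KO / (_KO + _KMK) * nai / (nai + _KMNA)
            / (1.0 + 0.1245 * np.exp(-0.1 * v / _RTONF)
               + 0.0353 * np.exp(-v / _RTONF)))

    ipca = p[8] * cai / (cai + _KPCA)
    ipk = p[9] * (v - ek) / (1.0 + np.exp((25.0 - v) / 5.98))
    ibna = p[10] * (v - ena)
    ibca = p[11] * (v - eca)

    iion = (ina + ik1 + ito + ikr + iks + ical + inaca + inak
            + ipca + ipk + ibna + ibca)

    # --- SR calcium handling ------------------------------------------
    kcasr = _MAXSR - (_MAXSR - _MINSR) / (1.0 + (_EC / casr) ** 2)
    k1 = _K1P / kcasr
    k2 = _K2P * kcasr
    rq = y[I_RQ]
    drq = -k2 * cass * rq + _K4 * (1.0 - rq)
    o_gate = k1 * cass * cass * rq / (_K3 + k1 * cass * cass)
    irel = _VREL * o_gate * (casr - cass)
    ileak = _VLEAK * (casr - cai)
    iup = _VMAXUP / (1.0 + (_KUP / cai) ** 2)
    ixfer = _VXFER * (cass - cai)

    bufc = 1.0 / (1.0 + _BUFC * _KBUFC / ((cai + _KBUFC) ** 2))
    bufsr = 1.0 / (1.0 + _BUFSR * _KBUFSR / ((casr + _KBUFSR) ** 2))
    bufss = 1.0 / (1.0 + _BUFSS * _KBUFSS / ((cass + _KBUFSS) ** 2))

    dcai = bufc * ((-(ibca + ipca - 2.0 * inaca)
                    * _CAPACITANCE / (2.0 * _VC * _FARADAY))
                   + (ileak - iup) * _VSR / _VC + ixfer)
    dcasr = bufsr * (iup - irel - ileak)
    dcass = bufss * (-ical * _CAPACITANCE / (2.0 * _VSS * _FARADAY)
                     + irel * _VSR / _VSS - ixfer * _VC / _VSS)

    dnai = -(ina + ibna + 3.0 * inak + 3.0 * inaca) * _CAPACITANCE / (_VC * _FARADAY)
    dki = -(-istim + ik1 + ito + ikr + iks - 2.0 * inak + ipk) \
        * _CAPACITANCE / (_VC * _FARADAY)

    # --- gate kinetics (Rush–Larsen) ----------------------------------
    minf = 1.0 / (1.0 + np.exp((-56.86 - v) / 9.03)) ** 2
    am = 1.0 / (1.0 + np.exp((-60.0 - v) / 5.0))
    bm = 0.1 / (1.0 + np.exp((v + 35.0) / 5.0)) \
        + 0.1 / (1.0 + np.exp((v - 50.0) / 200.0))
    taum = am * bm

    hinf = 1.0 / (1.0 + np.exp((v + 71.55) / 7.43)) ** 2
    if v >= -40.0:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + np.exp(-(v + 10.66) / 11.1)))
    else:
        ah = 0.057 * np.exp(-(v + 80.0) / 6.8)
        bh = 2.7 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.3485 * v)
    tauh = 1.0 / (ah + bh)

    jinf = hinf
    if v >= -40.0:
        aj = 0.0
        bj = 0.6 * np.exp(0.057 * v) / (1.0 + np.exp(-0.1 * (v + 32.0)))
    else:
        aj = ((-2.5428e4 * np.exp(0.2444 * v) - 6.948e-6 * np.exp(-0.04391 * v))
              * (v + 37.78) / (1.0 + np.exp(0.311 * (v + 79.23))))
        bj = 0.02424 * np.exp(-0.01052 * v) / (1.0 + np.exp(-0.1378 * (v + 40.14)))
    tauj = 1.0 / (aj + bj)

    xr1inf = 1.0 / (1.0 + np.exp((-26.0 - v) / 7.0))
    axr1 = 450.0 / (1.0 + np.exp((-45.0 - v) / 10.0))
    bxr1 = 6.0 / (1.0 + np.exp((v + 30.0) / 11.5))
    tauxr1 = axr1 * bxr1

    xr2inf = 1.0 / (1.0 + np.exp((v + 88.0) / 24.0))
    axr2 = 3.0 / (1.0 + np.exp((-60.0 - v) / 20.0))
    bxr2 = 1.12 / (1.0 + np.exp((v - 60.0) / 20.0))
    tauxr2 = axr2 * bxr2

    xsinf = 1.0 / (1.0 + np.exp((-5.0 - v) / 14.0))
    axs = 1400.0 / np.sqrt(1.0 + np.exp((5.0 - v) / 6.0))
    bxs = 1.0 / (1.0 + np.exp((v - 35.0) / 15.0))
    tauxs = axs * bxs + 80.0

    rinf = 1.0 / (1.0 + np.exp((20.0 - v) / 6.0))
    taur = 9.5 * np.exp(-(v + 40.0) ** 2 / 1800.0) + 0.8
    if endo:
        sinf = 1.0 / (1.0 + np.exp((v + 28.0) / 5.0))
        taus = 1000.0 * np.exp(-(v + 67.0) ** 2 / 1000.0) + 8.0
    else:
        sinf = 1.0 / (1.0 + np.exp((v + 20.0) / 5.0))
        taus = (85.0 * np.exp(-(v + 45.0) ** 2 / 320.0)
                + 5.0 / (1.0 + np.exp((v - 20.0) / 5.0)) + 3.0)

    dinf = 1.0 / (1.0 + np.exp((-8.0 - v) / 7.5))
    ad = 1.4 / (1.0 + np.exp((-35.0 - v) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + np.exp((v + 5.0) / 5.0))
    gd = 1.0 / (1.0 + np.exp((50.0 - v) / 20.0))
    taud = ad * bd + gd

    finf = 1.0 / (1.0 + np.exp((v + 20.0) / 7.0))
    tauf = (1102.5 * np.exp(-(v + 27.0) ** 2 / 225.0)
            + 200.0 / (1.0 + np.exp((13.0 - v) / 10.0))
            + 180.0 / (1.0 + np.exp((v + 30.0) / 10.0)) + 20.0)

    f2inf = 0.67 / (1.0 + np.exp((v + 35.0) / 7.0)) + 0.33
    tauf2 = (562.0 * np.exp(-(v + 27.0) ** 2 / 240.0)
             + 31.0 / (1.0 + np.exp((25.0 - v) / 10.0))
             + 80.0 / (1.0 + np.exp((v + 30.0) / 10.0)))

    fcassinf = 0.6 / (1.0 + (cass / 0.05) ** 2) + 0.4
    taufcass = 80.0 / (1.0 + (cass / 0.05) ** 2) + 2.0

    y[I_M] = minf - (minf - y[I_M]) * np.exp(-dt / taum)
    y[I_H] = hinf - (hinf - y[I_H]) * np.exp(-dt / tauh)
    y[I_J] = jinf - (jinf - y[I_J]) * np.exp(-dt / tauj)
    y[I_XR1] = xr1inf - (xr1inf - y[I_XR1]) * np.exp(-dt / tauxr1)
    y[I_XR2] = xr2inf - (xr2inf - y[I_XR2]) * np.exp(-dt / tauxr2)
    y[I_XS] = xsinf - (xsinf - y[I_XS]) * np.exp(-dt / tauxs)
    y[I_R] = rinf - (rinf - y[I_R]) * np.exp(-dt / taur)
    y[I_S] = sinf - (sinf - y[I_S]) * np.exp(-dt / taus)
    y[I_D] = dinf - (dinf - y[I_D]) * np.exp(-dt / taud)
    y[I_F] = finf - (finf - y[I_F]) * np.exp(-dt / tauf)
    y[I_F2] = f2inf - (f2inf - y[I_F2]) * np.exp(-dt / tauf2)
    y[I_FCASS] = fcassinf - (fcassinf - y[I_FCASS]) * np.exp(-dt / taufcass)

    y[I_RQ] = rq + dt * drq
    y[I_CAI] = cai + dt * dcai
    y[I_CASR] = casr + dt * dcasr
    y[I_CASS] = cass + dt * dcass
    y[I_NAI] = nai + dt * dnai
    y[I_KI] = ki + dt * dki
    y[I_V] = v + dt * (-(iion) + istim)


# ---------------------------------------------------------------------------
# Reduced model kernel (three-current excitable model + calcium surrogate)
# ---------------------------------------------------------------------------

FK_V_REST = -85.0    # mV mapped onto u = 0
FK_V_SPAN = 120.0    # mV per unit u

_Y0_REDUCED = np.array([0.0, 1.0, 1.0, 0.0])   # u, v, w, c

#: The APD dial accelerates only the plateau decay of the slow gate w
#: (tau_w+ / gain). gain(m) = BASE * m**EXPONENT is calibrated so the paced
#: APD90 spans ~250 ms at multiplier 1 down to ~74 ms at multiplier 100.
_FK_GAIN_BASE = 1.55
_FK_APD_EXPONENT = 0.453


def _fk_param_vector(gks_multiplier: float) -> np.ndarray:
    gain = _FK_GAIN_BASE * gks_multiplier ** _FK_APD_EXPONENT
    # u_csi lowered relative to the classic set so that propagated (rather
    # than directly stimulated) upstrokes, whose peak is reduced on coarse
    # desk-scale grids, still reach the slow-inward activation range.
    # tau_d, tau_r, tau_si, tau_0, tau_vp, tau_v1m, tau_v2m, tau_wp, tau_wm,
    # u_c, u_v, u_csi, k, tau_ca, apd_gain
    return np.array([
        0.25, 33.33, 29.0, 12.5, 3.33, 1250.0, 19.6, 870.0, 41.0,
        0.13, 0.04, 0.5, 10.0, 30.0, gain,
    ])


@njit(cache=True)
def _fk_step(y, dt, istim, p):
    """Advance one reduced-model cell by dt.

    State: u (scaled voltage), v (fast gate), w (slow gate),
    c (phenomenological calcium transient, relaxed first-order toward u).
    ``istim`` is in the same scaled-voltage units per ms.
    """
    u = y[0]
    vg = y[1]
    w = y[2]
    c = y[3]
    pgate = 1.0 if u >= p[9] else 0.0
    qgate = 1.0 if u >= p[10] else 0.0

    jfi = -vg * pgate * (u - p[9]) * (1.0 - u) / p[0]
    jso_sub = u * (1.0 - pgate) / p[3]
    jso_plateau = pgate / p[1]
    jsi = -w * (1.0 + np.tanh(p[12] * (u - p[11]))) / (2.0 * p[2])

    # fast-gate recovery: slow while u is above u_v, fast once repolarized
    tauvm = qgate * p[5] + (1.0 - qgate) * p[6]
    dv = (1.0 - pgate) * (1.0 - vg) / tauvm - pgate * vg / p[4]
    # The APD dial p[14] accelerates only the plateau decay of the slow
    # gate w; front kinetics (jfi, sub-threshold leak, v gate) are untouched
    # so excitation threshold and conduction are independent of the dial.
    dw = (1.0 - pgate) * (1.0 - w) / p[8] - pgate * w * p[14] / p[7]

    y[0] = u + dt * (-(jfi + jso_sub + jso_plateau + jsi) + istim)
    y[1] = vg + dt * dv
    y[2] = w + dt * dw
    y[3] = c + dt * (max(u, 0.0) - c) / p[13]


# ---------------------------------------------------------------------------
# Single-cell drivers
# ---------------------------------------------------------------------------

@njit(cache=True)
def _paced_loop(y, detailed, p, dt, bcl, n_beats, stim_amp, stim_dur, stride):
    nsteps = int(round(bcl / dt)) * n_beats
    nrec = nsteps // stride + 1
    t_rec = np.empty(nrec)
    v_rec = np.empty(nrec)
    c_rec = np.empty(nrec)
    irec = 0
    for step in range(nsteps):
        if step % stride == 0:
            t_rec[irec] = step * dt
            if detailed:
                v_rec[irec] = y[I_V]
                c_rec[irec] = y[I_CAI]
            else:
                v_rec[irec] = FK_V_REST + FK_V_SPAN * y[0]
                c_rec[irec] = 1e-4 + 1e-3 * y[3]
            irec += 1
        phase = (step * dt) % bcl
        istim = stim_amp if phase < stim_dur else 0.0
        if detailed:
            _tp06_step(y, dt, istim, p)
        else:
            _fk_step(y, dt, istim, p)
    # trailing sample
    t_rec[irec] = nsteps * dt
    if detailed:
        v_rec[irec] = y[I_V]
        c_rec[irec] = y[I_CAI]
    else:
        v_rec[irec] = FK_V_REST + FK_V_SPAN * y[0]
        c_rec[irec] = 1e-4 + 1e-3 * y[3]
    return t_rec[:irec + 1], v_rec[:irec + 1], c_rec[:irec + 1]


def make_state(params: CellParams) -> CellState:
    """Resting initial state for the requested model."""
    y0 = _Y0_DETAILED if params.model_kind == "detailed" else _Y0_REDUCED
    return CellState(y0.copy(), params.model_kind)


def step_ionic(state: CellState, params: CellParams, dt: float,
               istim: float = 0.0) -> CellState:
    """Advance a single cell by one step of ``dt`` ms and return the new state.

    Raises :class:`IntegrationFailure` naming the first non-finite variable.
    """
    if params.model_kind == "detailed" and not (0.0 < dt <= 0.1):
        raise ValueError("detailed model requires dt in (0, 0.1] ms")
    if dt <= 0:
        raise ValueError("dt must be positive")
    out = state.copy()
    p = params.vector()
    if params.model_kind == "detailed":
        _tp06_step(out.y, dt, istim, p)
    else:
        _fk_step(out.y, dt, istim, p)
    if not np.all(np.isfinite(out.y)):
        bad = int(np.flatnonzero(~np.isfinite(out.y))[0])
        raise IntegrationFailure(f"non-finite state variable at index {bad}")
    return out


def run_paced(params: CellParams, bcl: float, n_beats: int,
              state: CellState | None = None,
              record_dt: float | None = None) -> APTrace:
    """Pace a single cell at cycle length ``bcl`` for ``n_beats`` beats.

    The stimulus fires at the start of every cycle. Returns the full
    recording; raises :class:`NoCaptureError` if the first stimulus does
    not produce an upstroke.
    """
    if bcl < 200:
        raise ValueError("bcl must be >= 200 ms")
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    dt = params.default_dt
    if record_dt is None:
        record_dt = 0.1 if params.model_kind == "detailed" else 0.5
    stride = max(1, int(round(record_dt / dt)))
    detailed = params.model_kind == "detailed"
    y = (state.copy().y if state is not None else make_state(params).y)
    if detailed:
        stim_amp = params.stim_amplitude
    else:
        stim_amp = 3.0 if params.stim_amplitude != 0.0 else 0.0
    t, vm, cai = _paced_loop(y, detailed, params.vector(), dt, bcl,
                             n_beats, stim_amp, params.stim_duration, stride)
    if not np.all(np.isfinite(vm)):
        raise IntegrationFailure("non-finite membrane potential in paced run")
    if stim_amp != 0.0:
        first_cycle = vm[t < bcl]
        if first_cycle.max() < -40.0:
            raise NoCaptureError("stimulus did not elicit an upstroke")
    return APTrace(t, vm, cai, bcl)


# ---------------------------------------------------------------------------
# APD measurement
# ---------------------------------------------------------------------------

UPSTROKE_THRESHOLD = -40.0   # mV; upward crossing marks a new beat


def detect_upstrokes(t: np.ndarray, vm: np.ndarray,
                     threshold: float = UPSTROKE_THRESHOLD) -> np.ndarray:
    """Indices of samples where V_m crosses ``threshold`` upward."""
    above = vm >= threshold
    return np.flatnonzero(~above[:-1] & above[1:]) + 1


def apd90(trace: APTrace, beat_index: int = -1) -> float:
    """APD90 of one beat: depolarization onset to 90% repolarization.

    Onset is the time of maximal dV/dt on the upstroke; the 90% level is
    V_rest + 0.1 (V_peak - V_rest) with V_rest taken just before the
    upstroke, located on the falling limb with linear interpolation.
    """
    t, vm = trace.t, trace.vm
    ups = detect_upstrokes(t, vm)
    if len(ups) == 0:
        raise NoCaptureError("no upstroke in trace")
    idx = np.arange(len(ups))[beat_index]
    i_up = ups[idx]
    i_next = ups[idx + 1] if idx + 1 < len(ups) else len(t) - 1

    # beat window starts a little before the threshold crossing
    i_start = ups[idx - 1] if idx > 0 else 0
    pre = vm[i_start:i_up + 1]
    v_rest = pre.min() if len(pre) else vm[0]

    # onset: max dV/dt around the crossing
    lo = max(i_up - int(5.0 / trace.dt) - 1, i_start)
    hi = min(i_up + int(5.0 / trace.dt) + 1, len(t) - 1)
    dv = np.diff(vm[lo:hi + 1])
    # the steepest rise lies between samples k and k+1; onset is the
    # depolarized side of that interval
    i_on = lo + int(np.argmax(dv)) + 1
    t_on = t[i_on]

    seg_v = vm[i_on:i_next + 1]
    seg_t = t[i_on:i_next + 1]
    v_peak = seg_v.max()
    v90 = v_rest + 0.1 * (v_peak - v_rest)
    i_pk = int(np.argmax(seg_v))
    fall_v = seg_v[i_pk:]
    fall_t = seg_t[i_pk:]
    below = np.flatnonzero(fall_v <= v90)
    if len(below) == 0:
        raise CensoredAPDError("beat never repolarized to 90% within its cycle")
    k = below[0]
    if k == 0:
        t_cross = fall_t[0]
    else:
        v1, v2 = fall_v[k - 1], fall_v[k]
        t1, t2 = fall_t[k - 1], fall_t[k]
        t_cross = t1 + (v90 - v1) / (v2 - v1) * (t2 - t1)
    return float(t_cross - t_on)


def total_calcium(state: CellState) -> float:
    """Volume-weighted total calcium (free + buffered) over cytosol, dyadic
    subspace and SR, in mM * volume units. Conserved when all sarcolemmal
    calcium fluxes are zero."""
    if state.model_kind != "detailed":
        raise ValueError("total_calcium applies to the detailed model")
    cai, cass, casr = state.y[I_CAI], state.y[I_CASS], state.y[I_CASR]
    tot_c = cai + _BUFC * cai / (cai + _KBUFC)
    tot_ss = cass + _BUFSS * cass / (cass + _KBUFSS)
    tot_sr = casr + _BUFSR * casr / (casr + _KBUFSR)
    return float(tot_c * _VC + tot_ss * _VSS + tot_sr * _VSR)
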