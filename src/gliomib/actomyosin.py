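"""Pressure-driven acto-myosin kinetics, nucleus stiffening and drug dosing.

The mechanical confinement a migrating cell feels is proxied by a sensing
pressure: the fluid pressure averaged over disks around each membrane node
and then over the membrane.  The sensed pressure sets the available actin
concentration [a] = k_p * p^s, which drives reversible myosin-II binding

    d[m_b]/dt = k1 [m_T] [a] - (k1 [a] + k_-1) [m_b],

with steady state [m_b]_s = [m_T][a] / ([a] + 1/K), K = k1/k_-1.  Bound
myosin softens the nucleus through a decreasing Hill function of [m_b]:
the stiffening rate r ranges from k_s + k_s_min (rigid, low myosin) down to
k_s_min (soft, high myosin), and multiplies the basal nucleus stiffness.

Two anti-invasion drugs are modeled as pulsed inputs: blebbistatin B(t)
degrades bound myosin (-alpha B [m_b]) and an actin-myosin association
inhibitor D(t) scales the association rate by exp(-D).  Both follow
dC/dt = I * (pulse on/off) - mu C with a pulse at the start of each
injection cycle.  All ODE updates are exact exponential steps with
coefficients frozen over the step, which is unconditionally stable and
introduces no solver tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ib_structures import BoundaryCurve


@dataclass
class MyosinState:
    """Bound myosin-II concentration and kinetic constants (Table-of-
    parameters defaults: k1 = 0.002 /uM/s, k_-1 = 1e-4 /s, m_T = 1 uM,
    k_p = 0.9 (wild type) or 0.045 (MYOII-KD), R_s = 4.69 um)."""

    mb: float = 0.0            # bound myosin II (uM)
    mT: float = 1.0            # total myosin II (uM)
    k1: float = 0.002          # association rate (1/(uM s))
    k_1: float = 1.0e-4        # dissociation rate (1/s)
    kp: float = 0.9            # myosin-pressure sensitivity (uM s^2/(g cm))
    Rs: float = 4.69e-4        # pressure sensing radius (cm)
    pressure_scale: float = 1.0  # overall calibration of the sensed pressure

    def __post_init__(self):
        if self.k1 <= 0 or self.k_1 <= 0:
            raise ValueError("kinetic rates must be positive")
        self.mb = float(np.clip(self.mb, 0.0, self.mT))

    @property
    def K(self) -> float:
        return self.k1 / self.k_1


@dataclass
class StiffeningParams:
    """Hill-type nucleus stiffening: r in [ks_min, ks + ks_min]."""

    ceGn_b: float = 3.8e-5     # basal nucleus stiffness (g cm/s^2)
    ks: float = 5.0
    ks_min: float = 0.1
    Kmb: float = 1.8           # reciprocal critical threshold (1/uM)
    n: float = 10.0            # Hill coefficient
    stiffness_fold: float = 1.0


@dataclass
class DrugState:
    """Pulsed blebbistatin (B) and association-inhibitor (D) schedules.

    Each drug is injected at strength I during the first
    ``pulse_fraction * tau`` of each of the N cycles (cycle j starts at
    j * tau, t0 = 0) and decays at rate mu throughout.  The default pulse
    fraction corresponds to a 1/3-hour pulse per 1-hour unit of tau.
    """

    B: float = 0.0
    D: float = 0.0
    IB: float = 0.0            # blebbistatin injection strength (uM/s scale)
    ID: float = 0.0
    tauB: float = 2.0          # injection interval (hours)
    tauD: float = 2.0
    NB: int = 0                # number of injections
    ND: int = 0
    muB: float = 5.13e-4       # decay rate (1/s)
    muD: float = 5.13e-4
    alpha_bleb: float = 1.0e-4  # bound-myosin degradation by B (1/(s uM))
    pulse_hours: float = 1.0 / 3.0  # pulse duration per cycle (hours)

    def __post_init__(self):
        if self.B < 0 or self.D < 0:
            raise ValueError("drug concentrations must be non-negative")


# ---------------------------------------------------------------------------
# sensing


def disk_average_stencil(Rs: float, h: float) -> np.ndarray:
    """Grid-index offsets (k, 2) of points within a disk of radius Rs."""
    r = max(int(math.floor(Rs / h)), 0)
    di, dj = np.mgrid[-r:r + 1, -r:r + 1]
    mask = (di ** 2 + dj ** 2) * h ** 2 <= Rs ** 2 + 1e-30
    return np.column_stack([di[mask], dj[mask]])


def sensing_pressure(p: np.ndarray, membrane: BoundaryCurve, Rs: float,
                     h: float, stencil: np.ndarray | None = None) -> float:
    """Membrane-averaged, disk-smoothed pressure p^s (zero-mean gauge).

    Each node's local pressure is the average of the grid pressure over a
    disk of radius Rs around it; p^s is the mean over all membrane nodes.
    """
    n = p.shape[0]
    if stencil is None:
        stencil = disk_average_stencil(Rs, h)
    idx = np.rint(membrane.X / h).astype(int)            # nearest grid point
    ii = (idx[:, 0, None] + stencil[:, 0]) % n
    jj = (idx[:, 1, None] + stencil[:, 1]) % n
    return float(p[ii, jj].mean())


def actin_concentration(ps: float, kp: float,
                        pressure_scale: float = 1.0) -> float:
    """[a] = max(0, kp * ps); negative gauge pressure yields no actin."""
    return max(0.0, kp * pressure_scale * ps)


# ---------------------------------------------------------------------------
# kinetics


def steady_state_mb(a: float, state: MyosinState) -> float:
    """Equilibrium bound myosin [m_T][a] / ([a] + 1/K)."""
    if a < 0:
        raise ValueError("actin concentration must be non-negative")
    return state.mT * a / (a + 1.0 / state.K)


def step_myosin(state: MyosinState, a: float, drug: DrugState,
                dt: float) -> MyosinState:
    """Exact exponential update of the bound-myosin ODE over dt.

    d[mb]/dt = k1 e^{-D} mT a - (k1 e^{-D} a + k_-1 + alpha B) mb.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if a < 0:
        raise ValueError("actin concentration must be non-negative")
    kon = state.k1 * math.exp(-drug.D)
    lam = kon * a + state.k_1 + drug.alpha_bleb * drug.B
    mb_inf = kon * state.mT * a / lam
    mb = mb_inf + (state.mb - mb_inf) * math.exp(-lam * dt)
    new = MyosinState(**{**state.__dict__, "mb": mb})
    return new


def stiffening_rate(mb: float, params: StiffeningParams) -> float:
    """Hill-type nucleus stiffening rate, decreasing in [m_b].

    r = ks * (1/mb)^n / (Kmb^n + (1/mb)^n) + ks_min, with the mb -> 0 limit
    ks + ks_min.  Evaluated in log space to avoid overflow at large n.
    """
    if mb <= 0.0:
        return params.ks + params.ks_min
    # y = (1/(mb*Kmb))^n ;  r = ks * y/(1+y) + ks_min
    logy = -params.n * (math.log(mb) + math.log(params.Kmb))
    if logy > 500.0:
        frac = 1.0
    else:
        y = math.exp(logy)
        frac = y / (1.0 + y)
    return params.ks * frac + params.ks_min


def nucleus_stiffness(r: float, params: StiffeningParams) -> float:
    """c_e^Gn = fold * basal stiffness * stiffening rate."""
    if r < 0:
        raise ValueError("stiffening rate must be non-negative")
    return params.stiffness_fold * params.ceGn_b * r


# ---------------------------------------------------------------------------
# drugs


def _pulse_bounds(tau_s: float, pulse_s: float, n_cycles: int):
    """(start, end) of each injection pulse in seconds."""
    starts = np.arange(n_cycles) * tau_s
    return starts, starts + pulse_s


def _integrate_pulsed(conc: float, I: float, tau_h: float, n_cycles: int,
                      mu: float, pulse_h: float, t: float, dt: float
                      ) -> float:
    """Exact piecewise-linear-ODE integration of dc/dt = I*on(t) - mu c."""
    tau_s = tau_h * 3600.0
    pulse_s = min(pulse_h, tau_h) * 3600.0
    t_end = t + dt
    # event times: pulse on/off edges inside (t, t_end)
    edges = [t, t_end]
    if n_cycles > 0 and I != 0.0:
        j0 = max(0, int(math.floor(t / tau_s)) - 1)
        j1 = min(n_cycles, int(math.ceil(t_end / tau_s)) + 1)
        for j in range(j0, j1):
            for e in (j * tau_s, j * tau_s + pulse_s):
                if t < e < t_end:
                    edges.append(e)
    edges = sorted(edges)
    c = conc
    for a, b in zip(edges[:-1], edges[1:]):
        mid = 0.5 * (a + b)
        j = int(math.floor(mid / tau_s)) if tau_s > 0 else 0
        on = (0 <= j < n_cycles) and (mid - j * tau_s) < pulse_s and I != 0.0
        span = b - a
        if mu > 0:
            if on:
                c = I / mu + (c - I / mu) * math.exp(-mu * span)
            else:
                c = c * math.exp(-mu * span)
        else:
            c = c + (I * span if on else 0.0)
    return c


def drug_step(drug: DrugState, t: float, dt: float) -> DrugState:
    """Advance both drug concentrations from t to t+dt (exact per piece)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    B = _integrate_pulsed(drug.B, drug.IB, drug.tauB, drug.NB, drug.muB,
                          drug.pulse_hours, t, dt)
    D = _integrate_pulsed(drug.D, drug.ID, drug.tauD, drug.ND, drug.muD,
                          drug.pulse_hours, t, dt)
    new = DrugState(**{**drug.__dict__, "B": B, "D": D})
    return new
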