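"""Two-phase amoeboid migration cycle and chemotaxis-driven active force.

Migration alternates between an elongation step (front protrudes under an
active force while the rear is tethered to frozen attachment sites) and a
retraction step (rear releases, front tethers, the body is pulled forward).
Switching is driven by the smoothed rate of change of the cell-body length
L(t): elongation ends when L' decays to the retention rate delta_ret+ > 0,
retraction ends when L' rises to delta_ret- < 0, and either switch is forced
after a maximum phase duration.

The migration direction d is the disk-averaged chemoattractant gradient,
normalized to a unit vector; the active force magnitude is

    c_a = chi * (alpha + |F_C|),   F_C = grad C / (1 + lambda_s |grad C|^2),

so |F_C| <= 1/(2 sqrt(lambda_s)) is bounded no matter how steep the
gradient.  The active force c_a * d is applied as a boundary force density
on the front membrane arc during elongation only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import chemofield
from .ib_structures import GliomaCell

ELONGATION = "elongation"
RETRACTION = "retraction"


@dataclass
class MigrationCycle:
    """State machine for the elongation/retraction cycle.

    delta_ret_plus / delta_ret_minus are the retention rates (cm/s); their
    difference is the width of the retention strip.  L_history stores
    (t, L) samples used for the smoothed centered-difference estimate of
    L'(t).
    """

    phase: str = ELONGATION
    delta_ret_plus: float = 2.0e-6     # +0.02 um/s
    delta_ret_minus: float = -2.0e-6   # -0.02 um/s
    max_phase_duration: float = 120.0  # s
    min_phase_duration: float = 0.0    # adhesion-turnover floor (s)
    smooth_window: int = 5
    L_history: list = field(default_factory=list)
    phase_started: float = 0.0
    switch_log: list = field(default_factory=list)
    direction: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 1.0]))

    def __post_init__(self):
        if not (self.delta_ret_plus > 0.0 > self.delta_ret_minus):
            raise ValueError("retention rates must satisfy "
                             "delta_ret+ > 0 > delta_ret-")

    @property
    def retention_width(self) -> float:
        return self.delta_ret_plus - self.delta_ret_minus

    def smoothed_rate(self) -> float | None:
        """Centered-difference L' over a moving-average window of L."""
        w = self.smooth_window
        if len(self.L_history) < 2 * w:
            return None
        hist = self.L_history[-2 * w:]
        t0 = np.mean([h[0] for h in hist[:w]])
        t1 = np.mean([h[0] for h in hist[w:]])
        L0 = np.mean([h[1] for h in hist[:w]])
        L1 = np.mean([h[1] for h in hist[w:]])
        if t1 <= t0:
            return None
        return (L1 - L0) / (t1 - t0)


def update_phase(cycle: MigrationCycle, L_now: float, t: float) -> bool:
    """Record the current length and switch phases when warranted.

    Returns True exactly when a switch occurred (the caller then re-freezes
    the tether anchors and re-selects the front/rear arcs).  Phases strictly
    alternate; a switch is forced at max_phase_duration.
    """
    cycle.L_history.append((t, L_now))
    if len(cycle.L_history) > 4 * cycle.smooth_window:
        del cycle.L_history[:-4 * cycle.smooth_window]
    rate = cycle.smoothed_rate()
    elapsed = t - cycle.phase_started
    switch = False
    if elapsed >= cycle.max_phase_duration:
        switch = True
    elif rate is not None and elapsed >= cycle.min_phase_duration \
            and elapsed > 0:
        if cycle.phase == ELONGATION and rate <= cycle.delta_ret_plus:
            switch = True
        elif cycle.phase == RETRACTION and rate >= cycle.delta_ret_minus:
            switch = True
    if switch:
        cycle.phase = RETRACTION if cycle.phase == ELONGATION else ELONGATION
        cycle.phase_started = t
        cycle.switch_log.append((t, cycle.phase))
        cycle.L_history.clear()
    return switch


@dataclass
class ActiveForceParams:
    """Chemotactic active-force parameters (tabulated defaults)."""

    chi: float = 0.7           # basal active force strength
    alpha_sig: float = 0.15    # basal signaling strength
    lambda_s: float = 20.0     # chemotactic saturation parameter
    sensing_radius_chem: float = 0.4e-4  # R_s^c (cm)

    def __post_init__(self):
        if self.chi < 0 or self.lambda_s <= 0:
            raise ValueError("need chi >= 0 and lambda_s > 0")


def migration_direction(field: chemofield.ChemField, x, Rsc: float,
                        prev_dir=None, grad: np.ndarray | None = None
                        ) -> np.ndarray:
    """Unit vector along the disk-averaged gradient of C around x.

    When the sensing disk is smaller than ~2 grid cells the disk average is
    the bilinearly interpolated gradient at x (an under-resolved disk
    integral would be noisier); otherwise grid points within the disk are
    averaged.  A vanishing average gradient retains the previous direction.
    """
    x = np.asarray(x, dtype=float)
    if grad is None:
        grad = chemofield.gradient(field)
    if Rsc < 2.0 * field.h:
        g = chemofield.gradient_at(field, grad, x[None, :])[0]
    else:
        cc = field.cell_centers()
        dx = cc[:, None] - x[0]
        dy = cc[None, :] - x[1]
        mask = dx ** 2 + dy ** 2 <= Rsc ** 2
        g = np.array([grad[0][mask].mean(), grad[1][mask].mean()])
    norm = np.linalg.norm(g)
    if norm < 1e-14:
        if prev_dir is None:
            return np.array([0.0, 1.0])
        return np.asarray(prev_dir, dtype=float)
    return g / norm


def chemotactic_force_strength(gradC, params: ActiveForceParams
                               ) -> tuple[float, float]:
    """(|F_C|, c_a) from the local chemoattractant gradient.

    |F_C| = |grad C| / (1 + lambda_s |grad C|^2) is bounded by
    1/(2 sqrt(lambda_s)); c_a = chi (alpha + |F_C|).
    """
    g = float(np.linalg.norm(np.asarray(gradC, dtype=float)))
    Fc = g / (1.0 + params.lambda_s * g * g)
    ca = params.chi * (params.alpha_sig + Fc)
    return Fc, ca


def active_force(cell: GliomaCell, cycle: MigrationCycle, ca: float,
                 direction) -> np.ndarray:
    """Active protrusion force density on the membrane nodes.

    Front-arc nodes receive c_a * d during elongation; the force vanishes
    during retraction.
    """
    F = np.zeros_like(cell.membrane.X)
    if cycle.phase == ELONGATION:
        if cell.front_nodes.size == 0:
            raise ValueError("front node set is empty")
        d = np.asarray(direction, dtype=float)
        F[cell.front_nodes] = ca * d
    return F


def glioma_membrane_force(cell: GliomaCell, cycle: MigrationCycle,
                          ca: float, direction) -> np.ndarray:
    """Total force density on the glioma membrane.

    Sum of the elastic stretching force, the phase-dependent tether force
    (rear arc pulled toward the frozen rear anchors Zr during elongation,
    front arc toward the frozen front anchors Zf during retraction) and the
    active protrusion force.
    """
    from .ib_structures import elastic_force, tether_force

    F = elastic_force(cell.membrane)
    if cycle.phase == ELONGATION:
        if cell.Zr is not None and cell.rear_nodes.size:
            F[cell.rear_nodes] += tether_force(
                cell.membrane.X[cell.rear_nodes], cell.Zr, cell.ct)
    else:
        if cell.Zf is not None and cell.front_nodes.size:
            F[cell.front_nodes] += tether_force(
                cell.membrane.X[cell.front_nodes], cell.Zf, cell.ct)
    F += active_force(cell, cycle, ca, direction)
    return F
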