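"""Spectral solver for the 2D incompressible Navier-Stokes equations.

The cell-scale flow is solved on a square periodic box with an FFT-based
projection scheme: the viscous term is integrated exactly per Fourier mode
(exponential integrating factor), advection (skew-symmetric form) is
explicit, and incompressibility is enforced by an exact spectral projection
whose multiplier is the pressure.  At the Reynolds numbers of cell migration (Re ~ 1e-6) the flow is
effectively Stokes flow; advection is retained for completeness and can be
disabled.

Units are CGS throughout: the 0.1 mm tissue domain is a 0.01 cm box, the
interstitial fluid has density rho = 1.35 g/cm^3 and viscosity
mu = 2.7 g/(cm s).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class FluidInstabilityError(RuntimeError):
    """Raised when non-finite values appear in the fluid fields."""


@dataclass
class FluidState:
    """Velocity/pressure fields on an N x N periodic grid.

    Attributes
    ----------
    u : ndarray, shape (2, N, N)
        Velocity components (cm/s); ``u[0]`` is the x component.  Grid point
        (i, j) sits at (i*h, j*h).
    p : ndarray, shape (N, N)
        Pressure (g/(cm s^2)), zero spatial mean (gauge fixed).
    h : float
        Grid spacing (cm).
    rho, mu : float
        Fluid density (g/cm^3) and viscosity (g/(cm s)).
    t : float
        Simulated time (s).
    step_index : int
        Number of steps taken; pressure is undefined before the first step.
    """

    u: np.ndarray
    p: np.ndarray
    h: float
    rho: float
    mu: float
    t: float = 0.0
    step_index: int = 0

    @property
    def n(self) -> int:
        return self.u.shape[-1]

    @property
    def box_size(self) -> float:
        return self.n * self.h


def make_fluid_state(n: int, box_size: float, rho: float = 1.35,
                     mu: float = 2.7) -> FluidState:
    """Quiescent fluid on an n x n periodic grid covering ``box_size``^2."""
    return FluidState(
        u=np.zeros((2, n, n)),
        p=np.zeros((n, n)),
        h=box_size / n,
        rho=rho,
        mu=mu,
    )


_WAVENUMBER_CACHE: dict = {}


def _wavenumbers(n: int, h: float):
    """Full/half-spectrum wavenumbers for rfft2 layouts (cached)."""
    key = (n, h)
    if key not in _WAVENUMBER_CACHE:
        k = 2.0 * np.pi * np.fft.fftfreq(n, d=h)
        kr = 2.0 * np.pi * np.fft.rfftfreq(n, d=h)
        kx = k[:, None]
        ky = kr[None, :]
        k2 = kx ** 2 + ky ** 2
        _WAVENUMBER_CACHE[key] = (kx, ky, k2)
    return _WAVENUMBER_CACHE[key]


def _spectral_advection(u: np.ndarray, kx, ky) -> np.ndarray:
    """Skew-symmetric advection term 0.5*(u.grad u + div(u u)), spectrally."""
    from scipy.fft import irfft2, rfft2

    n = u.shape[-1]
    uh = rfft2(u)
    ux = irfft2(1j * kx * uh, s=(n, n))
    uy = irfft2(1j * ky * uh, s=(n, n))
    conv = u[0] * ux + u[1] * uy            # (u . grad) u
    uu = np.stack([u[0] * u[0], u[0] * u[1],
                   u[1] * u[0], u[1] * u[1]])
    uuh = rfft2(uu)
    div = np.empty_like(u)
    div[0] = irfft2(1j * kx * uuh[0] + 1j * ky * uuh[1], s=(n, n))
    div[1] = irfft2(1j * kx * uuh[2] + 1j * ky * uuh[3], s=(n, n))
    return 0.5 * (conv + div)


def navier_stokes_step(state: FluidState, f: np.ndarray, dt: float,
                       advection: bool = True,
                       remove_mean_force: bool = True) -> FluidState:
    """Advance the fluid one step under the body-force field ``f``.

    Exact per-mode viscous integrating factor, explicit (skew-symmetric)
    advection, exact spectral projection.  The returned velocity is
    discretely divergence-free and the pressure is the zero-mean multiplier
    of the quasi-static force balance.

    With ``remove_mean_force`` (the momentum gauge) the spatial-mean force
    mode is dropped so a net active force cannot accelerate the whole
    periodic box; disable it to evolve the k=0 momentum mode exactly.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if f.shape != state.u.shape:
        raise ValueError(f"force field shape {f.shape} != velocity shape "
                         f"{state.u.shape}")
    if not np.all(np.isfinite(f)):
        raise FluidInstabilityError(
            f"non-finite body force at step {state.step_index}")
    if not np.all(np.isfinite(state.u)):
        raise FluidInstabilityError(
            f"non-finite velocity at step {state.step_index}")

    from scipy.fft import irfft2, rfft2

    n, h, rho, mu = state.n, state.h, state.rho, state.mu
    kx, ky, k2 = _wavenumbers(n, h)

    rhs = f.copy()
    if advection:
        rhs -= rho * _spectral_advection(state.u, kx, ky)

    uh = rfft2(state.u)
    rh = rfft2(rhs)
    if remove_mean_force:
        rh[:, 0, 0] = 0.0
    # drop Nyquist modes: their derivative (hence projection) is not
    # well-defined for real fields
    rh[:, n // 2, :] = 0.0
    rh[:, :, -1] = 0.0
    uh[:, n // 2, :] = 0.0
    uh[:, :, -1] = 0.0

    # pressure from the quasi-static force balance (divergence-free
    # constraint on the projected forcing):  p_hat = -i (k . r_hat) / k^2
    k2s = np.where(k2 > 0, k2, 1.0)
    ph = -1j * (kx * rh[0] + ky * rh[1]) / k2s
    ph[0, 0] = 0.0
    rh[0] -= 1j * kx * ph          # projected forcing (divergence-free)
    rh[1] -= 1j * ky * ph

    # exact viscous integrating factor per mode (exponential integrator):
    #   u_new = e^{-nu k^2 dt} u + (1 - e^{-nu k^2 dt})/(nu k^2) * r/rho
    # which damps grid-scale modes strongly and reproduces analytic Stokes
    # decay to machine precision when the forcing vanishes
    nu = mu / rho
    E = np.exp(-nu * k2 * dt)
    with np.errstate(divide="ignore", invalid="ignore"):
        G = np.where(k2 > 0, (1.0 - E) / (nu * k2s * rho), dt / rho)
    unew_h = E * uh + G * rh
    # remove residual divergence (roundoff accumulation) exactly
    kdotu = kx * unew_h[0] + ky * unew_h[1]
    unew_h[0] -= kx * kdotu / k2s
    unew_h[1] -= ky * kdotu / k2s

    unew = irfft2(unew_h, s=(n, n))
    pnew = irfft2(ph, s=(n, n))
    pnew -= pnew.mean()

    if not np.all(np.isfinite(unew)):
        raise FluidInstabilityError(
            f"fluid solve produced non-finite velocity at step "
            f"{state.step_index + 1}; dt={dt} likely exceeds the stability "
            "bound of the explicit coupling")

    return replace(state, u=unew, p=pnew, t=state.t + dt,
                   step_index=state.step_index + 1)


def pressure_field(state: FluidState) -> np.ndarray:
    """Zero-mean pressure from the most recent projection step."""
    if state.step_index == 0:
        raise RuntimeError("pressure is undefined before the first fluid step")
    return state.p


def divergence(state: FluidState) -> np.ndarray:
    """Spectral divergence of the velocity field (diagnostic)."""
    from scipy.fft import irfft2, rfft2

    n = state.n
    kx, ky, _ = _wavenumbers(n, state.h)
    uh = rfft2(state.u)
    return irfft2(1j * kx * uh[0] + 1j * ky * uh[1], s=(n, n))


def kinetic_energy(state: FluidState) -> float:
    return 0.5 * state.rho * float(np.sum(state.u ** 2)) * state.h ** 2


@dataclass
class StiffnessSummary:
    """What the coupled structures impose on the explicit coupling.

    ``elastic`` holds (stiffness c in g cm/s^2, node spacing ds in cm) pairs,
    ``tether`` the tether coefficients c_t in g/(cm s^2).
    """

    elastic: list = field(default_factory=list)
    tether: list = field(default_factory=list)


def stability_dt(state: FluidState, stiffness: StiffnessSummary,
                 configured_dt: float, cfl: float = 0.5,
                 elastic_safety: float = 0.5) -> float:
    """Largest usable step <= ``configured_dt``.

    Combines the advective CFL bound with relaxation-rate bounds for the
    explicitly coupled elastic and tether forces.  A boundary mode of
    wavenumber pi/ds with stiffness c relaxes at roughly c (pi/ds)^2 h / mu;
    a tether at c_t h / mu.  The returned dt keeps every rate * dt below
    ``elastic_safety``.
    """
    dt = configured_dt
    umax = float(np.max(np.abs(state.u)))
    if umax > 0:
        dt = min(dt, cfl * state.h / umax)
    for c, ds in stiffness.elastic:
        if c > 0 and ds > 0:
            rate = c * (np.pi / ds) ** 2 * state.h / state.mu
            if rate > 0:
                dt = min(dt, elastic_safety / rate)
    for ct in stiffness.tether:
        if ct > 0:
            rate = ct * state.h / state.mu
            dt = min(dt, elastic_safety / rate)
    return dt
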