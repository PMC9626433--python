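"""Herschel-Bulkley blood rheology and analytic channel-flow oracles.

Blood in small cerebral arteries is mildly shear-thinning with a small yield
stress.  The Herschel-Bulkley (HB) generalized-Newtonian law models this as

    eta(gamma_dot) = kappa * gamma_dot**(n - 1) + tau0 / gamma_dot

with consistency ``kappa`` (Pa s^n), power-law index ``n`` and yield stress
``tau0`` (Pa).  The raw law diverges as the shear rate vanishes, so the
implementation uses a bi-viscosity regularization: below ``gamma_min`` the
viscosity is frozen at its value at ``gamma_min``.

The module also provides the exact plane-Poiseuille solution of an HB fluid,
used throughout the test-suite as an independent oracle for the finite-element
flow solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

__all__ = [
    "RheologyParams",
    "effective_viscosity",
    "shear_rate",
    "channel_flow_oracle",
    "channel_pressure_gradient_for_mean_velocity",
    "pipe_wall_shear_newtonian",
    "reynolds_number",
    "ChannelFlowSolution",
]


@dataclass(frozen=True)
class RheologyParams:
    """Herschel-Bulkley constants and blood density.

    Defaults are literature values for cerebral blood:
    kappa = 8.9721e-3 Pa s^n, n = 0.8601, tau0 = 0.0175 Pa, rho = 1020 kg/m3.
    ``mu_ref`` is the Newtonian reference viscosity (0.04 g/(cm s) converted
    to 0.004 Pa s) used only for Reynolds-number reporting.
    """

    kappa: float = 8.9721e-3   # consistency factor, Pa s^n
    n: float = 0.8601          # power-law index
    tau0: float = 0.0175       # yield shear stress, Pa
    rho: float = 1020.0        # density, kg/m^3
    mu_ref: float = 0.004      # reference Newtonian viscosity, Pa s
    gamma_min: float = 1e-3    # regularization shear rate, 1/s

    def __post_init__(self) -> None:
        if not (self.kappa > 0):
            raise ValueError("kappa must be positive")
        if not (0 < self.n <= 1.5):
            raise ValueError("power-law index n must lie in (0, 1.5]")
        if self.tau0 < 0:
            raise ValueError("yield stress tau0 must be non-negative")
        if not (self.rho > 0):
            raise ValueError("density must be positive")
        if not (self.gamma_min > 0):
            raise ValueError("gamma_min must be positive")

    def newtonian(self, mu: float | None = None) -> "RheologyParams":
        """Return a Newtonian variant (n=1, tau0=0) with viscosity ``mu``."""
        mu = self.mu_ref if mu is None else mu
        return replace(self, kappa=mu, n=1.0, tau0=0.0, mu_ref=mu)


def effective_viscosity(gamma_dot, params: RheologyParams):
    """Regularized Herschel-Bulkley effective viscosity, Pa s.

    ``gamma_dot`` may be a scalar or array of non-negative shear rates (1/s).
    Below ``params.gamma_min`` the value is frozen (bi-viscosity cutoff).
    """
    g = np.asarray(gamma_dot, dtype=float)
    if not np.all(np.isfinite(g)):
        raise ValueError("non-finite shear rate: invalid field state")
    if np.any(g < 0):
        raise ValueError("shear rate must be non-negative")
    gc = np.maximum(g, params.gamma_min)
    eta = params.kappa * gc ** (params.n - 1.0)
    if params.tau0 > 0:
        eta = eta + params.tau0 / gc
    return eta if eta.ndim else float(eta)


def shear_rate(grad_v):
    """Scalar shear rate sqrt(2 e:e) from velocity-gradient tensor(s).

    ``grad_v`` has shape (..., 2, 2) with entries d(v_i)/d(x_j); the scalar
    rate is the second invariant of its symmetric part, which is rotation
    invariant and vanishes for rigid-body motion.
    """
    G = np.asarray(grad_v, dtype=float)
    if G.shape[-2:] != (2, 2):
        raise ValueError("grad_v must have shape (..., 2, 2)")
    if not np.all(np.isfinite(G)):
        raise ValueError("non-finite velocity gradient")
    E = 0.5 * (G + np.swapaxes(G, -1, -2))
    gd = np.sqrt(2.0 * np.einsum("...ij,...ij->...", E, E))
    return gd if gd.ndim else float(gd)


@dataclass
class ChannelFlowSolution:
    """Exact fully developed plane-channel (gap ``h``) HB solution.

    The channel occupies ``|y| <= h/2`` with pressure gradient ``G = -dp/dx``.
    Force balance gives a linear shear-stress profile ``tau(y) = G*y`` with
    wall value ``G*h/2``; material below the yield stress moves as a plug.
    """

    pressure_gradient: float
    gap: float
    params: RheologyParams
    mean_velocity: float
    wall_shear_stress: float
    plug_half_width: float
    profile: Callable[[np.ndarray], np.ndarray] = field(repr=False)

    @property
    def flux(self) -> float:
        return self.mean_velocity * self.gap


def channel_flow_oracle(pressure_gradient: float, gap: float,
                        params: RheologyParams) -> ChannelFlowSolution:
    """Exact plane-Poiseuille solution for a Herschel-Bulkley fluid.

    Returns mean velocity, wall shear stress ``G*h/2`` and a pointwise
    velocity profile sampler.  If the wall shear stress does not exceed the
    yield stress the fluid does not yield and the flow is identically zero.
    """
    if gap <= 0:
        raise ValueError("gap must be positive")
    if pressure_gradient < 0:
        raise ValueError("pressure gradient must be non-negative")
    G, h, k, n, tau0 = (pressure_gradient, gap, params.kappa,
                        params.n, params.tau0)
    half = h / 2.0
    tau_w = G * half

    if tau_w <= tau0 or G == 0.0:
        def zero_profile(y):
            return np.zeros_like(np.asarray(y, dtype=float))
        return ChannelFlowSolution(G, h, params, 0.0,
                                   tau_w if G > 0 else 0.0, half, zero_profile)

    a = 1.0 / n
    y0 = tau0 / G                       # plug half-width

    def u_of_y(yv):
        """Velocity at |y| (integrating gamma_dot = ((G y - tau0)/k)^(1/n))."""
        y = np.abs(np.asarray(yv, dtype=float))
        yy = np.clip(y, y0, half)
        c = k / (G * (a + 1.0))
        u = c * (((G * half - tau0) / k) ** (a + 1.0)
                 - ((G * yy - tau0) / k) ** (a + 1.0))
        return u if u.ndim else float(u)

    # mean over the half channel: plug contribution + yielded-region quadrature
    u_plug = u_of_y(0.0)
    integral, _ = quad(u_of_y, y0, half, epsabs=1e-14, epsrel=1e-12)
    mean_v = (u_plug * y0 + integral) / half
    return ChannelFlowSolution(G, h, params, mean_v, tau_w, y0, u_of_y)


def channel_pressure_gradient_for_mean_velocity(
        mean_velocity: float, gap: float, params: RheologyParams) -> float:
    """Invert the channel oracle: pressure gradient giving the target mean.

    Newtonian closed form seeds a bracketed root-find; exact for n=1, tau0=0.
    """
    if mean_velocity == 0.0:
        return 0.0
    if mean_velocity < 0:
        raise ValueError("mean velocity must be non-negative")
    mu_guess = effective_viscosity(6.0 * mean_velocity / gap, params)
    G0 = 12.0 * mu_guess * mean_velocity / gap ** 2
    if params.n == 1.0 and params.tau0 == 0.0:
        return 12.0 * params.kappa * mean_velocity / gap ** 2

    def f(G):
        return channel_flow_oracle(G, gap, params).mean_velocity - mean_velocity

    lo, hi = G0, G0
    while f(lo) > 0:
        lo /= 2.0
    while f(hi) < 0:
        hi *= 2.0
    return brentq(f, lo, hi, xtol=1e-14 * G0, rtol=1e-14)


def pipe_wall_shear_newtonian(mean_velocity: float, diameter: float,
                              mu: float) -> float:
    """Circular-pipe Newtonian wall shear ``8 mu V / D`` (documentation aid)."""
    return 8.0 * mu * mean_velocity / diameter


def reynolds_number(mean_velocity: float, diameter: float,
                    params: RheologyParams, viscosity: float | None = None) -> float:
    """Reynolds number rho*V*D/mu; ``viscosity`` defaults to ``mu_ref``."""
    mu = params.mu_ref if viscosity is None else viscosity
    if mu <= 0:
        raise ValueError("viscosity must be positive")
    if mean_velocity < 0 or diameter <= 0:
        raise ValueError("mean velocity must be >= 0 and diameter > 0")
    return params.rho * mean_velocity * diameter / mu
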