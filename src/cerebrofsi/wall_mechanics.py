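"""Incompressible neo-Hookean arterial wall: constitutive law and membranes.

The arterial and aneurysm walls are modelled as incompressible neo-Hookean
membranes with strain energy ``W = C1 (I1 - 3)`` (the volumetric term drops in
the exact-incompressibility limit ``D1 = 0``).  Closed-form thin-wall
equilibria for a pressurized tube and a spherical sac act both as oracles and
as physical sanity anchors; the discrete curvilinear membrane solver
(:func:`membrane_wall_update`) is the structural half of the FSI loop.

Conventions: the vessel is axially tethered (axial stretch 1), so a wall
segment deforms in plane strain with principal stretches (lam, 1, 1/lam);
hence I1 = lam^2 + 1 + lam^(-2), membrane tension per unit depth
T(lam) = 2 C1 t0 (lam - lam^-3) and Cauchy hoop stress 2 C1 (lam^2 - lam^-2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.sparse import diags
from scipy.sparse.linalg import spsolve

__all__ = [
    "WallMaterial",
    "MembraneState",
    "strain_energy",
    "uniaxial_nominal_stress",
    "tube_equilibrium",
    "sphere_equilibrium",
    "sphere_limit_point",
    "membrane_wall_update",
]

_LAMBDA_STAR = 7.0 ** (1.0 / 6.0)  # balloon limit-point stretch


@dataclass(frozen=True)
class WallMaterial:
    """Neo-Hookean constants and wall-thickness map.

    ``C1`` is the linear part of the elastic energy (Pa); ``D1`` the
    compressibility parameter (1/Pa) with 0 meaning exactly incompressible.
    Default thicknesses: 125 um for the artery, 27 um for the aneurysm sac.
    """

    C1: float = 166e3
    D1: float = 0.0
    thickness_artery: float = 125e-6
    thickness_sac: float = 27e-6

    def __post_init__(self) -> None:
        if not (self.C1 > 0):
            raise ValueError("C1 must be positive")
        if self.D1 < 0:
            raise ValueError("D1 must be non-negative")
        if not (self.thickness_artery > 0 and self.thickness_sac > 0):
            raise ValueError("thicknesses must be positive")

    @property
    def shear_modulus(self) -> float:
        """Small-strain shear modulus mu = 2 C1."""
        return 2.0 * self.C1


@dataclass(frozen=True)
class MembraneState:
    """Equilibrium state of an inflated thin-walled membrane."""

    stretch: float                 # circumferential stretch lam
    displacement: float            # radial displacement (lam - 1) R0, m
    hoop_stress: float             # Cauchy hoop stress, Pa
    thickness: float               # current thickness t0 / lam, m


def strain_energy(I1, J, mat: WallMaterial):
    """Strain energy density W(I1, J) in J/m^3.

    ``W = C1 (I1 - 3) + (1/D1)(J - 1)^2`` for compressible materials; with
    ``D1 = 0`` the material is exactly incompressible and J must equal 1.
    """
    I1 = np.asarray(I1, dtype=float)
    J = np.asarray(J, dtype=float)
    if np.any(J <= 0):
        raise ValueError("volume ratio J must be positive")
    if np.any(I1 < 3.0 - 1e-12):
        raise ValueError("I1 < 3 is not attainable for isochoric deformation")
    iso = mat.C1 * (I1 - 3.0)
    if mat.D1 == 0.0:
        if np.any(np.abs(J - 1.0) > 1e-12):
            raise ValueError(
                "incompressible material (D1 = 0) requires J = 1")
        W = iso
    else:
        W = iso + (J - 1.0) ** 2 / mat.D1
    return W if W.ndim else float(W)


def uniaxial_nominal_stress(lam, mat: WallMaterial):
    """Nominal (first Piola-Kirchhoff) uniaxial stress 2 C1 (lam - lam^-2)."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch must be positive")
    s = 2.0 * mat.C1 * (lam - lam ** -2)
    return s if s.ndim else float(s)


def tube_equilibrium(transmural_pressure: float, R0: float, t0: float,
                     mat: WallMaterial) -> MembraneState:
    """Inflation of an axially tethered incompressible neo-Hookean tube.

    Solves ``mu (lam^2 - lam^-2) = P lam^2 R0 / t0`` (Laplace balance in the
    deformed configuration, mu = 2 C1), which rearranges to the closed form
    ``lam = (mu / (mu - P R0 / t0))**(1/4)``.  Equilibrium exists only for
    ``P < mu t0 / R0``.
    """
    if R0 <= 0 or t0 <= 0:
        raise ValueError("R0 and t0 must be positive")
    if transmural_pressure < 0:
        raise ValueError("transmural pressure must be non-negative")
    mu = mat.shear_modulus
    P_lim = mu * t0 / R0
    if transmural_pressure >= P_lim:
        raise ValueError(
            f"loss of stability: P = {transmural_pressure:.6g} Pa exceeds the "
            f"tube equilibrium limit mu*t0/R0 = {P_lim:.6g} Pa "
            "(unbounded inflation)")
    lam = (mu / (mu - transmural_pressure * R0 / t0)) ** 0.25
    return MembraneState(
        stretch=lam,
        displacement=(lam - 1.0) * R0,
        hoop_stress=2.0 * mat.C1 * (lam ** 2 - lam ** -2),
        thickness=t0 / lam,
    )


def sphere_pressure(lam, R0: float, t0: float, mat: WallMaterial):
    """Balloon inflation curve P(lam) = 2 mu (t0/R0) (lam^-1 - lam^-7)."""
    lam = np.asarray(lam, dtype=float)
    P = 2.0 * mat.shear_modulus * (t0 / R0) * (lam ** -1.0 - lam ** -7.0)
    return P if P.ndim else float(P)


def sphere_limit_point(R0: float, t0: float, mat: WallMaterial):
    """Limit-point stretch 7**(1/6) and its pressure for the balloon curve."""
    return _LAMBDA_STAR, sphere_pressure(_LAMBDA_STAR, R0, t0, mat)


def sphere_equilibrium(transmural_pressure: float, R0: float, t0: float,
                       mat: WallMaterial) -> MembraneState:
    """Ascending-branch inflation of an incompressible neo-Hookean sphere.

    The classic balloon relation ``P(lam) = 2 mu (t0/R0)(lam^-1 - lam^-7)``
    has a limit point at ``lam* = 7**(1/6)``; only the stable ascending branch
    ``lam <= lam*`` is returned.
    """
    if R0 <= 0 or t0 <= 0:
        raise ValueError("R0 and t0 must be positive")
    if transmural_pressure < 0:
        raise ValueError("transmural pressure must be non-negative")
    lam_star, P_max = sphere_limit_point(R0, t0, mat)
    if transmural_pressure > P_max:
        raise ValueError(
            f"limit point exceeded: P = {transmural_pressure:.6g} Pa is above "
            f"the balloon limit-point pressure P_max = {P_max:.6g} Pa "
            f"(at stretch {lam_star:.4f})")
    if transmural_pressure == 0.0:
        lam = 1.0
    else:
        def f(l):
            return sphere_pressure(l, R0, t0, mat) - transmural_pressure
        lam = brentq(f, 1.0, lam_star, xtol=1e-15, rtol=1e-15)
    # equibiaxial sphere: Cauchy stress from Laplace sigma = P r / (2 t)
    t_cur = t0 / lam ** 2
    sigma = (transmural_pressure * lam * R0 / (2.0 * t_cur)
             if transmural_pressure > 0 else 0.0)
    return MembraneState(stretch=lam, displacement=(lam - 1.0) * R0,
                         hoop_stress=sigma, thickness=t_cur)


# ---------------------------------------------------------------------------
# discrete curvilinear membrane
# ---------------------------------------------------------------------------

def _segment_quantities(x, L0):
    d = x[1:] - x[:-1]
    L = np.sqrt((d * d).sum(axis=1))
    e = d / L[:, None]
    lam = L / L0
    return e, lam


def membrane_wall_update(points, normals, traction, mat: WallMaterial,
                         anchors=None, thickness=None, prestress_tension=None,
                         tol=1e-12, max_iter=200):
    """Equilibrium normal displacement of a 1D membrane along a wall curve.

    Parameters
    ----------
    points : (n, 2) ordered reference positions of the wall nodes.
    normals : (n, 2) unit outward normals; nodes displace along these only.
    traction : (n,) applied normal traction, Pa, positive along the outward
        normal (a transmural pressure pushing the wall outwards is positive).
        When ``prestress_tension`` is given this is the traction *increment*
        relative to the load the prestressed reference state already carries.
    mat : wall material; segment tension is ``T0 + 2 C1 t (lam - lam^-3)``.
    anchors : node indices clamped to zero displacement (default: both ends).
    thickness : per-node reference thickness, m (default ``thickness_artery``).
    prestress_tension : per-segment (n-1,) or scalar pre-tension N/m carried
        by the reference configuration; its nodal force at zero displacement
        is subtracted from the residual, so the reference state is an
        equilibrium of the unperturbed load by construction.

    Returns
    -------
    (n,) normal displacement, m (zero at anchors).

    Notes
    -----
    Nodal equilibrium balances the two adjacent segment tensions against the
    applied normal load (a discrete Young-Laplace balance: tension times
    curvature equals normal traction).  A damped Newton iteration with a
    tridiagonal Jacobian is used; the flat unstressed membrane has a singular
    tangent at zero displacement, so the iteration starts from a small bump
    and falls back to stronger damping when needed.
    """
    X = np.asarray(points, dtype=float)
    N = np.asarray(normals, dtype=float)
    q = np.asarray(traction, dtype=float)
    n = len(X)
    if n < 3:
        raise ValueError("need at least 3 wall nodes")
    if anchors is None:
        anchors = [0, n - 1]
    anchors = np.asarray(sorted(set(int(a) for a in anchors)), dtype=int)
    if anchors.size == 0:
        raise ValueError("anchors must be nonempty (ends are clamped)")
    t0 = np.full(n, mat.thickness_artery) if thickness is None \
        else np.asarray(thickness, dtype=float)
    t_seg = 0.5 * (t0[1:] + t0[:-1])
    L0 = np.sqrt(((X[1:] - X[:-1]) ** 2).sum(axis=1))
    l0 = np.zeros(n)                       # nodal control lengths
    l0[:-1] += 0.5 * L0
    l0[1:] += 0.5 * L0
    if prestress_tension is None:
        T0 = np.zeros(n - 1)
    else:
        T0 = np.broadcast_to(np.asarray(prestress_tension, dtype=float),
                             (n - 1,)).copy()

    free = np.setdiff1d(np.arange(n), anchors)

    # orientation of the outward edge normal rot(d) = s*(d_y, -d_x): choose
    # the sign that aligns with the supplied nodal normals
    d_ref = X[1:] - X[:-1]
    rot_ref = np.stack([d_ref[:, 1], -d_ref[:, 0]], axis=1)
    n_seg = 0.5 * (N[1:] + N[:-1])
    rot_sign = 1.0 if (rot_ref * n_seg).sum() >= 0 else -1.0

    def nodal_internal_force(w):
        x = X + w[:, None] * N
        e, lam = _segment_quantities(x, L0)
        T = T0 + 2.0 * mat.C1 * t_seg * (lam - lam ** -3.0)
        F = np.zeros((n, 2))
        F[:-1] += T[:, None] * e           # pull of segment j on node j
        F[1:] -= T[:, None] * e            # reaction on node j+1
        return F

    def load_force(w):
        # follower pressure load: q per unit *deformed* length, acting along
        # the deformed outward edge normals (exact for uniform inflation)
        x = X + w[:, None] * N
        d = x[1:] - x[:-1]
        rot = rot_sign * np.stack([d[:, 1], -d[:, 0]], axis=1)
        F = np.zeros((n, 2))
        F[:-1] += 0.5 * q[:-1, None] * rot
        F[1:] += 0.5 * q[1:, None] * rot
        return F

    F_ref = nodal_internal_force(np.zeros(n))

    def residual(w):
        F = nodal_internal_force(w) - F_ref + load_force(w)
        R = (F * N).sum(axis=1)
        R[anchors] = 0.0
        return R

    def jacobian(w):
        # tridiagonal structure: FD with three colorings
        eps = 1e-9 * max(1.0, np.abs(w).max()) + 1e-12
        R0_ = residual(w)
        main = np.zeros(n)
        lower = np.zeros(n - 1)
        upper = np.zeros(n - 1)
        for color in range(3):
            idx = np.arange(color, n, 3)
            wp = w.copy()
            wp[idx] += eps
            dR = (residual(wp) - R0_) / eps
            for i in idx:
                main[i] = dR[i]
                if i > 0:
                    upper[i - 1] = dR[i - 1]
                if i < n - 1:
                    lower[i] = dR[i + 1]
        main[anchors] = 1.0
        for a in anchors:
            if a > 0:
                lower[a - 1] = 0.0
            if a < n - 1:
                upper[a] = 0.0
        return diags([lower, main, upper], [-1, 0, 1], format="csc")

    if np.abs(q).max() < 1e-4:
        # zero or numerically negligible load: 1e-4 Pa displaces the wall by
        # well under an angstrom, far below the coupling tolerance, and a
        # relative residual is meaningless against round-off-level loads
        return np.zeros(n)
    scale = max(float(np.abs(q * l0).max()), 1e-30)

    def finish(w):
        w = w.copy()
        w[anchors] = 0.0
        return w

    w = np.zeros(n)
    if np.all(T0 == 0.0):
        # break the flat-membrane singularity with a small load-aligned bump
        span = L0.sum()
        s = np.concatenate([[0.0], np.cumsum(L0)]) / span
        sign = np.sign(q[free] @ l0[free]) or 1.0
        w = 1e-3 * span * sign * np.sin(np.pi * s)
        w[anchors] = 0.0

    R = residual(w)
    best = np.linalg.norm(R)
    best_w = w.copy()
    no_improve = 0
    for _ in range(max_iter):
        if np.linalg.norm(R) / scale < tol and np.abs(R).max() / scale < tol:
            return finish(w)
        J = jacobian(w)
        try:
            dw = spsolve(J, -R)
        except Exception as exc:   # pragma: no cover - singular fallback
            raise RuntimeError(
                f"membrane Newton failed: {exc}; residual {best:.3e}") from exc
        if not np.all(np.isfinite(dw)):
            raise RuntimeError(
                f"membrane Newton diverged (non-finite step); "
                f"residual norm {best:.3e}")
        alpha = 1.0
        for _ls in range(40):
            w_try = w + alpha * dw
            R_try = residual(w_try)
            if np.linalg.norm(R_try) < (1.0 - 1e-4 * alpha) * np.linalg.norm(R):
                break
            alpha *= 0.5
        else:
            # stagnation: accept a tiny damped step to escape plateaus
            w_try = w + 1e-3 * dw
            R_try = residual(w_try)
        w, R = w_try, R_try
        rn = np.linalg.norm(R)
        if rn < 0.99 * best:
            best, best_w, no_improve = rn, w.copy(), 0
        else:
            no_improve += 1
        # stagnation at the floating-point noise floor (e.g. the rigid
        # limit, where tension differences cancel catastrophically):
        # accept once the residual is far below the load scale
        if no_improve >= 8 and best / scale < 1e-4:
            return finish(best_w)
    if np.linalg.norm(R) / scale < 1e-4:
        return finish(w)
    raise RuntimeError(
        f"membrane Newton did not converge: residual norm {np.linalg.norm(R):.3e} "
        f"(relative {np.linalg.norm(R) / scale:.3e})")
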