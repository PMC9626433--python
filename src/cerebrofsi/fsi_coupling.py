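"""Partitioned fluid-wall coupling with quasi-static mesh morphing.

The steady flow problem and the membrane wall problem are solved
alternately, exchanging traction and displacement at the luminal interface
(no-slip and traction compatibility), with Aitken dynamic under-relaxation
of the interface displacement until the update drops below tolerance.

Prestress convention.  In vivo the imaged geometry is already loaded: a
16 kPa luminal pressure acting on the stress-free sac would exceed its
balloon limit point, so small reported displacements are only consistent
with perturbations about a prestressed state.  With ``prestress=True``
(default) the reference geometry is taken to be the equilibrium under the
uniform reference pressure (``FlowBCs.inlet_reference_pressure``); the wall
carries the corresponding Laplace pre-tension ``T0 = (p_ref - p_ext) R_eff``
and responds only to the *anomaly* of the flow-induced load (local pressure
and viscous traction relative to the inlet mean).  Displacements are
therefore reported relative to that in-vivo datum.  With
``prestress=False`` the wall is stress-free in the reference configuration
and the full transmural load is applied (useful for oracle checks on
channels; the sac has no such equilibrium at 16 kPa).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import splu

from .flow_solver import (FlowBCs, FlowField, SolverSettings,
                          solve_steady_flow, _element_geometry)
from .hemodynamics_post import recover_gradients
from .rheology import RheologyParams, effective_viscosity
from .scenario_geometry import INLET, WALL, Mesh
from .wall_mechanics import WallMaterial, membrane_wall_update

__all__ = [
    "CouplingSettings", "CouplingState", "InterfaceTraction",
    "interface_traction", "aitken_factor", "morph_mesh", "solve_fsi",
    "FSIError",
]


class FSIError(RuntimeError):
    """Coupling failure; carries the interface increment history."""

    def __init__(self, message, history=None):
        super().__init__(message)
        self.history = list(history or [])


@dataclass(frozen=True)
class CouplingSettings:
    """Outer-loop controls of the partitioned coupling."""

    max_outer_iters: int = 50
    interface_tol: float = 1e-7          # m, max displacement increment
    relaxation: str = "aitken"           # "aitken" or "fixed"
    relaxation_factor: float = 0.5
    relaxation_clamp: tuple = (0.1, 1.0)
    prestress: bool = True
    external_pressure: float = 0.0       # perivascular pressure, Pa

    def __post_init__(self) -> None:
        if self.interface_tol <= 0:
            raise ValueError("interface tolerance must be positive")
        lo, hi = self.relaxation_clamp
        if not (0 < lo <= self.relaxation_factor <= hi <= 1.0):
            raise ValueError("relaxation factor must lie within its clamp")
        if self.relaxation not in ("aitken", "fixed"):
            raise ValueError("relaxation must be 'aitken' or 'fixed'")


@dataclass
class CouplingState:
    """Diagnostics of the outer fixed-point iteration."""

    iterations: int = 0
    converged: bool = False
    increment_norms: list = field(default_factory=list)   # max |dw| per iter
    relaxation_factors: list = field(default_factory=list)
    displacement_history: list = field(default_factory=list)
    wall_node_ids: Optional[np.ndarray] = None
    interface_displacement: Optional[np.ndarray] = None   # (k,) normal, m
    interface_traction: Optional[np.ndarray] = None       # (k,) normal, Pa


@dataclass
class InterfaceTraction:
    """Fluid traction at wall nodes, outward-from-lumen normal convention.

    ``traction`` is the full stress vector ``(-p I + 2 eta e) . n`` the blood
    exerts on the wall; ``normal_push`` is its outward-pushing normal scalar
    (positive when the lumen pressure inflates the vessel) and ``tangential``
    the in-plane (WSS) vector.
    """

    node_ids: np.ndarray
    traction: np.ndarray          # (k, 2) Pa
    normal_push: np.ndarray       # (k,) Pa
    tangential: np.ndarray        # (k, 2) Pa
    normals: np.ndarray           # (k, 2) outward unit normals


def interface_traction(flow: FlowField, mesh: Mesh,
                       params: RheologyParams) -> InterfaceTraction:
    """Full fluid traction ``(-p I + 2 eta e) . n`` at every wall node."""
    normals_map = mesh.boundary_node_normals()
    ids = mesh.wall_nodes
    for i in ids:
        if int(i) not in normals_map:
            raise ValueError(f"wall node {i} has no boundary normal")
    n = np.asarray([normals_map[int(i)] for i in ids])
    if not np.all(np.isfinite(n)):
        raise ValueError("degenerate boundary edge: undefined normal")
    grads = recover_gradients(mesh, flow.velocity, ids)
    E = 0.5 * (grads + grads.transpose(0, 2, 1))
    gamma = np.sqrt(2.0 * np.einsum("kij,kij->k", E, E))
    eta = np.asarray(effective_viscosity(gamma, params))
    t = -flow.pressure[ids, None] * n \
        + 2.0 * eta[:, None] * np.einsum("kij,kj->ki", E, n)
    t_nn = np.einsum("ki,ki->k", t, n)
    tang = t - t_nn[:, None] * n
    return InterfaceTraction(node_ids=ids, traction=t, normal_push=-t_nn,
                             tangential=tang, normals=n)


def aitken_factor(increments, prev_factor: float = 0.5,
                  clamp: tuple = (0.1, 1.0), initial: float = 0.5) -> float:
    """Classical Aitken dynamic relaxation update, clamped.

    ``increments`` is the history of interface displacement increments (the
    unrelaxed residuals); at least two are needed, otherwise the initial
    factor is returned.
    """
    if len(increments) < 2:
        return float(np.clip(initial, *clamp))
    r_new = np.asarray(increments[-1], dtype=float)
    r_old = np.asarray(increments[-2], dtype=float)
    diff = r_new - r_old
    denom = float(diff @ diff)
    if denom <= 0.0 or not np.isfinite(denom):
        return float(np.clip(prev_factor, *clamp))
    factor = -prev_factor * float(r_old @ diff) / denom
    if not np.isfinite(factor):
        factor = initial
    return float(np.clip(factor, *clamp))


# ---------------------------------------------------------------------------
# mesh morphing
# ---------------------------------------------------------------------------

def _laplacian_factor(mesh: Mesh):
    """Factorized P1 Laplacian with Dirichlet rows on all boundary nodes."""
    b, A = _element_geometry(mesh)
    tri = mesh.triangles
    n = len(mesh.points)
    bb = np.einsum("eid,ejd->eij", b, b) * A[:, None, None]
    I = tri[:, :, None].repeat(3, axis=2).ravel()
    J = tri[:, None, :].repeat(3, axis=1).ravel()
    K = coo_matrix((bb.ravel(), (I, J)), shape=(n, n)).tolil()
    bnodes = np.unique(mesh.boundary_edges)
    K[bnodes, :] = 0.0
    K[bnodes, bnodes] = 1.0
    return splu(K.tocsc()), bnodes


def morph_mesh(mesh: Mesh, wall_displacement: dict | np.ndarray,
               lap=None) -> Mesh:
    """Move wall nodes by their normal displacement; relax the interior.

    ``wall_displacement`` maps wall node id -> scalar normal displacement
    (or is a dense per-node array).  Interior nodes follow by harmonic
    extension (Laplacian smoothing as a boundary-value problem); inlet and
    outlet nodes stay fixed.  Raises if an element inverts or a displacement
    exceeds 10% of the local channel width.
    """
    normals_map = mesh.boundary_node_normals()
    n = len(mesh.points)
    disp_b = np.zeros((n, 2))
    reff = mesh.wall_node_values(mesh.edge_r_eff)
    if isinstance(wall_displacement, dict):
        items = wall_displacement.items()
    else:
        wd = np.asarray(wall_displacement, dtype=float)
        items = ((int(i), wd[int(i)]) for i in mesh.wall_nodes)
    for i, w in items:
        if abs(w) > 0.2 * reff.get(i, np.inf):
            raise ValueError(
                f"wall displacement {w:.3e} m at node {i} exceeds 10% of the "
                "local channel width; quasi-static morphing is invalid")
        disp_b[i] = w * normals_map[i]
    if lap is None:
        lap = _laplacian_factor(mesh)
    lu, bnodes = lap
    rhs = np.zeros((n, 2))
    rhs[bnodes] = disp_b[bnodes]
    disp = np.stack([lu.solve(rhs[:, 0]), lu.solve(rhs[:, 1])], axis=1)
    new = Mesh(points=mesh.points + disp, triangles=mesh.triangles.copy(),
               boundary_edges=mesh.boundary_edges.copy(),
               edge_tags=mesh.edge_tags.copy(),
               edge_thickness=mesh.edge_thickness.copy(),
               edge_r_eff=mesh.edge_r_eff.copy(),
               target_points=dict(mesh.target_points), spec=mesh.spec,
               build_args=dict(mesh.build_args),
               channel_info=mesh.channel_info)
    if np.any(new.triangle_areas() <= 0):
        raise ValueError("mesh morphing inverted an element")
    return new


# ---------------------------------------------------------------------------
# coupled solve
# ---------------------------------------------------------------------------

def _wall_load_anomaly(flow: FlowField, mesh: Mesh, tr: InterfaceTraction,
                       cset: CouplingSettings, bcs: FlowBCs) -> np.ndarray:
    """Normal wall load the membrane must respond to, per wall node."""
    if cset.prestress:
        inlet_nodes = mesh.nodes_of(INLET)
        p_mean = float(flow.pressure[inlet_nodes].mean())
        return tr.normal_push - p_mean
    return tr.normal_push - cset.external_pressure


def solve_fsi(mesh: Mesh, params: RheologyParams, mat: WallMaterial,
              bcs: FlowBCs | None = None,
              cset: CouplingSettings | None = None,
              settings: SolverSettings | None = None,
              inlet_scale: float = 1.0,
              initial_flow: FlowField | None = None):
    """Partitioned steady FSI on the reference mesh.

    Loop: solve flow -> extract interface traction -> membrane update ->
    under-relax -> morph mesh, until the maximum interface displacement
    increment is below ``cset.interface_tol``.  Returns
    ``(flow, displacement, state)`` where ``displacement`` is the (n, 2)
    nodal displacement field of the final morphed configuration relative to
    the reference mesh (the prestressed in-vivo datum when
    ``cset.prestress``), and ``state`` the coupling diagnostics.
    """
    bcs = bcs or FlowBCs()
    cset = cset or CouplingSettings()
    settings = settings or SolverSettings()

    chains = [c for c in mesh.wall_chains() if len(c) >= 3]
    normals_map = mesh.boundary_node_normals()
    thick_map = mesh.wall_node_values(mesh.edge_thickness)
    reff_map = mesh.wall_node_values(mesh.edge_r_eff)
    wall_ids = mesh.wall_nodes
    pos = {int(i): k for k, i in enumerate(wall_ids)}

    # per-chain static data
    chain_data = []
    p_pre = (bcs.inlet_reference_pressure - cset.external_pressure) \
        if cset.prestress else 0.0
    for chain in chains:
        pts = mesh.points[chain]
        nrm = np.asarray([normals_map[int(i)] for i in chain])
        th = np.asarray([thick_map[int(i)] for i in chain])
        re_n = np.asarray([reff_map[int(i)] for i in chain])
        T0 = p_pre * 0.5 * (re_n[1:] + re_n[:-1]) if cset.prestress else None
        chain_data.append((chain, pts, nrm, th, T0))

    lap = _laplacian_factor(mesh)
    w = np.zeros(len(wall_ids))          # normal displacement per wall node
    state = CouplingState(wall_node_ids=wall_ids)
    flow = initial_flow
    mesh_k = mesh
    relax = cset.relaxation_factor
    increments = []

    for it in range(1, cset.max_outer_iters + 1):
        flow = solve_steady_flow(mesh_k, params, bcs, settings,
                                 initial_state=flow, inlet_scale=inlet_scale)
        tr = interface_traction(flow, mesh_k, params)
        dq_all = _wall_load_anomaly(flow, mesh_k, tr, cset, bcs)
        dq = {int(i): q for i, q in zip(tr.node_ids, dq_all)}

        w_new = np.zeros_like(w)
        for chain, pts, nrm, th, T0 in chain_data:
            q = np.asarray([dq[int(i)] for i in chain])
            try:
                wc = membrane_wall_update(pts, nrm, q, mat,
                                          anchors=[0, len(chain) - 1],
                                          thickness=th, prestress_tension=T0)
            except RuntimeError as exc:
                raise FSIError(f"membrane solve failed at outer iteration "
                               f"{it}: {exc}", state.increment_norms) from exc
            for i, wi in zip(chain, wc):
                w_new[pos[int(i)]] = wi

        dw = w_new - w
        increments.append(dw.copy())
        state.increment_norms.append(float(np.abs(dw).max()))
        if cset.relaxation == "aitken":
            relax = aitken_factor(increments, prev_factor=relax,
                                  clamp=cset.relaxation_clamp,
                                  initial=cset.relaxation_factor)
        else:
            relax = cset.relaxation_factor if it > 1 else 1.0
        state.relaxation_factors.append(relax)
        w = w + relax * dw
        state.displacement_history.append(w.copy())
        state.iterations = it

        if state.increment_norms[-1] < cset.interface_tol:
            state.converged = True
            break
        try:
            mesh_k = morph_mesh(mesh, {int(i): wi
                                       for i, wi in zip(wall_ids, w)}, lap)
        except ValueError as exc:
            raise FSIError(f"mesh morphing failed at outer iteration {it}: "
                           f"{exc}", state.increment_norms) from exc

    if not state.converged:
        raise FSIError(
            f"FSI outer loop did not converge in {cset.max_outer_iters} "
            f"iterations (last increment "
            f"{state.increment_norms[-1]:.3e} m)", state.increment_norms)

    # final morph so the reported field matches the converged interface state
    mesh_k = morph_mesh(mesh, {int(i): wi for i, wi in zip(wall_ids, w)}, lap)
    tr = interface_traction(flow, mesh_k, params)
    state.interface_displacement = w
    state.interface_traction = tr.normal_push
    displacement = mesh_k.points - mesh.points
    return flow, displacement, state
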