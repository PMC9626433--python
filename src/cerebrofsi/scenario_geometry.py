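"""Parametric 2D midplane geometries and meshes for the three study scenarios.

This module is the study's data generator.  It builds planar midplane
outlines of an intracranial arterial bifurcation in three configurations --
INTACT (healthy), ICAS (occluded by atherosclerotic stenoses) and ACA (the
same bifurcation carrying a saccular aneurysm at the flow divider) -- and
meshes them with linear triangles.  Defaults are the study conditions:
parent diameter 3.2 mm, daughter diameters 2 mm, sac radius 2.5 mm, wall
thickness 125 um (artery) / 27 um (sac).

Coordinates are SI meters.  The flow-divider apex sits at the origin and the
parent artery runs along -x; the daughters leave the centerline junction at
+/- the bifurcation half-angle (default 50 deg, typical of intracranial
bifurcations).  Boundary edges are tagged INLET, OUTLET_1, OUTLET_2 or WALL;
wall edges carry a thickness and a local effective radius (half-width of the
channel, or the sac radius), the latter used for membrane prestress.

Geometry is fully deterministic for a given spec; the ``seed`` field is part
of the determinism contract and is threaded through unchanged.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

import numpy as np
import shapely
from scipy.spatial import Delaunay
from shapely.geometry import Polygon

__all__ = [
    "Scenario", "Branch", "WallSide", "StenosisSpec", "ScenarioSpec",
    "Mesh", "build_scenario", "build_channel", "stenosis_profile",
    "target_points", "refine", "default_spec", "build_annulus_channel",
    "INLET", "OUTLET_1", "OUTLET_2", "WALL",
]

INLET = "INLET"
OUTLET_1 = "OUTLET_1"
OUTLET_2 = "OUTLET_2"
WALL = "WALL"


class Scenario(str, Enum):
    INTACT = "intact"
    ICAS = "icas"
    ACA = "aca"


class Branch(str, Enum):
    PARENT = "parent"
    DAUGHTER_1 = "daughter_1"   # upper daughter (+half-angle)
    DAUGHTER_2 = "daughter_2"   # lower daughter (-half-angle)


class WallSide(str, Enum):
    WALL_A = "wall_a"   # upper parent wall / outer daughter wall
    WALL_B = "wall_b"   # lower parent wall / inner daughter wall


@dataclass(frozen=True)
class StenosisSpec:
    """One atherosclerotic plaque, shaped as a C1 cosine bump.

    ``center_offset`` is measured along the branch centerline from the
    centerline junction point; ``degree`` is the fraction of the local
    channel width occluded.  ``side=None`` (default) splits the bump
    symmetrically between the two walls, so the throat width is
    ``(1 - degree) * width``; WALL_A/WALL_B applies the per-wall inset on one
    side only.
    """

    branch: Branch = Branch.PARENT
    center_offset: float = 4.8e-3
    length: float = 1.6e-3
    degree: float = 0.5
    side: Optional[WallSide] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.degree < 1.0):
            raise ValueError("stenosis degree must lie in [0, 1)")
        if self.length <= 0:
            raise ValueError("stenosis length must be positive")


def _default_stenoses() -> tuple:
    return (
        StenosisSpec(Branch.PARENT, 4.8e-3, 1.6e-3, 0.5),
        StenosisSpec(Branch.DAUGHTER_1, 3.0e-3, 1.6e-3, 0.5),
        StenosisSpec(Branch.DAUGHTER_2, 3.0e-3, 1.6e-3, 0.5),
    )


@dataclass(frozen=True)
class ScenarioSpec:
    """Full parametric description of one scenario geometry (SI units)."""

    scenario: Scenario = Scenario.INTACT
    parent_diameter: float = 3.2e-3
    daughter_diameter: float = 2.0e-3
    bifurcation_half_angle: float = 50.0     # degrees
    parent_length: float = 12e-3
    daughter_length: float = 10e-3
    stenoses: tuple = ()
    sac_radius: float = 2.5e-3
    sac_neck_width: float = 2.2e-3
    mesh_size: float = 2.0e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.parent_diameter <= 0 or self.daughter_diameter <= 0:
            raise ValueError("diameters must be positive")
        if not (0 < self.bifurcation_half_angle < 90):
            raise ValueError("bifurcation half angle must lie in (0, 90) deg")
        if self.mesh_size <= 0:
            raise ValueError("mesh size must be positive")
        if self.scenario == Scenario.INTACT and self.stenoses:
            raise ValueError("INTACT scenario carries no stenoses")
        if self.scenario == Scenario.ICAS and len(self.stenoses) < 1:
            raise ValueError("ICAS scenario requires at least one stenosis")
        if self.scenario == Scenario.ACA and not (self.sac_radius > 0):
            raise ValueError("ACA scenario requires a positive sac radius")
        if (self.scenario == Scenario.ACA
                and self.sac_neck_width >= 2 * self.sac_radius):
            raise ValueError("sac neck must be narrower than the sac diameter")


def default_spec(scenario: Scenario | str, **overrides) -> ScenarioSpec:
    """The study's default configuration for a scenario.

    INTACT has no plaques; ICAS carries three degree-0.5 stenoses (one in the
    parent 4.8 mm upstream of the junction, one per daughter 3 mm
    downstream); ACA is the stenosed artery plus the saccular aneurysm.
    """
    scenario = Scenario(scenario)
    stenoses: tuple = ()
    if scenario in (Scenario.ICAS, Scenario.ACA):
        stenoses = _default_stenoses()
    return ScenarioSpec(scenario=scenario, stenoses=stenoses, **overrides)


def stenosis_profile(s, sten: StenosisSpec, width: float):
    """Per-wall inset of the cosine plaque bump at centerline coordinate s.

    ``inset(s) = (degree*width/2) * (1 + cos(2 pi (s - c)/L)) / 2`` for
    ``|s - c| <= L/2`` and zero outside; value and slope vanish at the bump
    ends (C1 continuity).  The bump integral is ``degree*width*L/4``.
    """
    s = np.asarray(s, dtype=float)
    amp = sten.degree * width / 2.0
    x = s - sten.center_offset
    out = np.where(np.abs(x) <= sten.length / 2.0,
                   amp * (1.0 + np.cos(2.0 * np.pi * x / sten.length)) / 2.0,
                   0.0)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# mesh container
# ---------------------------------------------------------------------------

@dataclass
class Mesh:
    """Tagged 2D triangular mesh.

    ``boundary_edges[k] = (i, j)`` runs counter-clockwise around the domain
    (interior on the left of i->j), so the outward normal of an edge with
    direction d is (d_y, -d_x).  Node indices are 0-based; all triangles have
    positive signed area.
    """

    points: np.ndarray               # (n, 2)
    triangles: np.ndarray            # (m, 3)
    boundary_edges: np.ndarray       # (b, 2)
    edge_tags: np.ndarray            # (b,) str
    edge_thickness: np.ndarray       # (b,) m
    edge_r_eff: np.ndarray           # (b,) m
    target_points: dict = field(default_factory=dict)
    spec: Optional[ScenarioSpec] = None
    build_args: dict = field(default_factory=dict)
    channel_info: Optional[dict] = None

    def triangle_areas(self) -> np.ndarray:
        p, t = self.points, self.triangles
        d1 = p[t[:, 1]] - p[t[:, 0]]
        d2 = p[t[:, 2]] - p[t[:, 0]]
        return 0.5 * (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])

    def edge_lengths(self, edges=None) -> np.ndarray:
        e = self.boundary_edges if edges is None else np.asarray(edges)
        d = self.points[e[:, 1]] - self.points[e[:, 0]]
        return np.sqrt((d * d).sum(axis=1))

    def edges_of(self, tag: str) -> np.ndarray:
        return self.boundary_edges[self.edge_tags == tag]

    def nodes_of(self, tag: str) -> np.ndarray:
        return np.unique(self.edges_of(tag))

    @property
    def wall_nodes(self) -> np.ndarray:
        return self.nodes_of(WALL)

    def wall_chains(self) -> list:
        """Maximal runs of consecutive WALL edges as ordered node-id arrays."""
        b = len(self.boundary_edges)
        is_wall = self.edge_tags == WALL
        if is_wall.all():
            loop = list(self.boundary_edges[:, 0])
            return [np.asarray(loop + [loop[0]])]
        start = int(np.argmin(is_wall))
        order = np.r_[start:b, 0:start]
        chains, current = [], []
        for k in order:
            if is_wall[k]:
                if not current:
                    current = [self.boundary_edges[k, 0]]
                current.append(self.boundary_edges[k, 1])
            elif current:
                chains.append(np.asarray(current))
                current = []
        if current:
            chains.append(np.asarray(current))
        return chains

    def boundary_node_normals(self) -> dict:
        """Outward unit normal per boundary node (mean of adjacent edges)."""
        acc: dict = {}
        p = self.points
        for (i, j) in self.boundary_edges:
            d = p[j] - p[i]
            nrm = np.array([d[1], -d[0]])
            nrm = nrm / np.linalg.norm(nrm)
            for k in (int(i), int(j)):
                acc.setdefault(k, np.zeros(2))
                acc[k] += nrm
        return {k: v / np.linalg.norm(v) for k, v in acc.items()}

    def wall_node_values(self, edge_values) -> dict:
        """Average a per-boundary-edge quantity onto wall nodes."""
        out: dict = {}
        cnt: dict = {}
        for (i, j), tag, v in zip(self.boundary_edges, self.edge_tags,
                                  edge_values):
            if tag != WALL:
                continue
            for k in (int(i), int(j)):
                out[k] = out.get(k, 0.0) + v
                cnt[k] = cnt.get(k, 0) + 1
        return {k: out[k] / cnt[k] for k in out}

    def validate(self) -> None:
        areas = self.triangle_areas()
        if np.any(areas <= 0):
            raise ValueError("mesh contains non-positive triangle areas")
        if not np.array_equal(self.boundary_edges[1:, 0],
                              self.boundary_edges[:-1, 1]) or \
                self.boundary_edges[-1, 1] != self.boundary_edges[0, 0]:
            raise ValueError("boundary edges do not form a closed loop")

    # -- I/O ---------------------------------------------------------------
    def to_vtk(self, point_data: dict | None = None,
               cell_data: dict | None = None) -> str:
        """Serialize mesh (and optional fields) as VTK legacy ASCII text."""
        lines = ["# vtk DataFile Version 3.0", "cerebrofsi mesh", "ASCII",
                 "DATASET UNSTRUCTURED_GRID",
                 f"POINTS {len(self.points)} double"]
        lines += [f"{x:.17g} {y:.17g} 0" for x, y in self.points]
        m = len(self.triangles)
        lines.append(f"CELLS {m} {4 * m}")
        lines += [f"3 {a} {b} {c}" for a, b, c in self.triangles]
        lines.append(f"CELL_TYPES {m}")
        lines += ["5"] * m

        def emit(block: dict, count: int, header: str):
            out = [f"{header} {count}"]
            for name, arr in block.items():
                arr = np.asarray(arr, dtype=float)
                if arr.ndim == 1:
                    out.append(f"SCALARS {name} double 1")
                    out.append("LOOKUP_TABLE default")
                    out += [f"{v:.17g}" for v in arr]
                else:
                    out.append(f"VECTORS {name} double")
                    out += [f"{v[0]:.17g} {v[1]:.17g} 0" for v in arr]
            return out

        if point_data:
            lines += emit(point_data, len(self.points), "POINT_DATA")
        if cell_data:
            lines += emit(cell_data, m, "CELL_DATA")
        return "\n".join(lines) + "\n"

    def write(self, path_prefix: str, point_data: dict | None = None) -> None:
        """Write ``<prefix>.vtk`` plus a JSON sidecar with tags and targets."""
        with open(f"{path_prefix}.vtk", "w") as fh:
            fh.write(self.to_vtk(point_data=point_data))
        sidecar = {
            "boundary_edges": np.asarray(self.boundary_edges).tolist(),
            "edge_tags": list(self.edge_tags),
            "edge_thickness": np.asarray(self.edge_thickness).tolist(),
            "edge_r_eff": np.asarray(self.edge_r_eff).tolist(),
            "target_points": {k: int(v) for k, v in self.target_points.items()},
        }
        with open(f"{path_prefix}.json", "w") as fh:
            json.dump(sidecar, fh, indent=1)

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_vtk().encode()).hexdigest()


# ---------------------------------------------------------------------------
# boundary outline
# ---------------------------------------------------------------------------

class _Loop:
    """Accumulates sampled boundary pieces into a closed CCW loop."""

    def __init__(self):
        self.pts: list = []
        self.reff: list = []
        self.sac_dist: list = []     # chain distance into the sac, inf outside
        self.arrive_tag: list = []   # tag of the edge arriving at pts[k]

    def add(self, pts, tag, reff, sac_dist=None):
        pts = np.asarray(pts, dtype=float)
        npts = len(pts)
        reff = np.broadcast_to(np.asarray(reff, dtype=float), (npts,))
        if sac_dist is None:
            sac_dist = np.full(npts, np.inf)
        start = 0
        if self.pts and np.allclose(self.pts[-1], pts[0], atol=1e-14):
            start = 1
            # a sac entry point overrides the artery marker of the joint
            self.sac_dist[-1] = min(self.sac_dist[-1], sac_dist[0])
        for k in range(start, npts):
            self.pts.append(pts[k])
            self.reff.append(float(reff[k]))
            self.sac_dist.append(float(sac_dist[k]))
            self.arrive_tag.append(tag)

    def finish(self):
        pts = np.asarray(self.pts)
        if not np.allclose(pts[0], pts[-1], atol=1e-14):
            raise ValueError("boundary loop failed to close")
        pts = pts[:-1]
        reff = np.asarray(self.reff[:-1])
        sac = np.asarray(self.sac_dist[:-1])
        # edge k joins point k to k+1 (mod n); its tag is the tag of the edge
        # arriving at point k+1, with the closing edge arriving at point 0
        tags = np.asarray(self.arrive_tag[1:], dtype=object)
        return pts, tags, reff, sac


def _sample_line(p0, p1, h):
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    n = max(1, int(round(np.linalg.norm(p1 - p0) / h)))
    t = np.linspace(0.0, 1.0, n + 1)
    return p0[None, :] + t[:, None] * (p1 - p0)[None, :]


def _mirror(p):
    return np.asarray(p, float) * np.array([1.0, -1.0])


def _geometry_frame(spec: ScenarioSpec) -> dict:
    """Anchor points of the outline, shared by builder and target lookup."""
    th = np.deg2rad(spec.bifurcation_half_angle)
    c, s = np.cos(th), np.sin(th)
    hp = spec.parent_diameter / 2.0
    hd = spec.daughter_diameter / 2.0
    u1 = np.array([c, s])
    n1 = np.array([-s, c])
    J = np.array([-hd / s, 0.0])
    t_corner = (hp - hd * c) / s
    C_up = J + hd * n1 + t_corner * u1
    O1 = J + spec.daughter_length * u1
    frame = dict(c=c, s=s, hp=hp, hd=hd, u1=u1, n1=n1, J=J,
                 t_corner=t_corner, C_up=C_up,
                 E1o=O1 + hd * n1, E1i=O1 - hd * n1,
                 x_in=J[0] - spec.parent_length,
                 apex=np.array([0.0, 0.0]))
    if spec.scenario == Scenario.ACA:
        R = spec.sac_radius
        half_neck = spec.sac_neck_width / 2.0
        P1 = (half_neck / s) * u1
        chord_off = np.sqrt(R ** 2 - half_neck ** 2)
        margin = max(5e-5, 0.25 * spec.mesh_size)
        Ox = max(P1[0] + 1e-4 + chord_off, (R + margin) / s)
        frame.update(R=R, half_neck=half_neck, P1=P1,
                     chord_off=chord_off, Ox=Ox,
                     A1=np.array([Ox - chord_off, half_neck]),
                     sac_center=np.array([Ox, 0.0]),
                     sac_vertex=np.array([Ox + R, 0.0]))
    return frame


def _validate_stenoses(spec: ScenarioSpec, fr: dict) -> None:
    for st in spec.stenoses:
        if st.branch == Branch.PARENT:
            lo, hi = max(0.0, fr["J"][0] - fr["C_up"][0]), spec.parent_length
        else:
            lo, hi = fr["t_corner"], spec.daughter_length
        if st.center_offset - st.length / 2 < lo or \
                st.center_offset + st.length / 2 > hi - spec.mesh_size:
            raise ValueError(
                f"stenosis on {st.branch.value} (center {st.center_offset:g}, "
                f"length {st.length:g}) does not lie fully inside its branch "
                f"range [{lo:.4g}, {hi:.4g}]")
        per_wall = st.degree if st.side is not None else st.degree / 2.0
        if per_wall >= 0.5:
            raise ValueError(
                "stenosis would close the channel (one-sided degree too high)")


def _outline(spec: ScenarioSpec):
    fr = _geometry_frame(spec)
    _validate_stenoses(spec, fr)
    h = spec.mesh_size
    c, s = fr["c"], fr["s"]
    hp, hd = fr["hp"], fr["hd"]
    u1, n1, J = fr["u1"], fr["n1"], fr["J"]
    u2 = _mirror(u1)
    apex, C_up, E1o, E1i = fr["apex"], fr["C_up"], fr["E1o"], fr["E1i"]
    C_dn, E2o, E2i = _mirror(C_up), _mirror(E1o), _mirror(E1i)
    x_in = fr["x_in"]

    def s_coord(pts, branch):
        if branch == Branch.PARENT:
            return J[0] - pts[:, 0]
        u = u1 if branch == Branch.DAUGHTER_1 else u2
        return (pts - J) @ u

    def wall(p0, p1, branch, side, inward, width, base_reff):
        pts = _sample_line(p0, p1, h)
        inset = np.zeros(len(pts))
        scl = s_coord(pts, branch)
        for st in spec.stenoses:
            if st.branch != branch or (st.side is not None and st.side != side):
                continue
            inset += stenosis_profile(scl, st, width)
        pts = pts + inset[:, None] * np.asarray(inward, float)[None, :]
        return pts, np.maximum(base_reff - inset, 0.25 * width)

    loop = _Loop()
    Dp, Dd = spec.parent_diameter, spec.daughter_diameter

    # inward normals: toward the branch centerline
    in_parent_lo = np.array([0.0, 1.0])
    in_parent_up = np.array([0.0, -1.0])
    in_d1_outer = -n1
    in_d1_inner = n1
    in_d2_outer = _mirror(in_d1_outer)
    in_d2_inner = _mirror(in_d1_inner)

    # 1) inlet edge, top to bottom
    loop.add(_sample_line((x_in, hp), (x_in, -hp), h), INLET, hp)
    # 2) parent lower wall
    w_pts, w_reff = wall((x_in, -hp), C_dn, Branch.PARENT, WallSide.WALL_B,
                         in_parent_lo, Dp, hp)
    loop.add(w_pts, WALL, w_reff)
    # 3) daughter-2 outer wall
    w_pts, w_reff = wall(C_dn, E2o, Branch.DAUGHTER_2, WallSide.WALL_A,
                         in_d2_outer, Dd, hd)
    loop.add(w_pts, WALL, w_reff)
    # 4) outlet-2 edge
    loop.add(_sample_line(E2o, E2i, h), OUTLET_2, hd)

    if spec.scenario == Scenario.ACA:
        R, half_neck = fr["R"], fr["half_neck"]
        P1, A1, Ox = fr["P1"], fr["A1"], fr["Ox"]
        P2, A2 = _mirror(P1), _mirror(A1)
        # 5a) daughter-2 inner wall down to the neck cut
        w_pts, w_reff = wall(E2i, P2, Branch.DAUGHTER_2, WallSide.WALL_B,
                             in_d2_inner, Dd, hd)
        loop.add(w_pts, WALL, w_reff)
        # 5b) lower neck segment
        neck2 = _sample_line(P2, A2, h)
        d2s = np.linalg.norm(neck2 - neck2[0], axis=1)
        loop.add(neck2, WALL, R, sac_dist=d2s)
        neck_len = d2s[-1]
        # 5c) sac arc A2 -> vertex -> A1 (mirror-exact construction)
        phi = np.arctan2(half_neck, A1[0] - Ox)       # in (pi/2, pi)
        n_half = max(4, int(round(phi * R / h)))
        ang_up = np.linspace(0.0, phi, n_half + 1)
        arc_up = np.stack([Ox + R * np.cos(ang_up), R * np.sin(ang_up)], axis=1)
        arc_up[-1] = A1
        arc_dn = arc_up[::-1] * np.array([1.0, -1.0])
        arc = np.vstack([arc_dn, arc_up[1:]])
        arc_s = np.r_[0.0, np.cumsum(np.linalg.norm(np.diff(arc, axis=0),
                                                    axis=1))]
        d_sac = neck_len + np.minimum(arc_s, arc_s[-1] - arc_s)
        loop.add(arc, WALL, R, sac_dist=d_sac)
        # 5d) upper neck segment
        neck1 = _sample_line(A1, P1, h)
        d1s = np.linalg.norm(neck1 - neck1[-1], axis=1)
        loop.add(neck1, WALL, R, sac_dist=d1s)
        # 5e) daughter-1 inner wall
        w_pts, w_reff = wall(P1, E1i, Branch.DAUGHTER_1, WallSide.WALL_B,
                             in_d1_inner, Dd, hd)
        loop.add(w_pts, WALL, w_reff)
    else:
        # 5) inner walls through the flow-divider apex
        w_pts, w_reff = wall(E2i, apex, Branch.DAUGHTER_2, WallSide.WALL_B,
                             in_d2_inner, Dd, hd)
        loop.add(w_pts, WALL, w_reff)
        w_pts, w_reff = wall(apex, E1i, Branch.DAUGHTER_1, WallSide.WALL_B,
                             in_d1_inner, Dd, hd)
        loop.add(w_pts, WALL, w_reff)

    # 6) outlet-1 edge
    loop.add(_sample_line(E1i, E1o, h), OUTLET_1, hd)
    # 7) daughter-1 outer wall
    w_pts, w_reff = wall(E1o, C_up, Branch.DAUGHTER_1, WallSide.WALL_A,
                         in_d1_outer, Dd, hd)
    loop.add(w_pts, WALL, w_reff)
    # 8) parent upper wall, closing the loop
    w_pts, w_reff = wall(C_up, (x_in, hp), Branch.PARENT, WallSide.WALL_A,
                         in_parent_up, Dp, hp)
    loop.add(w_pts, WALL, w_reff)

    pts, tags, reff, sac_dist = loop.finish()
    return pts, tags, reff, sac_dist, fr


# ---------------------------------------------------------------------------
# triangulation
# ---------------------------------------------------------------------------

def _triangulate_polygon(bpts: np.ndarray, h: float):
    """Triangulate the interior of a sampled polygon.

    Returns (points, triangles) with the boundary samples first (indices
    0..nb-1 in loop order).  Raises if the triangulation does not conform to
    the polygon boundary (the caller refines and retries).
    """
    nb = len(bpts)
    poly = Polygon(bpts)
    if not poly.is_valid or poly.area <= 0:
        raise ValueError(
            "self-intersecting or degenerate geometry (check stenosis "
            "degrees and sac placement)")
    # interior lattice, clipped away from the boundary
    inner = poly.buffer(-0.62 * h)
    minx, miny, maxx, maxy = poly.bounds
    dy = h * np.sqrt(3.0) / 2.0
    # rows mirror-symmetric about y = 0 so symmetric outlines get symmetric
    # interior lattices (and hence nearly symmetric discrete solutions)
    kmax = int(np.ceil(max(abs(miny), abs(maxy)) / dy))
    ys = np.arange(-kmax, kmax + 1) * dy
    ys = ys[(ys > miny) & (ys < maxy)]
    rows = []
    for y in ys:
        k = int(round(abs(y) / dy))
        x0 = minx + (0.25 + 0.5 * (k % 2)) * h
        xs = np.arange(x0, maxx, h)
        rows.append(np.stack([xs, np.full_like(xs, y)], axis=1))
    lattice = np.vstack(rows) if rows else np.zeros((0, 2))
    if len(lattice):
        keep = shapely.contains_xy(inner, lattice[:, 0], lattice[:, 1])
        lattice = lattice[keep]
    pts = np.vstack([bpts, lattice])
    tri = Delaunay(pts)
    cent = pts[tri.simplices].mean(axis=1)
    inside = shapely.contains_xy(poly, cent[:, 0], cent[:, 1])
    tris = tri.simplices[inside]

    # conformity: free edges of the kept triangles must be the polygon edges
    edges = np.vstack([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    key = np.sort(edges, axis=1)
    uniq, counts = np.unique(key, axis=0, return_counts=True)
    free = {tuple(e) for e in uniq[counts == 1]}
    expected = {tuple(sorted((k, (k + 1) % nb))) for k in range(nb)}
    if free != expected:
        missing = expected - free
        raise _NonConforming([tuple(sorted(e)) for e in missing])

    # drop unused lattice points, remap indices
    used = np.unique(tris)
    if len(used) < len(pts):
        remap = -np.ones(len(pts), dtype=int)
        remap[used] = np.arange(len(used))
        if np.any(remap[:nb] != np.arange(nb)):
            raise _NonConforming([])   # an orphan boundary node: refine
        pts = pts[used]
        tris = remap[tris]
    return pts, tris


class _NonConforming(Exception):
    def __init__(self, missing_edges):
        super().__init__("non-conforming boundary")
        self.missing_edges = missing_edges


def _smooth(points, tris, nb, iters=8):
    """Laplacian smoothing of interior nodes, boundary held fixed."""
    n = len(points)
    nbr = [set() for _ in range(n)]
    for a, b, c in tris:
        nbr[a].update((b, c))
        nbr[b].update((a, c))
        nbr[c].update((a, b))
    interior = np.arange(nb, n)
    p = points.copy()
    for _ in range(iters):
        q = p.copy()
        for i in interior:
            ids = list(nbr[i])
            q[i] = p[ids].mean(axis=0)
        # guard against inversion: fall back toward the previous state
        for _damp in range(12):
            d1 = q[tris[:, 1]] - q[tris[:, 0]]
            d2 = q[tris[:, 2]] - q[tris[:, 0]]
            areas = 0.5 * (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])
            if np.all(np.abs(areas) > 0):
                break
            q = 0.5 * (q + p)
        p = q
    return p


def _orient(points, tris):
    d1 = points[tris[:, 1]] - points[tris[:, 0]]
    d2 = points[tris[:, 2]] - points[tris[:, 0]]
    areas = 0.5 * (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])
    flip = areas < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]
    return tris


def build_scenario(spec: ScenarioSpec, thickness_artery: float = 125e-6,
                   thickness_sac: float = 27e-6,
                   neck_blend_band: float = 3e-4) -> Mesh:
    """Build the tagged triangular mesh for a scenario.

    Wall thickness is ``thickness_artery`` everywhere except on the aneurysm
    sac, where it drops to ``thickness_sac`` with a linear blend over
    ``neck_blend_band`` of wall arc length across the neck.
    """
    pts, tags, reff, sac_dist, fr = _outline(spec)
    h = spec.mesh_size
    for _attempt in range(6):
        try:
            points, tris = _triangulate_polygon(pts, h)
            break
        except _NonConforming as exc:
            # refine the offending (or all, if unknown) boundary edges
            nb = len(pts)
            split = set(exc.missing_edges) or \
                {tuple(sorted((k, (k + 1) % nb))) for k in range(nb)}
            new_pts, new_tags, new_reff, new_sac = [], [], [], []
            for k in range(nb):
                k2 = (k + 1) % nb
                new_pts.append(pts[k])
                new_reff.append(reff[k])
                new_sac.append(sac_dist[k])
                new_tags.append(tags[k])
                if tuple(sorted((k, k2))) in split:
                    new_pts.append(0.5 * (pts[k] + pts[k2]))
                    new_reff.append(0.5 * (reff[k] + reff[k2]))
                    sd = 0.5 * (sac_dist[k] + sac_dist[k2]) \
                        if np.isfinite(sac_dist[k]) and np.isfinite(sac_dist[k2]) \
                        else np.inf
                    new_sac.append(sd)
                    new_tags.append(tags[k])
            pts = np.asarray(new_pts)
            tags = np.asarray(new_tags, dtype=object)
            reff = np.asarray(new_reff)
            sac_dist = np.asarray(new_sac)
    else:
        raise ValueError("could not build a boundary-conforming mesh; "
                         "geometry may be nearly self-intersecting")

    nb = len(pts)
    points = _smooth(points, tris, nb)
    tris = _orient(points, tris)

    boundary_edges = np.stack([np.arange(nb), (np.arange(nb) + 1) % nb], axis=1)
    # per-point thickness from the sac-distance marker, then per-edge means
    t_pt = np.where(
        np.isfinite(sac_dist),
        thickness_artery + (thickness_sac - thickness_artery)
        * np.clip(sac_dist / neck_blend_band, 0.0, 1.0),
        thickness_artery)
    edge_thick = 0.5 * (t_pt + t_pt[(np.arange(nb) + 1) % nb])
    edge_reff = 0.5 * (reff + reff[(np.arange(nb) + 1) % nb])

    mesh = Mesh(points=points, triangles=tris,
                boundary_edges=boundary_edges,
                edge_tags=np.asarray(tags, dtype=object),
                edge_thickness=edge_thick, edge_r_eff=edge_reff,
                spec=spec,
                build_args=dict(thickness_artery=thickness_artery,
                                thickness_sac=thickness_sac,
                                neck_blend_band=neck_blend_band))
    mesh.validate()
    mesh.target_points = target_points(mesh, spec)
    return mesh


def target_points(mesh: Mesh, spec: ScenarioSpec | None = None) -> dict:
    """Named measurement nodes: the mid-bifurcation wall point, or the sac
    vertex for the aneurysm model (nearest-wall-node snap, stable under
    refinement)."""
    spec = spec or mesh.spec
    if spec is None:
        raise ValueError("mesh carries no scenario spec")
    fr = _geometry_frame(spec)
    wall_ids = mesh.wall_nodes
    wp = mesh.points[wall_ids]

    def nearest(target):
        return int(wall_ids[np.argmin(((wp - target) ** 2).sum(axis=1))])

    if spec.scenario == Scenario.ACA:
        return {"sac_vertex": nearest(fr["sac_vertex"])}
    return {"bifurcation_apex": nearest(fr["apex"])}


def refine(mesh: Mesh, factor: float) -> Mesh:
    """Rebuild the mesh with a uniformly ``factor``-times smaller size field."""
    if factor <= 0:
        raise ValueError("refinement factor must be positive")
    if mesh.channel_info is not None:
        info = dict(mesh.channel_info)
        info["mesh_size"] = info["mesh_size"] / factor
        if info.pop("kind", None) == "annulus":
            return build_annulus_channel(**info)
        return build_channel(**info)
    if mesh.spec is None:
        raise ValueError("mesh carries no build provenance; cannot refine")
    spec = replace(mesh.spec, mesh_size=mesh.spec.mesh_size / factor)
    return build_scenario(spec, **mesh.build_args)


# ---------------------------------------------------------------------------
# structured straight channel (verification workhorse)
# ---------------------------------------------------------------------------

def build_channel(length: float = 12e-3, width: float = 3.2e-3,
                  mesh_size: float = 2.0e-4,
                  thickness: float = 125e-6) -> Mesh:
    """Structured straight-channel mesh: INLET at x=0, OUTLET_1 at x=length.

    The channel spans ``|y| <= width/2``; quads are split with alternating
    diagonals so the mesh is symmetric about the axis.  Used by the analytic
    Poiseuille/Herschel-Bulkley oracles to verify the flow solver.
    """
    nx = max(2, int(round(length / mesh_size)))
    ny = max(2, int(round(width / mesh_size)))
    xs = np.linspace(0.0, length, nx + 1)
    ys = np.linspace(-width / 2.0, width / 2.0, ny + 1)
    X, Y = np.meshgrid(xs, ys)
    points = np.stack([X.ravel(), Y.ravel()], axis=1)

    def nid(i, j):
        return j * (nx + 1) + i

    tris = []
    for j in range(ny):
        for i in range(nx):
            a, b = nid(i, j), nid(i + 1, j)
            c, d = nid(i + 1, j + 1), nid(i, j + 1)
            if (i + j) % 2 == 0:
                tris += [[a, b, c], [a, c, d]]
            else:
                tris += [[a, b, d], [b, c, d]]
    tris = np.asarray(tris)

    edges, tags = [], []
    for i in range(nx):                      # bottom wall, left -> right
        edges.append((nid(i, 0), nid(i + 1, 0)))
        tags.append(WALL)
    for j in range(ny):                      # outlet, bottom -> top
        edges.append((nid(nx, j), nid(nx, j + 1)))
        tags.append(OUTLET_1)
    for i in range(nx, 0, -1):               # top wall, right -> left
        edges.append((nid(i, ny), nid(i - 1, ny)))
        tags.append(WALL)
    for j in range(ny, 0, -1):               # inlet, top -> bottom
        edges.append((nid(0, j), nid(0, j - 1)))
        tags.append(INLET)

    b = len(edges)
    mesh = Mesh(points=points, triangles=_orient(points, tris),
                boundary_edges=np.asarray(edges),
                edge_tags=np.asarray(tags, dtype=object),
                edge_thickness=np.full(b, thickness),
                edge_r_eff=np.full(b, width / 2.0),
                channel_info=dict(length=length, width=width,
                                  mesh_size=mesh_size, thickness=thickness))
    mesh.validate()
    mid = np.array([length / 2.0, width / 2.0])
    wall_ids = mesh.wall_nodes
    wp = mesh.points[wall_ids]
    mesh.target_points = {
        "mid_wall": int(wall_ids[np.argmin(((wp - mid) ** 2).sum(axis=1))])}
    return mesh


def build_annulus_channel(centerline_radius: float = 6e-3,
                          width: float = 3.2e-3,
                          angle: float = 120.0,
                          mesh_size: float = 2.0e-4,
                          thickness: float = 125e-6) -> Mesh:
    """Structured curved-channel mesh: a circular-arc vessel segment.

    The channel sweeps ``angle`` degrees around the origin at the given
    centerline radius; INLET at the first radial face, OUTLET_1 at the last.
    Curved walls make the membrane response stiffness-dominated (material,
    not pre-tension), which the straight channel cannot probe.
    """
    if width >= 2 * centerline_radius:
        raise ValueError("channel width exceeds the centerline diameter")
    theta = np.deg2rad(angle)
    nt = max(4, int(round(theta * centerline_radius / mesh_size)))
    nr = max(2, int(round(width / mesh_size)))
    ths = np.linspace(0.0, theta, nt + 1)
    rs = np.linspace(centerline_radius - width / 2.0,
                     centerline_radius + width / 2.0, nr + 1)
    TH, R = np.meshgrid(ths, rs)
    points = np.stack([(R * np.cos(TH)).ravel(), (R * np.sin(TH)).ravel()],
                      axis=1)

    def nid(i, j):                 # i along theta, j along r
        return j * (nt + 1) + i

    tris = []
    for j in range(nr):
        for i in range(nt):
            a, b = nid(i, j), nid(i + 1, j)
            c, d = nid(i + 1, j + 1), nid(i, j + 1)
            if (i + j) % 2 == 0:
                tris += [[a, b, c], [a, c, d]]
            else:
                tris += [[a, b, d], [b, c, d]]
    tris = np.asarray(tris)

    edges, tags = [], []
    for i in range(nt):                       # outer wall, theta increasing
        edges.append((nid(i, nr), nid(i + 1, nr)))
        tags.append(WALL)
    for j in range(nr, 0, -1):                # outlet, outer -> inner
        edges.append((nid(nt, j), nid(nt, j - 1)))
        tags.append(OUTLET_1)
    for i in range(nt, 0, -1):                # inner wall, theta decreasing
        edges.append((nid(i, 0), nid(i - 1, 0)))
        tags.append(WALL)
    for j in range(nr):                       # inlet, inner -> outer
        edges.append((nid(0, j), nid(0, j + 1)))
        tags.append(INLET)

    b = len(edges)
    mesh = Mesh(points=points, triangles=_orient(points, tris),
                boundary_edges=np.asarray(edges),
                edge_tags=np.asarray(tags, dtype=object),
                edge_thickness=np.full(b, thickness),
                edge_r_eff=np.full(b, width / 2.0),
                channel_info=dict(centerline_radius=centerline_radius,
                                  width=width, angle=angle,
                                  mesh_size=mesh_size, thickness=thickness,
                                  kind="annulus"))
    mesh.validate()
    return mesh
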