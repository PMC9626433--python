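"""Wall-shear-stress extraction, target-point series and scenario summaries.

WSS is the tangential part of the viscous traction the blood exerts on the
luminal wall: with the symmetric rate-of-deformation tensor ``e`` built from
recovered velocity gradients, the traction is ``(-p I + 2 eta e) . n`` and
WSS is its component perpendicular to the wall normal.  The viscosity
entering the formula is the local converged effective viscosity of the
generalized-Newtonian law, evaluated at the recovered shear rate, so the
extraction is consistent with the momentum equation actually solved.

Velocity gradients at wall nodes are recovered by a least-squares quadratic
fit of each velocity component over the node's topological 2-ring (extended
to 3 rings where the patch is small).  The fit reproduces quadratic fields
exactly, so plane Poiseuille WSS is recovered to round-off; rigid rotations
and uniform translations give identically zero WSS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .rheology import RheologyParams, effective_viscosity
from .scenario_geometry import WALL, Mesh
from .flow_solver import FlowField

__all__ = [
    "WSSField", "TargetPointSeries", "compute_wss", "recover_gradients",
    "extract_series", "summarize", "weighted_median",
]


# ---------------------------------------------------------------------------
# gradient recovery
# ---------------------------------------------------------------------------

def _node_adjacency(mesh: Mesh):
    cache = getattr(mesh, "_adj_cache", None)
    if cache is not None and cache[0] is mesh.points:
        return cache[1]
    adj = [set() for _ in range(len(mesh.points))]
    for a, b, c in mesh.triangles:
        adj[a].update((b, c))
        adj[b].update((a, c))
        adj[c].update((a, b))
    mesh._adj_cache = (mesh.points, adj)
    return adj


def _patch(adj, k: int, rings: int) -> set:
    patch = {k}
    frontier = {k}
    for _ in range(rings):
        frontier = set().union(*(adj[i] for i in frontier)) - patch
        patch |= frontier
    return patch


def recover_gradients(mesh: Mesh, velocity: np.ndarray, node_ids) -> np.ndarray:
    """Recovered velocity-gradient tensors d(v_i)/d(x_j) at the given nodes.

    Least-squares quadratic fit over the topological 2-ring of each node
    (3-ring when fewer than 10 neighbours), exact for globally quadratic
    velocity fields.  Returns an array of shape (len(node_ids), 2, 2).
    """
    adj = _node_adjacency(mesh)
    pts = mesh.points
    out = np.empty((len(node_ids), 2, 2))
    for row, k in enumerate(node_ids):
        k = int(k)
        patch = _patch(adj, k, 2)
        if len(patch) < 10:
            patch = _patch(adj, k, 3)
        ids = np.fromiter(patch, dtype=int)
        d = pts[ids] - pts[k]
        r = max(np.abs(d).max(), 1e-300)
        dx, dy = d[:, 0] / r, d[:, 1] / r
        basis = np.stack([np.ones_like(dx), dx, dy,
                          dx * dx, dx * dy, dy * dy], axis=1)
        coef, *_ = np.linalg.lstsq(basis, velocity[ids], rcond=None)
        out[row, 0, :] = coef[1] / r          # d(vx)/dx, d(vy)/dx
        out[row, 1, :] = coef[2] / r          # d(vx)/dy, d(vy)/dy
    # convention: out[:, j, i] currently holds d(v_i)/d(x_j); transpose
    return out.transpose(0, 2, 1)


# ---------------------------------------------------------------------------
# WSS field
# ---------------------------------------------------------------------------

@dataclass
class WSSField:
    """Tangential wall traction along the luminal wall.

    ``node_ids`` lists the wall nodes in chain order (chains concatenated);
    ``arclength`` restarts at zero on each chain and ``chain_id`` tells the
    chains apart.  ``normal_pressure`` is the compressive normal traction
    ``-(sigma n).n`` (approximately the local pressure).
    """

    node_ids: np.ndarray
    wss_vector: np.ndarray          # (w, 2) Pa
    wss_magnitude: np.ndarray       # (w,) Pa
    normal_pressure: np.ndarray     # (w,) Pa
    arclength: np.ndarray           # (w,) m
    chain_id: np.ndarray            # (w,) int
    normals: np.ndarray             # (w, 2) outward unit normals
    mesh: Optional[Mesh] = None

    def at_node(self, node_id: int) -> float:
        idx = np.flatnonzero(self.node_ids == node_id)
        if len(idx) == 0:
            raise KeyError(f"node {node_id} is not a wall node")
        return float(self.wss_magnitude[idx[0]])


def compute_wss(flow: FlowField, mesh: Mesh,
                params: RheologyParams) -> WSSField:
    """Extract the WSS vector at every wall node of a converged flow field.

    Builds the symmetric rate-of-deformation tensor from recovered nodal
    velocity gradients, forms ``2 eta e . n`` with the local effective
    viscosity, and removes the normal component; the result is tangential to
    the wall by construction (asserted to round-off).
    """
    if flow.viscosity is None:
        raise ValueError("flow field carries no converged viscosity")
    normals_map = mesh.boundary_node_normals()
    chains = mesh.wall_chains()
    ids, chain_id, arcl = [], [], []
    for ci, chain in enumerate(chains):
        seg = np.linalg.norm(np.diff(mesh.points[chain], axis=0), axis=1)
        s = np.r_[0.0, np.cumsum(seg)]
        ids.extend(int(i) for i in chain)
        chain_id.extend([ci] * len(chain))
        arcl.extend(s)
    ids = np.asarray(ids)
    grads = recover_gradients(mesh, flow.velocity, ids)
    E = 0.5 * (grads + grads.transpose(0, 2, 1))
    gamma = np.sqrt(2.0 * np.einsum("kij,kij->k", E, E))
    eta = np.asarray(effective_viscosity(gamma, params))
    n = np.asarray([normals_map[int(i)] for i in ids])
    t_visc = 2.0 * eta[:, None] * np.einsum("kij,kj->ki", E, n)
    t_nn = np.einsum("ki,ki->k", t_visc, n)
    wss_vec = t_visc - t_nn[:, None] * n
    res = np.abs(np.einsum("ki,ki->k", wss_vec, n))
    scale = np.maximum(np.linalg.norm(wss_vec, axis=1), 1e-30)
    assert np.all(res <= 1e-10 * np.maximum(scale, 1.0)), \
        "WSS vector failed tangentiality"
    p_nodes = flow.pressure[ids]
    normal_pressure = p_nodes - t_nn
    return WSSField(node_ids=ids, wss_vector=wss_vec,
                    wss_magnitude=np.linalg.norm(wss_vec, axis=1),
                    normal_pressure=normal_pressure,
                    arclength=np.asarray(arcl),
                    chain_id=np.asarray(chain_id), normals=n, mesh=mesh)


# ---------------------------------------------------------------------------
# series and summaries
# ---------------------------------------------------------------------------

@dataclass
class TargetPointSeries:
    """Ramp histories of the hemodynamic state at one named target node."""

    name: str
    node_id: int
    times: np.ndarray               # s, strictly increasing
    velocity: np.ndarray            # m/s (magnitude)
    pressure: np.ndarray            # Pa
    displacement: np.ndarray        # m (magnitude)
    wss: np.ndarray                 # Pa (magnitude)

    def __post_init__(self) -> None:
        lens = {len(self.times), len(self.velocity), len(self.pressure),
                len(self.displacement), len(self.wss)}
        if len(lens) != 1:
            raise ValueError("series columns must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time stamps must be strictly increasing")

    def to_csv(self) -> str:
        lines = ["time,velocity,pressure,displacement,wss"]
        for row in zip(self.times, self.velocity, self.pressure,
                       self.displacement, self.wss):
            lines.append(",".join(f"{v:.10g}" for v in row))
        return "\n".join(lines) + "\n"


def extract_series(times, fields, mesh: Mesh, target: str | int,
                   params: RheologyParams,
                   displacements=None, name: str | None = None
                   ) -> TargetPointSeries:
    """Sample the state histories at a target node (exact nodal sampling).

    ``fields`` is the ordered list of flow states; ``displacements`` an
    optional matching list of per-node wall displacement magnitudes (zeros
    when absent, e.g. for rigid-wall runs).
    """
    if isinstance(target, str):
        if target not in mesh.target_points:
            raise KeyError(f"unknown target point {target!r}; mesh has "
                           f"{sorted(mesh.target_points)}")
        node = int(mesh.target_points[target])
        name = name or target
    else:
        node = int(target)
        name = name or f"node_{node}"
    times = np.asarray(times, dtype=float)
    if len(times) != len(fields):
        raise ValueError("times and fields length mismatch")
    vel, pres, wss, disp = [], [], [], []
    for k, f in enumerate(fields):
        vel.append(float(np.linalg.norm(f.velocity[node])))
        pres.append(float(f.pressure[node]))
        g = recover_gradients(mesh, f.velocity, [node])[0]
        E = 0.5 * (g + g.T)
        gamma = float(np.sqrt(2.0 * (E * E).sum()))
        eta = effective_viscosity(gamma, params)
        nrm = mesh.boundary_node_normals().get(node)
        if nrm is None:
            wss.append(0.0)
        else:
            tv = 2.0 * eta * E @ nrm
            tv = tv - (tv @ nrm) * nrm
            wss.append(float(np.linalg.norm(tv)))
        if displacements is None:
            disp.append(0.0)
        else:
            d = np.asarray(displacements[k])
            disp.append(float(d[node]) if d.ndim == 1
                        else float(np.linalg.norm(d[node])))
    return TargetPointSeries(name=name, node_id=node, times=times,
                             velocity=np.asarray(vel),
                             pressure=np.asarray(pres),
                             displacement=np.asarray(disp),
                             wss=np.asarray(wss))


def weighted_median(values, weights) -> float:
    """Weighted median (lower weighted 50th percentile, refinement-stable)."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if len(v) == 0:
        raise ValueError("empty sample")
    order = np.argsort(v)
    v, w = v[order], w[order]
    cdf = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5 * w.sum(), cdf, v))


def _wall_node_weights(mesh: Mesh) -> dict:
    """Half the summed length of adjacent wall edges, per wall node."""
    weights: dict = {}
    p = mesh.points
    for (i, j), tag in zip(mesh.boundary_edges, mesh.edge_tags):
        if tag != WALL:
            continue
        ell = float(np.linalg.norm(p[j] - p[i]))
        for k in (int(i), int(j)):
            weights[k] = weights.get(k, 0.0) + 0.5 * ell
    return weights


def summarize(wss: WSSField, flow: FlowField, displacement, mesh: Mesh) -> dict:
    """Wall-wide and target-point statistics of one converged scenario state.

    Medians over wall nodes are weighted by adjacent wall-edge length so they
    are stable under mesh refinement.  ``displacement`` is a per-node array
    (magnitude, or (n, 2) vectors) or None for rigid-wall runs.
    """
    wmap = _wall_node_weights(mesh)
    w = np.asarray([wmap[int(i)] for i in wss.node_ids])
    # deduplicate nodes shared by two chains
    _, first = np.unique(wss.node_ids, return_index=True)
    mags = wss.wss_magnitude[first]
    wts = w[first]
    out = {
        "max_wss": float(mags.max()),
        "median_wss": weighted_median(mags, wts),
        "peak_velocity": float(flow.speed.max()),
        "peak_pressure": float(flow.pressure.max()),
    }
    for name, node in mesh.target_points.items():
        out[f"wss_at_{name}"] = wss.at_node(int(node))
    if displacement is not None:
        d = np.asarray(displacement, dtype=float)
        dm = np.abs(d) if d.ndim == 1 else np.linalg.norm(d, axis=1)
        ids = np.unique(wss.node_ids)
        dw = dm[ids]
        ww = np.asarray([wmap[int(i)] for i in ids])
        out["max_displacement"] = float(dw.max())
        out["median_displacement"] = weighted_median(dw, ww)
    return out


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

@dataclass
class ComparativeReport:
    """Cross-scenario summary of the full three-model comparison."""

    scenarios: dict                    # name -> summary dict
    ordering_flags: dict               # name -> bool
    config_echo: str
    version: str
    series: dict = field(default_factory=dict)   # name -> TargetPointSeries

    def to_json(self) -> str:
        import json
        payload = {
            "version": self.version,
            "scenarios": self.scenarios,
            "ordering_flags": self.ordering_flags,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    def to_markdown(self) -> str:
        lines = ["# Scenario comparison", "",
                 f"cerebrofsi {self.version}", "",
                 "| quantity | " + " | ".join(self.scenarios) + " |",
                 "|---|" + "---|" * len(self.scenarios)]
        keys = sorted({k for s in self.scenarios.values() for k in s})
        for k in keys:
            row = [f"{self.scenarios[s].get(k, float('nan')):.4g}"
                   for s in self.scenarios]
            lines.append(f"| {k} | " + " | ".join(row) + " |")
        lines += ["", "## Ordering checks", ""]
        for name, ok in self.ordering_flags.items():
            lines.append(f"- {name}: {'PASS' if ok else 'FAIL'}")
        return "\n".join(lines) + "\n"


def _ramp_with_wall_response(mesh, params, mat, bcs, settings, cset,
                             series_steps=None):
    """Quasi-static ramp with one-way wall response per step (for series)."""
    from dataclasses import replace as _replace
    from .flow_solver import ramp_series
    from .fsi_coupling import (interface_traction, _wall_load_anomaly,
                               CouplingSettings)
    from .wall_mechanics import membrane_wall_update
    if series_steps is not None:
        settings = _replace(settings, ramp_steps=int(series_steps))
    times, fields = ramp_series(mesh, params, bcs, settings)
    normals_map = mesh.boundary_node_normals()
    thick_map = mesh.wall_node_values(mesh.edge_thickness)
    reff_map = mesh.wall_node_values(mesh.edge_r_eff)
    p_pre = bcs.inlet_reference_pressure - cset.external_pressure
    disps = []
    chains = [c for c in mesh.wall_chains() if len(c) >= 3]
    for f in fields:
        tr = interface_traction(f, mesh, params)
        dq_all = _wall_load_anomaly(f, mesh, tr, cset, bcs)
        dq = {int(i): q for i, q in zip(tr.node_ids, dq_all)}
        d = np.zeros(len(mesh.points))
        for chain in chains:
            pts = mesh.points[chain]
            nrm = np.asarray([normals_map[int(i)] for i in chain])
            th = np.asarray([thick_map[int(i)] for i in chain])
            re_n = np.asarray([reff_map[int(i)] for i in chain])
            T0 = p_pre * 0.5 * (re_n[1:] + re_n[:-1]) if cset.prestress \
                else None
            q = np.asarray([dq[int(i)] for i in chain])
            w = membrane_wall_update(pts, nrm, q, mat,
                                     anchors=[0, len(chain) - 1],
                                     thickness=th, prestress_tension=T0)
            d[chain] = np.abs(w)
        disps.append(d)
    return times, fields, disps


def run_pipeline(config, out_dir=None) -> ComparativeReport:
    """Run the full multi-scenario study and write the comparative report.

    ``config`` is a YAML path/text/dict or a resolved
    :class:`~cerebrofsi.config.PipelineConfig`.  For every requested
    scenario: build the mesh, record the quasi-static startup series at the
    target point (one-way wall response), solve the fully coupled steady FSI
    state, extract WSS, and summarize.  Ordering flags compare peak WSS
    across scenarios and against twice the intact physiological reference
    (the mid-parent developed-wall WSS).

    Artifacts (when ``out_dir`` is given): per-scenario VTK fields, CSV
    series, ``report.json``, ``report.md`` and a bar-chart figure.
    """
    import os
    from . import __version__
    from .config import load_config, config_to_yaml
    from .fsi_coupling import solve_fsi
    from .scenario_geometry import build_scenario, Scenario

    cfg = load_config(config)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)

    summaries, series_map = {}, {}
    for scenario in cfg.scenarios:
        name = Scenario(scenario).value
        try:
            spec = cfg.spec_for(scenario)
            mesh = build_scenario(spec,
                                  thickness_artery=cfg.wall.thickness_artery,
                                  thickness_sac=cfg.wall.thickness_sac)
            times, fields, disps = _ramp_with_wall_response(
                mesh, cfg.rheology, cfg.wall, cfg.bcs, cfg.solver,
                cfg.coupling, cfg.series_steps)
            flow, disp, state = solve_fsi(mesh, cfg.rheology, cfg.wall,
                                          cfg.bcs, cfg.coupling, cfg.solver,
                                          initial_flow=fields[-1])
            wss = compute_wss(flow, mesh, cfg.rheology)
            target = next(iter(mesh.target_points))
            ser = extract_series(times, fields, mesh, target, cfg.rheology,
                                 displacements=disps)
            summaries[name] = summarize(wss, flow, disp, mesh)
            summaries[name]["fsi_outer_iterations"] = state.iterations
            series_map[name] = ser
            if out_dir is not None:
                dm = np.linalg.norm(disp, axis=1)
                wmag = np.zeros(len(mesh.points))
                wmag[wss.node_ids] = wss.wss_magnitude
                mesh.write(os.path.join(out_dir, f"{name}_mesh"))
                with open(os.path.join(out_dir, f"{name}_fields.vtk"),
                          "w") as fh:
                    fh.write(mesh.to_vtk(point_data={
                        "velocity": flow.velocity,
                        "pressure": flow.pressure,
                        "displacement": disp,
                        "displacement_magnitude": dm,
                        "wss_magnitude": wmag}))
                with open(os.path.join(out_dir, f"{name}_series.csv"),
                          "w") as fh:
                    fh.write(ser.to_csv())
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage '{name}' failed: {exc}") from exc

    flags = {}
    names = [Scenario(s).value for s in cfg.scenarios]
    if set(names) >= {"intact", "icas", "aca"}:
        flags["peak_wss_aca_ge_icas"] = (
            summaries["aca"]["max_wss"] >= summaries["icas"]["max_wss"])
        flags["peak_wss_icas_ge_intact"] = (
            summaries["icas"]["max_wss"] >= summaries["intact"]["max_wss"])
        # physiological reference: intact median (developed parent) WSS
        flags["stenosed_peak_ge_2x_reference"] = (
            max(summaries["icas"]["max_wss"], summaries["aca"]["max_wss"])
            >= 2.0 * summaries["intact"]["median_wss"])

    report = ComparativeReport(scenarios=summaries, ordering_flags=flags,
                               config_echo=_echo(cfg), version=__version__,
                               series=series_map)
    if out_dir is not None:
        import os
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            fh.write(report.to_json())
        with open(os.path.join(out_dir, "report.md"), "w") as fh:
            fh.write(report.to_markdown())
        with open(os.path.join(out_dir, "config_echo.yaml"), "w") as fh:
            fh.write(report.config_echo)
        _report_figure(report, os.path.join(out_dir, "wss_comparison.png"))
    return report


def _echo(cfg) -> str:
    from .config import config_to_yaml
    return config_to_yaml(cfg)


def _report_figure(report: ComparativeReport, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    names = list(report.scenarios)
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for ax, (key, label) in zip(axes, [
            ("max_wss", "peak WSS [Pa]"),
            ("max_displacement", "peak displacement [m]")]):
        vals = [report.scenarios[n].get(key, np.nan) for n in names]
        ax.bar(names, vals, color=["#4c72b0", "#dd8452", "#55a868"][:len(names)])
        ax.set_ylabel(label)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
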