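"""Build the three scenario meshes and write them as VTK + JSON sidecars."""
import os

from cerebrofsi import build_scenario, default_spec

os.makedirs("out_geometries", exist_ok=True)
for name in ("intact", "icas", "aca"):
    mesh = build_scenario(default_spec(name))
    mesh.write(os.path.join("out_geometries", f"{name}_mesh"))
    print(f"{name:6s}: {len(mesh.points):5d} nodes, "
          f"{len(mesh.triangles):5d} triangles, "
          f"targets {dict(mesh.target_points)}")
# The intact and stenosed models share the bifurcation-apex target node;
# the aneurysm model measures at the sac vertex instead.
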