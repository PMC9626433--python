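# cerebrofsi

Desk-scale fluid–structure interaction (FSI) of atherosclerotic
intracranial bifurcations: how do plaque stenoses change the hemodynamics
— velocity, pressure, wall displacement and above all **wall shear stress
(WSS)** — of a cerebral artery bifurcation, and of a saccular aneurysm
sitting on it?

The package is written for vascular-biomechanics researchers who want a
reproducible, fully scripted 2D reference pipeline rather than a
commercial FEM model: every ingredient (geometry, rheology, wall law,
solvers) is parametric, tested against closed-form oracles, and runs in
minutes on one core.

Three scenarios share one parametric geometry (parent artery Ø 3.2 mm,
daughters Ø 2 mm, wall 125 µm; sac radius 2.5 mm, wall 27 µm):

| scenario | description |
|---|---|
| `intact` | healthy bifurcation |
| `icas`   | the same artery occluded by three atherosclerotic stenoses |
| `aca`    | the stenosed bifurcation carrying a saccular aneurysm |

## Model

* **Blood** is a Herschel–Bulkley fluid,
  `η(γ̇) = κ γ̇ⁿ⁻¹ + τ₀/γ̇` with κ = 8.9721·10⁻³ Pa·sⁿ, n = 0.8601,
  τ₀ = 0.0175 Pa, ρ = 1020 kg/m³ (bi-viscosity regularized), solved as
  steady incompressible Navier–Stokes with stabilized P1–P1 finite
  elements (parabolic inlet, mean 0.23 m/s; outlets at 4 kPa; Re ≈ 190).
* **The wall** is an incompressible neo-Hookean membrane,
  `W = C₁(I₁ − 3)` with C₁ = 166 kPa, prestressed to carry the 16 kPa
  (~120 mmHg) in-vivo pressure; displacements are reported about that
  loaded datum.
* **Coupling** is partitioned and quasi-static: flow → interface traction
  → membrane update → Aitken under-relaxation → mesh morphing, iterated
  to a 10⁻⁷ m interface tolerance.
* **WSS** is the tangential part of `(−pI + 2ηε̇)·n` from recovered
  velocity gradients, with the local converged effective viscosity.

See `docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

```python
from cerebrofsi import (RheologyParams, build_scenario, compute_wss,
                        default_spec, solve_steady_flow, summarize)

params = RheologyParams()
mesh = build_scenario(default_spec("intact"))
flow = solve_steady_flow(mesh, params)
wss = compute_wss(flow, mesh, params)
print(summarize(wss, flow, None, mesh))
```

prints (examples/04_steady_flow_wss.py):

```
Picard iterations        : 28
peak velocity            : 0.346 m/s
wall WSS max / median    : 5.37 / 1.74 Pa
WSS at bifurcation apex  : 0.000 Pa
```

The healthy wall sits inside the 1–7 Pa physiological WSS band; the
median 1.74 Pa is the developed parent-artery value, and the apex node is
the stagnation point of a mirror-symmetric flow, far below the 5 Pa bound
for the bifurcation target.
The `examples/` directory has one short script per capability (rheology
oracles, wall inflation closed forms, geometry building, steady WSS,
coupled FSI, and the full three-scenario comparison); the `cerebrofsi`
CLI wraps the same stages (`build | flow | fsi | wss | report | validate`).

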