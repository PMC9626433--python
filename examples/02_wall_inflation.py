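"""Neo-Hookean thin-wall equilibria: artery tube and aneurysm sac balloon.

Inflates the 1.6 mm-radius artery (125 um wall) and the 2.5 mm aneurysm sac
(27 um wall) and prints stretch, displacement and the sac's limit point.
"""
from cerebrofsi import WallMaterial, sphere_limit_point, sphere_equilibrium, \
    tube_equilibrium

mat = WallMaterial()               # C1 = 166 kPa, incompressible
print("artery tube (R0=1.6 mm, t0=125 um):")
for P in (1e3, 2e3, 5e3, 10e3):
    st = tube_equilibrium(P, 1.6e-3, 125e-6, mat)
    print(f"  P = {P/1e3:4.1f} kPa -> stretch {st.stretch:.4f}, "
          f"radial displacement {st.displacement*1e6:6.1f} um")

lam_star, p_max = sphere_limit_point(2.5e-3, 27e-6, mat)
print(f"\nsac balloon limit point: stretch {lam_star:.4f}, "
      f"P_max = {p_max/1e3:.2f} kPa")
st = sphere_equilibrium(2e3, 2.5e-3, 27e-6, mat)
print(f"sac at 2 kPa: stretch {st.stretch:.4f}")
# P_max ~ 4.4 kPa is far below the 16 kPa luminal pressure: the imaged sac
# must already be prestressed, which is why the FSI pipeline reports
# displacements relative to the loaded in-vivo configuration.
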