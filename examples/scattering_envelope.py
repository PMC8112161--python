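"""Constrained scattering envelope and the resolution it implies.

For each ion at its fixed-range energy: the lateral path uncertainty at
the phantom mid-plane (where the tomogram is reconstructed) and the
scattering-only MTF 10% frequency that follows from it.
"""

import ionct as ic

geometry = ic.TrackerGeometry(x0=0.0, x1=200.0)

print("Ion      sigma_mid [mm]  MTF10 [lp/cm]  gain vs proton")
base = None
for row in ic.load_fixture("fixed_range"):
    ion = ic.get_ion(row.ion)
    env = ic.constrained_envelope(row.E_init, ion, geometry)
    f10 = ic.mtf10_closed_form(env.sigma_mid) * 10.0
    base = base or f10
    print(f"{ion.name:8s} {env.sigma_mid:10.3f}     {f10:9.2f}"
          f"      {f10 / base:6.2f}x")

print()
print("The envelope is pinned to zero at both trackers and peaks just")
print("downstream of mid-depth; halving the charge-to-mass ratio halves it.")
print("Carbon resolves ~3.6x finer than protons at the same range.")
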