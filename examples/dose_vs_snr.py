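"""Dose required to reach a target SNR in the central voxel, per ion.

Pure arithmetic on the packaged table rows: sigma_WET, the nuclear
fluence-loss factors and the per-particle central dose.
"""

import ionct as ic

scenario = ic.ImagingScenario(pixel_size=1.0)
rows = {r.ion: r for r in ic.load_fixture("fixed_range")}
target_snr = 10.0

d_p = ic.dose_for_snr(target_snr, scenario, rows["proton"].sigma_wet,
                      rows["proton"].nuclear_factors())
print(f"Fixed range R = 26 cm, SNR target {target_snr:.0f}, 1 mm pixels:")
print("Ion       dose [mGy]   vs proton   sigma(dose)/dose")
for name, row in rows.items():
    nuc = row.nuclear_factors()
    d = ic.dose_for_snr(target_snr, scenario, row.sigma_wet, nuc)
    sd = ic.propagate_dose_uncertainty(d, row.sigma_wet, row.sigma_wet_err, nuc)
    print(f"{name:9s} {ic.dose_in_mgy(d):9.3f}   {100*(d/d_p-1):+6.1f}%"
          f"     {100*sd/d:5.1f}%")

print()
print("Protons need the least dose at fixed range: their nuclear stability")
print("(small g factors) and low dose per primary beat their larger WET")
print("noise, which enters squared but is offset by sigma_WET cancelling")
print("against the SNR definition.")
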