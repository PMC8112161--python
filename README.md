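# ionct — image-quality limits of energy-loss ion CT

`ionct` models the statistical limits of relative-stopping-power (RSP)
imaging with light ion beams — ¹H, ⁴He, ⁶Li, ¹⁰B and ¹²C — crossing a
20 cm water cylinder, the reference geometry of list-mode particle CT.
It is written for medical-physics researchers comparing ion species for
imaging: which ion buys spatial resolution, which buys SNR per unit
dose, and why no single ion maximises both.

## The model

A particle measured by entry/exit trackers and a residual-energy
detector yields one line integral of RSP, the water-equivalent
thickness WET = ∫ dE / S_w(E).  Three pieces of physics set the image
quality:

* **Energy loss** — Bethe stopping power for water (no density-effect or
  shell corrections, I = 78 eV), CSDA ranges and depth–energy transport,
  valid 1–1000 MeV/u.
* **Noise** — energy straggling with the Tschalär variance
  σ²_strag(E_out) = k₁²(E_out) ∫ k₂/k₁³ dE (k₁ the stopping power, k₂
  the Bohr straggling power ∝ Z²), plus the scattering contribution
  σ²_MCS = E[ΔE²] − E[ΔE]² over the ensemble of tracker-constrained
  paths.  The quadrature sum propagates to the WET noise
  σ_WET = σ_E_out / S_w(E_out), and to the central-voxel SNR and the
  dose D_c required to reach a target SNR,

      SNR = √(3Ma²/π²) · S_w(E_out) √N_D RSP̂ / σ_E_out,
      D_c = π² SNR² σ²_WET g_ph g_dt S_MC / (3a⁴ ρ RSP̂²),

  where the nuclear fluence-loss factors g_ph, g_dt and the per-particle
  central dose S_MC are Monte Carlo inputs shipped as packaged tables
  (they depend on hadronic cross-section models outside the
  electromagnetic scope of this package).
* **Resolution** — Fermi–Eyges scattering moments with the Highland
  parametrisation, conditioned on the boundary measurements to give the
  lateral path-uncertainty envelope σ_scatt(x) (zero at both trackers,
  maximal near mid-depth), and the MTF with pixel sampling,
  MTF(ε) = sinc(εa) exp(−2π²σ²_scatt ε²) ⊛ III₁/ₐ, capped at the
  Nyquist frequency 1/(2a).  The resolution metric is MTF₁₀% in lp/cm.

A seeded condensed-history electromagnetic Monte Carlo (straggling +
multiple Coulomb scattering, 1 mm steps) validates each analytic piece
and reproduces the lateral noise structure of radiographs, including the
off-centre noise bumps characteristic of proton imaging.

## Worked example

```python
import ionct as ic

# WET noise for the 200 MeV/u fixed-range beams
for ion in (ic.PROTON, ic.HELIUM):
    b = ic.noise_budget(200.0, ion, thickness=200.0)
    print(ion.name, round(b.sigma_wet, 2), "mm")

# scattering-limited resolution
print(round(ic.mtf10(200.0, ic.PROTON, 200.0)[0], 2), "lp/cm")
```

prints

```
proton 2.64 mm
helium 1.33 mm
5.46 lp/cm
```

i.e. a 200 MeV proton beam leaves the 20 cm phantom with 2.6 mm of WET
noise per particle and resolves 5.5 lp/cm; helium at the same range
halves the noise (the σ ∝ Z/S_w scaling) and doubles the resolution.
The `examples/` directory holds one short script per capability
(ranges, envelope/MTF, noise budget, dose-vs-SNR, energy selection, MC
validation); each prints a table and a sentence on what it means.  The
same computations are exposed on the command line:

```
ionct iontable --table fixed_range     # packaged per-ion parameters
ionct snrdose                          # dose [mGy] vs SNR target per ion
ionct mtfscan --ion proton --energy 200
ionct mcsim --ion proton --energy 200 --histories 100000 --seed 1
ionct validate                         # analytic model vs packaged table
```

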