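"""Physical constants shared across the package.

Energies are MeV, lengths mm, unless a name says otherwise.  Kinetic
energies are stored *per nucleon* (MeV/u) everywhere in the public API;
total-energy conversions happen only inside the kinematic and straggling
kernels.
"""

#: Electron rest energy [MeV].
M_E_C2 = 0.51099895

#: Proton rest energy [MeV] (rest energy per nucleon for 1H).
M_P_C2 = 938.27208816

#: Atomic mass unit [MeV]; rest energy per nucleon used for A > 1 ions.
M_U_C2 = 931.49410242

#: Highland constant [MeV/c].
E0_HIGHLAND = 13.6

#: Lynch-Dahl coefficient of the logarithmic Highland correction.
#: (1/9, the coefficient of Highland's original log10 form, is accepted
#: as an alternative by the scattering module.)
HIGHLAND_LOG_COEFF = 0.038

#: Bethe coefficient for liquid water [MeV/mm]:
#: 0.307075 MeV cm^2/g  x  Z/A = 0.55509  x  rho = 1 g/cm^3, per mm.
K_BETHE_WATER = 0.307075 * 0.55509 / 10.0

#: Bohr straggling coefficient for water [MeV^2/mm] for unit charge:
#: K_BETHE_WATER * m_e c^2 = 0.00871 MeV^2/mm (0.0871 MeV^2/cm).
K_STRAGGLING_WATER = K_BETHE_WATER * M_E_C2

#: Mean excitation energy of water [MeV] (78 eV, the Geant4 default).
I_WATER = 78e-6

#: Radiation length of water [mm].
X0_WATER = 360.8

#: Low-energy validity floor of the Bethe model [MeV/u].
E_MIN = 1.0

#: MeV/g -> Gy.
MEV_PER_G_TO_GY = 1.602176634e-10
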