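# Methods

This note records the model assumptions, the numerical choices, and the
places where the design was genuinely open, in enough detail to judge
what the tests do and do not demonstrate.

## Stopping power and transport

The electromagnetic stopping power is the uncorrected Bethe formula for
liquid water,

    S(E) = Z² K / β² [ ln(2 m_e c² / I · β²γ²) − β² ],

with K = 0.1704 MeV/cm (0.307075 MeV cm²/g × Z/A = 0.55509 × ρ = 1) and
I = 78 eV, the Geant4 default for water.  Density-effect and shell
corrections are omitted; the validity floor is 1 MeV/u.  Between 75 and
78 eV the CSDA ranges shift by about 0.5%, which is the scale of the
differences against published range tables — with I = 78 eV the model
gives R(350 MeV p) = 66.6 cm where condensed-history simulation reports
66.2 cm (+0.6%).  All public energies are kinetic energy per nucleon;
conversions to total energy happen only inside the pv and straggling
kernels (pv = A·E(E+2m_u)/(E+m_u)).

Ranges are adaptive quadrature of 1/S down to the validity floor (the
neglected sub-floor residual range is < 0.03 mm for protons);
depth–energy transport is fixed-step classical RK4, 0.1 mm by default
(a keyword on every transport call).  `energy_for_range` inverts the
range integral by bracketed root solve.

## Scattering moments and the constrained envelope

Fermi–Eyges moments use the Highland scattering power with the
logarithmic thickness correction applied to the accumulated water path:

    A_n(x) = Z² E₀² (1 + c ln(t/X₀))² ∫ (x−x′)ⁿ dx′ / (pv(x′)² X₀),

E₀ = 13.6 MeV/c, X₀ = 360.8 mm (water, constant — the phantom is
uniform), lever arm (x−x′)ⁿ about the evaluation plane.  Two choices
deserve comment:

* **Log coefficient c.**  Highland's correction appears in the
  literature both as 1/9·log₁₀ (original) and 0.038·ln (Lynch–Dahl).
  The package defaults to c = 0.038, which reproduces both published
  proton resolution anchors for this geometry (5.73 lp/cm at 200 MeV,
  10.0 lp/cm at 350 MeV, both within 5%); c = 1/9 (with ln) is accepted
  as `log_coeff=1/9` for sensitivity studies and shifts σ_scatt by
  about −10%, overshooting the 350 MeV anchor by 16%.  The bracket is
  clamped at zero for paths shorter than X₀·e^(−1/c) so the scattering
  power can never go negative on sub-millimetre paths.
* **Conditioning.**  The envelope σ_scatt(x) is the posterior standard
  deviation of the lateral position given the boundary measurements.
  The beam enters with no angular divergence, so the entry *vector*
  (y₀, θ₀) is known exactly; at the exit the measurement used is the
  crossing *position* only (`conditioning="exit_point"`, the default):
  paths pinned at fixed points.  Conditioning on the full exit vector
  (`"exit_vector"`) tightens the mid-plane σ from 0.63 to 0.46 mm for
  200 MeV protons; the point-conditioned value is the one consistent
  with the published 5.73 lp/cm proton resolution, and is validated
  against the Monte Carlo conditional spread to 1%.  The envelope is
  *not* mid-plane symmetric: the scattering power grows as pv falls, so
  the peak sits at 55–65% depth for protons.  σ_scatt(r) entering the
  MTF is the envelope at mid-depth, the reconstruction point of the
  central voxel.

The posterior is computed per depth grid point (401 points over the
slab by default) from cumulative moment tables, so the whole envelope
costs one depth–energy sweep plus O(n) 2×2 inversions.

## Path ensemble and scattering energy noise

The energy-loss spread induced by scattering is computed over a
deterministic quantile sample of the envelope: path k follows
y_k(x) = z_k σ(x) with z_k the standard-normal quantile at level
(k+½)/n, weight 1/n, n = 65 by default (odd, so the median/straight
path is always present).  Each path's energy loss integrates the
stopping power along its arc length.  The midpoint-quantile
discretisation truncates the Gaussian tails: the sampled lateral
variance is 1.9% below σ² at n = 65 and 1.0% at n = 129; the expected
energy loss itself is stable to < 10⁻⁵ under doubling.  This scaled-
envelope path shape preserves the envelope exactly and is sufficient
because only the induced arc-length distribution enters the noise; it
does not model per-path curvature beyond the envelope scaling.

## Straggling

The Tschalär variance is integrated in energy with adaptive quadrature,
with k₂ = Z² η_e K m_e c² (1 − β²/2)/(1 − β²) per unit path.  Two
normalisation choices are frozen here: the Z² charge scaling (required
by Bohr's formula and by the observed helium/proton noise ratio of
one half at equal range) and the absorbed 2m_ec² factor, fixed once so
the thin-slab limit reproduces Bohr's 0.0871 MeV²/cm for unit charge in
water (asserted to 5% in the tests).  Against the packaged
condensed-history values the analytic σ_WET runs 5–8% high for all five
ions — consistent with a Gaussian Bohr/Tschalär kernel versus a
restricted-loss fluctuation model — which is why σ_WET agreement is
asserted at 10%, not at the tables' printed ~5% statistical bars.
σ_WET is evaluated at the phantom exit; the mid-plane tracker position
only re-bins the same detector measurement.

## SNR, dose and MTF

The SNR and dose formulas are implemented verbatim (see README).  Dose
is reported in MeV/mm³ per unit relative density, with
1 MeV mm⁻³/(g cm⁻³) = 1.602·10⁻⁴ mGy.  Nuclear factors must always be
passed explicitly; a missing factor raises rather than defaulting to 1,
because silently dropping the fluence loss flips the ion ranking.  The
comb convolution of the sampled MTF folds ±3 aliased replicas
(contributions beyond are < 10⁻⁶ for the relevant σ); sinc(k) vanishes
at nonzero integers, so MTF(0) = 1 without renormalisation.  MTF₁₀% is
closed-form for the scattering-only mode and a bracketed root solve
below Nyquist for the complete mode, returning the Nyquist frequency
with a flag when the curve never falls to 10%.  Pixel defaults follow
the study configuration: 1 mm for SNR/dose, 0.25 mm for resolution
figures.

Energy selection implements the two study policies: `fixed_range`
inverts the range integral; `fixed_mtf` solves MTF₁₀% = target (0.05
lp/cm tolerance) subject to the hard floor E_out ≥ 70 MeV/u after the
phantom.  For every ion heavier than hydrogen the floor binds at 10
lp/cm and the selected energies land within 1% of the published
fixed-resolution beam energies.

## Monte Carlo validator

The MC is condensed-history, electromagnetic only, one transverse
plane, 1 mm steps, marched in lockstep over all histories (vectorised;
10⁵ histories through the world take a few seconds).  Per step, in
water: RK4 mean slowing at each history's own energy — which is what
turns the local Bohr kernel into Tschalär-amplified straggling without
any explicit correlation term — plus a Gaussian straggling kick of
variance k₂(E)Δs, plus a correlated (θ, y) kick with the standard step
covariance [[TΔs³/3, TΔs²/2], [TΔs²/2, TΔs]].  The local scattering
power T is the derivative of the cumulative Highland-corrected A₀(t),
evaluated with the bracket term (1+c ln)(1+c ln+2c), so the accumulated
direction variance matches the analytic moments by construction and the
position variance to ~2%.  Air is treated as vacuum.  Nuclear
interactions are absent by design; the packaged g/S_MC factors carry
their effect into the dose equation.  Histories that range out are
recorded as stopped and excluded from exit statistics.  Identical seeds
reproduce identical track streams.

Validation levels (all seeded, tolerances set by the history counts):
straggling-only exit-energy σ within 10% of the Tschalär integral
(measured −1%), MCS-only exit-position σ within 10% of the n = 2 moment
(measured −2%), conditional mid-plane spread within 10% of the envelope
(measured +1%), rear-tracker central σ_WET within 10% of the packaged
proton value (+5%), and the qualitative front-tracker structure: the
proton noise profile has off-centre local maxima (chord-gradient
scattering noise) that fall off again before the edge-overlap spikes,
while carbon's rises monotonically into the edge.

## Synthetic-data scope

The generator (MC + packaged tables) emulates the study conditions:
uniform water cylinder, ideal noise-free trackers at the phantom faces,
no detector energy resolution, no nuclear products in the signal, beams
either pencil or uniform flat fields with zero divergence.  It does not
emulate heterogeneous anatomy, tracker material budget or spacing,
detector noise, or imperfect nuclear-event filtering — so passing tests
bound the *electromagnetic statistical* limits, not end-to-end scanner
performance.  History counts in the tests (2–15·10⁴ per run) are chosen
so each statistical comparison has a few-percent standard error against
a 10% assertion band.

## Known limitations

* Water only; no air gap between trackers and phantom (air ≈ vacuum).
* Gaussian noise models throughout: no Vavilov/Landau straggling tails,
  no non-Gaussian scattering tails, no nuclear-interaction noise.
* The dose/SNR relation is exact only at the centre of a uniform
  cylinder; heterogeneous objects raise the scattering noise,
  disproportionately for light ions.
* Analytic σ_WET carries the 5–8% Bohr-vs-restricted-loss bias noted
  above; resolution values inherit the ~5% model-form uncertainty of
  the Highland-corrected envelope.
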