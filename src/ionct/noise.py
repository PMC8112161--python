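"""Energy-domain noise and its propagation to water-equivalent thickness.

Two independent stochastic processes blur the measured energy loss:

* **Straggling** - fluctuation in the number and size of ion-electron
  collisions.  Its variance at the exit energy follows Tschalar's
  solution of the straggling transport equation,

      sigma^2_strag(E_out) = k1^2(E_out) int_{E_out}^{E_0} k2(E)/k1^3(E) dE,

  where k1 is the stopping power and k2 the straggling power
  (Bohr kernel with the relativistic Tschalar correction),

      k2(E) = Z^2 eta_e K m_e c^2 (1 - beta^2/2) / (1 - beta^2),

  which reduces to Bohr's 0.0871 MeV^2/cm for unit charge in water in
  the thin-slab limit.  The k1^2/k1^3 weighting captures the
  amplification of an energy fluctuation by the larger stopping power
  at lower energy.

* **Scattering (MCS) noise** - particles take different curved paths
  between the trackers, hence traverse different arc lengths and lose
  different amounts of energy: sigma^2_MCS = E[dE^2] - E[dE]^2 over the
  constrained path distribution.

The two add in quadrature, and the WET noise at the detector follows by
first-order propagation through the range integral:
sigma_WET = sigma_E_out / S(E_out).  All sigma^2 here are in *total*
(not per-nucleon) MeV^2, matching the total stopping power.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
import json

import numpy as np
from scipy.integrate import quad

from . import constants
from .ions import IonSpecies, Medium, WATER
from .physics import beta_squared, csda_range, energy_at_depth, stopping_power
from .scattering import PathSet, TrackerGeometry, constrained_envelope, sample_paths

__all__ = [
    "straggling_power",
    "straggling_variance",
    "expected_energy_loss",
    "scattering_energy_variance",
    "wet_from_energies",
    "sigma_wet",
    "NoiseBudget",
    "noise_budget",
]


def straggling_power(E_u, ion: IonSpecies, medium: Medium = WATER):
    """k2(E): straggling variance growth per unit path [MeV^2/mm]."""
    b2 = beta_squared(np.asarray(E_u, dtype=float), ion.m_u)
    out = (
        ion.Z**2
        * medium.eta_e
        * medium.density
        * constants.K_STRAGGLING_WATER
        * (1.0 - 0.5 * b2)
        / (1.0 - b2)
    )
    return out.item() if out.ndim == 0 else out


def straggling_variance(E0_u: float, Eout_u: float, ion: IonSpecies,
                        medium: Medium = WATER) -> float:
    """Tschalar straggling variance of the *total* exit energy [MeV^2]."""
    if Eout_u > E0_u:
        raise ValueError("exit energy cannot exceed the initial energy")
    if Eout_u == E0_u:
        return 0.0
    k1_out = stopping_power(Eout_u, ion, medium)

    def integrand(e_u: float) -> float:
        return (
            straggling_power(e_u, ion, medium)
            / stopping_power(e_u, ion, medium) ** 3
            * ion.A  # dE_total = A dE_u
        )

    val, _ = quad(integrand, Eout_u, E0_u, limit=200)
    return k1_out**2 * val


class _RangeTable:
    """Fine-grid interpolants between energy per nucleon and CSDA range."""

    def __init__(self, ion: IonSpecies, medium: Medium, E_max: float,
                 n: int = 4000) -> None:
        e = np.linspace(constants.E_MIN, E_max, n)
        inv_s = ion.A / stopping_power(e, ion, medium)
        r = np.concatenate(([0.0], np.cumsum(
            0.5 * (inv_s[1:] + inv_s[:-1]) * np.diff(e))))
        self.e, self.r = e, r

    def range_of(self, E_u):
        return np.interp(E_u, self.e, self.r)

    def energy_of(self, R):
        return np.interp(R, self.r, self.e)


@lru_cache(maxsize=32)
def _range_table(ion: IonSpecies, medium: Medium, E_max: float) -> _RangeTable:
    return _RangeTable(ion, medium, E_max)


def _path_energy_losses(paths: PathSet, E0_u: float, ion: IonSpecies,
                        medium: Medium, lateral_bound: float | None
                        ) -> np.ndarray:
    """Per-path energy loss [MeV/u] from the arc length through the slab."""
    if lateral_bound is not None and np.any(np.abs(paths.y) > lateral_bound):
        raise ValueError("a sampled path exits the phantom laterally")
    table = _range_table(ion, medium, max(2.0 * E0_u, 100.0))
    R0 = table.range_of(E0_u)
    arcs = paths.arc_lengths()
    if np.any(arcs >= R0):
        raise ValueError("a sampled path exceeds the particle range")
    return E0_u - table.energy_of(R0 - arcs)


def expected_energy_loss(paths: PathSet, E0_u: float, ion: IonSpecies,
                         medium: Medium = WATER,
                         lateral_bound: float | None = None) -> float:
    """Probability-weighted mean energy loss over the path set [MeV/u].

    Each path's loss is obtained by slowing the ion down along the
    path's arc length; curved paths are longer than the chord, so the
    expectation exceeds the straight-path loss.
    """
    dE = _path_energy_losses(paths, E0_u, ion, medium, lateral_bound)
    return float(np.dot(paths.weights, dE))


def scattering_energy_variance(paths: PathSet, E0_u: float, ion: IonSpecies,
                               medium: Medium = WATER,
                               lateral_bound: float | None = None) -> float:
    """Variance of the *total* energy loss across the path set [MeV^2]."""
    dE = _path_energy_losses(paths, E0_u, ion, medium, lateral_bound) * ion.A
    mean = np.dot(paths.weights, dE)
    return float(np.dot(paths.weights, (dE - mean) ** 2))


def wet_from_energies(E0_u: float, Eout_u: float, ion: IonSpecies,
                      medium: Medium = WATER) -> float:
    """Water-equivalent thickness [mm] of an ``E0 -> E_out`` energy loss.

    WET = int_{E_out}^{E_0} dE / S(E), i.e. the difference of CSDA
    ranges; additive over consecutive segments by construction.
    """
    if Eout_u > E0_u:
        raise ValueError("exit energy cannot exceed the initial energy")
    if Eout_u == E0_u:
        return 0.0
    return csda_range(E0_u, ion, medium) - csda_range(Eout_u, ion, medium)


def sigma_wet(sigma2_E_out: float, Eout_u: float, ion: IonSpecies,
              medium: Medium = WATER) -> float:
    """WET noise [mm]: sigma_E_out / S(E_out), with sigma^2 in MeV^2 total."""
    if sigma2_E_out < 0:
        raise ValueError("variance must be non-negative")
    if Eout_u < constants.E_MIN:
        raise ValueError("exit energy at/below the model validity floor")
    return float(np.sqrt(sigma2_E_out) / stopping_power(Eout_u, ion, medium))


@dataclass(frozen=True)
class NoiseBudget:
    """Quadrature budget of the exit-energy noise and its WET image.

    ``sigma2_strag`` and ``sigma2_mcs`` are variances of the total exit
    energy [MeV^2]; ``sigma_wet`` is their quadrature sum propagated to
    water-equivalent thickness [mm].
    """

    ion_name: str
    E0_u: float
    E_out_u: float
    thickness: float
    sigma2_strag: float
    sigma2_mcs: float
    sigma_wet: float

    @property
    def sigma2_E_out(self) -> float:
        return self.sigma2_strag + self.sigma2_mcs

    @property
    def sigma_E_out(self) -> float:
        return float(np.sqrt(self.sigma2_E_out))

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "ion": self.ion_name,
                "E0_MeV_per_u": self.E0_u,
                "E_out_MeV_per_u": self.E_out_u,
                "thickness_mm": self.thickness,
                "sigma2_strag_MeV2": self.sigma2_strag,
                "sigma2_MCS_MeV2": self.sigma2_mcs,
                "sigma2_E_out_MeV2": self.sigma2_E_out,
                "sigma_WET_mm": self.sigma_wet,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def noise_budget(E0_u: float, ion: IonSpecies, thickness: float = 200.0,
                 medium: Medium = WATER, n_paths: int = 65) -> NoiseBudget:
    """Full analytic noise budget for a beam crossing a uniform slab.

    Combines the Tschalar straggling variance with the path-ensemble MCS
    energy variance (default 65 quantile paths of the constrained
    envelope) and propagates the quadrature sum to sigma_WET at the exit
    plane.
    """
    E_out = energy_at_depth(E0_u, thickness, ion, medium)
    s2_strag = straggling_variance(E0_u, E_out, ion, medium)
    geometry = TrackerGeometry(0.0, thickness)
    env = constrained_envelope(E0_u, ion, geometry, medium)
    paths = sample_paths(env, n_paths)
    s2_mcs = scattering_energy_variance(paths, E0_u, ion, medium)
    sw = sigma_wet(s2_strag + s2_mcs, E_out, ion, medium)
    return NoiseBudget(
        ion_name=ion.name,
        E0_u=E0_u,
        E_out_u=E_out,
        thickness=thickness,
        sigma2_strag=s2_strag,
        sigma2_mcs=s2_mcs,
        sigma_wet=sw,
    )
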