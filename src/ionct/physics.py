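"""Electromagnetic stopping, kinematics and depth-energy transport.

The stopping power is the uncorrected Bethe formula for water,

    S(E) = Z^2 K / beta^2 [ ln(2 m_e c^2 / I * beta^2 gamma^2) - beta^2 ],

with K = 0.1704 MeV/cm the Bethe coefficient for water (0.307075
MeV cm^2/g x Z/A x rho).  Density-effect and shell corrections are
omitted; the model is valid between 1 and ~1000 MeV/u, which covers the
whole imaging regime studied here.  Energies are kinetic energy per
nucleon [MeV/u]; the returned stopping power is the *total* stopping
power of the ion [MeV/mm], so the per-nucleon slowing is ``S/A``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from . import constants
from .ions import IonSpecies, Medium, WATER

__all__ = [
    "beta_squared",
    "pv",
    "stopping_power",
    "csda_range",
    "energy_for_range",
    "energy_at_depth",
    "DepthEnergyProfile",
    "depth_energy_profile",
]


def beta_squared(E_u, m_u: float):
    """(v/c)^2 for kinetic energy per nucleon ``E_u`` [MeV/u]."""
    gamma = 1.0 + np.asarray(E_u, dtype=float) / m_u
    return 1.0 - 1.0 / gamma**2


def pv(E_u, ion: IonSpecies):
    """Momentum times velocity [MeV] (total, for the whole ion).

    Uses the relativistic identity pv = E (E + 2 m) / (E + m) per
    nucleon, scaled by the mass number.  Returns 0 at rest.
    """
    E_u = np.asarray(E_u, dtype=float)
    if np.any(E_u < 0):
        raise ValueError("kinetic energy must be non-negative")
    out = ion.A * E_u * (E_u + 2.0 * ion.m_u) / (E_u + ion.m_u)
    return out.item() if np.isscalar(E_u) or out.ndim == 0 else out


def _check_validity(E_u) -> None:
    if np.any(np.asarray(E_u) < constants.E_MIN):
        raise ValueError(
            f"energy below the {constants.E_MIN} MeV/u validity floor of the "
            "Bethe model"
        )


def stopping_power(E_u, ion: IonSpecies, medium: Medium = WATER):
    """Total electromagnetic stopping power [MeV/mm].

    Scales exactly as Z^2 between ions at equal energy per nucleon.
    Raises for energies below the 1 MeV/u validity floor.
    """
    E_u = np.asarray(E_u, dtype=float)
    _check_validity(E_u)
    b2 = beta_squared(E_u, ion.m_u)
    K = constants.K_BETHE_WATER * medium.eta_e * medium.density
    bracket = np.log(2.0 * constants.M_E_C2 / medium.I * b2 / (1.0 - b2)) - b2
    out = ion.Z**2 * K / b2 * bracket
    return out.item() if out.ndim == 0 else out


def csda_range(E_u: float, ion: IonSpecies, medium: Medium = WATER) -> float:
    """Continuous-slowing-down range [mm]: R = int_0^E dE' / S(E').

    The integral runs down to the 1 MeV/u validity floor; the residual
    range below it (< 0.03 mm for protons) is neglected.
    """
    _check_validity(E_u)
    val, err = quad(
        lambda e: ion.A / stopping_power(e, ion, medium),
        constants.E_MIN,
        E_u,
        limit=200,
    )
    if not np.isfinite(val) or err > 1e-3 * max(val, 1.0):
        raise RuntimeError(
            f"range integral did not converge (value={val}, err={err})"
        )
    return val


def energy_for_range(R: float, ion: IonSpecies, medium: Medium = WATER,
                     E_max: float = 1000.0) -> float:
    """Kinetic energy per nucleon [MeV/u] whose CSDA range equals ``R`` mm."""
    if R <= 0:
        raise ValueError("range must be positive")
    if csda_range(E_max, ion, medium) < R:
        raise ValueError(f"range {R} mm exceeds the integrable domain")
    return brentq(
        lambda e: csda_range(e, ion, medium) - R,
        constants.E_MIN + 1e-9,
        E_max,
        xtol=1e-8,
    )


def energy_at_depth(E0_u: float, x: float, ion: IonSpecies,
                    medium: Medium = WATER, step: float = 0.1) -> float:
    """Residual kinetic energy per nucleon after ``x`` mm of medium.

    Solves dE/dx = -S(E)/A with fixed-step classical RK4 (default step
    0.1 mm).  Raises if the particle ranges out before ``x``.
    """
    if x < 0:
        raise ValueError("depth must be non-negative")
    if x == 0:
        return float(E0_u)
    R = csda_range(E0_u, ion, medium)
    if x >= R:
        raise ValueError(
            f"particle stops inside the medium (range {R:.1f} mm < depth {x} mm)"
        )
    n = max(1, int(np.ceil(x / step)))
    h = x / n
    E = float(E0_u)

    def f(e: float) -> float:
        return -stopping_power(e, ion, medium) / ion.A

    for _ in range(n):
        k1 = f(E)
        k2 = f(E + 0.5 * h * k1)
        k3 = f(E + 0.5 * h * k2)
        k4 = f(E + h * k3)
        E += h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return E


@dataclass(frozen=True)
class DepthEnergyProfile:
    """Kinetic energy, pv and beta tabulated on a depth grid.

    ``E_u`` is strictly decreasing with depth; the grid spans the slab
    the beam crosses (it must end before the range).
    """

    ion: IonSpecies
    medium: Medium
    depth: np.ndarray          # [mm]
    E_u: np.ndarray            # [MeV/u]
    pv: np.ndarray             # [MeV], total
    beta: np.ndarray

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "depth_mm": self.depth,
                "E_MeV_per_u": self.E_u,
                "pv_MeV": self.pv,
                "beta": self.beta,
            }
        ).to_csv(path, index=False)


def depth_energy_profile(E0_u: float, thickness: float, ion: IonSpecies,
                         medium: Medium = WATER, n_points: int = 401
                         ) -> DepthEnergyProfile:
    """Transport ``E0_u`` through ``thickness`` mm on a uniform grid.

    Single RK4 sweep over the grid (the grid spacing, ~0.5 mm at the
    defaults, is the integration step).
    """
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    R = csda_range(E0_u, ion, medium)
    if thickness >= R:
        raise ValueError(
            f"beam does not cross: range {R:.1f} mm < thickness {thickness} mm"
        )
    x = np.linspace(0.0, thickness, n_points)
    h = x[1] - x[0]
    E = np.empty(n_points)
    E[0] = E0_u

    def f(e: float) -> float:
        return -stopping_power(e, ion, medium) / ion.A

    for i in range(n_points - 1):
        e = E[i]
        k1 = f(e)
        k2 = f(e + 0.5 * h * k1)
        k3 = f(e + 0.5 * h * k2)
        k4 = f(e + h * k3)
        E[i + 1] = e + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return DepthEnergyProfile(
        ion=ion,
        medium=medium,
        depth=x,
        E_u=E,
        pv=pv(E, ion),
        beta=np.sqrt(beta_squared(E, ion.m_u)),
    )
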