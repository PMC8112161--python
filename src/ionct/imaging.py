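"""Tomographic figures of merit: SNR, dose at fixed SNR, and the MTF.

For the central voxel of a uniform water cylinder imaged in list mode,

    SNR  = sqrt(3 M a^2 / pi^2) S_w(E_out) sqrt(N_D) RSP_hat / sigma_E_out,

    D_c  = pi^2 SNR^2 sigma_WET^2 g_ph g_dt S_MC(E_c, d/2)
           / (3 a^4 rho RSP_hat^2),

where M is the number of projections, a the pixel size, N_D the detected
particle count, g_ph/g_dt the nuclear fluence-loss factors in phantom and
detector, and S_MC the primary dose per particle in the centre voxel.
The nuclear factors are Monte Carlo inputs (they depend on hadronic
cross-section models outside this package's electromagnetic scope) and
are supplied from the packaged tables.

Spatial resolution is described by the modulation transfer function with
pixel sampling,

    MTF(eps) = sinc(eps a) exp(-2 pi^2 sigma_scatt(r)^2 eps^2) * III_{1/a},

whose comb convolution folds aliased replicas back below the Nyquist
frequency 1/(2a).  The resolution metric is the frequency where the MTF
falls to 10%, in line pairs per cm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from . import constants
from .ions import IonSpecies, Medium, WATER
from .physics import csda_range, energy_at_depth, energy_for_range, stopping_power
from .scattering import TrackerGeometry, constrained_envelope

__all__ = [
    "ImagingScenario",
    "NuclearFactors",
    "MtfCurve",
    "snr",
    "dose_for_snr",
    "dose_in_mgy",
    "mtf",
    "mtf10",
    "mtf10_closed_form",
    "select_energy",
    "EnergySelection",
    "binomial_variance",
    "propagate_dose_uncertainty",
]


@dataclass(frozen=True)
class ImagingScenario:
    """Acquisition geometry and statistics for one tomographic scan.

    Defaults follow the reference configuration: 20 cm water cylinder,
    1 mm pixels for SNR/dose (0.25 mm is used for resolution figures),
    and unit reconstructed RSP for water.
    """

    diameter: float = 200.0     # phantom diameter d [mm]
    pixel_size: float = 1.0     # a [mm]
    projections: int = 360      # M
    n_detected: int = 100       # N_D per pixel
    rsp: float = 1.0            # reconstructed RSP
    density: float = 1.0        # rho [g/cm^3]

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.diameter <= 0:
            raise ValueError("geometry dimensions must be positive")
        if self.projections < 1 or self.n_detected < 1:
            raise ValueError("projections and particle count must be >= 1")


@dataclass(frozen=True)
class NuclearFactors:
    """Nuclear-interaction inputs to the dose equation, with uncertainties.

    ``g_ph``/``g_dt`` are the fluence correction factors (>= 1) for
    primaries lost in the phantom and in the energy detector; ``S_MC``
    is the primary dose per particle in the centre voxel [MeV/mm^3].
    """

    g_ph: float
    g_dt: float
    S_MC: float
    sigma_g_ph: float = 0.0
    sigma_g_dt: float = 0.0
    sigma_S_MC: float = 0.0

    def __post_init__(self) -> None:
        if self.g_ph < 1.0 or self.g_dt < 1.0:
            raise ValueError("attenuation factors must be >= 1")
        if self.S_MC <= 0:
            raise ValueError("S_MC must be positive")
        if min(self.sigma_g_ph, self.sigma_g_dt, self.sigma_S_MC) < 0:
            raise ValueError("uncertainties must be non-negative")


def snr(scenario: ImagingScenario, Eout_u: float, sigma_E_out: float,
        ion: IonSpecies, medium: Medium = WATER) -> float:
    """Signal-to-noise ratio of the reconstructed RSP in the centre voxel.

    ``sigma_E_out`` is the total exit-energy noise [MeV].  SNR grows as
    sqrt(N_D) and linearly with the pixel size.
    """
    if sigma_E_out <= 0:
        raise ValueError("degenerate noise: sigma_E_out must be positive")
    s = scenario
    return float(
        np.sqrt(3.0 * s.projections * s.pixel_size**2 / np.pi**2)
        * stopping_power(Eout_u, ion, medium)
        * np.sqrt(s.n_detected)
        * s.rsp
        / sigma_E_out
    )


def dose_for_snr(target_snr: float, scenario: ImagingScenario,
                 sigma_wet: float, nuclear: NuclearFactors) -> float:
    """Central-voxel dose [MeV/mm^3 / (g/cm^3)] to reach ``target_snr``.

    Quadratic in the SNR and in sigma_WET, and inversely proportional to
    the fourth power of the pixel size.  The nuclear factors must be
    supplied explicitly; they are never silently defaulted to 1.
    """
    if nuclear is None:
        raise ValueError("nuclear factors are required to compute dose")
    if target_snr <= 0 or sigma_wet <= 0:
        raise ValueError("SNR and sigma_WET must be positive")
    s = scenario
    return float(
        np.pi**2
        * target_snr**2
        * sigma_wet**2
        * nuclear.g_ph
        * nuclear.g_dt
        * nuclear.S_MC
        / (3.0 * s.pixel_size**4 * s.density * s.rsp**2)
    )


def dose_in_mgy(dose: float) -> float:
    """Convert a dose from MeV/mm^3 per (g/cm^3) to mGy.

    1 MeV mm^-3 / (g cm^-3) = 10^3 MeV/g = 1.602e-7 Gy.
    """
    return dose * 1e3 * constants.MEV_PER_G_TO_GY * 1e3


@dataclass(frozen=True)
class MtfCurve:
    """MTF sampled on a spatial-frequency grid [lp/mm]."""

    freqs: np.ndarray
    values: np.ndarray
    sigma_scatt: float
    pixel_size: float | None
    mode: str

    @property
    def nyquist(self) -> float | None:
        return None if self.pixel_size is None else 0.5 / self.pixel_size


def _mtf_base(freqs: np.ndarray, sigma: float, a: float) -> np.ndarray:
    return np.sinc(freqs * a) * np.exp(-2.0 * np.pi**2 * sigma**2 * freqs**2)


def mtf(freqs, sigma_scatt: float, pixel_size: float | None = None,
        mode: str = "scattering_only", n_replicas: int = 3) -> MtfCurve:
    """Modulation transfer function of the scattering-blurred system.

    ``scattering_only`` returns the Gaussian factor
    exp(-2 pi^2 sigma^2 eps^2); ``complete`` multiplies by the pixel
    sinc and folds ``n_replicas`` aliased comb replicas at multiples of
    the sampling frequency 1/a.  Frequencies are lp/mm and must be
    non-negative.
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if np.any(freqs < 0):
        raise ValueError("frequencies must be non-negative")
    if sigma_scatt < 0:
        raise ValueError("sigma_scatt must be non-negative")
    if mode == "scattering_only":
        vals = np.exp(-2.0 * np.pi**2 * sigma_scatt**2 * freqs**2)
        return MtfCurve(freqs, vals, sigma_scatt, pixel_size, mode)
    if mode != "complete":
        raise ValueError(f"unknown MTF mode {mode!r}")
    if pixel_size is None or pixel_size <= 0:
        raise ValueError("complete mode requires a positive pixel size")
    a = pixel_size
    vals = np.zeros_like(freqs)
    for k in range(-n_replicas, n_replicas + 1):
        vals += _mtf_base(freqs - k / a, sigma_scatt, a)
    # sinc(k) = 0 at nonzero integers, so MTF(0) = 1 without renormalising
    vals = np.abs(vals)
    return MtfCurve(freqs, vals, sigma_scatt, a, mode)


def mtf10_closed_form(sigma_scatt: float) -> float:
    """Scattering-only MTF 10% frequency [lp/mm]: sqrt(ln 10 / 2 pi^2)/sigma."""
    if sigma_scatt <= 0:
        raise ValueError("sigma_scatt must be positive")
    return float(np.sqrt(np.log(10.0) / (2.0 * np.pi**2)) / sigma_scatt)


def mtf10(E0_u: float, ion: IonSpecies, thickness: float = 200.0,
          medium: Medium = WATER, mode: str = "scattering_only",
          pixel_size: float = 0.25, n_points: int = 401,
          log_coeff: float = constants.HIGHLAND_LOG_COEFF
          ) -> tuple[float, bool]:
    """Spatial resolution [lp/cm] for a beam crossing ``thickness`` mm.

    sigma_scatt is the constrained envelope evaluated at mid-depth (the
    reconstruction point of the central voxel).  Returns ``(frequency,
    capped)`` where ``capped`` flags a complete-mode MTF that stays
    above 10% all the way to the Nyquist frequency.
    """
    env = constrained_envelope(
        E0_u, ion, TrackerGeometry(0.0, thickness), medium,
        n_points=n_points, log_coeff=log_coeff,
    )
    sigma = env.sigma_mid
    if mode == "scattering_only":
        return mtf10_closed_form(sigma) * 10.0, False
    nyq = 0.5 / pixel_size

    def f(eps: float) -> float:
        return float(mtf([eps], sigma, pixel_size, "complete").values[0] - 0.1)

    if f(nyq) > 0:
        return nyq * 10.0, True
    return brentq(f, 1e-6, nyq, xtol=1e-6) * 10.0, False


@dataclass(frozen=True)
class EnergySelection:
    """Outcome of the beam-energy selection policy."""

    E_u: float                  # selected energy [MeV/u]
    mtf10: float                # resolution at that energy [lp/cm]
    E_out_u: float              # exit energy [MeV/u]
    bound_by_exit_energy: bool  # True if the >70 MeV/u floor was binding


def _min_crossing_energy(ion: IonSpecies, thickness: float, medium: Medium,
                         exit_floor: float) -> float:
    """Lowest energy crossing ``thickness`` with exit energy >= floor."""
    target_range = thickness + csda_range(exit_floor, ion, medium)
    return energy_for_range(target_range, ion, medium)


def select_energy(ion: IonSpecies, thickness: float = 200.0,
                  policy: str = "fixed_range", *, R: float | None = None,
                  mtf_target: float | None = None,
                  exit_floor: float = 70.0, medium: Medium = WATER,
                  mtf_tol: float = 0.05) -> EnergySelection:
    """Choose the beam energy for one of the two study policies.

    ``fixed_range`` returns the energy whose CSDA range equals ``R``.
    ``fixed_mtf`` searches (by bracketed root solve, the MTF being
    monotone in energy) for the energy whose scattering-only resolution
    equals ``mtf_target`` [lp/cm], subject to the hard floor that the
    exit energy after ``thickness`` stays above ``exit_floor`` MeV/u;
    if the floor binds, the minimum crossing energy is returned with
    ``bound_by_exit_energy`` set.
    """
    if policy == "fixed_range":
        if R is None or R <= 0:
            raise ValueError("fixed_range policy requires R > 0")
        E = energy_for_range(R, ion, medium)
    elif policy == "fixed_mtf":
        if mtf_target is None or mtf_target <= 0:
            raise ValueError("fixed_mtf policy requires a positive target")
        E_min = _min_crossing_energy(ion, thickness, medium, exit_floor)
        m_min = mtf10(E_min, ion, thickness, medium)[0]
        if m_min >= mtf_target:
            # resolution already at/above target at the lowest usable
            # energy: condition (i) binds
            return EnergySelection(E_min, m_min,
                                   energy_at_depth(E_min, thickness, ion,
                                                   medium), True)
        E_hi = E_min
        for _ in range(12):
            E_hi *= 1.5
            if mtf10(E_hi, ion, thickness, medium)[0] >= mtf_target:
                break
        else:
            raise RuntimeError("MTF target unreachable below 1 GeV/u bracket")
        E = brentq(
            lambda e: mtf10(e, ion, thickness, medium)[0] - mtf_target,
            E_min, E_hi, xtol=mtf_tol,
        )
    else:
        raise ValueError(f"unknown policy {policy!r}")
    m = mtf10(E, ion, thickness, medium)[0]
    return EnergySelection(E, m, energy_at_depth(E, thickness, ion, medium),
                           False)


def binomial_variance(p_eff: float) -> float:
    """Binomial variance p(1-p) of a fractional attenuation estimate."""
    if not 0.0 <= p_eff <= 1.0:
        raise ValueError("p_eff must lie in [0, 1]")
    return p_eff * (1.0 - p_eff)


def propagate_dose_uncertainty(dose: float, sigma_wet: float,
                               sigma_sigma_wet: float,
                               nuclear: NuclearFactors) -> float:
    """First-order uncorrelated error propagation through the dose formula.

    D is a product of powers of its inputs, so the relative variance is
    the quadrature sum of the relative input errors, with sigma_WET
    entering squared (factor 2 on its log-derivative).
    """
    if min(sigma_wet, dose) <= 0:
        raise ValueError("dose and sigma_wet must be positive")
    if sigma_sigma_wet < 0:
        raise ValueError("uncertainties must be non-negative")
    rel2 = (
        (2.0 * sigma_sigma_wet / sigma_wet) ** 2
        + (nuclear.sigma_g_ph / nuclear.g_ph) ** 2
        + (nuclear.sigma_g_dt / nuclear.g_dt) ** 2
        + (nuclear.sigma_S_MC / nuclear.S_MC) ** 2
    )
    return dose * float(np.sqrt(rel2))
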