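"""Multiple-Coulomb-scattering moments and the constrained path envelope.

The lateral spread of a beam in the (y, theta_y) plane is modelled as a
bivariate Gaussian whose covariance follows Fermi-Eyges theory with the
Highland parametrisation of the scattering power:

    A_n(x) = Z^2 E0^2 (1 + c ln(t/X0))^2
             int_{x0}^{x} (x - x')^n dx' / (pv(x')^2 X0),   n = 0, 1, 2,

where t = x - x0 is the traversed path, E0 = 13.6 MeV/c and c is the
logarithmic correction coefficient (Lynch-Dahl 0.038 by default; 1/9 is
accepted for sensitivity studies).  A0 is the direction variance [rad^2],
A1 the position-direction covariance [mm rad], A2 the position variance
[mm^2].

The tracker-constrained envelope is the posterior standard deviation of
the lateral position at each interior depth given the boundary
measurements: the entry *vector* (y0, theta0) - both known exactly for a
pencil beam with no initial divergence - and the exit *position* y1.
It vanishes at both tracker planes and peaks near mid-depth; it is the
sigma_scatt(r) that enters the modulation transfer function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.stats import norm

from . import constants
from .ions import IonSpecies, Medium, WATER
from .physics import DepthEnergyProfile, depth_energy_profile

__all__ = [
    "ScatteringMoments",
    "TrackerGeometry",
    "EnvelopeProfile",
    "PathSet",
    "fermi_eyges_moments",
    "constrained_envelope",
    "sample_paths",
]


@dataclass(frozen=True)
class ScatteringMoments:
    """Fermi-Eyges covariance moments accumulated from ``x0`` to ``x``."""

    x0: float
    x: float
    A0: float  # direction variance [rad^2]
    A1: float  # position-direction covariance [mm rad]
    A2: float  # position variance [mm^2]

    def covariance(self) -> np.ndarray:
        """2x2 covariance of (y, theta_y)."""
        return np.array([[self.A2, self.A1], [self.A1, self.A0]])

    def moment(self, n: int) -> float:
        return {0: self.A0, 1: self.A1, 2: self.A2}[n]


@dataclass(frozen=True)
class TrackerGeometry:
    """Ideal (noise-free) tracker planes at the phantom faces.

    ``y0``/``theta0`` are the entry measurement, ``y1`` the exit
    position measurement; defaults describe an on-axis pencil beam.
    """

    x0: float
    x1: float
    y0: float = 0.0
    theta0: float = 0.0
    y1: float = 0.0

    def __post_init__(self) -> None:
        if self.x1 <= self.x0:
            raise ValueError("exit plane must lie downstream of entry plane")

    @property
    def thickness(self) -> float:
        return self.x1 - self.x0


@dataclass(frozen=True)
class EnvelopeProfile:
    """Constrained lateral path uncertainty sigma_scatt(x) on a depth grid."""

    depth: np.ndarray      # [mm], absolute (tracker frame)
    sigma: np.ndarray      # [mm]
    geometry: TrackerGeometry

    @property
    def sigma_max(self) -> float:
        return float(self.sigma.max())

    @property
    def sigma_mid(self) -> float:
        """Envelope at the mid-plane (the tomographic reconstruction point)."""
        return float(np.interp(0.5 * (self.geometry.x0 + self.geometry.x1),
                               self.depth, self.sigma))

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"depth_mm": self.depth, "sigma_mm": self.sigma}).to_csv(
            path, index=False
        )


class _MomentTable:
    """Cumulative integrals of the reduced scattering power 1/(pv^2 X0).

    Lets segment moments over [x_a, x_b] with an arbitrary lever point be
    evaluated in O(1) from three cumulative tables.
    """

    def __init__(self, profile: DepthEnergyProfile, Z: int,
                 log_coeff: float = constants.HIGHLAND_LOG_COEFF) -> None:
        x = profile.depth
        T0 = 1.0 / (profile.pv**2 * profile.medium.X0)
        self.x = x
        self.X0 = profile.medium.X0
        self.Z = Z
        self.log_coeff = log_coeff
        self.I0 = cumulative_trapezoid(T0, x, initial=0.0)
        self.I1 = cumulative_trapezoid(T0 * x, x, initial=0.0)
        self.I2 = cumulative_trapezoid(T0 * x * x, x, initial=0.0)

    def _log_factor(self, t: float) -> float:
        # clamp at zero for paths shorter than X0 e^{-1/c}: the Highland
        # correction must not drive the scattering power negative
        if t <= 0:
            return 0.0
        return max(0.0, 1.0 + self.log_coeff * np.log(t / self.X0)) ** 2

    def moments(self, ia: int, ib: int, lever: float
                ) -> tuple[float, float, float]:
        """(A0, A1, A2) over grid indices [ia, ib] about ``lever`` [mm]."""
        i0 = self.I0[ib] - self.I0[ia]
        i1 = self.I1[ib] - self.I1[ia]
        i2 = self.I2[ib] - self.I2[ia]
        fac = (self.Z * constants.E0_HIGHLAND) ** 2 * self._log_factor(
            self.x[ib] - self.x[ia]
        )
        A0 = fac * i0
        A1 = fac * (lever * i0 - i1)
        A2 = fac * (lever**2 * i0 - 2.0 * lever * i1 + i2)
        return A0, A1, A2


def fermi_eyges_moments(E0_u: float, ion: IonSpecies, x0: float, x: float,
                        medium: Medium = WATER, n: int | None = None,
                        log_coeff: float = constants.HIGHLAND_LOG_COEFF,
                        n_points: int = 401):
    """Scattering moments accumulated between depths ``x0`` and ``x``.

    With ``n`` in {0, 1, 2} returns that single moment, otherwise the
    full :class:`ScatteringMoments`.  The lever arm of the position
    moments is taken about the evaluation plane ``x``.
    """
    if x < x0:
        raise ValueError("x must be >= x0")
    if x == x0:
        mom = ScatteringMoments(x0, x, 0.0, 0.0, 0.0)
        return mom.moment(n) if n is not None else mom
    profile = depth_energy_profile(E0_u, x - x0, ion, medium, n_points)
    table = _MomentTable(profile, ion.Z, log_coeff)
    A0, A1, A2 = table.moments(0, n_points - 1, lever=x - x0)
    mom = ScatteringMoments(x0, x, A0, A1, A2)
    if n is not None:
        if n not in (0, 1, 2):
            raise ValueError("n must be 0, 1 or 2")
        return mom.moment(n)
    return mom


def constrained_envelope(E0_u: float, ion: IonSpecies,
                         geometry: TrackerGeometry,
                         medium: Medium = WATER,
                         n_points: int = 401,
                         log_coeff: float = constants.HIGHLAND_LOG_COEFF,
                         conditioning: str = "exit_point") -> EnvelopeProfile:
    """Posterior lateral spread given the boundary tracker measurements.

    ``conditioning`` selects the exit-plane information used:

    - ``"exit_point"`` (default): exit position only; the entry (y,
      theta) vector is fully known.  This is the envelope of paths
      pinned at fixed points, the quantity entering the MTF.
    - ``"exit_vector"``: both exit position and direction; the tighter
      envelope appropriate when the rear tracker also measures angle.
    """
    L = geometry.thickness
    profile = depth_energy_profile(E0_u, L, ion, medium, n_points)
    table = _MomentTable(profile, ion.Z, log_coeff)
    x = profile.depth
    sigma = np.zeros(n_points)
    last = n_points - 1
    for i in range(1, last):
        # forward: covariance of (y, theta) at x[i] given the entry vector
        A0, A1, A2 = table.moments(0, i, lever=x[i])
        S1 = np.array([[A2, A1], [A1, A0]])
        # backward: scattering accumulated from x[i] to the exit plane,
        # lever about the exit plane
        B0, B1, B2 = table.moments(i, last, lever=L)
        d = L - x[i]
        prec1 = np.linalg.inv(S1)
        if conditioning == "exit_point":
            v = np.array([1.0, d])
            post = np.linalg.inv(prec1 + np.outer(v, v) / B2)
        elif conditioning == "exit_vector":
            R = np.array([[1.0, d], [0.0, 1.0]])
            S2 = np.array([[B2, B1], [B1, B0]])
            post = np.linalg.inv(prec1 + R.T @ np.linalg.inv(S2) @ R)
        else:
            raise ValueError(f"unknown conditioning {conditioning!r}")
        sigma[i] = np.sqrt(max(post[0, 0], 0.0))
    return EnvelopeProfile(depth=geometry.x0 + x, sigma=sigma,
                           geometry=geometry)


@dataclass(frozen=True)
class PathSet:
    """Quantile paths of the constrained scattering distribution.

    Path k follows y_k(x) = z_k sigma(x) + y_straight(x), with z_k the
    standard-normal quantile at probability level (k + 1/2)/n; each path
    carries weight 1/n.
    """

    depth: np.ndarray          # [mm]
    y: np.ndarray              # (n_paths, n_depth) [mm]
    z: np.ndarray              # quantile scores
    weights: np.ndarray

    @property
    def n_paths(self) -> int:
        return len(self.weights)

    def arc_lengths(self) -> np.ndarray:
        """Arc length of each path [mm] (>= the straight chord)."""
        dx = np.diff(self.depth)
        dy = np.diff(self.y, axis=1)
        return np.sqrt(dx**2 + dy**2).sum(axis=1)

    def lateral_variance(self, x: float) -> float:
        """Weighted lateral variance of the path set at depth ``x``."""
        yx = np.array([np.interp(x, self.depth, yi) for yi in self.y])
        mean = float(np.dot(self.weights, yx))
        return float(np.dot(self.weights, (yx - mean) ** 2))


def sample_paths(envelope: EnvelopeProfile, quantiles: int = 65) -> PathSet:
    """Deterministic quantile sample of the constrained path distribution.

    ``quantiles`` must be odd so the median (straight) path is included.
    A degenerate all-zero envelope yields the single straight path.
    """
    if quantiles < 1 or quantiles % 2 == 0:
        raise ValueError("quantiles must be a positive odd integer")
    g = envelope.geometry
    straight = np.interp(
        envelope.depth, [g.x0, g.x1], [g.y0, g.y1]
    )
    if quantiles == 1 or envelope.sigma_max == 0.0:
        z = np.zeros(1)
    else:
        p = (np.arange(quantiles) + 0.5) / quantiles
        z = norm.ppf(p)
    y = straight[None, :] + z[:, None] * envelope.sigma[None, :]
    w = np.full(len(z), 1.0 / len(z))
    return PathSet(depth=envelope.depth.copy(), y=y, z=z, weights=w)
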