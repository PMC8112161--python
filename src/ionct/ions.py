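"""Ion species and medium descriptors.

The five species compared throughout the package are the light ions in
clinical or pre-clinical use for particle imaging: 1H, 4He, 6Li, 10B and
12C.  An ion is fully described by its charge number Z, mass number A and
rest energy per nucleon; a medium by its density, mean excitation energy,
radiation length and relative electron density (all of which equal the
water values for the uniform water phantom considered here).
"""

from __future__ import annotations

from dataclasses import dataclass

from . import constants


@dataclass(frozen=True)
class IonSpecies:
    """A fully stripped ion, identified by charge and mass number.

    Parameters
    ----------
    name:
        Human-readable label (e.g. ``"helium"``).
    Z:
        Atomic charge number.
    A:
        Mass number.
    m_u:
        Rest energy per nucleon [MeV].
    """

    name: str
    Z: int
    A: int
    m_u: float

    def __post_init__(self) -> None:
        if self.Z < 1:
            raise ValueError(f"Z must be >= 1, got {self.Z}")
        if self.A < self.Z:
            raise ValueError(f"A must be >= Z, got A={self.A}, Z={self.Z}")
        if self.m_u <= 0:
            raise ValueError(f"m_u must be positive, got {self.m_u}")

    @property
    def rest_energy(self) -> float:
        """Total rest energy [MeV]."""
        return self.A * self.m_u


@dataclass(frozen=True)
class Medium:
    """Stopping/scattering medium constants.

    density [g/cm^3], mean excitation energy I [MeV], radiation length
    X0 [mm] and electron density relative to water eta_e.
    """

    label: str
    density: float
    I: float
    X0: float
    eta_e: float

    def __post_init__(self) -> None:
        for field in ("density", "I", "X0", "eta_e"):
            if getattr(self, field) <= 0:
                raise ValueError(f"{field} must be positive")


#: Liquid water with the Geant4 default mean excitation energy.
WATER = Medium(
    label="water",
    density=1.0,
    I=constants.I_WATER,
    X0=constants.X0_WATER,
    eta_e=1.0,
)

PROTON = IonSpecies("proton", 1, 1, constants.M_P_C2)
HELIUM = IonSpecies("helium", 2, 4, constants.M_U_C2)
LITHIUM = IonSpecies("lithium", 3, 6, constants.M_U_C2)
BORON = IonSpecies("boron", 5, 10, constants.M_U_C2)
CARBON = IonSpecies("carbon", 6, 12, constants.M_U_C2)

ION_REGISTRY: dict[str, IonSpecies] = {
    ion.name: ion for ion in (PROTON, HELIUM, LITHIUM, BORON, CARBON)
}


def get_ion(name: str) -> IonSpecies:
    """Look up one of the registered species by name."""
    try:
        return ION_REGISTRY[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown ion {name!r}; registered: {sorted(ION_REGISTRY)}"
        ) from None
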