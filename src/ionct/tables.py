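"""Packaged Monte Carlo parameter tables for the two beam-energy policies.

Two reference scenarios are shipped as plain-CSV fixtures:

* ``fixed_range``  - each ion's energy chosen for a 26 cm range in water,
* ``fixed_mtf``    - each ion's energy chosen for a 10 lp/cm resolution
  target, subject to crossing the phantom with > 70 MeV/u exit energy.

Each row carries the per-ion beam energy, the WET noise measured from
electromagnetic-only radiographs, the nuclear fluence-loss factors for
phantom and detector, the primary central-voxel dose per particle, the
exit energy, and (for the fixed-resolution table) the range and the
achieved resolution.  The two-significant-figure uncertainties are
stored verbatim; the files are integrity-checked against frozen SHA-256
digests on load.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, fields
from importlib import resources

import pandas as pd

from .imaging import NuclearFactors

__all__ = ["IonScenarioRow", "load_fixture", "save_rows", "load_rows",
           "FIXTURE_CHECKSUMS"]

FIXTURE_CHECKSUMS = {
    "fixed_range": "19a583d60986429d6032da4e05a690ce078ac10fa27a93db58203900acfeb7bf",
    "fixed_mtf": "5a4efe6978b68011013b2d04a6bad973807d34ad480837897cd5821d03762f28",
}


class CorruptedFixtureError(RuntimeError):
    pass


@dataclass(frozen=True)
class IonScenarioRow:
    """One ion's Monte Carlo parameters for a beam-energy policy."""

    ion: str
    E_init: float               # [MeV/u]
    sigma_wet: float            # [mm]
    sigma_wet_err: float
    g_ph: float
    g_ph_err: float
    g_dt: float
    g_dt_err: float
    S_MC: float                 # [MeV/mm^3]
    S_MC_err: float
    E_out: float                # [MeV/u]
    range_cm: float | None = None
    mtf10: float | None = None  # [lp/cm]

    def __post_init__(self) -> None:
        for err in (self.sigma_wet_err, self.g_ph_err, self.g_dt_err,
                    self.S_MC_err):
            if err < 0:
                raise ValueError("uncertainties must be non-negative")

    def nuclear_factors(self) -> NuclearFactors:
        return NuclearFactors(
            g_ph=self.g_ph, g_dt=self.g_dt, S_MC=self.S_MC,
            sigma_g_ph=self.g_ph_err, sigma_g_dt=self.g_dt_err,
            sigma_S_MC=self.S_MC_err,
        )


def _fixture_text(table: str) -> str:
    name = f"table_{table}.csv"
    ref = resources.files("ionct.data").joinpath(name)
    text = ref.read_text()
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != FIXTURE_CHECKSUMS[table]:
        raise CorruptedFixtureError(
            f"fixture {name} checksum mismatch: {digest}"
        )
    return text


def load_fixture(table: str = "fixed_range") -> list[IonScenarioRow]:
    """Load the five ion rows of one packaged table.

    ``table`` is ``"fixed_range"`` or ``"fixed_mtf"``.
    """
    if table not in FIXTURE_CHECKSUMS:
        raise ValueError(f"unknown table {table!r}; use fixed_range/fixed_mtf")
    import io

    df = pd.read_csv(io.StringIO(_fixture_text(table)))
    rows = []
    for rec in df.to_dict("records"):
        rows.append(IonScenarioRow(**{
            f.name: rec[f.name] for f in fields(IonScenarioRow)
            if f.name in rec
        }))
    return rows


def save_rows(rows: list[IonScenarioRow], path) -> None:
    """Serialize rows back to CSV (lossless round trip with the loader)."""
    cols = [f.name for f in fields(IonScenarioRow)
            if any(getattr(r, f.name) is not None for r in rows)]
    df = pd.DataFrame([{c: getattr(r, c) for c in cols} for r in rows])
    df.to_csv(path, index=False)


def load_rows(path) -> list[IonScenarioRow]:
    """Read rows from a CSV written by :func:`save_rows`."""
    df = pd.read_csv(path)
    return [
        IonScenarioRow(**{
            f.name: rec[f.name] for f in fields(IonScenarioRow)
            if f.name in rec
        })
        for rec in df.to_dict("records")
    ]
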