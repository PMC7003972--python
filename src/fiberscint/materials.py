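"""Packaged physical constants: photon attenuation and electron range data.

The per-material mass attenuation tables (photoelectric, incoherent/Compton,
pair production; cm^2/g) are shipped as CSV fixtures on a 0.01-6 MeV grid and
interpolated log-log.  Electron ranges use a water CSDA table plus constant
mass-stopping-power ratios per material, which is adequate for the simplified
straight-track electron model used by the transport module.
"""
from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

PROCESSES = ("photoelectric", "compton", "pair")

#: bulk densities, g/cm^3
DENSITY = {
    "water": 1.00,
    "polystyrene": 1.05,
    "pmma": 1.19,
    "fluorpoly": 1.43,
    "epoxy": 1.10,
    "lead": 11.35,
}

#: mass stopping power relative to water (electrons, ~0.1-6 MeV)
STOPPING_RATIO = {
    "water": 1.00,
    "polystyrene": 0.97,
    "pmma": 0.97,
    "fluorpoly": 0.90,
    "epoxy": 0.97,
    "lead": 0.62,
}

#: radiation length, g/cm^2 (for the Highland multiple-scattering angle)
RADIATION_LENGTH = {
    "water": 36.08,
    "polystyrene": 43.79,
    "pmma": 40.55,
    "fluorpoly": 33.0,
    "epoxy": 40.0,
    "lead": 6.37,
}


@dataclass(frozen=True)
class MuTable:
    """Mass attenuation coefficients for one material."""

    material: str
    energy_mev: np.ndarray
    coefficients: dict[str, np.ndarray]   # per process, cm^2/g
    density: float

    @property
    def total(self) -> np.ndarray:
        return sum(self.coefficients[p] for p in PROCESSES)

    def __post_init__(self):
        e = self.energy_mev
        if np.any(np.diff(e) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        for p in PROCESSES:
            if np.any(self.coefficients[p] < 0):
                raise ValueError(f"negative coefficient in {p}")


def _data_path(name: str):
    return resources.files("fiberscint.data").joinpath(name)


@functools.lru_cache(maxsize=None)
def load_mu_table(material: str) -> MuTable:
    """Load the packaged attenuation table for *material*."""
    if material not in DENSITY:
        raise KeyError(f"unknown material {material!r}")
    with _data_path(f"mu_{material}.csv").open() as fh:
        df = pd.read_csv(fh)
    return MuTable(
        material=material,
        energy_mev=df["energy_mev"].to_numpy(),
        coefficients={p: df[p].to_numpy() for p in PROCESSES},
        density=DENSITY[material],
    )


def mu_lookup(table: MuTable, energy_mev, process: str | None = None):
    """Mass attenuation coefficient (cm^2/g) at *energy_mev*, log-log interpolated.

    With ``process=None`` the total is returned.  Energies outside the grid
    are rejected.  Exact at grid nodes.
    """
    e = np.asarray(energy_mev, dtype=float)
    grid = table.energy_mev
    if np.any(e < grid[0]) or np.any(e > grid[-1]):
        raise ValueError(
            f"energy outside table range [{grid[0]}, {grid[-1]}] MeV")
    loge = np.log(e)
    loggrid = np.log(grid)

    def _one(vals):
        # zeros (e.g. pair below threshold) cannot go through log space
        tiny = 1e-300
        out = np.exp(np.interp(loge, loggrid, np.log(np.maximum(vals, tiny))))
        return np.where(out < 1e-250, 0.0, out)

    if process is not None:
        if process == "total":
            return _one(table.total)
        return _one(table.coefficients[process])
    return _one(table.total)


@functools.lru_cache(maxsize=None)
def _csda_water() -> tuple[np.ndarray, np.ndarray]:
    with _data_path("csda_water.csv").open() as fh:
        df = pd.read_csv(fh)
    return df["energy_mev"].to_numpy(), df["csda_g_cm2"].to_numpy()


def csda_range(energy_mev, material: str = "water"):
    """CSDA range in g/cm^2 (log-log interpolation of the water table, scaled
    by the inverse relative mass stopping power of *material*)."""
    e_grid, r_grid = _csda_water()
    e = np.clip(np.asarray(energy_mev, dtype=float), e_grid[0], e_grid[-1])
    r_w = np.exp(np.interp(np.log(e), np.log(e_grid), np.log(r_grid)))
    return r_w / STOPPING_RATIO[material]


def energy_from_water_range(r_g_cm2):
    """Inverse of the water CSDA table: electron energy (MeV) with the given
    residual water-equivalent range."""
    e_grid, r_grid = _csda_water()
    r = np.asarray(r_g_cm2, dtype=float)
    out = np.exp(np.interp(np.log(np.maximum(r, r_grid[0])),
                           np.log(r_grid), np.log(e_grid)))
    return np.where(r <= r_grid[0], e_grid[0], out)
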