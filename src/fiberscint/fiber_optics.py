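"""Analytic optics of the double-clad fiber and the optical readout chain.

Scintillation photons emitted isotropically in the core are guided to a
fiber end when their incidence angle on the cladding exceeds the critical
angle; the meridional-ray solid-angle fraction per end is (1 - n2/n1)/2
with n1 the core and n2 the outer-cladding index.  Bulk absorption follows
a single attenuation length; interface losses use the normal-incidence
Fresnel transmission.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import FiberSpec


@dataclass(frozen=True)
class SpectrumCurve:
    """Tabulated curve over wavelength: emission density or quantum efficiency."""

    wavelength_nm: np.ndarray
    value: np.ndarray
    band: tuple[float, float] = (420.0, 560.0)

    def __post_init__(self):
        wl = np.asarray(self.wavelength_nm, dtype=float)
        v = np.asarray(self.value, dtype=float)
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "value", v)
        if wl.ndim != 1 or wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if v.shape != wl.shape:
            raise ValueError("value/wavelength shape mismatch")
        lo, hi = self.band
        if lo < wl[0] or hi > wl[-1]:
            raise ValueError("band edges outside the wavelength grid")


@dataclass(frozen=True)
class OpticalChain:
    """Transmission factors between fiber end and PMT photocathode."""

    gamma: float = 0.40   # optical switch + long-fiber transmission
    xi: float = 0.85      # fiber-PMT interface (configured constant)
    eta: float = 0.18     # band-averaged PMT optical QE

    def __post_init__(self):
        for name in ("gamma", "xi", "eta"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")

    @property
    def eta_prime(self) -> float:
        return self.eta * self.gamma * self.xi


def acceptance_angles(fiber: FiberSpec) -> tuple[float, float]:
    """Critical angles (degrees from the interface normal) at the
    core/inner-cladding and inner/outer-cladding interfaces."""
    a1 = math.degrees(math.asin(fiber.inner_clad_index / fiber.core_index))
    a2 = math.degrees(math.asin(fiber.outer_clad_index / fiber.inner_clad_index))
    return a1, a2


def trapped_fraction(fiber: FiberSpec, ends: str = "one") -> float:
    """Fraction of isotropically emitted core photons guided to the end(s).

    Meridional-ray solid-angle formula: photons within the cone of half-angle
    90 deg - arcsin(n_outer_clad/n_core) about the fiber axis are totally
    internally reflected all the way down; per end that cone subtends
    (1 - n_outer_clad/n_core)/2 of the full sphere.
    """
    if ends not in ("one", "both"):
        raise ValueError("ends must be 'one' or 'both'")
    f = (1.0 - fiber.outer_clad_index / fiber.core_index) / 2.0
    return 2 * f if ends == "both" else f


def bulk_transmission(path_length_mm, attenuation_length_mm: float):
    """exp(-path/Lambda) survival through the fiber bulk."""
    path = np.asarray(path_length_mm, dtype=float)
    if np.any(path < 0) or attenuation_length_mm <= 0:
        raise ValueError("lengths must be non-negative (attenuation > 0)")
    return np.exp(-path / attenuation_length_mm)


def fresnel_normal(n1: float, n2: float) -> float:
    """Normal-incidence Fresnel transmission between media n1 and n2."""
    if n1 < 1 or n2 < 1:
        raise ValueError("refractive indices must be >= 1")
    r = (n1 - n2) / (n1 + n2)
    return 1.0 - r * r


def mean_optical_qe(qe: SpectrumCurve, emission: SpectrumCurve,
                    band: tuple[float, float] | None = None) -> float:
    """Emission-weighted mean quantum efficiency over the band (trapezoid rule)."""
    lo, hi = band if band is not None else emission.band
    if qe.wavelength_nm[-1] < lo or qe.wavelength_nm[0] > hi:
        raise ValueError("QE and emission curves have disjoint support")
    n = max(emission.wavelength_nm.size, qe.wavelength_nm.size, 64)
    wl = np.linspace(lo, hi, 4 * n)
    w = np.interp(wl, emission.wavelength_nm, emission.value)
    q = np.interp(wl, qe.wavelength_nm, qe.value)
    denom = np.trapezoid(w, wl)
    if denom <= 0:
        raise ValueError("emission curve has no weight in the band")
    return float(np.trapezoid(q * w, wl) / denom)


def pde_thin(counts, pde: float, seed_or_rng) -> np.ndarray:
    """Independent binomial thinning of per-event photon counts."""
    if not 0 < pde <= 1:
        raise ValueError("pde must lie in (0, 1]")
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    counts = counts.astype(np.int64)
    if pde == 1.0:
        return counts.copy()
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    return rng.binomial(counts, pde)


def read_spectrum_csv(path, band: tuple[float, float] = (420.0, 560.0)
                      ) -> SpectrumCurve:
    """Load a two-column (wavelength_nm, value) CSV as a SpectrumCurve."""
    import pandas as pd
    df = pd.read_csv(path)
    wl, val = df.columns[:2]
    return SpectrumCurve(df[wl].to_numpy(), df[val].to_numpy(), band)


def write_spectrum_csv(curve: SpectrumCurve, path,
                       value_name: str = "value") -> None:
    import pandas as pd
    pd.DataFrame({"wavelength_nm": curve.wavelength_nm,
                  value_name: curve.value}).to_csv(path, index=False)


def trapped_fraction_mc(fiber: FiberSpec, n: int = 1_000_000,
                        seed: int = 0, ends: str = "one") -> float:
    """Monte Carlo estimate of the trapped fraction: sample isotropic emission
    directions on the axis and apply the meridional TIR criterion at the
    core/outer-cladding index step."""
    rng = np.random.default_rng(seed)
    cos_t = rng.uniform(-1.0, 1.0, n)
    # incidence on the wall is 90 deg - polar angle: TIR down the fiber
    # requires cos(polar) >= sin(critical) = n_outer/n_core
    sin_crit = fiber.outer_clad_index / fiber.core_index
    if ends == "one":
        trapped = cos_t > sin_crit
    else:
        trapped = np.abs(cos_t) > sin_crit
    return float(np.mean(trapped))
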