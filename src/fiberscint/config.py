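"""Detector configuration: defaults reproduce the studied detector.

The default block is the honeycomb lead/fiber matrix: 1 mm double-clad
fibers, 1.35 mm in-layer pitch, 1.22 mm layer spacing, 2 cm thick.  The
lead/epoxy split of the matrix is anchored to the measured 35% x-ray
absorption efficiency under the default 6-MV spectrum (see the methods
note for why the quoted bulk density is not used for this).

Configs are plain YAML with ``fiber``, ``lattice`` and ``composite``
sections; any omitted key falls back to the defaults.
"""
from __future__ import annotations

import dataclasses
import functools
from pathlib import Path

import yaml

from .beam_attenuation import (EnergySpectrum, build_6mv_spectrum,
                               calibrate_composite_to_absorption)
from .geometry import (CompositeSpec, DetectorSpec, FiberSpec, LatticeSpec,
                       fill_factor)

MEASURED_ABSORPTION_EFFICIENCY = 0.35


@functools.lru_cache(maxsize=4)
def default_spectrum() -> EnergySpectrum:
    return build_6mv_spectrum()


@functools.lru_cache(maxsize=4)
def reference_detector(ae_anchor: float = MEASURED_ABSORPTION_EFFICIENCY
                        ) -> DetectorSpec:
    """The default detector: geometry as published, composite anchored to the
    measured absorption efficiency."""
    fiber = FiberSpec()
    lattice = LatticeSpec()
    ff = fill_factor(lattice, fiber)
    comp = calibrate_composite_to_absorption(
        ff, default_spectrum(), lattice.thickness, ae_anchor, fiber)
    return DetectorSpec(fiber, lattice, comp)


def detector_from_config(cfg: dict) -> DetectorSpec:
    """Build a DetectorSpec from a (possibly partial) config mapping."""
    fiber = FiberSpec(**cfg.get("fiber", {}))
    lattice = LatticeSpec(**cfg.get("lattice", {}))
    comp_cfg = dict(cfg.get("composite", {}))
    ff = fill_factor(lattice, fiber)
    if {"fiber_fraction", "lead_fraction", "epoxy_fraction"} <= comp_cfg.keys():
        comp = CompositeSpec(**comp_cfg)
    else:
        anchor = comp_cfg.get("ae_anchor", MEASURED_ABSORPTION_EFFICIENCY)
        comp = calibrate_composite_to_absorption(
            ff, default_spectrum(), lattice.thickness, anchor, fiber)
    return DetectorSpec(fiber, lattice, comp)


def load_detector(path: str | Path | None = None) -> DetectorSpec:
    if path is None:
        return reference_detector()
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return detector_from_config(cfg)


def detector_report(detector: DetectorSpec) -> dict:
    """JSON-serialisable geometry/composite summary."""
    from .geometry import block_mass
    lat, comp = detector.lattice, detector.composite
    return {
        "fill_factor": fill_factor(detector.lattice, detector.fiber),
        "fiber_fraction": comp.fiber_fraction,
        "lead_fraction": comp.lead_fraction,
        "epoxy_fraction": comp.epoxy_fraction,
        "composite_density_g_cm3": comp.composite_density,
        "block_mass_43x43x2_kg": block_mass(
            (43.0, 43.0, lat.thickness / 10.0), comp.composite_density),
        "n_layers": lat.n_layers,
        "thickness_mm": lat.thickness,
    }


def dump_detector(detector: DetectorSpec, path: str | Path) -> None:
    cfg = {
        "fiber": dataclasses.asdict(detector.fiber),
        "lattice": dataclasses.asdict(detector.lattice),
        "composite": dataclasses.asdict(detector.composite),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
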