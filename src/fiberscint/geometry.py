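"""Honeycomb lattice and composite-material arithmetic.

The energy-conversion block is a honeycomb of double-clad scintillating
fibers running parallel to the beam axis (z), embedded in a lead/epoxy
matrix.  Fibers sit in layers (rows along x) stacked along y; alternate
layers are staggered by half the in-layer pitch.  All lengths are mm
internally; densities are g/cm^3.

Coordinates: x = in-layer pitch direction, y = layer-stacking direction,
z = beam axis (0 at the top face, increasing into the block), origin at the
block centre of the top face.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

MATRIX = "matrix"            # homogenised lead + epoxy between fibers
CORE = "core"
INNER_CLAD = "inner_clad"
OUTER_CLAD = "outer_clad"
OUTSIDE = "outside"


@dataclass(frozen=True)
class FiberSpec:
    """Double-clad scintillating fiber (Kuraray SCSF-78-type defaults)."""

    diameter: float = 1.0                 # mm
    core_index: float = 1.59
    inner_clad_index: float = 1.49
    outer_clad_index: float = 1.42
    inner_clad_fraction: float = 0.03     # of diameter
    outer_clad_fraction: float = 0.01
    core_density: float = 1.05
    inner_clad_density: float = 1.19
    outer_clad_density: float = 1.43
    bulk_attenuation_length: float = 3500.0   # mm
    scintillation_yield: float = 8000.0       # photons / MeV in core

    def __post_init__(self):
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if not (self.core_index > self.inner_clad_index
                > self.outer_clad_index > 1.0):
            raise ValueError("refractive indices must satisfy "
                             "core > inner clad > outer clad > 1")
        for f in (self.inner_clad_fraction, self.outer_clad_fraction):
            if not 0 < f < 0.5:
                raise ValueError("cladding fractions must lie in (0, 0.5)")
        if self.inner_clad_fraction + self.outer_clad_fraction >= 0.5:
            raise ValueError("claddings thicker than the fiber radius")
        if self.scintillation_yield <= 0:
            raise ValueError("scintillation yield must be positive")

    @property
    def r_outer(self) -> float:
        return self.diameter / 2

    @property
    def r_inner(self) -> float:
        return self.r_outer - self.outer_clad_fraction * self.diameter

    @property
    def r_core(self) -> float:
        return self.r_inner - self.inner_clad_fraction * self.diameter

    @property
    def area_fractions(self) -> dict[str, float]:
        """Cross-section area shares of core and claddings within the fiber."""
        ro2, ri2, rc2 = self.r_outer ** 2, self.r_inner ** 2, self.r_core ** 2
        return {CORE: rc2 / ro2,
                INNER_CLAD: (ri2 - rc2) / ro2,
                OUTER_CLAD: (ro2 - ri2) / ro2}

    @property
    def bundle_density(self) -> float:
        """Area-weighted mean density of core + claddings, g/cm^3."""
        a = self.area_fractions
        return (a[CORE] * self.core_density
                + a[INNER_CLAD] * self.inner_clad_density
                + a[OUTER_CLAD] * self.outer_clad_density)


@dataclass(frozen=True)
class LatticeSpec:
    """Staggered fiber lattice: rows along x, stacked along y, fibers along z."""

    in_layer_pitch: float = 1.35      # mm, centre spacing within a layer
    layer_spacing: float = 1.22       # mm, centre spacing between layers
    thickness: float = 20.0           # mm, fiber length along the beam
    layer_offset: float | None = None  # mm stagger; default half pitch
    area_x: float = 313.4             # mm
    area_y: float = 283.2             # mm

    def __post_init__(self):
        if self.layer_spacing <= 0 or self.thickness <= 0:
            raise ValueError("layer spacing and thickness must be positive")
        if self.layer_offset is None:
            object.__setattr__(self, "layer_offset", self.in_layer_pitch / 2)

    @property
    def n_layers(self) -> int:
        return int(math.floor(self.area_y / self.layer_spacing))

    @property
    def cell_area(self) -> float:
        """Unit-cell area per fiber in the transverse plane, mm^2."""
        return self.in_layer_pitch * self.layer_spacing


@dataclass(frozen=True)
class CompositeSpec:
    """Volume-fraction description of the fiber/lead/epoxy composite."""

    fiber_fraction: float
    lead_fraction: float
    epoxy_fraction: float
    fiber_density: float = 1.08       # bundle mean; overridden when derived
    lead_density: float = 11.35
    epoxy_density: float = 1.10

    def __post_init__(self):
        fracs = (self.fiber_fraction, self.lead_fraction, self.epoxy_fraction)
        if any(f < -1e-12 for f in fracs):
            raise ValueError("volume fractions must be non-negative")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("volume fractions must sum to 1")

    @property
    def composite_density(self) -> float:
        return (self.fiber_fraction * self.fiber_density
                + self.lead_fraction * self.lead_density
                + self.epoxy_fraction * self.epoxy_density)

    @property
    def matrix_lead_share(self) -> float:
        """Lead volume share within the non-fiber (matrix) region."""
        m = self.lead_fraction + self.epoxy_fraction
        return self.lead_fraction / m if m > 0 else 0.0

    @property
    def matrix_density(self) -> float:
        s = self.matrix_lead_share
        return s * self.lead_density + (1 - s) * self.epoxy_density


@dataclass(frozen=True)
class DetectorSpec:
    fiber: FiberSpec
    lattice: LatticeSpec
    composite: CompositeSpec

    def __post_init__(self):
        ff = fill_factor(self.lattice, self.fiber)
        if abs(self.composite.fiber_fraction - ff) > 0.005:
            raise ValueError(
                f"composite fiber fraction {self.composite.fiber_fraction:.4f} "
                f"inconsistent with lattice fill factor {ff:.4f}")


# ---------------------------------------------------------------- operations

def fill_factor(lattice: LatticeSpec, fiber: FiberSpec) -> float:
    """Scintillator fill factor: fiber cross-section over unit-cell area."""
    d = fiber.diameter
    if d > lattice.in_layer_pitch or d > lattice.layer_spacing:
        raise ValueError("fibers overlap: diameter exceeds lattice pitch")
    return math.pi * d * d / 4 / lattice.cell_area


def block_mass(dims_cm, composite_density: float) -> float:
    """Mass (kg) of a rectangular block, dimensions in cm, density in g/cm^3."""
    dims = [float(d) for d in dims_cm]
    if any(d < 0 for d in dims):
        raise ValueError("negative dimension")
    return dims[0] * dims[1] * dims[2] * composite_density / 1000.0


def solve_composite(fill: float, target_density: float,
                    fiber_density: float = 1.08,
                    lead_density: float = 11.35,
                    epoxy_density: float = 1.10) -> CompositeSpec:
    """Solve the lead/epoxy volume split so the composite density matches.

    The fiber fraction is fixed (the lattice fill factor); lead + epoxy make
    up the remainder.  Raises if the target is outside the achievable range.
    """
    rest = 1.0 - fill
    lo = fill * fiber_density + rest * min(epoxy_density, lead_density)
    hi = fill * fiber_density + rest * max(epoxy_density, lead_density)
    if not (lo - 1e-9 <= target_density <= hi + 1e-9):
        raise ValueError(
            f"target density {target_density} g/cm^3 unachievable; "
            f"feasible range [{lo:.3f}, {hi:.3f}]")
    if rest == 0:
        return CompositeSpec(fill, 0.0, 0.0, fiber_density,
                             lead_density, epoxy_density)
    lead = (target_density - fill * fiber_density - rest * epoxy_density) \
        / (lead_density - epoxy_density)
    lead = min(max(lead, 0.0), rest)
    return CompositeSpec(fill, lead, rest - lead, fiber_density,
                         lead_density, epoxy_density)


def geometric_blur(sdd_cm: float, thickness_cm: float,
                   field_side_at_iso_cm: float, sad_cm: float = 100.0) -> float:
    """Entry-to-exit radial shift (mm) of the most oblique in-field ray.

    For an unfocused detector the ray to the field edge enters the block at
    radius r*SDD/SAD and exits at r*(SDD+L)/SAD; the lateral traversal over
    the detector depth is r*L/SAD.  Zero on the central axis.
    """
    if not sdd_cm > sad_cm > 0:
        raise ValueError("require SDD > SAD > 0")
    half_field = field_side_at_iso_cm / 2
    return half_field * thickness_cm / sad_cm * 10.0


# ------------------------------------------------------------- point lookup

def fiber_center(lattice: LatticeSpec, layer: int, index: int) -> tuple[float, float]:
    """Transverse centre (x, y) of fiber (layer, index)."""
    xo = lattice.layer_offset if layer % 2 else 0.0
    return index * lattice.in_layer_pitch + xo, layer * lattice.layer_spacing


def locate(x: float, y: float, fiber: FiberSpec, lattice: LatticeSpec):
    """Material and fiber id at transverse point (x, y).

    Returns ``(material, (layer, index) | None)``.  Because the layer spacing
    exceeds the fiber diameter, only the nearest layer can contain the point.
    """
    if abs(x) > lattice.area_x / 2 or abs(y) > lattice.area_y / 2:
        return OUTSIDE, None
    sp = lattice.layer_spacing
    j = round(y / sp)
    dy = y - j * sp
    if abs(dy) > fiber.r_outer:
        return MATRIX, None
    xo = lattice.layer_offset if j % 2 else 0.0
    pitch = lattice.in_layer_pitch
    i = round((x - xo) / pitch)
    dx = x - xo - i * pitch
    r2 = dx * dx + dy * dy
    if r2 <= fiber.r_core ** 2:
        return CORE, (j, i)
    if r2 <= fiber.r_inner ** 2:
        return INNER_CLAD, (j, i)
    if r2 <= fiber.r_outer ** 2:
        return OUTER_CLAD, (j, i)
    return MATRIX, None


# ---------------------------------------------------------------- ray trace

@dataclass(frozen=True)
class RaySegment:
    material: str
    length: float
    fiber: tuple[int, int] | None = None


def _box_clip(p, d, lattice: LatticeSpec):
    """Parameter interval [t0, t1] of the ray inside the block, or None."""
    lo = np.array([-lattice.area_x / 2, -lattice.area_y / 2, 0.0])
    hi = np.array([lattice.area_x / 2, lattice.area_y / 2, lattice.thickness])
    t0, t1 = 0.0, np.inf
    for k in range(3):
        if abs(d[k]) < 1e-15:
            if not (lo[k] - 1e-12 <= p[k] <= hi[k] + 1e-12):
                return None
        else:
            a, b = (lo[k] - p[k]) / d[k], (hi[k] - p[k]) / d[k]
            t0, t1 = max(t0, min(a, b)), min(t1, max(a, b))
    return (t0, t1) if t1 > t0 + 1e-12 else None


def trace_ray(entry, direction, detector: DetectorSpec) -> list[RaySegment]:
    """Ordered material segments of a ray through the block.

    Segment lengths are exact (cylinder-shell intersections in the transverse
    plane); their sum equals the chord length through the block.
    """
    fiber, lattice = detector.fiber, detector.lattice
    p = np.asarray(entry, dtype=float)
    d = np.asarray(direction, dtype=float)
    n = np.linalg.norm(d)
    if n == 0:
        raise ValueError("zero direction")
    d = d / n
    clip = _box_clip(p, d, lattice)
    if clip is None:
        return []
    t0, t1 = clip

    dt2 = math.hypot(d[0], d[1])
    if dt2 < 1e-12:
        # transversely stationary: single material along the whole chord
        mat, fib = locate(p[0], p[1], fiber, lattice)
        return [RaySegment(mat, t1 - t0, fib)]

    # candidate fiber centres near the projected transverse segment
    a0 = p[:2] + t0 * d[:2]
    a1 = p[:2] + t1 * d[:2]
    margin = fiber.r_outer + 1e-9
    sp, pitch = lattice.layer_spacing, lattice.in_layer_pitch
    jmin = int(math.floor((min(a0[1], a1[1]) - margin) / sp))
    jmax = int(math.ceil((max(a0[1], a1[1]) + margin) / sp))
    ts = [t0, t1]
    radii = (fiber.r_core, fiber.r_inner, fiber.r_outer)
    for j in range(jmin, jmax + 1):
        cy = j * sp
        xo = lattice.layer_offset if j % 2 else 0.0
        imin = int(math.floor((min(a0[0], a1[0]) - margin - xo) / pitch))
        imax = int(math.ceil((max(a0[0], a1[0]) + margin - xo) / pitch))
        for i in range(imin, imax + 1):
            cx = i * pitch + xo
            # |p_t + t d_t - c|^2 = r^2
            ox, oy = p[0] - cx, p[1] - cy
            A = d[0] ** 2 + d[1] ** 2
            B = 2 * (ox * d[0] + oy * d[1])
            for r in radii:
                C = ox * ox + oy * oy - r * r
                disc = B * B - 4 * A * C
                if disc <= 0:
                    continue
                sq = math.sqrt(disc)
                for t in ((-B - sq) / (2 * A), (-B + sq) / (2 * A)):
                    if t0 < t < t1:
                        ts.append(t)
    ts = sorted(set(ts))
    segs: list[RaySegment] = []
    for ta, tb in zip(ts[:-1], ts[1:]):
        tm = 0.5 * (ta + tb)
        mat, fib = locate(p[0] + tm * d[0], p[1] + tm * d[1], fiber, lattice)
        if segs and segs[-1].material == mat and segs[-1].fiber == fib:
            segs[-1] = RaySegment(mat, segs[-1].length + (tb - ta), fib)
        else:
            segs.append(RaySegment(mat, tb - ta, fib))
    return segs
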