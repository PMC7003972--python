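"""Desk-scale Monte Carlo of pencil-beam x-ray histories in the fiber block.

Model summary
-------------
Photon transport uses the homogenised composite: photon mean free paths
(>= 4 cm) are ~30x the lattice period (1.35 mm), so attenuation is sampled
from the volume-weighted linear coefficient, and the interaction point is
then placed inside the local unit cell with probability proportional to the
local material's attenuation (transverse equilibrium).  An "aligned" mode is
provided for slit scans, where each ray attenuates in the material column it
actually traverses (the lattice is invariant along the fiber axis).

Electron transport is deliberately simple: a straight track of CSDA range
("csda-line"), marched through the true lattice with per-material stopping
power, or local deposition ("local").  Compton scatter uses the free-electron
Klein-Nishina distribution; pair production splits the available kinetic
energy uniformly between the pair and emits two 511 keV annihilation quanta;
secondary photons are tracked in the homogenised medium until escape or a
10 keV cutoff.

Optical collection uses the meridional acceptance cone and bulk attenuation
(photons crossing into the epoxy are absorbed): each core energy deposit
contributes a Poisson-thinned photon count at the bottom fiber end.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .beam_attenuation import (EnergySpectrum, REGION_MATERIAL,
                               build_6mv_spectrum, region_fractions)
from .fiber_optics import trapped_fraction
from .materials import (PROCESSES, RADIATION_LENGTH, STOPPING_RATIO,
                        csda_range, energy_from_water_range, load_mu_table,
                        mu_lookup)
from .geometry import DetectorSpec

MEC2 = 0.51099895
_EGRID = np.geomspace(0.01, 6.0, 241)
_LOGE = np.log(_EGRID)


@dataclass(frozen=True)
class McConfig:
    """Pencil-beam run configuration."""

    n_histories: int = 10_000
    seed: int = 0
    spectrum: EnergySpectrum | None = None        # default 6-MV model
    beam_center: tuple[float, float] = (0.0, 0.0)  # a fiber axis, mm
    footprint: tuple[float, float] = (1.0, 1.0)    # mm (x, y)
    electron_mode: str = "csda-mcs"     # or "csda-line" (straight) / "local"
    beam_mode: str = "equilibrium"                 # or "aligned"
    track_scatter: bool = True
    cutoff_mev: float = 0.010
    step_mm: float = 0.05
    roi_radius: float | None = None     # transverse score cut around roi_center
    roi_center: tuple[float, float] = (0.0, 0.0)
    readout_fiber: tuple[int, int] = (0, 0)   # (layer, index) tallied separately
    store_fiber_detail: bool = False

    def __post_init__(self):
        if self.n_histories < 0:
            raise ValueError("n_histories must be >= 0")
        if self.footprint[0] <= 0 or self.footprint[1] <= 0:
            raise ValueError("footprint must be positive")
        if self.electron_mode not in ("csda-mcs", "csda-line", "local"):
            raise ValueError(
                "electron_mode must be 'csda-mcs', 'csda-line' or 'local'")
        if self.beam_mode not in ("equilibrium", "aligned"):
            raise ValueError("beam_mode must be 'equilibrium' or 'aligned'")


@dataclass
class EventTally:
    event_id: int
    energy_mev: float
    interacted: bool
    deposit_core_mev: float
    deposit_total_mev: float
    photons_total: int
    photons_readout: int
    photons_by_fiber: dict | None = None


@dataclass
class TallyRun:
    """Columnar per-event tallies plus the run configuration echo."""

    config: McConfig
    detector: DetectorSpec
    energy_mev: np.ndarray
    interacted: np.ndarray
    deposit_core_mev: np.ndarray
    deposit_total_mev: np.ndarray
    photons_total: np.ndarray
    photons_readout: np.ndarray
    fiber_detail: list | None = None

    def __len__(self):
        return self.energy_mev.size

    @property
    def interaction_fraction(self) -> float:
        return float(np.mean(self.interacted)) if len(self) else 0.0

    def events(self):
        for i in range(len(self)):
            yield EventTally(
                i, float(self.energy_mev[i]), bool(self.interacted[i]),
                float(self.deposit_core_mev[i]), float(self.deposit_total_mev[i]),
                int(self.photons_total[i]), int(self.photons_readout[i]),
                None if self.fiber_detail is None else self.fiber_detail[i])

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({
            "event_id": np.arange(len(self)),
            "energy_mev": self.energy_mev,
            "interacted": self.interacted.astype(int),
            "deposit_core_mev": self.deposit_core_mev,
            "deposit_total_mev": self.deposit_total_mev,
            "photons_total": self.photons_total,
            "photons_readout": self.photons_readout,
        })


# ---------------------------------------------------------------- physics

class _Physics:
    """Precomputed cross-section and geometry constants for one detector."""

    def __init__(self, detector: DetectorSpec):
        self.detector = detector
        fib, lat = detector.fiber, detector.lattice
        comp = detector.composite

        # region -> (linear mu per process on _EGRID, total, rho, stopping)
        self.materials = {}
        mu_total_max = np.zeros_like(_EGRID)
        mu_hom = np.zeros_like(_EGRID)
        fracs = region_fractions(detector)
        for region, matname in REGION_MATERIAL.items():
            table = load_mu_table(matname)
            per = {p: table.density * mu_lookup(table, _EGRID, p)
                   for p in PROCESSES}
            tot = sum(per.values())
            self.materials[region] = {
                "per_process": per, "total": tot,
                "rho": table.density,
                "stop": STOPPING_RATIO[matname],
                "x0": RADIATION_LENGTH[matname],
            }
            mu_total_max = np.maximum(mu_total_max, tot)
            mu_hom += fracs[region] * tot
        # non-fiber space is a lead/epoxy homogenate for point classification:
        # the matrix region is represented by lead and epoxy separately via
        # sub-sampling with the matrix lead share
        self.matrix_lead_share = comp.matrix_lead_share
        self.mu_hom = mu_hom
        self.mu_max = mu_total_max
        self.log_mu_hom = np.log(mu_hom)

        # geometry constants (mm)
        self.sp = lat.layer_spacing
        self.pitch = lat.in_layer_pitch
        self.off = lat.layer_offset
        self.thick = lat.thickness
        self.ax2 = lat.area_x / 2
        self.ay2 = lat.area_y / 2
        self.rc2 = fib.r_core ** 2
        self.ri2 = fib.r_inner ** 2
        self.ro2 = fib.r_outer ** 2

        # matrix (lead/epoxy homogenate) bulk properties for electron steps
        s = comp.matrix_lead_share
        rho_m = comp.matrix_density
        if rho_m > 0:
            w_pb = s * 11.35 / rho_m
            w_ep = 1.0 - w_pb
            self.matrix_stop = w_pb * STOPPING_RATIO["lead"] \
                + w_ep * STOPPING_RATIO["epoxy"]
            self.matrix_x0 = 1.0 / (w_pb / RADIATION_LENGTH["lead"]
                                    + w_ep / RADIATION_LENGTH["epoxy"])
        else:
            self.matrix_stop, self.matrix_x0 = 1.0, RADIATION_LENGTH["epoxy"]
        self.matrix_rho = rho_m

        self.yield_per_mev = fib.scintillation_yield
        self.trap_one_end = trapped_fraction(fib, "one")
        self.att_len = fib.bulk_attenuation_length

        # water CSDA interpolation arrays
        self._loge = _LOGE

    # -- geometry ---------------------------------------------------------
    def locate(self, x: float, y: float):
        """(region, fiber_id) at a transverse point; matrix split lead/epoxy
        is NOT resolved here (see sample_matrix_material)."""
        if abs(x) > self.ax2 or abs(y) > self.ay2:
            return "outside", None
        j = round(y / self.sp)
        dy = y - j * self.sp
        if dy * dy > self.ro2:
            return "matrix", None
        xo = self.off if j % 2 else 0.0
        i = round((x - xo) / self.pitch)
        dx = x - xo - i * self.pitch
        r2 = dx * dx + dy * dy
        if r2 <= self.rc2:
            return "core", (j, i)
        if r2 <= self.ri2:
            return "inner_clad", (j, i)
        if r2 <= self.ro2:
            return "outer_clad", (j, i)
        return "matrix", None

    def resolve_matrix(self, rng) -> str:
        """Assign a matrix point to lead or epoxy by volume share."""
        return "lead" if rng.random() < self.matrix_lead_share else "epoxy"

    # -- lookups ----------------------------------------------------------
    def mu_region(self, region: str, e: float) -> float:
        return float(np.interp(math.log(e), self._loge,
                               self.materials[region]["total"]))

    def mu_homogenised(self, e: float) -> float:
        return float(np.interp(math.log(e), self._loge, self.mu_hom))

    def mu_max_at(self, e: float) -> float:
        return float(np.interp(math.log(e), self._loge, self.mu_max))

    def process_probs(self, region: str, e: float) -> tuple:
        per = self.materials[region]["per_process"]
        x = math.log(e)
        vals = [float(np.interp(x, self._loge, per[p])) for p in PROCESSES]
        s = sum(vals)
        return tuple(v / s for v in vals)


_PHYS_CACHE: dict[int, _Physics] = {}


def _physics(detector: DetectorSpec) -> _Physics:
    key = id(detector)
    if key not in _PHYS_CACHE:
        if len(_PHYS_CACHE) > 8:
            _PHYS_CACHE.clear()
        _PHYS_CACHE[key] = _Physics(detector)
    return _PHYS_CACHE[key]


# ------------------------------------------------------------ interactions

def _sample_compton(k: float, rng) -> tuple[float, float]:
    """Sample the scattered-photon energy fraction and cos(theta) from the
    free-electron Klein-Nishina distribution (mixture + rejection)."""
    emin = 1.0 / (1.0 + 2.0 * k)
    a1 = math.log(1.0 / emin)
    a2 = 0.5 * (1.0 - emin * emin)
    while True:
        if rng.random() * (a1 + a2) < a1:
            eps = emin * math.exp(a1 * rng.random())
        else:
            eps = math.sqrt(emin * emin + (1.0 - emin * emin) * rng.random())
        t = (1.0 - eps) / (k * eps)
        sin2 = t * (2.0 - t)
        if rng.random() <= 1.0 - eps * sin2 / (1.0 + eps * eps):
            return eps, 1.0 - t


def _rotate(direction, cos_t: float, phi: float):
    """Direction at polar angle about *direction* with azimuth *phi*."""
    wx, wy, wz = direction
    sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    # orthonormal frame
    if abs(wz) < 0.99:
        ux, uy, uz = -wy, wx, 0.0
    else:
        ux, uy, uz = 1.0, 0.0, 0.0
    n = math.sqrt(ux * ux + uy * uy + uz * uz)
    ux, uy, uz = ux / n, uy / n, uz / n
    vx = wy * uz - wz * uy
    vy = wz * ux - wx * uz
    vz = wx * uy - wy * ux
    cp, sp_ = math.cos(phi), math.sin(phi)
    return (sin_t * (cp * ux + sp_ * vx) + cos_t * wx,
            sin_t * (cp * uy + sp_ * vy) + cos_t * wy,
            sin_t * (cp * uz + sp_ * vz) + cos_t * wz)


def sample_interaction(energy_mev: float, material: str, rng,
                       detector: DetectorSpec | None = None,
                       direction=(0.0, 0.0, 1.0)):
    """Sample the interaction process and its secondaries in *material*.

    Returns ``(process, secondaries)`` where secondaries is a list of
    ``("e-"|"e+"|"gamma", energy, direction)`` tuples.
    """
    phys = _physics(detector if detector is not None else _default_detector())
    region = material if material in phys.materials else "core"
    if material in ("lead", "epoxy"):
        region = material
    p_pe, p_co, p_pp = phys.process_probs(region, energy_mev)
    u = rng.random()
    if u < p_pe:
        return "photoelectric", [("e-", energy_mev, direction)]
    if u < p_pe + p_co:
        k = energy_mev / MEC2
        eps, cos_tg = _sample_compton(k, rng)
        e_sc = eps * energy_mev
        e_el = energy_mev - e_sc
        phi = 2 * math.pi * rng.random()
        d_g = _rotate(direction, cos_tg, phi)
        # electron polar angle from Compton kinematics
        half = math.sqrt(max(1e-30, (1.0 - cos_tg) / 2.0))   # sin(theta_g/2)
        ch = math.sqrt(max(0.0, 1.0 - half * half))
        tan_half = half / max(ch, 1e-15)
        theta_e = math.atan2(1.0, (1.0 + k) * tan_half)
        d_e = _rotate(direction, math.cos(theta_e), phi + math.pi)
        return "compton", [("e-", e_el, d_e), ("gamma", e_sc, d_g)]
    # pair production
    e_kin = energy_mev - 2 * MEC2
    u_split = rng.random()
    return "pair", [("e-", u_split * e_kin, direction),
                    ("e+", (1 - u_split) * e_kin, direction)]


_DEFAULT_DET = None


def _default_detector():
    global _DEFAULT_DET
    if _DEFAULT_DET is None:
        from .config import reference_detector
        _DEFAULT_DET = reference_detector()
    return _DEFAULT_DET


# ------------------------------------------------------- electron transport

def deposit_electron(energy_mev: float, origin, direction,
                     detector: DetectorSpec, mode: str, rng,
                     step_mm: float = 0.05):
    """March an electron track and split its energy deposit by region.

    Modes: ``csda-mcs`` (default) marches a condensed-history track of CSDA
    length with Highland multiple-Coulomb-scattering deflections each step;
    ``csda-line`` is the same track without deflections; ``local`` deposits
    everything at the origin.

    Returns ``(per_material, core_deposits, escaped_mev)`` where
    *per_material* maps region name to MeV and *core_deposits* is a list of
    ``(fiber_id, deposit_mev, z_mid_mm)`` entries.
    """
    phys = _physics(detector)
    x, y, z = origin
    per_material: dict[str, float] = {}
    core: list = []
    if energy_mev <= 0:
        return per_material, core, 0.0
    region0, fiber0 = phys.locate(x, y)
    if region0 == "outside" or not 0.0 <= z <= phys.thick:
        return per_material, core, energy_mev
    if mode == "local":
        mat = phys.resolve_matrix(rng) if region0 == "matrix" else region0
        per_material[mat] = per_material.get(mat, 0.0) + energy_mev
        if region0 == "core":
            core.append((fiber0, energy_mev, z))
        return per_material, core, 0.0
    scatter = mode == "csda-mcs"

    dx, dy, dz = direction
    n = math.sqrt(dx * dx + dy * dy + dz * dz)
    dx, dy, dz = dx / n, dy / n, dz / n
    r_rem = float(csda_range(energy_mev))   # water-equivalent g/cm^2
    e_curr = energy_mev
    # march in fixed steps, flushing deposits at material-segment boundaries
    # (and every ~0.5 mm so the energy used for the scattering angle stays
    # fresh near the end of the track)
    seg_region, seg_fiber = region0, fiber0
    seg_mass = 0.0          # water-equivalent mass in current segment
    seg_zsum = 0.0
    seg_len = 0.0
    escaped = 0.0

    def flush():
        nonlocal seg_mass, seg_zsum, seg_len, e_curr, r_rem
        if seg_mass <= 0:
            return
        r_new = r_rem - seg_mass
        if r_new <= 1e-6:
            de = e_curr
            e_new = 0.0
        else:
            e_new = float(energy_from_water_range(r_new))
            de = max(0.0, e_curr - e_new)
        mat = seg_region
        if mat == "matrix":
            mat = phys.resolve_matrix(rng)
        per_material[mat] = per_material.get(mat, 0.0) + de
        if seg_region == "core" and de > 0:
            core.append((seg_fiber, de, seg_zsum / max(seg_len, 1e-12)))
        e_curr = e_new
        r_rem = max(r_new, 0.0)
        seg_mass = 0.0
        seg_zsum = 0.0
        seg_len = 0.0

    while r_rem > 1e-6 and e_curr > 0:
        x += dx * step_mm
        y += dy * step_mm
        z += dz * step_mm
        if not (0.0 <= z <= phys.thick):
            flush()
            escaped = e_curr
            e_curr = 0.0
            break
        region, fiber = phys.locate(x, y)
        if region == "outside":
            flush()
            escaped = e_curr
            e_curr = 0.0
            break
        if region != seg_region or fiber != seg_fiber:
            flush()
            if e_curr <= 0:
                break
            seg_region, seg_fiber = region, fiber
        elif seg_len >= 0.5:
            flush()
            if e_curr <= 0:
                break
        if region == "matrix":
            rho, stop, x0 = phys.matrix_rho, phys.matrix_stop, phys.matrix_x0
        else:
            m = phys.materials[region]
            rho, stop, x0 = m["rho"], m["stop"], m["x0"]
        dm = step_mm * rho * stop / 10.0      # g/cm^2 water-equivalent
        last = dm >= r_rem - seg_mass
        if last:
            dm = r_rem - seg_mass
        seg_mass += dm
        seg_zsum += z * step_mm
        seg_len += step_mm
        if last:
            flush()
            break
        if scatter:
            # Highland plane-projected rms angle for this step
            pc2 = e_curr * (e_curr + 2 * MEC2)
            beta_pc = pc2 / (e_curr + MEC2)
            t_rad = step_mm * rho / 10.0 / x0
            theta0 = 0.0
            if t_rad > 0:
                corr = max(0.25, 1.0 + 0.038 * math.log(t_rad))
                theta0 = min(13.6 / beta_pc * math.sqrt(t_rad) * corr, 1.2)
            if theta0 > 0:
                g1, g2, g3 = rng.standard_normal(3)
                # remove the component along the current direction
                dot = g1 * dx + g2 * dy + g3 * dz
                px, py, pz = g1 - dot * dx, g2 - dot * dy, g3 - dot * dz
                dx += theta0 * px
                dy += theta0 * py
                dz += theta0 * pz
                nn = math.sqrt(dx * dx + dy * dy + dz * dz)
                dx, dy, dz = dx / nn, dy / nn, dz / nn
    flush()
    return per_material, core, escaped


# ------------------------------------------------------------ scintillation

def scintillate_and_collect(core_deposits, fiber_spec, pde: float, rng,
                            thickness_mm: float | None = None):
    """Poisson scintillation photons per core deposit, thinned by the
    one-end trapping fraction, bulk transmission to the bottom end and PDE.

    *core_deposits*: iterable of ``(fiber_id, deposit_mev, z_mm)``.
    Returns ``(collected, detected)`` dicts keyed by fiber id (collected is
    at PDE 1).
    """
    if not 0 < pde <= 1:
        raise ValueError("pde must lie in (0, 1]")
    thick = thickness_mm if thickness_mm is not None else 20.0
    trap = trapped_fraction(fiber_spec, "one")
    lam_by_fiber: dict = {}
    for fiber_id, dep, z in core_deposits:
        if dep <= 0:
            continue
        surv = trap * math.exp(-(thick - z) / fiber_spec.bulk_attenuation_length)
        lam_by_fiber[fiber_id] = (lam_by_fiber.get(fiber_id, 0.0)
                                  + fiber_spec.scintillation_yield * dep * surv)
    collected = {f: int(rng.poisson(lam)) for f, lam in lam_by_fiber.items()}
    if pde == 1.0:
        detected = dict(collected)
    else:
        detected = {f: int(rng.binomial(n, pde)) for f, n in collected.items()}
    return collected, detected


# ----------------------------------------------------------------- main run

def run_pencil_beam(config: McConfig, detector: DetectorSpec) -> TallyRun:
    """Run the pencil-beam Monte Carlo and tally per-event optical photons.

    Bit-exactly reproducible for a fixed seed: each history uses its own
    counter-derived random stream, so results are independent of execution
    order.
    """
    phys = _physics(detector)
    spectrum = config.spectrum if config.spectrum is not None \
        else build_6mv_spectrum()
    n = config.n_histories
    edges, pmf = spectrum.bin_edges, spectrum.fluence
    cdf = np.cumsum(pmf)

    energy = np.zeros(n)
    interacted = np.zeros(n, dtype=bool)
    dep_core = np.zeros(n)
    dep_total = np.zeros(n)
    m_total = np.zeros(n, dtype=np.int64)
    m_readout = np.zeros(n, dtype=np.int64)
    detail = [] if config.store_fiber_detail else None

    bx, by = config.beam_center
    fx, fy = config.footprint
    rx, ry = config.roi_center
    roi2 = None if config.roi_radius is None else config.roi_radius ** 2
    readout = config.readout_fiber
    thick_mm = phys.thick

    for idx in range(n):
        rng = np.random.default_rng((config.seed, idx))
        # --- primary energy and interaction point
        e0 = _sample_energy(rng, edges, cdf)
        energy[idx] = e0
        x = bx + (rng.random() - 0.5) * fx
        y = by + (rng.random() - 0.5) * fy
        if config.beam_mode == "aligned":
            region, fib = phys.locate(x, y)
            if region == "outside":
                continue
            mat = region
            if region == "matrix":
                mat = phys.resolve_matrix(rng)
            mu = phys.mu_region(mat, e0)
            path_mm = -math.log(rng.random()) / mu * 10.0
            if path_mm > thick_mm:
                continue
            z = path_mm
            birth = (x, y, z, mat, fib)
        else:
            mu = phys.mu_homogenised(e0)
            path_mm = -math.log(rng.random()) / mu * 10.0
            if path_mm > thick_mm:
                continue
            z = path_mm
            birth = _equilibrium_point(phys, rng, x, y, z, e0)
            if birth is None:
                continue
        interacted[idx] = True

        if roi2 is not None:
            bx_, by_ = birth[0], birth[1]
            if (bx_ - rx) ** 2 + (by_ - ry) ** 2 > roi2:
                continue    # interaction counted, light cannot reach the ROI

        core_deps, per_mat = _cascade(phys, config, rng, birth, e0)
        dep_total[idx] = sum(per_mat.values())
        dep_core[idx] = per_mat.get("core", 0.0)
        collected, _ = scintillate_and_collect(
            core_deps, detector.fiber, 1.0, rng, thickness_mm=thick_mm)
        m_total[idx] = sum(collected.values())
        m_readout[idx] = collected.get(readout, 0)
        if detail is not None:
            detail.append(collected)

    return TallyRun(config, detector, energy, interacted, dep_core,
                    dep_total, m_total, m_readout, detail)


def _sample_energy(rng, edges, cdf) -> float:
    u = rng.random()
    b = int(np.searchsorted(cdf, u))
    b = min(b, edges.size - 2)
    lo, hi = edges[b], edges[b + 1]
    return lo + (hi - lo) * rng.random()


def _equilibrium_point(phys: _Physics, rng, x0, y0, z, e0):
    """Place the interaction in the unit cell around (x0, y0) with
    probability proportional to the local linear attenuation."""
    mu_max = phys.mu_max_at(e0)
    for _ in range(200):
        x = x0 + (rng.random() - 0.5) * phys.pitch
        y = y0 + (rng.random() - 0.5) * phys.sp
        region, fib = phys.locate(x, y)
        if region == "outside":
            continue
        mat = region
        if region == "matrix":
            mat = phys.resolve_matrix(rng)
        if rng.random() * mu_max <= phys.mu_region(mat, e0):
            return (x, y, z, mat, fib)
    return None


def _cascade(phys: _Physics, config: McConfig, rng, birth, e0):
    """Process the interaction cascade; returns (core deposits, per-material)."""
    detector = phys.detector
    core_deps: list = []
    per_mat: dict[str, float] = {}
    # photon stack entries: (x, y, z, energy, direction, material-or-None)
    photons = [(birth[0], birth[1], birth[2], e0, (0.0, 0.0, 1.0),
                birth[3], birth[4])]
    guard = 0
    while photons and guard < 64:
        guard += 1
        x, y, z, e, d, mat, fib = photons.pop()
        if e < config.cutoff_mev:
            per_mat[mat or "epoxy"] = per_mat.get(mat or "epoxy", 0.0) + e
            continue
        process, secondaries = sample_interaction(e, mat, rng, detector, d)
        for kind, es, ds in secondaries:
            if kind == "gamma":
                if not config.track_scatter or es < config.cutoff_mev:
                    continue
                nxt = _photon_flight(phys, rng, (x, y, z), ds, es)
                if nxt is not None:
                    photons.append(nxt)
                continue
            # electron or positron
            pm, cd, _ = deposit_electron(es, (x, y, z), ds, detector,
                                         config.electron_mode, rng,
                                         config.step_mm)
            for m, v in pm.items():
                per_mat[m] = per_mat.get(m, 0.0) + v
            core_deps.extend(cd)
            if kind == "e+" and config.track_scatter:
                phi = 2 * math.pi * rng.random()
                ct = 2 * rng.random() - 1
                da = _rotate((0.0, 0.0, 1.0), ct, phi)
                for sgn in (1.0, -1.0):
                    dd = (sgn * da[0], sgn * da[1], sgn * da[2])
                    nxt = _photon_flight(phys, rng, (x, y, z), dd, MEC2)
                    if nxt is not None:
                        photons.append(nxt)
    return core_deps, per_mat


def _photon_flight(phys: _Physics, rng, origin, direction, energy):
    """Fly a secondary photon through the homogenised block; return its next
    interaction site (with a locally resolved material) or None on escape."""
    mu = phys.mu_homogenised(energy)
    s_mm = -math.log(rng.random()) / mu * 10.0
    x = origin[0] + direction[0] * s_mm
    y = origin[1] + direction[1] * s_mm
    z = origin[2] + direction[2] * s_mm
    if not (0.0 <= z <= phys.thick) or abs(x) > phys.ax2 or abs(y) > phys.ay2:
        return None
    pt = _equilibrium_point(phys, rng, x, y, z, energy)
    if pt is None:
        return None
    return (pt[0], pt[1], z, energy, direction, pt[3], pt[4])
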