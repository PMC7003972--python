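"""Slit-method spatial-resolution pipeline.

A narrow slit beam is scanned across the detector; the single-fiber reading
versus slit position is the raw line spread function (LSF).  A companion
"no-slit" scan (slit rotated off alignment, leakage through the blocks)
provides the background.  The corrected LSF is symmetrised about its peak,
its tails are extended with a fitted exponential, and the modulus of the
Fourier transform, normalised at zero frequency, is the MTF.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ScanProfile:
    """Position-signal series from a slit scan."""

    positions: np.ndarray            # mm, strictly increasing
    slit: np.ndarray | None = None   # raw slit readings
    noslit: np.ndarray | None = None
    lsf: np.ndarray | None = None    # corrected LSF
    axis: str = "y"

    def __post_init__(self):
        p = np.asarray(self.positions, dtype=float)
        if p.ndim != 1 or p.size < 2 or np.any(np.diff(p) <= 0):
            raise ValueError("positions must be strictly increasing")
        object.__setattr__(self, "positions", p)
        for name in ("slit", "noslit", "lsf"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != p.shape:
                    raise ValueError(f"{name} readings do not match positions")
                object.__setattr__(self, name, v)

    @property
    def step(self) -> float:
        d = np.diff(self.positions)
        if np.ptp(d) > 1e-6 * d.mean():
            raise ValueError("non-uniform position grid")
        return float(d.mean())


@dataclass(frozen=True)
class MtfResult:
    frequency: np.ndarray     # mm^-1
    mtf: np.ndarray
    f50: float | None         # None when the MTF never falls to 0.5
    fwhm: float | None        # mm, from the LSF

    def __post_init__(self):
        if abs(self.mtf[0] - 1.0) > 1e-9:
            raise ValueError("MTF must be normalised to 1 at zero frequency")


# ---------------------------------------------------------------- pipeline

def correct_lsf(slit: ScanProfile, noslit: ScanProfile) -> ScanProfile:
    """Elementwise slit - noslit; negative residuals (noise) are allowed."""
    if not np.array_equal(slit.positions, noslit.positions):
        raise ValueError("slit and no-slit scans use different position grids")
    s = slit.slit if slit.slit is not None else slit.lsf
    b = noslit.noslit if noslit.noslit is not None else noslit.slit
    if s is None or b is None:
        raise ValueError("missing readings")
    return ScanProfile(slit.positions, slit=s, noslit=b, lsf=s - b,
                       axis=slit.axis)


def _center(profile: ScanProfile, values: np.ndarray) -> float:
    """Centroid of the top-3 samples (leftmost wins ties)."""
    order = np.argsort(-values, kind="stable")[:3]
    w = values[order]
    if np.all(w <= 0):
        raise ValueError("flat or non-positive profile has no centre")
    return float(np.sum(profile.positions[order] * w) / np.sum(w))


def symmetrize_lsf(profile: ScanProfile) -> ScanProfile:
    """Centre the LSF on its peak and average the mirrored half-profiles."""
    v = profile.lsf if profile.lsf is not None else profile.slit
    if v is None:
        raise ValueError("no LSF values")
    if np.ptp(v) == 0:
        raise ValueError("flat profile cannot be symmetrised")
    c = _center(profile, v)
    step = profile.step
    half_span = min(c - profile.positions[0], profile.positions[-1] - c)
    n_half = int(math.floor(half_span / step))
    xs = np.arange(-n_half, n_half + 1) * step
    right = np.interp(c + xs, profile.positions, v)
    left = np.interp(c - xs, profile.positions, v)
    # mirror-average: value at +x and -x averaged -> exactly symmetric
    sym = 0.5 * (right + left)
    return ScanProfile(xs, lsf=sym, axis=profile.axis)


def extend_tails(profile: ScanProfile, fit_fraction: float = 0.3,
                 stop_rel: float = 1e-4) -> ScanProfile:
    """Fit a single exponential to each outer tail and extend the grid until
    the modelled amplitude falls below *stop_rel* of the peak.

    Fits least squares on log-values of the strictly positive tail samples;
    fewer than 3 usable points on a side is an error, except when the tail
    has already decayed below the stopping threshold (nothing to extend).
    """
    v = (profile.lsf if profile.lsf is not None else profile.slit).copy()
    x = profile.positions
    step = profile.step
    peak = float(v.max())
    if peak <= 0:
        raise ValueError("non-positive profile")
    n = v.size
    n_fit = max(int(round(fit_fraction * (n // 2))), 3)

    def fit_side(xs, ys):
        if ys.max() < stop_rel * peak:
            return None          # compactly supported side: nothing to do
        mask = ys > 0
        if mask.sum() < 3:
            raise ValueError("fewer than 3 positive tail points to fit")
        coef = np.polyfit(xs[mask], np.log(ys[mask]), 1)
        return coef   # slope, intercept of log-linear model

    out_x = [x]
    out_v = [v]
    span = x[-1] - x[0]    # cap: never extend further than the scanned span
    fit_r = fit_side(x[-n_fit:], v[-n_fit:])
    if fit_r is not None and fit_r[0] < 0:
        slope_r, icpt_r = fit_r
        x_stop = min((math.log(stop_rel * peak) - icpt_r) / slope_r,
                     x[-1] + span)
        if x_stop > x[-1]:
            xs = np.arange(x[-1] + step, x_stop + step, step)
            out_x.append(xs)
            out_v.append(np.exp(icpt_r + slope_r * xs))
    fit_l = fit_side(x[:n_fit], v[:n_fit])
    if fit_l is not None and fit_l[0] > 0:
        slope_l, icpt_l = fit_l
        x_stop = max((math.log(stop_rel * peak) - icpt_l) / slope_l,
                     x[0] - span)
        if x_stop < x[0]:
            xs = np.arange(x[0] - step, x_stop - step, -step)[::-1]
            out_x.insert(0, xs)
            out_v.insert(0, np.exp(icpt_l + slope_l * xs))
    xx = np.concatenate(out_x)
    vv = np.concatenate(out_v)
    order = np.argsort(xx)
    return ScanProfile(xx[order], lsf=vv[order], axis=profile.axis)


def mtf_from_lsf(profile: ScanProfile) -> MtfResult:
    """Modulus of the discrete Fourier transform, unity at zero frequency."""
    v = profile.lsf if profile.lsf is not None else profile.slit
    step = profile.step            # raises on non-uniform grids
    spec = np.abs(np.fft.rfft(v))
    if spec[0] == 0:
        raise ValueError("zero-sum LSF cannot be normalised")
    mtf = spec / spec[0]
    freq = np.fft.rfftfreq(v.size, d=step)
    f50 = _crossing(freq, mtf, 0.5)
    fwhm = lsf_fwhm(profile)
    return MtfResult(freq, mtf, f50, fwhm)


def _crossing(xs, ys, level):
    """Lowest x where ys crosses *level* downward (linear interpolation)."""
    below = np.nonzero(ys < level)[0]
    if below.size == 0:
        return None
    i = below[0]
    if i == 0:
        return float(xs[0])
    x0, x1, y0, y1 = xs[i - 1], xs[i], ys[i - 1], ys[i]
    return float(x0 + (level - y0) * (x1 - x0) / (y1 - y0))


def lsf_fwhm(profile: ScanProfile) -> float | None:
    """Full width at half maximum by linear interpolation of the crossings."""
    v = profile.lsf if profile.lsf is not None else profile.slit
    x = profile.positions
    peak_i = int(np.argmax(v))
    half = v[peak_i] / 2.0
    if v[peak_i] <= 0:
        return None
    left = None
    for i in range(peak_i, 0, -1):
        if v[i - 1] < half <= v[i]:
            left = x[i - 1] + (half - v[i - 1]) / (v[i] - v[i - 1]) \
                * (x[i] - x[i - 1])
            break
    right = None
    for i in range(peak_i, v.size - 1):
        if v[i] >= half > v[i + 1]:
            right = x[i] + (half - v[i]) / (v[i + 1] - v[i]) \
                * (x[i + 1] - x[i])
            break
    if left is None or right is None:
        return None
    return float(right - left)


def resolution_metrics(result: MtfResult,
                       lsf: ScanProfile | None = None) -> dict:
    """f50 (mm^-1) and LSF FWHM (mm); out-of-range metrics are None."""
    fwhm = lsf_fwhm(lsf) if lsf is not None else result.fwhm
    return {"f50_mm^-1": result.f50, "fwhm_mm": fwhm}


def process_scan(slit: ScanProfile, noslit: ScanProfile,
                 fit_fraction: float = 0.3) -> tuple[MtfResult, ScanProfile]:
    """Full pipeline: background correction, symmetrisation, tail extension,
    Fourier transform.  Returns the MTF and the corrected symmetric LSF."""
    corrected = correct_lsf(slit, noslit)
    sym = symmetrize_lsf(corrected)
    ext = extend_tails(sym, fit_fraction)
    res = mtf_from_lsf(ext)
    return MtfResult(res.frequency, res.mtf, res.f50, lsf_fwhm(sym)), sym


# ------------------------------------------------------------- MC slit scan

def apply_crosstalk_kernel(profile: ScanProfile, fraction: float,
                           length_mm: float = 2.0) -> ScanProfile:
    """Optical cross-talk through the epoxy channels between fibers.

    Along the in-layer (x) direction the fibers are connected by thin
    transparent epoxy channels, so a fraction of each fiber's light leaks to
    its neighbours.  Modelled as convolution with a normalised kernel
    (1-f) delta + f exp(-|x|/l); off by default in the simulator.
    """
    if not 0 <= fraction < 1:
        raise ValueError("cross-talk fraction must lie in [0, 1)")
    v = profile.slit if profile.slit is not None else profile.lsf
    if fraction == 0:
        return profile
    step = profile.step
    half = int(math.ceil(5 * length_mm / step))
    xs = np.arange(-half, half + 1) * step
    kern = np.exp(-np.abs(xs) / length_mm)
    kern = fraction * kern / kern.sum()
    kern[half] += 1 - fraction
    out = np.convolve(v, kern, mode="same")
    return ScanProfile(profile.positions, slit=out, noslit=profile.noslit,
                       lsf=None if profile.lsf is None else out,
                       axis=profile.axis)


def simulate_slit_scan(detector, n_histories_per_pos: int = 3000,
                       slit_width_mm: float = 0.08,
                       scan_range_mm: tuple[float, float] = (-15.0, 15.0),
                       step_mm: float = 0.25, axis: str = "y",
                       slit_length_mm: float = 8.0,
                       leakage_fraction: float = 0.042,
                       noise_rel: float = 0.01, seed: int = 0,
                       roi_radius_mm: float = 16.0,
                       crosstalk_fraction: float = 0.0,
                       crosstalk_length_mm: float = 2.0,
                       spectrum=None) -> tuple[ScanProfile, ScanProfile]:
    """Monte Carlo slit scan: per-position detected signal in the readout
    fiber with the pencil beam confined to the slit aperture.

    The no-slit (background) profile is a constant leakage level - the stated
    transmission through the slit blocks times the reconstructed open-beam
    signal - plus the same relative measurement noise.
    """
    from .transport import McConfig, run_pencil_beam

    if slit_width_mm <= 0 or step_mm <= 0:
        raise ValueError("slit width and step must be positive")
    lo, hi = scan_range_mm
    positions = np.arange(lo, hi + step_mm / 2, step_mm)
    signals = np.empty(positions.size)
    for k, pos in enumerate(positions):
        if axis == "y":
            center, footprint = (0.0, pos), (slit_length_mm, slit_width_mm)
        else:
            center, footprint = (pos, 0.0), (slit_width_mm, slit_length_mm)
        cfg = McConfig(
            n_histories=n_histories_per_pos,
            seed=int(np.random.SeedSequence((seed, k)).generate_state(1)[0]
                     % (2 ** 31)),
            spectrum=spectrum,
            beam_center=center, footprint=footprint,
            beam_mode="aligned", roi_radius=roi_radius_mm,
            roi_center=(0.0, 0.0))
        run = run_pencil_beam(cfg, detector)
        signals[k] = float(run.photons_readout.sum())

    # leakage background: transmission through the blocks times the open
    # (slit-removed) signal; the open signal is the scan integral divided by
    # the slit aperture
    open_signal = float(np.sum(signals) * step_mm / slit_width_mm)
    leak = leakage_fraction * open_signal * slit_width_mm / (hi - lo)
    rng = np.random.default_rng((seed, 987))
    if crosstalk_fraction > 0 and axis == "x":
        prof = apply_crosstalk_kernel(
            ScanProfile(positions, slit=signals, axis=axis),
            crosstalk_fraction, crosstalk_length_mm)
        signals = prof.slit
    slit_read = signals + leak
    noslit_read = np.full_like(signals, leak)
    if noise_rel > 0:
        scale = noise_rel * max(slit_read.max(), 1.0)
        slit_read = slit_read + rng.normal(0.0, scale, slit_read.size)
        noslit_read = noslit_read + rng.normal(0.0, scale, noslit_read.size)
    return (ScanProfile(positions, slit=slit_read, axis=axis),
            ScanProfile(positions, noslit=noslit_read, axis=axis))
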