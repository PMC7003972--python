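"""Seeded generators emulating every measured input of the study.

Each generator returns its data together with a ground-truth dict so every
downstream pipeline stage can be exercised as a closed recovery loop
(generate -> analyse -> compare to truth).  The default measurement noise is
1% relative Gaussian, matching the quoted LINAC output stability.
"""
from __future__ import annotations

import numpy as np

from .fiber_optics import SpectrumCurve
from .mtf import ScanProfile
from .scatter import FieldSeries
from .sensitivity import ChargeSample, PmtChain

DEFAULT_NOISE = 0.01


def _rng(seed):
    return (seed if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed))


def gen_emission_spectrum(peak_nm: float = 450.0,
                          band: tuple[float, float] = (420.0, 560.0),
                          noise: float = DEFAULT_NOISE, seed=0,
                          n_replicates: int = 78,
                          grid_nm=None):
    """Replicated emission spectra: an asymmetric peaked curve confined to
    the band, plus zero-mean noise everywhere (so the replicate mean outside
    the band tends to zero, as in background-subtracted measurements).

    Returns ``(replicates, mean_curve, truth)``; replicates is an
    (n_replicates, n_wavelength) array.
    """
    rng = _rng(seed)
    lo, hi = band
    wl = np.asarray(grid_nm, dtype=float) if grid_nm is not None \
        else np.arange(lo - 20.0, hi + 20.0 + 1e-9, 1.0)
    # skewed gamma-like shape: fast rise to the peak, slow decay to the red edge
    a = 2.0
    b = (peak_nm - lo) / a
    u = np.clip(wl - lo, 0.0, None)
    shape = (u / (a * b)) ** a * np.exp(a - u / b)
    shape[(wl < lo) | (wl > hi)] = 0.0
    peak_val = shape.max()
    reps = shape[None, :] + rng.normal(0.0, noise * max(peak_val, 1e-12),
                                       (n_replicates, wl.size))
    mean = reps.mean(axis=0)
    truth = {"peak_nm": float(wl[np.argmax(shape)]), "band": band,
             "noise": noise, "seed": seed}
    return reps, SpectrumCurve(wl, np.clip(mean, 0, None), band), truth


def gaussian_lsf(x_mm, sigma_mm: float = 0.6, amplitude: float = 1.0):
    return amplitude * np.exp(-np.asarray(x_mm) ** 2 / (2 * sigma_mm ** 2))


def gen_slit_scan(lsf_params: dict | None = None,
                  leakage: float = 0.05, noise: float = DEFAULT_NOISE,
                  seed=0, scan_range=(-15.0, 15.0), step: float = 0.25,
                  axis: str = "y"):
    """Synthetic slit / no-slit scan pair from a parametric true LSF.

    ``lsf_params``: ``{"kind": "gaussian", "sigma": 0.6, "amplitude": 1.0}``
    or ``{"kind": "gauss+exp", "sigma": ..., "tail_frac": ..., "tail_len": ...}``.
    Leakage is a constant background level relative to the LSF amplitude.
    """
    rng = _rng(seed)
    p = {"kind": "gaussian", "sigma": 0.6, "amplitude": 1.0}
    p.update(lsf_params or {})
    x = np.arange(scan_range[0], scan_range[1] + step / 2, step)
    if p["kind"] == "gaussian":
        true_lsf = gaussian_lsf(x, p["sigma"], p["amplitude"])
        fwhm = 2.0 * np.sqrt(2 * np.log(2)) * p["sigma"]
    elif p["kind"] == "gauss+exp":
        core = gaussian_lsf(x, p["sigma"], p["amplitude"])
        tail = (p.get("tail_frac", 0.2) * p["amplitude"]
                * np.exp(-np.abs(x) / p.get("tail_len", 2.0)))
        true_lsf = core + tail
        half = true_lsf.max() / 2
        above = x[true_lsf >= half]
        fwhm = float(above[-1] - above[0])
    else:
        raise ValueError(f"unknown LSF kind {p['kind']!r}")
    bkg = leakage * p["amplitude"]
    sd = noise * p["amplitude"]
    slit = true_lsf + bkg + rng.normal(0.0, sd, x.size)
    noslit = bkg + rng.normal(0.0, sd, x.size)
    truth = {"lsf": true_lsf, "fwhm_mm": fwhm, "params": p,
             "leakage": bkg, "noise": noise, "seed": seed}
    return (ScanProfile(x, slit=slit, axis=axis),
            ScanProfile(x, noslit=noslit, axis=axis), truth)


def gen_field_series(primary: float = 1.0, spr_curve=None,
                     noise: float = DEFAULT_NOISE, seed=0,
                     field_cm=None, air_gap_cm: float = 15.0,
                     sdd_cm: float = 145.0, phantom: bool = True):
    """Total-signal series T(fs) = P (1 + SPR(fs)) + noise.

    ``spr_curve`` maps field side (cm) to SPR; default is a linear rise
    typical of a mid-range air gap.
    """
    rng = _rng(seed)
    fs = np.asarray(field_cm, dtype=float) if field_cm is not None \
        else np.array([3.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0])
    if spr_curve is None:
        def spr_curve(f):
            return 0.012 * f
    spr = np.asarray([spr_curve(f) for f in fs], dtype=float)
    if np.any(spr < 0):
        raise ValueError("SPR curve must be non-negative")
    t = primary * (1.0 + spr)
    t_noisy = t + rng.normal(0.0, noise * primary, fs.size)
    truth = {"primary": primary, "spr": spr, "noise": noise, "seed": seed}
    return FieldSeries(fs, t_noisy, air_gap_cm, sdd_cm, phantom), truth


def gen_pmt_samples(nph_mean: float, chain: PmtChain, n: int = 146,
                    light: str = "poisson", overdispersion: float = 3.0,
                    seed=0):
    """Forward-simulate repeated PMT charge readings.

    Per reading: photon count N from the light model, detected electrons
    n ~ Binomial(N, eta'), anode charge Q = e * sum of n cascade gains with
    mean G and variance G^2/(delta - 1) (gamma-distributed, so the sum is
    again gamma).  Light models: "poisson", "deterministic", or
    "overdispersed" (negative binomial with variance = overdispersion*mean).
    """
    if n < 2:
        raise ValueError("need at least 2 repeats")
    rng = _rng(seed)
    mu = float(nph_mean)
    if light == "poisson":
        nph = rng.poisson(mu, n)
        sigma_ph = np.sqrt(mu)
    elif light == "deterministic":
        nph = np.full(n, round(mu), dtype=np.int64)
        sigma_ph = 0.0
    elif light == "overdispersed":
        var = overdispersion * mu
        p_nb = mu / var
        r_nb = mu * p_nb / (1 - p_nb)
        nph = rng.negative_binomial(r_nb, p_nb, n)
        sigma_ph = np.sqrt(var)
    else:
        raise ValueError(f"unknown light model {light!r}")
    ep = chain.eta_prime
    n_pe = rng.binomial(nph, ep)
    # sum of n_pe iid gamma gains (shape delta-1, scale G/(delta-1))
    shape = chain.delta - 1.0
    scale = chain.gain / shape
    total_gain = np.where(n_pe > 0,
                          rng.gamma(np.maximum(n_pe, 1) * shape, scale),
                          0.0)
    charges = chain.e * total_gain
    truth = {"nph_mean": float(np.mean(nph)), "sigma_ph": float(sigma_ph),
             "nph_nominal": mu, "light": light, "seed": seed}
    return ChargeSample(charges), truth


def gen_dose_series(slope: float = 1.0, intercept: float = 0.0,
                    dose_range=(10.0, 250.0), n_points: int = 9,
                    noise: float = DEFAULT_NOISE, seed=0,
                    quadratic: float = 0.0):
    """Linear dose-response series with optional quadratic contamination.

    ``quadratic`` is the relative deviation from linearity at the top dose.
    """
    rng = _rng(seed)
    d = np.linspace(dose_range[0], dose_range[1], n_points)
    s = slope * d + intercept
    if quadratic:
        s = s * (1.0 + quadratic * (d / dose_range[1]) ** 2)
    s_noisy = s + rng.normal(0.0, noise * np.max(np.abs(s)), d.size)
    truth = {"slope": slope, "intercept": intercept, "noise": noise,
             "quadratic": quadratic, "seed": seed}
    return d, s_noisy, truth
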