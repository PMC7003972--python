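"""Scatter-to-primary analysis by zero-field-size extrapolation.

The measured detector signal at a finite field size is primary + scatter,
T = P + S.  The primary is recovered by extrapolating T versus field size to
zero field; SPR = (T - P)/P.  The extrapolated primary is validated by its
inverse-square-like SDD dependence P ~ 1/(SDD (SDD + L)) for a detector of
thickness L, and by the air-gap independence of R0 = P/P'.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit


@dataclass(frozen=True)
class FieldSeries:
    """Total signal vs field size at fixed air gap / SDD."""

    field_cm: np.ndarray            # field side lengths at isocentre
    total: np.ndarray               # signals
    air_gap_cm: float = 15.0
    sdd_cm: float = 145.0
    phantom: bool = True

    def __post_init__(self):
        f = np.asarray(self.field_cm, dtype=float)
        t = np.asarray(self.total, dtype=float)
        if np.any(np.diff(f) <= 0):
            raise ValueError("field sizes must be strictly increasing")
        if t.shape != f.shape:
            raise ValueError("signal/field shape mismatch")
        object.__setattr__(self, "field_cm", f)
        object.__setattr__(self, "total", t)


@dataclass(frozen=True)
class SprResult:
    field_cm: np.ndarray
    spr: np.ndarray
    primary: float
    primary_se: float
    air_gap_cm: float
    intercept: float = 0.0
    slope: float = 0.0


def extrapolate_primary(series: FieldSeries,
                        regressor: str = "side") -> tuple[float, float]:
    """Least-squares linear extrapolation of signal to zero field size.

    ``regressor`` is the field side length (default) or "area".  Returns the
    intercept (the primary signal P) and its standard error.
    """
    if series.field_cm.size < 3:
        raise ValueError("need at least 3 field sizes to extrapolate")
    x = series.field_cm if regressor == "side" else series.field_cm ** 2
    coef, cov = np.polyfit(x, series.total, 1, cov=True)
    p = float(coef[1])
    se = float(np.sqrt(cov[1, 1]))
    return p, se


def compute_spr(total, primary: float):
    """SPR = (T - P)/P."""
    if primary <= 0:
        raise ValueError("primary signal must be positive")
    return (np.asarray(total, dtype=float) - primary) / primary


def spr_from_series(series: FieldSeries,
                    regressor: str = "side") -> SprResult:
    """Extrapolate the primary and report SPR per field size."""
    p, se = extrapolate_primary(series, regressor)
    x = series.field_cm if regressor == "side" else series.field_cm ** 2
    coef = np.polyfit(x, series.total, 1)
    spr = compute_spr(series.total, p)
    if np.any(np.diff(spr) < -4 * se / max(p, 1e-30)):
        import warnings
        warnings.warn("SPR not monotone in field size beyond fit noise",
                      stacklevel=2)
    return SprResult(series.field_cm, spr, p, se, series.air_gap_cm,
                     intercept=p, slope=float(coef[0]))


def fit_inverse_square(sdd_cm, primaries, thickness_cm: float | None = None):
    """Fit P = C / (SDD (SDD + L)).

    With *thickness_cm* given, L is fixed (one-parameter fit); otherwise both
    C and L are estimated.  Returns ``(C, L, residuals)``.
    """
    sdd = np.asarray(sdd_cm, dtype=float)
    p = np.asarray(primaries, dtype=float)
    if sdd.size < 3:
        raise ValueError("need at least 3 SDD points")
    if np.ptp(sdd) < 20:
        raise ValueError("SDD range too narrow (< 20 cm) to constrain the fit")

    if thickness_cm is None:
        def model(s, c, L):
            return c / (s * (s + L))
        c0 = p[0] * sdd[0] * (sdd[0] + 2.0)
        popt, _ = curve_fit(model, sdd, p, p0=[c0, 2.0])
        c_fit, l_fit = float(popt[0]), float(popt[1])
    else:
        def model(s, c):
            return c / (s * (s + thickness_cm))
        c0 = p[0] * sdd[0] * (sdd[0] + thickness_cm)
        popt, _ = curve_fit(model, sdd, p, p0=[c0])
        c_fit, l_fit = float(popt[0]), float(thickness_cm)
    resid = p - c_fit / (sdd * (sdd + l_fit))
    return c_fit, l_fit, resid


def compute_r0(p_with, p_without, air_gaps_cm=None,
               se_with=None, se_without=None) -> dict:
    """R0 = P/P' per air gap, with the constancy check over AG >= 15 cm.

    Flags air-gap dependence when the spread across large air gaps exceeds
    twice the combined standard error (the electron-contamination signature
    at small gaps is reported separately, not as a failure).
    """
    pw = np.atleast_1d(np.asarray(p_with, dtype=float))
    po = np.atleast_1d(np.asarray(p_without, dtype=float))
    if np.any(pw <= 0) or np.any(po <= 0):
        raise ValueError("primary signals must be positive")
    if pw.shape != po.shape:
        raise ValueError("mismatched primary series")
    r0 = pw / po
    ags = (np.asarray(air_gaps_cm, dtype=float) if air_gaps_cm is not None
           else np.full(r0.shape, np.nan))
    out = {"air_gap_cm": ags, "r0": r0}
    if se_with is not None and se_without is not None:
        se = r0 * np.sqrt((np.asarray(se_with) / pw) ** 2
                          + (np.asarray(se_without) / po) ** 2)
    else:
        se = np.zeros_like(r0)
    out["r0_se"] = se
    large = ags >= 15.0
    if large.sum() >= 2:
        spread = float(np.ptp(r0[large]))
        comb = float(2 * np.sqrt(np.mean(se[large] ** 2))) if se[large].any() \
            else 0.0
        out["ag_independent"] = bool(spread <= max(comb, 0.02 * r0[large].mean()))
        out["spread_large_ag"] = spread
    small = ags < 15.0
    if small.any() and large.any():
        out["small_gap_excess"] = float(r0[small].mean() - r0[large].mean())
    return out
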