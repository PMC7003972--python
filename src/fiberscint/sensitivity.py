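"""PMT readout chain: charge-photon conversion and noise transfer.

The mean number of scintillation photons reaching the PMT per reading is
recovered from the measured anode charge,

    Nph = Q / (e eta G gamma xi),

and the optical-signal rms follows from the noise-transfer relation through
a binomial detection stage and a stochastic gain cascade,

    sigma_d^2/e^2 = G^2 eta'^2 sigma_ph^2
                    + G^2 <Nph> eta'(1 - eta')
                    + eta' <Nph> sigma_PMT^2,

with eta' = eta gamma xi and sigma_PMT^2 = G^2/(delta - 1) the excess-noise
variance of a cascade with mean per-stage gain delta.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fiber_optics import OpticalChain

E_CHARGE = 1.602176634e-19   # C


class ChainInconsistencyError(ValueError):
    """Measured noise below the chain floor: inputs inconsistent."""


@dataclass(frozen=True)
class PmtChain:
    """Gain and optical constants of the PMT readout chain."""

    gain: float = 2.41e5
    delta: float = 3.09           # mean gain per dynode stage
    n_stages: int = 11            # delta^11 ~ 2.45e5, matching the gain
    optics: OpticalChain = field(default_factory=OpticalChain)
    e: float = E_CHARGE

    def __post_init__(self):
        if self.gain <= 1 or self.delta <= 1:
            raise ValueError("gain and per-stage gain must exceed 1")

    @property
    def sigma_pmt2(self) -> float:
        """Variance of the single-electron cascade gain, G^2/(delta - 1)."""
        return self.gain ** 2 / (self.delta - 1.0)

    @property
    def eta_prime(self) -> float:
        return self.optics.eta_prime


@dataclass(frozen=True)
class ChargeSample:
    """Repeated anode-charge readings (C)."""

    charges: np.ndarray

    def __post_init__(self):
        q = np.asarray(self.charges, dtype=float)
        if q.size < 2:
            raise ValueError("need at least 2 readings for an rms")
        object.__setattr__(self, "charges", q)

    @property
    def mean(self) -> float:
        return float(np.mean(self.charges))

    @property
    def sigma_d(self) -> float:
        return float(np.sqrt(np.mean(self.charges ** 2) - self.mean ** 2))


@dataclass(frozen=True)
class OpticalSignal:
    nph_mean: float
    sigma_ph: float

    def __post_init__(self):
        if self.nph_mean < 0 or self.sigma_ph < 0:
            raise ValueError("optical signal moments must be non-negative")


# --------------------------------------------------------------- operations

def photons_from_charge(q_coulomb, chain: PmtChain):
    """Invert Q = e eta G gamma xi Nph."""
    o = chain.optics
    denom = chain.e * o.eta * chain.gain * o.gamma * o.xi
    if denom <= 0:
        raise ValueError("zero factor in the readout chain")
    return np.asarray(q_coulomb, dtype=float) / denom


def charge_from_photons(nph, chain: PmtChain):
    o = chain.optics
    return np.asarray(nph, dtype=float) * chain.e * o.eta * chain.gain \
        * o.gamma * o.xi


def chain_efficiency(chain: PmtChain) -> float:
    """eta' = eta gamma xi."""
    return chain.eta_prime


def invert_noise_transfer(sample: ChargeSample,
                          chain: PmtChain) -> OpticalSignal:
    """Solve the noise-transfer relation for the optical-signal rms."""
    nph = float(photons_from_charge(sample.mean, chain))
    ep = chain.eta_prime
    g2 = chain.gain ** 2
    var_e = (sample.sigma_d / chain.e) ** 2
    num = var_e - g2 * nph * ep * (1 - ep) - ep * nph * chain.sigma_pmt2
    if num < 0:
        raise ChainInconsistencyError(
            "measured charge noise is below the binomial + gain-cascade "
            "floor; charge sample and chain constants are inconsistent")
    sigma_ph = float(np.sqrt(num / (g2 * ep * ep)))
    return OpticalSignal(nph, sigma_ph)


def forward_noise_sigma_d(nph_mean: float, sigma_ph: float,
                          chain: PmtChain) -> float:
    """Forward noise transfer: predicted charge rms (C)."""
    ep = chain.eta_prime
    g2 = chain.gain ** 2
    var_e = (g2 * ep * ep * sigma_ph ** 2
             + g2 * nph_mean * ep * (1 - ep)
             + ep * nph_mean * chain.sigma_pmt2)
    return float(chain.e * np.sqrt(var_e))


def quantum_limited_check(signal: OpticalSignal, pde: float,
                          electronic_noise_e: float = 2000.0) -> bool:
    """True when the PDE-scaled detector noise strictly exceeds the
    per-pixel electronic noise of the readout panel."""
    if pde < 0 or electronic_noise_e < 0:
        raise ValueError("inputs must be non-negative")
    return signal.sigma_ph * pde > electronic_noise_e


def fit_dose_response(doses_cgy, signals) -> dict:
    """Least-squares line through the dose series with residual diagnostics."""
    d = np.asarray(doses_cgy, dtype=float)
    s = np.asarray(signals, dtype=float)
    if d.size < 3:
        raise ValueError("need at least 3 dose points")
    coef, cov = np.polyfit(d, s, 1, cov=True)
    fit = np.polyval(coef, d)
    scale = float(np.max(np.abs(s))) or 1.0
    max_rel_resid = float(np.max(np.abs(s - fit)) / scale)
    return {"slope": float(coef[0]), "intercept": float(coef[1]),
            "slope_se": float(np.sqrt(cov[0, 0])),
            "intercept_se": float(np.sqrt(cov[1, 1])),
            "max_rel_residual": max_rel_resid}
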