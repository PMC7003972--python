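"""Zero-frequency DQE from per-event photon-count moments.

The detector signal for one incident x ray is the number m of optical
photons reaching the bottom fiber ends (integrated over all fibers).  With
Mn the n-th moment of m over ALL incident x rays (non-interacting events
contribute m = 0),

    DQE(0) = M1^2 / M2.

Binomial thinning by a photon detection efficiency p has the closed-form
effect  DQE_p(0) = M1^2 / (M2 + (1-p)/p * M1),  which is compared against
explicit thinning in the tests.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fiber_optics import pde_thin


@dataclass(frozen=True)
class PhotonCountDistribution:
    """Per-event detected photon counts for Nx incident x rays."""

    counts: np.ndarray        # length Nx, zeros included
    nx: int

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 1 or c.size == 0:
            raise ValueError("counts must be a non-empty 1-d sequence")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        if self.nx < c.size:
            raise ValueError("Nx must be >= number of events")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @classmethod
    def from_tallies(cls, tally_run) -> "PhotonCountDistribution":
        return cls(tally_run.photons_total, len(tally_run))


def photon_moments(dist: PhotonCountDistribution, n: int) -> float:
    """Mn = (1/Nx) * sum over events of m^n (zeros included)."""
    if dist.nx <= 0:
        raise ValueError("empty distribution")
    c = dist.counts.astype(float)
    # events absent from `counts` (nx > len) carry m = 0 and add nothing
    return float(np.sum(c ** n) / dist.nx)


def dqe0(dist: PhotonCountDistribution) -> float:
    m1 = photon_moments(dist, 1)
    m2 = photon_moments(dist, 2)
    if m2 <= 0:
        raise ValueError("all-zero distribution has no defined DQE")
    return m1 * m1 / m2


def dqe0_under_thinning(dist: PhotonCountDistribution, p: float) -> float:
    """Closed-form DQE(0) after independent binomial thinning with prob. p."""
    if not 0 < p <= 1:
        raise ValueError("p must lie in (0, 1]")
    m1 = photon_moments(dist, 1)
    m2 = photon_moments(dist, 2)
    denom = m2 + (1 - p) / p * m1
    if denom <= 0:
        raise ValueError("all-zero distribution has no defined DQE")
    return m1 * m1 / denom


def thin_distribution(dist: PhotonCountDistribution, p: float,
                      seed_or_rng) -> PhotonCountDistribution:
    """Empirically thinned copy (binomial per event)."""
    return PhotonCountDistribution(pde_thin(dist.counts, p, seed_or_rng),
                                   dist.nx)


def pulse_height_histogram(dist: PhotonCountDistribution,
                           bins=50, max_count: int | None = None):
    """Histogram of per-event counts; the zero bin is reported separately.

    Returns ``(bin_edges, frequencies, n_zero)`` with frequencies summing to
    the number of nonzero events.
    """
    c = dist.counts
    n_zero = int(np.sum(c == 0))
    nonzero = c[c > 0]
    if nonzero.size == 0:
        return np.array([0.0, 1.0]), np.array([0]), n_zero
    hi = max_count if max_count is not None else int(nonzero.max())
    freq, edges = np.histogram(nonzero, bins=bins, range=(0.5, hi + 0.5))
    return edges, freq, n_zero


def bootstrap_dqe0(dist: PhotonCountDistribution, n_boot: int = 200,
                   seed: int = 0) -> tuple[float, float]:
    """DQE(0) point estimate and bootstrap standard error over events."""
    rng = np.random.default_rng(seed)
    c = dist.counts.astype(float)
    n = c.size
    est = dqe0(dist)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        s = c[rng.integers(0, n, n)]
        m1 = s.mean()
        m2 = (s * s).mean()
        stats[b] = m1 * m1 / m2 if m2 > 0 else 0.0
    return est, float(np.std(stats, ddof=1))
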