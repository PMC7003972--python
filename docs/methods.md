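# Methods

`fiberscint` models a megavoltage portal-imaging detector whose energy
conversion layer is a 2-cm-thick honeycomb of 1-mm double-clad polystyrene
scintillating fibers embedded in a corrugated-lead/epoxy matrix, read out at
the bottom fiber ends by a flat-panel imager (AMFPI).  This note records the
model, its assumptions, the parameters that matter, and the places where the
design was genuinely open.

## Geometry

Fibers run parallel to the beam axis (z).  Rows of fibers along x
("layers") at 1.35 mm pitch are stacked along y at 1.22 mm spacing, with
alternate layers staggered by half a pitch.  The scintillator fill factor is
the fiber cross-section over the unit-cell area, pi/4 / (1.35 x 1.22) =
0.477.  Cladding thicknesses are not published; we default to 3% (inner) and
1% (outer) of the diameter, the vendor's standard for double-clad fiber, so
the scintillating core radius is 0.46 mm.

**Composite anchoring.** The lead sheet thickness is unpublished ("very
thin"), so the lead volume fraction must be calibrated from a published
quantity.  Two candidates exist and are mutually inconsistent:

* the quoted bulk density, 5.4 g/cm^3, implies 42 vol% lead;
* the measured x-ray absorption efficiency, 35% for a 6-MV beam over 2 cm,
  implies ~22 vol% lead (an independent full-transport simulation published alongside the
  measurement, 35.8 +/- 0.7%, agrees with the measurement).

These cannot both hold: with 42 vol% lead the interaction probability is at
least 42% for any 6-MV spectrum with mean energy below 2 MeV (lead's mass
attenuation has its minimum, 0.042 cm^2/g, near 4 MeV).  Because every
simulated quantity in this package (interaction fraction, DQE, LSF) flows
from the interaction physics rather than from the weight, the default
("reference-model") composite is anchored to the measured absorption efficiency:
the lead fraction is solved by root-finding so the analytic AE under the
default spectrum equals 0.35.  This yields 21.6 vol% lead and a bulk density
of 3.31 g/cm^3 — equivalent to ~0.19-mm corrugated sheets, consistent with
"very thin".  The density-anchored split remains available through
`geometry.solve_composite` and is reported by `analysis/01` for the
mass/weight arithmetic.

## 6-MV spectrum

The planning-system spectrum behind the measurements is not published.  The
default model is a gamma-law bremsstrahlung shape, fluence ~ E^1.2
exp(-E/0.8 MeV) on 0.25-6 MeV, mean 1.77 MeV — typical of flattened
clinical 6-MV beams.  This is the dominant systematic for the absorption
efficiency and the water-transmission ratio R0 and is fully configurable
(`beam_attenuation.build_6mv_spectrum`).

## Attenuation and range data

Per-material mass attenuation tables (photoelectric, incoherent, pair) are
packaged as CSV fixtures on a 25-point 0.01-6 MeV grid and interpolated
log-log.  The incoherent part is exact free-electron Klein-Nishina;
photoelectric and pair use lead anchor values scaled to other elements by
Z^4/A and Z(Z+1)/A respectively.  Coherent scattering is excluded (it
deposits no energy and barely attenuates at MV energies); the lead K-edge is
smoothed.  Water comes out at 0.0498 /cm at 2 MeV (reference 0.0494).
Electron ranges use a water CSDA table with constant per-material mass
stopping ratios.  These fixtures are hand-packaged constants; their few-
percent accuracy is well inside the tolerances of every result they feed.

## Monte Carlo transport

A two-scale model, chosen because photon mean free paths (>= 4 cm) are ~30x
the lattice period while electron ranges (~1-4 mm) are comparable to it:

* **Photons** move through the *homogenised* composite.  The interaction
  depth is sampled from the volume-weighted linear coefficient; the
  transverse interaction point is then placed within the local unit cell
  with probability proportional to the local material's attenuation
  (transverse equilibrium).  This makes the pencil-beam interaction fraction
  equal the analytic absorption efficiency by construction and averages over
  the unmeasurable sub-millimetre beam/fiber alignment.  For slit scans an
  "aligned" mode instead attenuates each ray in the material column it
  actually traverses, which is what produces the fiber-pitch structure of
  the line spread function.
* **Electrons and positrons** are tracked through the *true lattice* as
  condensed-history straight segments of CSDA length with Highland
  multiple-Coulomb-scattering deflections each 0.05 mm step (mode
  `csda-mcs`).  Energy is deposited per material segment via the
  water-equivalent residual range.  A straight-line mode (`csda-line`) and
  local deposition (`local`) are kept for comparison; the straight-line
  model is qualitatively wrong in this geometry — a forward electron born
  in the z-invariant matrix never crosses a fiber, which halves DQE(0).
* **Secondary photons** (Compton-scattered, annihilation) are tracked in the
  homogenised medium until escape or a 10 keV cutoff.  Bremsstrahlung
  photons are not tracked (radiative losses deposit locally); this is the
  main residual fidelity gap.
* **Optics.** Each core deposit emits Poisson photons at 8000/MeV (a
  vendor-typical polystyrene-fiber yield; the published work does not state
  its value), of which a fraction (1 - n_outerclad/n_core)/2 = 5.3% is
  guided to the bottom end (meridional acceptance cone), attenuated by
  exp(-distance/3.5 m).  Photons crossing into the epoxy are absorbed; no
  inter-fiber optical cross-talk by default.

Reproducibility: each history draws from its own counter-derived random
stream (`default_rng((seed, index))`), so runs are bit-identical for a fixed
seed and independent of execution order.

## DQE(0)

The detector signal per incident x ray is the total photon count m over all
fibers; with Mn the n-th moment of m over all histories (zeros included for
non-interacting x rays), DQE(0) = M1^2/M2.  Binomial thinning by a photon
detection efficiency p gives the closed form M1^2/(M2 + (1-p)/p M1), which
the tests verify against explicit per-event thinning.  Note that in this
model a substantial fraction of *interacting* events deposit nothing in any
core (the electron stops in lead), so the zero-count spike exceeds the
non-interaction probability; DQE(0) <= AE holds with margin.

At the default conditions (50 000 histories) the reference-model run gives
DQE(0) ~ 11.5-12% at PDE 100% — in agreement with the published 11.54% —
and a mean of ~25 photons per incident x ray.  The published DQE at PDE
0.2% (5.69%) back-implies ~56 photons per x ray through the thinning
formula; our absolute light scale is lower, so the thinned DQE comes out
near 3.5-3.7%.  The absolute scale depends on the unpublished lead content
and light yield and is documented in the original work as order-of-
magnitude only; we report the computed value rather than adjusting the
yield to match.

## Slit-method MTF

`mtf.simulate_slit_scan` confines the beam to an 80-um-wide aperture
(8 mm long), steps it from -15 to 15 mm in 0.25 mm steps across the fixed
readout fiber, and tallies that fiber's detected photons (aligned-mode
attenuation, full cascade).  The background ("no-slit") profile is the
stated 4.2% block transmission times the reconstructed open-beam signal,
plus the same 1% relative noise.  Processing follows the classic slit
pipeline: background subtraction, symmetrisation about the top-3-sample
centroid, single-exponential tail fits on the outer 30% of each side
extended to 1e-4 relative amplitude, then |DFT| normalised at zero
frequency.  Finite slit width is not deconvolved (80 um << 1.4 mm FWHM).

The simulated LSF has FWHM 1.33-1.35 mm (measured: ~1.4 mm) but thinner
tails than the measurement, so f50 comes out at ~0.29-0.33 mm^-1 against
the measured 0.2 mm^-1.  Plausible contributors, in decreasing order: the
measured prototype read a horizontal fiber crossing the whole block, which
integrates scatter along its 12 cm length, whereas the simulation models
the proposed vertical-fiber AMFPI readout; slit penumbra (source size and
slit-depth divergence) broadens the measured beam; and the simplified
transport omits bremsstrahlung photon spread.  The FWHM and f50 are both
reported as computed.

## Primary transmission R0

R0 is the ratio of detector-weighted primary fluence behind a water slab to
the unattenuated one; the detector weight is AE(E) x E (signal is
approximately proportional to deposited energy).  Beam hardening is exact
by construction (each spectral component attenuates with its own
coefficient).  For 30 cm of water the default model gives R0 ~ 0.22.  The
measured value, ~0.30, implies an effective attenuation of 0.040 /cm —
equivalent to a ~3.2 MeV monoenergetic beam — and is unreachable for any
6-MV spectrum with mean energy below 2 MeV; scans over two spectrum
families put the ceiling at ~0.244.  The likeliest explanation is residual
scatter in the zero-field extrapolation of the measured primary (a convex
signal-vs-field-size curve extrapolated linearly biases the with-phantom
primary high).  We report the computed value.

## PMT noise transfer

The readout chain is Q = e eta G gamma xi Nph with eta = 0.18 (band-mean
photocathode QE over 420-560 nm), gamma = 0.40 (switch + 10 m fiber),
xi = 0.85 (fiber-PMT interface, kept as a configured constant — the
single-interface Fresnel value for the stated indices would be 0.948),
G = 2.41e5 and per-stage gain delta = 3.09 (11 stages: delta^11 ~ 2.45e5,
within 2% of G).  Noise transfer through the binomial detection stage and
the gain cascade uses the law-of-total-variance form

    sigma_d^2/e^2 = G^2 eta'^2 sigma_ph^2 + G^2 <N> eta'(1-eta')
                    + eta' <N> G^2/(delta-1),

inverted for sigma_ph; a measured rms below the binomial+cascade floor
raises a dedicated inconsistency error.  The forward simulator samples the
cascade as a gamma-distributed gain (shape delta-1), so the n-electron sum
is again gamma — exact and O(1) per reading.  At the published endpoint
(Nph = 3.52e6, sigma_ph = 2.69e4, i.e. x-ray-quantum-dominated light with
variance/mean ~ 206) the chain forward-computes <Q> ~ 8.3 nC and sigma_d ~
67 pC, and the PDE-scaled noise is far above the 2000-electron panel
noise: quantum limited.  LINAC output noise (1-2% of total) is neglected.

## Synthetic data

No measured series are deposited anywhere, so every input is emulated:
emission spectra (skewed 420-560 nm band peaking at 450 nm, 78 replicates,
zero-mean noise everywhere so the out-of-band mean vanishes), slit scans
from parametric LSFs, field-size series T = P(1 + SPR(fs)), repeated PMT
charges via the forward chain, and 10-250 cGy dose series.  The default
noise is 1% relative Gaussian, matching the quoted LINAC output stability.
Every generator returns its ground truth, and every pipeline stage is
tested as a closed generate-analyse-recover loop.  What passing these loops
shows is that the estimators are unbiased at the stated noise level — not
that the physical model reproduces every measured curve; the physical
comparisons live in the acceptance checks.

## Numerical choices and problem sizes

Log-log interpolation for all cross-section lookups; Kahn-style rejection
for Klein-Nishina sampling; brentq for the composite calibration;
least-squares line fits throughout (field-size extrapolation regresses on
the field side; the area regressor is a flag).  Default problem sizes:
50 000 histories for DQE (bootstrap SE < 0.5% absolute), 8000 histories
per slit position (121 positions), 1e6 directions for the trapping oracle
— chosen so each headline number's Monte Carlo error is well below its
comparison tolerance.  Ties in the symmetrisation centroid break leftmost;
thinning with p = 1 is an exact identity; tail extension skips sides that
are already below threshold and refuses fits with fewer than three positive
points.

## Known limitations

No bremsstrahlung or delta-ray transport; no optical ray tracing (skew rays
and cladding modes ignored — the meridional 5.3% is the trapping model);
no focal-spot or slit-penumbra blur in the slit simulator; the matrix is a
homogenised lead/epoxy mixture rather than explicit corrugated sheets; no
detector-edge effects (the pencil beam is central); absolute photon counts
are order-of-magnitude (unpublished yield and lead content).
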