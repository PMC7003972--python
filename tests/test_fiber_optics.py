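"""Trapping, transmission and quantum-efficiency analytics."""
import math

import numpy as np
import pytest

from fiberscint.fiber_optics import (OpticalChain, SpectrumCurve,
                                     acceptance_angles, bulk_transmission,
                                     fresnel_normal, mean_optical_qe,
                                     pde_thin, trapped_fraction,
                                     trapped_fraction_mc)
from fiberscint.geometry import FiberSpec


class TestAcceptanceAngles:
    def test_inner_outer_cladding_critical_angle(self):
        _, a2 = acceptance_angles(FiberSpec())
        assert a2 == pytest.approx(72.4, abs=0.1)

    def test_core_inner_cladding_critical_angle(self):
        a1, _ = acceptance_angles(FiberSpec())
        assert a1 == pytest.approx(69.6, abs=0.1)

    def test_near_equal_indices_approach_grazing(self):
        f = FiberSpec(core_index=1.5901, inner_clad_index=1.59,
                      outer_clad_index=1.58)
        a1, _ = acceptance_angles(f)
        assert a1 > 89.0


class TestTrappedFraction:
    def test_double_clad_fiber_traps_5_3_percent(self):
        assert trapped_fraction(FiberSpec(), "one") \
            == pytest.approx(0.0535, abs=5e-4)

    def test_single_clad_equivalent(self):
        f = FiberSpec(inner_clad_index=1.50, outer_clad_index=1.49)
        assert trapped_fraction(f, "one") \
            == pytest.approx((1 - 1.49 / 1.59) / 2, rel=1e-12)

    def test_vanishing_index_step_traps_nothing(self):
        f = FiberSpec(core_index=1.5900001, inner_clad_index=1.59,
                      outer_clad_index=1.5899999)
        assert trapped_fraction(f, "one") < 1e-6

    def test_both_ends_doubles_one_end(self):
        f = FiberSpec()
        assert trapped_fraction(f, "both") \
            == pytest.approx(2 * trapped_fraction(f, "one"))

    def test_agrees_with_independent_snell_oracle(self):
        # sample isotropic emission directions and apply Snell/TIR at both
        # cladding interfaces explicitly (meridional geometry)
        f = FiberSpec()
        rng = np.random.default_rng(123)
        n = 1_000_000
        cos_axis = rng.uniform(-1, 1, n)
        theta = np.arccos(cos_axis)          # polar angle from the fiber axis
        inc1 = np.pi / 2 - theta             # incidence at the core wall
        sin_i1 = np.cos(theta)
        # TIR at the core/inner interface traps directly
        tir_core = sin_i1 >= f.inner_clad_index / f.core_index
        # otherwise Snell refraction into the inner cladding, then TIR at
        # the inner/outer interface
        sin_i2 = np.clip(f.core_index / f.inner_clad_index * sin_i1, 0, 1)
        tir_inner = sin_i2 >= f.outer_clad_index / f.inner_clad_index
        trapped = (tir_core | tir_inner) & (cos_axis > 0)
        frac = trapped.mean()
        p = trapped_fraction(f, "one")
        sigma = math.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < 3 * sigma

    def test_package_mc_matches_formula(self):
        f = FiberSpec()
        p = trapped_fraction(f, "one")
        est = trapped_fraction_mc(f, n=1_000_000, seed=1)
        assert abs(est - p) < 3 * math.sqrt(p * (1 - p) / 1e6)


class TestBulkTransmission:
    @pytest.mark.parametrize("path,lam,expected", [
        (0.0, 3500.0, 1.0),
        (3500.0, 3500.0, math.exp(-1)),
        (20.0, 3500.0, math.exp(-0.02 / 3.5)),
    ])
    def test_attenuation_law(self, path, lam, expected):
        assert bulk_transmission(path, lam) == pytest.approx(expected,
                                                             rel=1e-12)

    def test_negative_path_rejected(self):
        with pytest.raises(ValueError):
            bulk_transmission(-1.0, 3500.0)


class TestFresnel:
    def test_matched_media_transmit_fully(self):
        assert fresnel_normal(1.5, 1.5) == 1.0

    def test_core_to_air(self):
        assert fresnel_normal(1.59, 1.0) == pytest.approx(0.948, abs=5e-4)

    def test_chained_interfaces_multiply(self):
        t = fresnel_normal(1.59, 1.46) * fresnel_normal(1.46, 1.52)
        assert t == pytest.approx(
            (1 - ((1.59 - 1.46) / (1.59 + 1.46)) ** 2)
            * (1 - ((1.46 - 1.52) / (1.46 + 1.52)) ** 2))


class TestMeanOpticalQe:
    def _emission(self):
        wl = np.arange(400.0, 601.0, 1.0)
        v = np.exp(-((wl - 450.0) / 30.0) ** 2)
        v[(wl < 420) | (wl > 560)] = 0.0
        return SpectrumCurve(wl, v)

    def test_flat_qe_is_returned_unchanged(self):
        wl = np.arange(400.0, 601.0, 5.0)
        qe = SpectrumCurve(wl, np.full(wl.size, 0.21))
        assert mean_optical_qe(qe, self._emission()) \
            == pytest.approx(0.21, rel=1e-9)

    def test_linear_qe_matches_fine_grid_quadrature(self):
        wl = np.arange(400.0, 601.0, 10.0)
        qe_vals = 0.25 + (0.10 - 0.25) * (wl - 420) / (560 - 420)
        qe = SpectrumCurve(wl, qe_vals)
        em = self._emission()
        # brute-force quadrature at 10x resolution
        f = np.linspace(420, 560, 14001)
        w = np.interp(f, em.wavelength_nm, em.value)
        q = np.interp(f, wl, qe_vals)
        expected = np.trapezoid(q * w, f) / np.trapezoid(w, f)
        assert mean_optical_qe(qe, em) == pytest.approx(expected, rel=1e-4)

    def test_invariant_to_emission_rescaling(self):
        em = self._emission()
        em10 = SpectrumCurve(em.wavelength_nm, 10.0 * em.value)
        wl = np.arange(400.0, 601.0, 10.0)
        qe = SpectrumCurve(wl, np.linspace(0.3, 0.1, wl.size))
        assert mean_optical_qe(qe, em) == pytest.approx(
            mean_optical_qe(qe, em10), rel=1e-12)

    def test_disjoint_supports_rejected(self):
        qe = SpectrumCurve(np.array([600.0, 700.0]), np.array([0.1, 0.1]),
                           band=(600.0, 700.0))
        with pytest.raises(ValueError, match="disjoint"):
            mean_optical_qe(qe, self._emission())


class TestPdeThin:
    def test_full_pde_is_identity(self):
        c = np.array([0, 5, 100, 3])
        assert np.array_equal(pde_thin(c, 1.0, 0), c)

    def test_binomial_mean(self):
        rng = np.random.default_rng(5)
        c = np.full(100_000, 100)
        thinned = pde_thin(c, 0.4, rng)
        se = math.sqrt(100 * 0.4 * 0.6 / c.size)
        assert abs(thinned.mean() - 40.0) < 3 * se

    def test_composition_matches_single_thinning_in_moments(self):
        rng = np.random.default_rng(9)
        c = rng.poisson(50, 200_000)
        two_step = pde_thin(pde_thin(c, 0.5, 1), 0.6, 2)
        one_step = pde_thin(c, 0.3, 3)
        for order in (1, 2):
            a = np.mean(two_step.astype(float) ** order)
            b = np.mean(one_step.astype(float) ** order)
            assert a == pytest.approx(b, rel=0.02)

    def test_invalid_pde_rejected(self):
        with pytest.raises(ValueError):
            pde_thin(np.array([1]), 0.0, 0)


class TestSpectrumCsvIo:
    def test_round_trip(self, tmp_path):
        from fiberscint.fiber_optics import (read_spectrum_csv,
                                             write_spectrum_csv)
        wl = np.arange(400.0, 601.0, 5.0)
        curve = SpectrumCurve(wl, np.linspace(0.0, 1.0, wl.size))
        path = tmp_path / "emission.csv"
        write_spectrum_csv(curve, path)
        back = read_spectrum_csv(path)
        assert np.allclose(back.wavelength_nm, curve.wavelength_nm)
        assert np.allclose(back.value, curve.value)


class TestOpticalChain:
    def test_eta_prime_is_the_product(self):
        chain = OpticalChain(gamma=0.40, xi=0.85, eta=0.18)
        assert chain.eta_prime == pytest.approx(0.0612, abs=1e-6)

    def test_factors_must_be_physical(self):
        with pytest.raises(ValueError):
            OpticalChain(gamma=1.2)
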