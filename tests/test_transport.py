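"""Pencil-beam Monte Carlo: sampling, electron deposition, scintillation."""
import math

import numpy as np
import pytest

from fiberscint.beam_attenuation import EnergySpectrum, absorption_efficiency
from fiberscint.geometry import (CompositeSpec, DetectorSpec, FiberSpec,
                                 LatticeSpec, fill_factor)
from fiberscint.materials import load_mu_table, mu_lookup
from fiberscint.transport import (McConfig, deposit_electron,
                                  run_pencil_beam, sample_interaction,
                                  scintillate_and_collect)

MEC2 = 0.51099895


class TestRunPencilBeam:
    def test_zero_histories_gives_empty_tallies(self, detector):
        run = run_pencil_beam(McConfig(n_histories=0, seed=0), detector)
        assert len(run) == 0
        assert run.interaction_fraction == 0.0

    def test_fixed_seed_is_bit_reproducible(self, detector):
        a = run_pencil_beam(McConfig(n_histories=500, seed=3), detector)
        b = run_pencil_beam(McConfig(n_histories=500, seed=3), detector)
        assert np.array_equal(a.photons_total, b.photons_total)
        assert np.array_equal(a.deposit_core_mev, b.deposit_core_mev)

    def test_interaction_fraction_matches_analytic_ae(self, detector):
        # across a mono-1-MeV, mono-4-MeV and the default 6-MV spectrum
        for sp in (EnergySpectrum.monoenergetic(1.0),
                   EnergySpectrum.monoenergetic(4.0), None):
            cfg = McConfig(n_histories=8000, seed=21, spectrum=sp)
            run = run_pencil_beam(cfg, detector)
            spectrum = sp if sp is not None else __import__(
                "fiberscint.config", fromlist=["default_spectrum"]
            ).default_spectrum()
            ae = absorption_efficiency(spectrum, detector)
            sigma = math.sqrt(ae * (1 - ae) / cfg.n_histories)
            assert abs(run.interaction_fraction - ae) < 3 * sigma

    def test_nearly_pure_lead_block_matches_closed_form(self):
        fiber = FiberSpec(diameter=0.01)
        lattice = LatticeSpec(thickness=5.0)
        ff = fill_factor(lattice, fiber)
        comp = CompositeSpec(ff, 1 - ff, 0.0,
                             fiber_density=fiber.bundle_density)
        det = DetectorSpec(fiber, lattice, comp)
        t = load_mu_table("lead")
        mu = mu_lookup(t, 2.0) * t.density
        expected = 1 - math.exp(-mu * 0.5)
        run = run_pencil_beam(
            McConfig(n_histories=10000, seed=4,
                     spectrum=EnergySpectrum.monoenergetic(2.0)), det)
        sigma = math.sqrt(expected * (1 - expected) / 10000)
        assert abs(run.interaction_fraction - expected) < 3 * sigma + ff

    def test_energy_deposits_never_exceed_incident(self, small_run):
        ok = small_run.deposit_total_mev <= small_run.energy_mev + 1e-9
        assert np.all(ok)

    def test_zero_spike_at_least_the_non_interaction_probability(self,
                                                                 small_run):
        n = len(small_run)
        p_no = 1 - small_run.interaction_fraction
        zero = np.mean(small_run.photons_total == 0)
        sigma = math.sqrt(p_no * (1 - p_no) / n)
        assert zero >= p_no - 3 * sigma

    def test_dqe_bounded_by_interaction_fraction(self, small_run):
        m = small_run.photons_total.astype(float)
        dqe = m.mean() ** 2 / np.mean(m ** 2)
        assert dqe <= small_run.interaction_fraction + 0.01


class TestSampleInteraction:
    def test_no_pair_production_below_threshold(self, detector):
        rng = np.random.default_rng(0)
        for _ in range(300):
            proc, _ = sample_interaction(0.5, "lead", rng, detector)
            assert proc != "pair"

    def test_process_shares_match_the_tables(self, detector):
        rng = np.random.default_rng(1)
        n = 30000
        counts = {"photoelectric": 0, "compton": 0, "pair": 0}
        for _ in range(n):
            proc, _ = sample_interaction(2.0, "core", rng, detector)
            counts[proc] += 1
        t = load_mu_table("polystyrene")
        shares = {p: float(mu_lookup(t, 2.0, p) / mu_lookup(t, 2.0))
                  for p in counts}
        for p, c in counts.items():
            sigma = math.sqrt(max(shares[p] * (1 - shares[p]) / n, 1e-12))
            assert abs(c / n - shares[p]) < 3 * sigma + 1e-3

    def test_compton_scattered_energy_has_backscatter_floor(self, detector):
        rng = np.random.default_rng(2)
        e0 = 2.0
        k = e0 / MEC2
        floor = e0 / (1 + 2 * k)
        energies = []
        for _ in range(3000):
            proc, secs = sample_interaction(e0, "core", rng, detector)
            if proc == "compton":
                energies.append([e for kind, e, _ in secs
                                 if kind == "gamma"][0])
        assert min(energies) >= floor - 1e-9
        assert min(energies) == pytest.approx(floor, abs=0.02)
        assert floor == pytest.approx(0.2266, abs=0.002)

    def test_compton_conserves_energy(self, detector):
        rng = np.random.default_rng(3)
        proc, secs = sample_interaction(3.0, "lead", rng, detector)
        while proc != "compton":
            proc, secs = sample_interaction(3.0, "lead", rng, detector)
        assert sum(e for _, e, _ in secs) == pytest.approx(3.0, rel=1e-12)


class TestDepositElectron:
    def test_electron_outside_the_block_deposits_nothing(self, detector):
        per, core, escaped = deposit_electron(
            1.0, (0.0, 0.0, -5.0), (0, 0, -1), detector, "csda-line",
            np.random.default_rng(0))
        assert per == {} and core == []
        assert escaped == 1.0

    def test_contained_electron_conserves_energy(self, detector):
        rng = np.random.default_rng(1)
        e0 = 0.3    # sub-mm range: fully contained from the block centre
        per, _, escaped = deposit_electron(
            e0, (0.0, 0.0, 10.0), (1, 1, 1), detector, "csda-mcs", rng)
        assert escaped == 0.0
        assert sum(per.values()) == pytest.approx(e0, abs=1e-9)

    def test_local_mode_deposits_at_origin_material(self, detector):
        per, core, _ = deposit_electron(
            2.0, (0.0, 0.0, 10.0), (0, 0, 1), detector, "local",
            np.random.default_rng(2))
        assert per == {"core": 2.0}
        assert core[0][0] == (0, 0)

    def test_straight_track_core_share_matches_stopping_weighted_oracle(
            self, detector):
        # isotropic 0.5 MeV electrons from random points; deposit share in
        # core should match a track-length x density x stopping estimate
        from fiberscint.geometry import trace_ray
        from fiberscint.materials import STOPPING_RATIO, csda_range
        rng = np.random.default_rng(7)
        lat = detector.lattice
        tot_core, tot_all = 0.0, 0.0
        for _ in range(400):
            x = rng.uniform(-lat.in_layer_pitch / 2, lat.in_layer_pitch / 2)
            y = rng.uniform(-lat.layer_spacing / 2, lat.layer_spacing / 2)
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            per, _, _ = deposit_electron(0.5, (x, y, 10.0), d, detector,
                                         "csda-line", rng)
            tot_core += per.get("core", 0.0)
            tot_all += sum(per.values())
        share = tot_core / tot_all
        # oracle: average over random chords of length = electron range
        est_core, est_all = 0.0, 0.0
        rng2 = np.random.default_rng(8)
        rho_stop = {"core": 1.05 * 0.97, "inner_clad": 1.19 * 0.97,
                    "outer_clad": 1.43 * 0.90,
                    "matrix": detector.composite.matrix_density * 0.75}
        for _ in range(2000):
            x = rng2.uniform(-lat.in_layer_pitch / 2, lat.in_layer_pitch / 2)
            y = rng2.uniform(-lat.layer_spacing / 2, lat.layer_spacing / 2)
            d = rng2.normal(size=3)
            d /= np.linalg.norm(d)
            segs = trace_ray((x, y, 10.0), d, detector)
            left = 3.0   # ~0.5 MeV range scale in mm of track, generous
            for s in segs:
                use = min(s.length, left)
                w = rho_stop.get(s.material, 1.0) * use
                est_all += w
                if s.material == "core":
                    est_core += w
                left -= use
                if left <= 0:
                    break
        oracle = est_core / est_all
        assert share == pytest.approx(oracle, abs=0.25 * oracle + 0.02)


class TestScintillateAndCollect:
    def test_zero_deposit_makes_no_light(self, detector):
        col, det = scintillate_and_collect([], detector.fiber, 1.0,
                                           np.random.default_rng(0))
        assert col == {} and det == {}

    def test_mean_light_matches_product_of_means(self, detector):
        # 1 MeV at the bottom face: yield x trapping, no bulk attenuation
        rng = np.random.default_rng(1)
        f = detector.fiber
        n, tot = 3000, 0
        for _ in range(n):
            col, _ = scintillate_and_collect([((0, 0), 1.0, 20.0)], f, 1.0,
                                             rng, thickness_mm=20.0)
            tot += col[(0, 0)]
        expected = f.scintillation_yield * 0.0535
        se = math.sqrt(expected / n) * 3
        assert tot / n == pytest.approx(expected, abs=3 * se + 3.0)

    def test_pde_halves_the_detected_mean(self, detector):
        rng = np.random.default_rng(2)
        f = detector.fiber
        tot1 = tot05 = 0
        n = 3000
        for _ in range(n):
            col, det1 = scintillate_and_collect([((0, 0), 1.0, 20.0)], f,
                                                1.0, rng)
            _, det05 = scintillate_and_collect([((0, 0), 1.0, 20.0)], f,
                                               0.5, rng)
            tot1 += det1[(0, 0)]
            tot05 += det05[(0, 0)]
        assert tot05 / tot1 == pytest.approx(0.5, abs=0.03)

    def test_depth_attenuation_reduces_collection(self, detector):
        rng = np.random.default_rng(3)
        f = detector.fiber
        lam_top = f.scintillation_yield * 0.0535 \
            * math.exp(-20.0 / f.bulk_attenuation_length)
        n, tot = 5000, 0
        for _ in range(n):
            col, _ = scintillate_and_collect([((0, 0), 1.0, 0.0)], f, 1.0,
                                             rng)
            tot += col[(0, 0)]
        assert tot / n == pytest.approx(lam_top, rel=0.05)


class TestConfigValidation:
    def test_bad_modes_rejected(self):
        with pytest.raises(ValueError):
            McConfig(electron_mode="ballistic")
        with pytest.raises(ValueError):
            McConfig(beam_mode="divergent")
        with pytest.raises(ValueError):
            McConfig(n_histories=-1)
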