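"""Slit-method LSF/MTF pipeline against closed-form oracles."""
import math

import numpy as np
import pytest

from fiberscint.mtf import (MtfResult, ScanProfile, correct_lsf,
                            extend_tails, lsf_fwhm, mtf_from_lsf,
                            process_scan, resolution_metrics,
                            symmetrize_lsf)
from fiberscint.synthetic import gen_slit_scan

X = np.arange(-15.0, 15.001, 0.25)


def gaussian(x, sigma=1.0):
    return np.exp(-x ** 2 / (2 * sigma ** 2))


class TestCorrectLsf:
    def test_zero_background_is_identity(self):
        s = ScanProfile(X, slit=gaussian(X))
        b = ScanProfile(X, noslit=np.zeros_like(X))
        assert np.array_equal(correct_lsf(s, b).lsf, gaussian(X))

    def test_leakage_background_cancels(self):
        true_lsf = gaussian(X, 0.8)
        leak = 0.3 * np.ones_like(X)
        s = ScanProfile(X, slit=true_lsf + leak)
        b = ScanProfile(X, noslit=leak)
        assert correct_lsf(s, b).lsf == pytest.approx(true_lsf, abs=1e-12)

    def test_grid_mismatch_rejected(self):
        s = ScanProfile(X, slit=gaussian(X))
        b = ScanProfile(X + 0.1, noslit=np.zeros_like(X))
        with pytest.raises(ValueError, match="grids"):
            correct_lsf(s, b)


class TestSymmetrize:
    def test_symmetric_gaussian_unchanged(self):
        prof = symmetrize_lsf(ScanProfile(X, lsf=gaussian(X)))
        assert np.abs(prof.lsf - prof.lsf[::-1]).max() < 1e-12
        mid = np.interp(0.0, prof.positions, prof.lsf)
        assert mid == pytest.approx(1.0, abs=1e-9)

    def test_shifted_gaussian_recentred(self):
        prof = symmetrize_lsf(ScanProfile(X, lsf=gaussian(X - 0.3)))
        assert np.abs(prof.lsf - prof.lsf[::-1]).max() < 1e-12
        # top-3-centroid centring lands within a fraction of the grid step
        assert prof.lsf.max() == pytest.approx(1.0, abs=5e-3)
        assert prof.positions[np.argmax(prof.lsf)] == pytest.approx(0.0)

    def test_peaked_profile_averages_mirrored_halves(self):
        # equal flank weights put the top-3 centroid exactly on the peak,
        # so the output is hand-computable: mean of the mirrored halves
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        v = np.array([0.1, 0.4, 1.0, 0.4, 0.2])
        prof = symmetrize_lsf(ScanProfile(x, lsf=v))
        assert prof.lsf == pytest.approx(
            [(0.1 + 0.2) / 2, 0.4, 1.0, 0.4, (0.2 + 0.1) / 2])

    def test_flat_profile_rejected(self):
        with pytest.raises(ValueError):
            symmetrize_lsf(ScanProfile(X, lsf=np.ones_like(X)))


class TestExtendTails:
    def test_pure_exponential_keeps_its_decay_constant(self):
        x = np.arange(-6.0, 6.001, 0.25)
        prof = ScanProfile(x, lsf=np.exp(-np.abs(x)))
        ext = extend_tails(prof)
        added = ext.positions > 6.0
        assert added.any()
        slope = np.polyfit(ext.positions[added],
                           np.log(ext.lsf[added]), 1)[0]
        assert slope == pytest.approx(-1.0, rel=0.01)

    def test_compact_triangle_appends_almost_nothing(self):
        x = np.arange(-5.0, 5.001, 0.25)
        tri = np.clip(1 - np.abs(x) / 4.9, 0, None)
        ext = extend_tails(ScanProfile(x, lsf=tri))
        added = np.abs(ext.positions) > 5.0
        if added.any():
            assert ext.lsf[added].max() < 0.02

    def test_gaussian_slope_matches_local_log_slope(self):
        x = np.arange(-4.0, 4.001, 0.25)
        prof = ScanProfile(x, lsf=gaussian(x, 1.0))
        n_fit = max(int(round(0.3 * (x.size // 2))), 3)
        window = x[-n_fit:]
        # local log-slope of a Gaussian is -x/sigma^2 at the window centre
        expected = -np.mean(window)
        ext = extend_tails(prof)
        added = ext.positions > 4.0
        slope = np.polyfit(ext.positions[added][:5],
                           np.log(ext.lsf[added][:5]), 1)[0]
        assert slope == pytest.approx(expected, rel=0.05)

    def test_zero_tail_below_threshold_is_skipped(self):
        x = np.arange(-5.0, 5.001, 0.25)
        v = np.where(np.abs(x) < 1.0, 1.0, 0.0)
        ext = extend_tails(ScanProfile(x, lsf=v))
        assert np.array_equal(ext.positions, x)

    def test_too_few_positive_points_above_threshold_rejected(self):
        x = np.arange(-5.0, 5.001, 0.25)
        v = np.where(np.abs(x) < 1.0, 1.0, 0.0)
        v[-2] = 0.3   # isolated spike in the fit window
        with pytest.raises(ValueError, match="tail"):
            extend_tails(ScanProfile(x, lsf=v))


class TestMtfFromLsf:
    def test_delta_like_lsf_has_flat_mtf(self):
        v = np.zeros_like(X)
        v[X.size // 2] = 1.0
        res = mtf_from_lsf(ScanProfile(X, lsf=v))
        assert np.allclose(res.mtf, 1.0)
        assert res.f50 is None

    def test_gaussian_matches_closed_form(self):
        prof = extend_tails(symmetrize_lsf(ScanProfile(X, lsf=gaussian(X))))
        res = mtf_from_lsf(prof)
        sel = res.frequency <= 0.5
        theory = np.exp(-2 * np.pi ** 2 * res.frequency[sel] ** 2)
        assert np.abs(res.mtf[sel] - theory).max() < 1e-3
        assert res.f50 == pytest.approx(math.sqrt(math.log(2) / 2) / math.pi,
                                        abs=2e-3)

    def test_amplitude_rescaling_leaves_mtf_unchanged(self):
        a = mtf_from_lsf(ScanProfile(X, lsf=gaussian(X)))
        b = mtf_from_lsf(ScanProfile(X, lsf=37.0 * gaussian(X)))
        assert np.allclose(a.mtf, b.mtf, rtol=1e-12)
        assert a.f50 == pytest.approx(b.f50, rel=1e-12)

    def test_non_uniform_grid_rejected(self):
        x = np.array([0.0, 1.0, 2.5, 3.0])
        with pytest.raises(ValueError, match="non-uniform"):
            mtf_from_lsf(ScanProfile(x, lsf=np.ones(4)))


class TestResolutionMetrics:
    def test_gaussian_fwhm(self):
        prof = ScanProfile(X, lsf=gaussian(X))
        assert lsf_fwhm(prof) == pytest.approx(2.3548, abs=0.01)

    def test_metrics_dict(self):
        prof = extend_tails(symmetrize_lsf(ScanProfile(X, lsf=gaussian(X))))
        res = mtf_from_lsf(prof)
        m = resolution_metrics(res, prof)
        assert m["f50_mm^-1"] == pytest.approx(0.1874, abs=2e-3)
        assert m["fwhm_mm"] == pytest.approx(2.3548, abs=0.02)


class TestCrosstalkKernel:
    def test_zero_fraction_is_identity(self):
        from fiberscint.mtf import apply_crosstalk_kernel
        prof = ScanProfile(X, slit=gaussian(X, 0.6))
        out = apply_crosstalk_kernel(prof, 0.0)
        assert np.array_equal(out.slit, prof.slit)

    def test_crosstalk_lowers_f50(self):
        # the qualitative ordering: epoxy cross-talk along x degrades the
        # resolution relative to the clean (y) direction
        from fiberscint.mtf import apply_crosstalk_kernel
        clean = ScanProfile(X, lsf=gaussian(X, 0.6))
        smeared = apply_crosstalk_kernel(
            ScanProfile(X, lsf=gaussian(X, 0.6)), 0.3, 2.0)
        f_clean = mtf_from_lsf(extend_tails(symmetrize_lsf(clean))).f50
        f_x = mtf_from_lsf(extend_tails(symmetrize_lsf(smeared))).f50
        assert f_x < f_clean

    def test_kernel_preserves_total_signal(self):
        from fiberscint.mtf import apply_crosstalk_kernel
        prof = ScanProfile(X, slit=gaussian(X, 0.6))
        out = apply_crosstalk_kernel(prof, 0.25, 1.5)
        assert out.slit.sum() == pytest.approx(prof.slit.sum(), rel=1e-6)


class TestEndToEnd:
    def test_gaussian_scan_recovers_truth_at_high_snr(self):
        # sigma 0.6 mm, SNR ~ 50, leakage background present
        slit, noslit, truth = gen_slit_scan(
            {"kind": "gaussian", "sigma": 0.6}, leakage=0.1, noise=0.02,
            seed=42)
        res, sym = process_scan(slit, noslit)
        sigma_from_f50 = math.sqrt(math.log(2) / 2) / math.pi / res.f50
        assert sigma_from_f50 == pytest.approx(0.6, rel=0.05)
        assert res.fwhm == pytest.approx(truth["fwhm_mm"], rel=0.08)

    def test_pipeline_is_linear_in_signal_scale(self):
        slit, noslit, _ = gen_slit_scan(seed=3, noise=0.0)
        res1, _ = process_scan(slit, noslit)
        big = ScanProfile(slit.positions, slit=slit.slit * 100.0)
        bigb = ScanProfile(noslit.positions, noslit=noslit.noslit * 100.0)
        res2, _ = process_scan(big, bigb)
        assert res2.f50 == pytest.approx(res1.f50, rel=1e-9)

    def test_heavy_tailed_truth_keeps_tail_junction_continuous(self):
        slit, noslit, _ = gen_slit_scan(
            {"kind": "gauss+exp", "sigma": 0.5, "tail_frac": 0.3,
             "tail_len": 2.0}, leakage=0.0, noise=0.0, seed=1)
        corrected = correct_lsf(slit, noslit)
        sym = symmetrize_lsf(corrected)
        ext = extend_tails(sym)
        # continuity at the junction: no jump larger than the local value
        j = np.searchsorted(ext.positions, sym.positions[-1])
        if j + 1 < ext.positions.size:
            jump = abs(ext.lsf[j + 1] - ext.lsf[j])
            assert jump < 0.5 * max(ext.lsf[j], 1e-12) + 1e-6
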