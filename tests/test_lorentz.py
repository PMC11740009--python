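"""Six-pool Lorentzian decomposition, AREX spectra and NOE(-1.6) extraction."""

import numpy as np
import pytest

from cestnoe.bloch import simulate_zspectrum
from cestnoe.core import LorentzPeak, lorentz_peak
from cestnoe.dataset import ZSpectrum
from cestnoe.lorentz import (
    PoolFitSpec,
    amine_guan_rex,
    arex_spectrum,
    b0_correct,
    default_pool_specs,
    extract_noe16,
    fit_map,
    fit_multipool,
    mt_rex,
    noe16_from_fit,
    s_lab,
    s_ref,
)


def synthetic_six_pool(grid, rng=None, noise=0.0):
    """Noiseless (or noisy) Z-spectrum built from six known Lorentzians."""
    specs = default_pool_specs()
    peaks = {}
    for s in specs:
        if rng is None:
            A, W, d = s.A[0], s.W[0], s.delta[0]
        else:
            # draw strictly inside the bounds so recovery is well-posed
            A = rng.uniform(s.A[0] * 0.5, min(s.A[0] * 1.8, s.A[2]))
            W = rng.uniform(max(s.W[0] * 0.7, s.W[1]), min(s.W[0] * 1.4, s.W[2]))
            d = rng.uniform(
                s.delta[0] - 0.3 * (s.delta[0] - s.delta[1]),
                s.delta[0] + 0.3 * (s.delta[2] - s.delta[0]),
            )
        peaks[s.name] = LorentzPeak(A=max(A, 1e-4), W=W, delta_ppm=d)
    z = 1 - sum(lorentz_peak(p, grid.offsets_ppm) for p in peaks.values())
    if noise:
        z = z + (rng or np.random.default_rng(0)).normal(0, noise, size=z.shape)
    return ZSpectrum(grid=grid, z=z, R1obs=0.6, fm=0.07), peaks


class TestFit:
    def test_noiseless_recovery(self, grid):
        rng = np.random.default_rng(17)
        for _ in range(10):
            zs, truth = synthetic_six_pool(grid, rng)
            fit = fit_multipool(zs)
            assert fit.converged
            for name, peak in truth.items():
                got = fit.pools[name]
                assert got.A == pytest.approx(peak.A, rel=0.02), name
                assert got.W == pytest.approx(peak.W, rel=0.05), name

    def test_flat_spectrum(self, grid):
        zs = ZSpectrum(grid=grid, z=np.ones(len(grid)), R1obs=0.6, fm=0.0)
        fit = fit_multipool(zs)
        # water is box-bounded away from zero; every solute amplitude vanishes
        assert all(p.A < 1e-3 for name, p in fit.pools.items() if name != "water")
        assert fit.pools["water"].A <= 0.4 + 1e-9  # pinned at its lower bound

    def test_residual_bounded_by_noise(self, grid):
        rng = np.random.default_rng(3)
        zs, _ = synthetic_six_pool(grid, rng, noise=0.005)
        fit = fit_multipool(zs)
        assert fit.residual <= 0.006  # no systematic underfit

    def test_noisy_noe16_recovery_median(self, grid):
        """With sigma=0.005 noise the NOE(-1.6) amplitude degrades but stays usable."""
        rng = np.random.default_rng(11)
        zs0, truth = synthetic_six_pool(grid)
        errs = []
        for _ in range(60):
            zn = ZSpectrum(
                grid=grid, z=zs0.z + rng.normal(0, 0.005, len(grid)),
                R1obs=0.6, fm=0.07,
            )
            fit = fit_multipool(zn)
            errs.append(abs(fit.pools["noe16"].A - truth["noe16"].A) / truth["noe16"].A)
        assert np.median(errs) < 0.45  # measured ~0.33 at this depth/noise ratio

    def test_bad_start_validation(self):
        with pytest.raises(ValueError):
            PoolFitSpec("x", A=(0.5, 0.0, 0.2), W=(1, 0.5, 2), delta=(0, -1, 1))


class TestLabelReference:
    def test_sref_minus_slab_is_the_pool(self, grid, brain_fit):
        x = grid.offsets_ppm
        for name, peak in brain_fit.pools.items():
            L = peak.A / (1 + ((x - peak.delta_ppm) / (0.5 * peak.W)) ** 2)
            np.testing.assert_allclose(
                s_ref(brain_fit, name, x) - s_lab(brain_fit, x), L, atol=1e-14
            )

    def test_excluding_empty_pool_is_identity(self, grid):
        zs, _ = synthetic_six_pool(grid)
        fit = fit_multipool(zs)
        fit.pools["amide"] = LorentzPeak(A=0.0, W=1.5, delta_ppm=3.5)
        x = grid.offsets_ppm
        np.testing.assert_allclose(s_ref(fit, "amide", x), s_lab(fit, x), atol=1e-15)

    def test_unknown_pool(self, grid, brain_fit):
        with pytest.raises(KeyError):
            s_ref(brain_fit, "nope", grid.offsets_ppm)

    def test_sref_at_center_gives_fitted_amplitude(self, grid):
        zs, _ = synthetic_six_pool(grid)
        fit = fit_multipool(zs)
        d = fit.pools["noe16"].delta_ppm
        gap = s_ref(fit, "noe16", d) - s_lab(fit, d)
        assert gap == pytest.approx(fit.pools["noe16"].A, rel=1e-9)


class TestArexSpectra:
    def test_zero_pool_gives_zero_spectrum(self, grid):
        zs, _ = synthetic_six_pool(grid)
        fit = fit_multipool(zs)
        fit.pools["amide"] = LorentzPeak(A=0.0, W=1.5, delta_ppm=3.5)
        np.testing.assert_allclose(
            arex_spectrum(fit, "amide", 0.6, 0.07, grid.offsets_ppm), 0.0, atol=1e-15
        )

    def test_center_value_matches_hand_evaluation(self, grid, brain_fit):
        d = brain_fit.pools["noe16"].delta_ppm
        zl = s_lab(brain_fit, d)
        zr = s_ref(brain_fit, "noe16", d)
        expected = 0.6 * (1 / zl - 1 / zr) * 1.07
        got = arex_spectrum(brain_fit, "noe16", 0.6, 0.07, np.array([d]))
        assert got[0] == pytest.approx(float(expected))

    def test_peakedness(self, grid, brain_fit):
        p = brain_fit.pools["noe16"]
        x = np.array([p.delta_ppm - 2 * p.W, p.delta_ppm, p.delta_ppm + 2 * p.W])
        v = arex_spectrum(brain_fit, "noe16", 0.6, 0.07, x)
        assert v[1] > v[0] and v[1] > v[2]

    def test_mt_rex(self, grid):
        zs, _ = synthetic_six_pool(grid)
        fit = fit_multipool(zs)
        # scalar check: L_MT = 0.5 at its centre with R1obs = 1 gives 1 s^-1
        fit.pools["mt"] = LorentzPeak(A=0.5, W=25.0, delta_ppm=-2.5)
        assert mt_rex(fit, 1.0, np.array([-2.5]))[0] == pytest.approx(1.0)
        # monotone in L at fixed R1obs
        off = np.array([-2.5, 0.0, 5.0])
        v = mt_rex(fit, 1.0, off)
        assert v[0] > v[1] > v[2]
        fit.pools["mt"] = LorentzPeak(A=0.0, W=25.0, delta_ppm=-2.5)
        np.testing.assert_allclose(mt_rex(fit, 1.0, off), 0.0)

    def test_amine_guan_uses_measured_label(self, grid):
        zs, _ = synthetic_six_pool(grid)
        fit = fit_multipool(zs)
        via_fit = arex_spectrum(fit, "amine_guan", zs.R1obs, zs.fm, grid.offsets_ppm)
        # measured Z equal to the fitted label signal reproduces the fit-based AREX
        fitted_lab = ZSpectrum(grid=grid, z=s_lab(fit, grid.offsets_ppm),
                               R1obs=zs.R1obs, fm=zs.fm)
        via_meas = amine_guan_rex(fit, fitted_lab, zs.R1obs, zs.fm)
        np.testing.assert_allclose(via_meas, via_fit, atol=1e-9)
        # a measured Z below the fitted label increases the AREX everywhere
        lower = ZSpectrum(grid=grid, z=np.clip(s_lab(fit, grid.offsets_ppm) - 0.01, 1e-3, None),
                          R1obs=zs.R1obs, fm=zs.fm)
        assert np.all(amine_guan_rex(fit, lower, zs.R1obs, zs.fm) > via_fit - 1e-12)


class TestB0Correct:
    def test_zero_shift(self, brain_spectrum):
        _, shift = b0_correct(brain_spectrum)
        assert abs(shift) < 0.01

    def test_recovers_injected_shift(self, grid, sat, brain_model):
        import dataclasses

        shifted = dataclasses.replace(brain_model, b0_shift_ppm=0.05)
        zs = simulate_zspectrum(shifted, sat, grid)
        corrected, est = b0_correct(zs)
        assert est == pytest.approx(0.05, abs=0.01)
        _, second = b0_correct(corrected)
        assert abs(second) < 0.005

    def test_large_shift_rejected(self, grid, brain_spectrum):
        rolled = ZSpectrum(
            grid=grid, z=np.roll(brain_spectrum.z, 8), R1obs=0.6, fm=0.07
        )
        with pytest.raises(ValueError):
            b0_correct(rolled, max_shift_ppm=0.5)


class TestExtractNoe16:
    dense = np.arange(-3.0, 0.0, 0.005)

    def test_exact_lorentzian_identity(self):
        vals = lorentz_peak(LorentzPeak(A=0.05, W=0.7, delta_ppm=-1.6), self.dense)
        A, W, peak, censored = extract_noe16(self.dense, vals)
        assert not censored
        assert A == pytest.approx(0.05, rel=0.01)
        assert W == pytest.approx(0.7, rel=0.01)
        assert peak.delta_ppm == -1.6

    def test_off_center_peak_recentred(self):
        vals = lorentz_peak(LorentzPeak(A=0.04, W=0.6, delta_ppm=-1.4), self.dense)
        A, W, peak, _ = extract_noe16(self.dense, vals)
        assert A == pytest.approx(0.04, rel=0.01)  # windowed max is the true peak
        assert peak.delta_ppm == -1.6  # regenerated peak is re-centred

    def test_two_bump_brute_force_max(self):
        vals = lorentz_peak(LorentzPeak(A=0.03, W=0.4, delta_ppm=-1.8), self.dense)
        vals = vals + lorentz_peak(LorentzPeak(A=0.05, W=0.3, delta_ppm=-1.2), self.dense)
        A, _, _, _ = extract_noe16(self.dense, vals)
        brute = np.arange(-2.0, -1.0, 1e-4)
        expected = (
            lorentz_peak(LorentzPeak(A=0.03, W=0.4, delta_ppm=-1.8), brute)
            + lorentz_peak(LorentzPeak(A=0.05, W=0.3, delta_ppm=-1.2), brute)
        ).max()
        assert A == pytest.approx(expected, rel=0.01)

    def test_wide_peak_censored_at_window(self):
        vals = lorentz_peak(LorentzPeak(A=0.05, W=3.0, delta_ppm=-1.6), self.dense)
        _, W, _, censored = extract_noe16(self.dense, vals)
        assert censored
        assert W <= 1.0 + 1e-9  # clipped to the window width

    def test_grid_must_cover_window(self):
        with pytest.raises(ValueError):
            extract_noe16(np.arange(-1.5, 0.0, 0.01), np.zeros(150))


class TestFitMap:
    def test_uniform_phantom_constant_map(self, grid, brain_spectrum):
        out = fit_map([brain_spectrum] * 4)
        assert out["ok"].all()
        assert np.ptp(out["A"]) == 0.0

    def test_two_region_matches_scalar_fits(self, grid, sat, brain_model):
        low = brain_model.replace_param("noe16.fs", brain_model.pools["noe16"].fs * 0.5)
        za = simulate_zspectrum(brain_model, sat, grid)
        zb = simulate_zspectrum(low, sat, grid)
        out = fit_map([za, zb, za, zb])
        fa, _, _, _ = noe16_from_fit(fit_multipool(za), za.R1obs, za.fm, grid)
        fb, _, _, _ = noe16_from_fit(fit_multipool(zb), zb.R1obs, zb.fm, grid)
        np.testing.assert_allclose(out["A"], [fa, fb, fa, fb], rtol=1e-9)

    def test_flat_spectra_give_zero_amplitude(self, grid):
        flat = ZSpectrum(grid=grid, z=np.ones(len(grid)), R1obs=0.6, fm=0.0)
        out = fit_map([flat, flat])
        assert np.all(out["A"][out["ok"]] < 1e-3)
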