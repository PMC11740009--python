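"""Bloch–McConnell simulator: generator structure, spectra, datasets, noise."""

import dataclasses

import numpy as np
import pytest

from cestnoe.bloch import (
    SimDatasetSpec,
    TissueModel,
    WaterPool,
    add_noise,
    assemble_bm_generator,
    generate_dataset,
    ground_truth,
    perturb_parameters,
    simulate_zspectrum,
    tissue_mimicking_spec,
)
from cestnoe.core import PoolParams, SaturationParams, rex

LARMOR = 42.5764 * 4.7


def two_pool_model(rng=None):
    if rng is None:
        return TissueModel(
            water=WaterPool(R1w=0.6, R2w=25.0),
            pools={"s": PoolParams("s", fs=2e-3, ksw=20.0, R2s=30.0, delta_ppm=-1.6)},
        )
    return TissueModel(
        water=WaterPool(R1w=rng.uniform(0.4, 1.0), R2w=rng.uniform(10, 30)),
        pools={
            "s": PoolParams(
                "s",
                fs=rng.uniform(1e-3, 1e-2),
                ksw=rng.uniform(10, 100),
                R2s=rng.uniform(10, 60),
                delta_ppm=rng.uniform(-4, 4),
            )
        },
    )


class TestGenerator:
    def test_water_only_no_rf_decouples_mz(self, grid):
        model = TissueModel(water=WaterPool(), pools={})
        G = assemble_bm_generator(model, SaturationParams(B1_uT=0.0), 100.0, LARMOR)
        # Mz row/column couples only to the constant term, not to Mx/My
        assert G[2, 0] == G[2, 1] == 0.0
        assert G[0, 2] == G[1, 2] == 0.0
        assert G[2, 3] == pytest.approx(model.water.R1w)

    def test_exchange_conserves_magnetization(self, grid, sat):
        model = two_pool_model()
        G = assemble_bm_generator(model, sat, 500.0, LARMOR)
        pool = model.pools["s"]
        # water <-> solute exchange entries, per component
        for c in range(3):
            assert G[c, 3 + c] == pytest.approx(pool.ksw)
            assert G[3 + c, c] == pytest.approx(pool.ksw * pool.fs)

    def test_eigenvalues_nonpositive_real(self, rng, sat):
        for _ in range(50):
            model = two_pool_model(rng)
            G = assemble_bm_generator(model, sat, rng.uniform(-1e4, 1e4), LARMOR)
            eig = np.linalg.eigvals(G[:-1, :-1])
            assert np.all(eig.real <= 1e-9)


class TestSimulate:
    def test_no_saturation_gives_unity(self, grid, brain_model):
        zs = simulate_zspectrum(brain_model, SaturationParams(B1_uT=0.0), grid)
        np.testing.assert_allclose(zs.z, 1.0, atol=1e-10)

    def test_full_on_resonance_saturation(self, grid):
        model = TissueModel(water=WaterPool(R1w=1.0, R2w=20.0), pools={})
        zs = simulate_zspectrum(model, SaturationParams(B1_uT=5.0, t_sat=10.0), grid)
        i = np.argmin(np.abs(grid.offsets_ppm))
        assert zs.z[i] < 0.01

    def test_two_pool_matches_analytic_rex(self, grid, sat):
        """Inverse Z difference at the pool centre reproduces the closed-form Rex."""
        model = two_pool_model()
        ref = dataclasses.replace(model, pools={})
        z = simulate_zspectrum(model, sat, grid).z
        z0 = simulate_zspectrum(ref, sat, grid).z
        i = np.argmin(np.abs(grid.offsets_ppm + 1.6))
        dwc = grid.ppm_to_radps(-1.6)
        cos2 = dwc**2 / (sat.omega1**2 + dwc**2)
        rex_sim = model.water.R1w * (1 / z[i] - 1 / z0[i]) * cos2
        rex_an = rex(model.pools["s"], sat, dwc, grid.larmor_MHz)
        assert rex_sim == pytest.approx(rex_an, rel=0.05)

    def test_mirror_symmetry(self, grid, sat):
        model = TissueModel(
            water=WaterPool(),
            pools={
                "a": PoolParams("a", 2e-3, 50.0, 40.0, 2.5),
                "b": PoolParams("b", 1e-3, 30.0, 20.0, -1.0),
            },
        )
        flipped = TissueModel(
            water=WaterPool(),
            pools={
                "a": PoolParams("a", 2e-3, 50.0, 40.0, -2.5),
                "b": PoolParams("b", 1e-3, 30.0, 20.0, 1.0),
            },
        )
        z = simulate_zspectrum(model, sat, grid).z
        zf = simulate_zspectrum(flipped, sat, grid).z
        np.testing.assert_allclose(z, zf[::-1], atol=1e-12)

    def test_larger_pool_saturates_more(self, grid, sat, brain_model):
        i = np.argmin(np.abs(grid.offsets_ppm + 1.6))
        z_small = simulate_zspectrum(brain_model, sat, grid).z[i]
        bigger = brain_model.replace_param("noe16.fs", brain_model.pools["noe16"].fs * 2)
        z_big = simulate_zspectrum(bigger, sat, grid).z[i]
        assert z_big < z_small

    def test_b0_shift_moves_water_dip(self, grid, sat, brain_model):
        shifted = dataclasses.replace(brain_model, b0_shift_ppm=0.25)
        z = simulate_zspectrum(shifted, sat, grid).z
        dip = grid.offsets_ppm[np.argmin(z)]
        assert dip == pytest.approx(-0.25, abs=0.07)

    def test_propagator_matches_rk4_integration(self, grid, sat):
        """Matrix exponential agrees with fine-step (0.1 ms) RK4 integration."""
        rng = np.random.default_rng(5)
        for _ in range(2):
            model = two_pool_model(rng)
            zs = simulate_zspectrum(model, sat, grid)
            for ppm in (-1.6, 0.375, 3.0):
                i = np.argmin(np.abs(grid.offsets_ppm - ppm))
                G = assemble_bm_generator(model, sat, grid.offsets_radps[i], LARMOR)
                M = np.zeros(G.shape[0])
                M[2] = 1.0
                M[5] = model.pools["s"].fs
                M[-1] = 1.0
                dt = 1e-4
                for _ in range(int(round(sat.t_sat / dt))):
                    k1 = G @ M
                    k2 = G @ (M + 0.5 * dt * k1)
                    k3 = G @ (M + 0.5 * dt * k2)
                    k4 = G @ (M + dt * k3)
                    M = M + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
                assert M[2] == pytest.approx(zs.z[i], abs=1e-4)


class TestDataset:
    def test_factorial_counting(self, grid, sat, brain_model):
        spec = SimDatasetSpec(
            template=brain_model, sat=sat, grid=grid,
            varied_params=[("noe16.fs", (1e-3, 2e-3, 3e-3)), ("mt.fs", (0.05, 0.07, 0.09))],
        )
        assert spec.n_total() == 9
        samples = generate_dataset(spec)
        assert len(samples) == 9

    def test_tissue_mimicking_grid_size(self, grid, sat):
        spec = tissue_mimicking_spec(sat, grid, n_select=5, seed=0)
        assert len(spec.varied_params) == 11
        assert spec.n_total() == 177_147  # 3^11
        samples = generate_dataset(spec)
        assert len(samples) == 5

    def test_ground_truth_is_analytic(self, grid, sat):
        spec = tissue_mimicking_spec(
            sat, grid, n_select=4, seed=3, varied_paths=["noe16.fs", "noe16.ksw"]
        )
        for s in generate_dataset(spec):
            fs, ksw = s.params["noe16.fs"], s.params["noe16.ksw"]
            pool = PoolParams("noe16", fs=fs, ksw=ksw, R2s=30.0, delta_ppm=-1.6)
            expected = rex(pool, sat, grid.ppm_to_radps(-1.6), grid.larmor_MHz)
            assert s.target_A == pytest.approx(float(expected), rel=1e-12)

    def test_cap_refusal(self, grid, sat, brain_model):
        spec = SimDatasetSpec(
            template=brain_model, sat=sat, grid=grid,
            varied_params=[(f"noe16.fs", tuple(np.linspace(1e-3, 5e-3, 30)))] * 4,
            max_size=1000,
        )
        with pytest.raises(ValueError, match="cap"):
            generate_dataset(spec)

    def test_selection_is_seeded(self, grid, sat):
        a = generate_dataset(tissue_mimicking_spec(sat, grid, n_select=3, seed=9,
                                                   varied_paths=["noe16.fs", "mt.fs"]))
        b = generate_dataset(tissue_mimicking_spec(sat, grid, n_select=3, seed=9,
                                                   varied_paths=["noe16.fs", "mt.fs"]))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.zspec.z, y.zspec.z)


class TestPerturb:
    def test_zero_spread_identity(self, brain_model):
        assert perturb_parameters(brain_model, 0.0, seed=1) is brain_model

    def test_multiplier_ranges(self, brain_model):
        rng = np.random.default_rng(0)
        ratios = []
        for _ in range(300):
            p = perturb_parameters(brain_model, 0.3, seed=rng)
            for name in p.pools:
                if name == "noe16":
                    # NOE(-1.6) parameters must never be perturbed
                    assert p.pools[name] == brain_model.pools[name]
                else:
                    ratios.append(p.pools[name].fs / brain_model.pools[name].fs)
        ratios = np.array(ratios)
        assert np.all((ratios >= 0.7) & (ratios <= 1.3))
        assert ratios.mean() == pytest.approx(1.0, abs=0.01)

    def test_binary_mode_endpoints(self, brain_model):
        rng = np.random.default_rng(1)
        p = perturb_parameters(brain_model, 0.3, seed=rng, mode="binary")
        for name in p.pools:
            if name == "noe16":
                continue
            ratio = p.pools[name].fs / brain_model.pools[name].fs
            assert min(abs(ratio - 0.7), abs(ratio - 1.3)) < 1e-12


class TestNoise:
    def test_deterministic(self, brain_spectrum):
        a = add_noise(brain_spectrum, 75.0, seed=4)
        b = add_noise(brain_spectrum, 75.0, seed=4)
        np.testing.assert_array_equal(a.z, b.z)

    def test_std_matches_inverse_snr(self, brain_spectrum):
        rng = np.random.default_rng(2)
        devs = np.concatenate(
            [add_noise(brain_spectrum, 200.0, seed=rng).z - brain_spectrum.z
             for _ in range(1200)]
        )
        assert devs.std() == pytest.approx(0.005, rel=0.02)
        assert devs.mean() == pytest.approx(0.0, abs=1e-4)

    def test_infinite_snr_limit(self, brain_spectrum):
        out = add_noise(brain_spectrum, 1e12, seed=0)
        np.testing.assert_allclose(out.z, brain_spectrum.z, atol=1e-10)
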