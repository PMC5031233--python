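import dataclasses

import numpy as np
import pytest

import krigfield as kf
from krigfield import constants
from krigfield.normal_modes import NormalModeSet
from krigfield.sampler import (
    SamplerConfig,
    amplitudes,
    assign_phases,
    distribute_energy,
    generate,
    generate_multi,
    total_energy,
)


class TestEnergyBookkeeping:
    def test_total_energy_formula(self):
        e = total_energy(42, 300.0)
        assert np.isclose(e, 42 * constants.BOLTZMANN_HARTREE_PER_K * 150.0,
                          rtol=1e-14)

    def test_distribution_conserves_total_exactly(self):
        rng = np.random.default_rng(0)
        e = distribute_energy(1.234e-3, 42, rng)
        assert e.size == 42
        assert np.all(e >= 0)
        assert abs(e.sum() - 1.234e-3) <= 1e-12 * 1.234e-3

    def test_single_mode_gets_everything(self):
        rng = np.random.default_rng(0)
        assert distribute_energy(2.0, 1, rng)[0] == 2.0

    def test_negative_energy_rejected(self):
        with pytest.raises(ValueError):
            distribute_energy(-1.0, 3, np.random.default_rng(0))

    def test_amplitude_energy_identity(self):
        # k A^2 / 2 = E for every mode
        rng = np.random.default_rng(1)
        e = rng.uniform(0.0, 1e-3, size=5)
        k = rng.uniform(1e-5, 1e-3, size=5)
        a = amplitudes(e, k)
        assert np.allclose(0.5 * k * a**2, e, rtol=1e-12)

    def test_nonpositive_force_constant_rejected(self):
        with pytest.raises(ValueError):
            amplitudes(np.array([1.0]), np.array([0.0]))


class TestPhases:
    def test_uniform_range(self):
        ph = assign_phases(1000, np.random.default_rng(0))
        assert ph.min() >= 0.0 and ph.max() < 2 * np.pi

    def test_coherent_mode_zeroes_phases(self):
        assert np.all(assign_phases(7, np.random.default_rng(0), coherent=True) == 0)


class TestGenerate:
    def test_zero_temperature_reproduces_seed(self, triatomic, triatomic_modes):
        cfg = SamplerConfig(temperature_K=0.0, n_samples=5, seed=3)
        out = generate(triatomic.geometry, triatomic_modes, cfg)
        for g in out:
            assert np.abs(g.coords - triatomic.geometry.coords).max() < 1e-12

    def test_sample_count_and_determinism(self, triatomic, triatomic_modes):
        cfg = SamplerConfig(n_samples=17, seed=5)
        a = generate(triatomic.geometry, triatomic_modes, cfg)
        b = generate(triatomic.geometry, triatomic_modes, cfg)
        assert len(a) == len(b) == 17
        assert all(np.array_equal(x.coords, y.coords) for x, y in zip(a, b))

    def test_different_seed_differs(self, triatomic, triatomic_modes):
        base = SamplerConfig(n_samples=4, seed=5)
        other = dataclasses.replace(base, seed=6)
        a = generate(triatomic.geometry, triatomic_modes, base)
        b = generate(triatomic.geometry, triatomic_modes, other)
        assert not np.allclose(a[0].coords, b[0].coords)

    def test_single_mode_matches_closed_harmonic_form(self, triatomic, triatomic_modes):
        # keep only one vibrational mode; the Cartesian displacement must be
        # A sin(2 pi s/ncycle + phi) * shape / sqrt(m) exactly
        one = NormalModeSet(
            eigenvalues=triatomic_modes.eigenvalues[:1],
            eigenvectors=triatomic_modes.eigenvectors[:, :1],
            frequencies=triatomic_modes.frequencies[:1],
            force_constants=triatomic_modes.force_constants[:1],
            reduced_masses=triatomic_modes.reduced_masses[:1],
        )
        cfg = SamplerConfig(n_samples=6, seed=11, ncycle=10, nreset=100)
        out = generate(triatomic.geometry, one, cfg)

        rng = np.random.default_rng(cfg.seed)
        e = distribute_energy(total_energy(1, cfg.temperature_K), 1, rng)
        phi = assign_phases(1, rng)[0]
        amp = amplitudes(e, one.eigenvalues)[0]
        inv_sqrt_m = 1.0 / np.sqrt(np.repeat(triatomic.geometry.masses, 3))
        for s, g in enumerate(out):
            arg = 2 * np.pi * (s + 1) / cfg.ncycle + phi
            dx = (amp * np.sin(arg) * one.eigenvectors[:, 0] * inv_sqrt_m)
            ref = triatomic.geometry.coords + dx.reshape(-1, 3)
            assert np.abs(g.coords - ref).max() < 1e-10

    def test_energy_reset_every_nreset_samples(self, triatomic, triatomic_modes):
        # with nreset=2 and ncycle=10, samples 0 and 1 share amplitudes and
        # phases; sample 2 starts a fresh block and must differ from the
        # continuation of block 1
        cfg = SamplerConfig(n_samples=4, seed=7, nreset=2, ncycle=10)
        out = generate(triatomic.geometry, triatomic_modes, cfg)
        cfg_long = dataclasses.replace(cfg, nreset=4)
        out_long = generate(triatomic.geometry, triatomic_modes, cfg_long)
        # same first block
        assert np.allclose(out[0].coords, out_long[0].coords, atol=1e-14)
        assert np.allclose(out[1].coords, out_long[1].coords, atol=1e-14)
        # diverges after the redraw
        assert not np.allclose(out[2].coords, out_long[2].coords)

    def test_imaginary_mode_rejected(self, triatomic, triatomic_modes):
        bad = NormalModeSet(
            eigenvalues=-triatomic_modes.eigenvalues,
            eigenvectors=triatomic_modes.eigenvectors,
            frequencies=-triatomic_modes.frequencies,
            force_constants=triatomic_modes.force_constants,
            reduced_masses=triatomic_modes.reduced_masses,
        )
        with pytest.raises(ValueError, match="minimum"):
            generate(triatomic.geometry, bad, SamplerConfig(n_samples=1))


class TestGenerateMulti:
    def test_splits_counts_over_seed_minima(self, triatomic_modes):
        fx = kf.make_fixture("double_well", n_minima=3)
        seeds = [
            (g, kf.vibrational_analysis(g, h))
            for g, h in zip(fx.geometries, fx.hessians)
        ]
        out = generate_multi(seeds, SamplerConfig(n_samples=10, seed=0))
        assert len(out) == 10
        # earlier seeds absorb the remainder: 4 + 3 + 3
        com0 = fx.geometries[0].coords.mean(axis=0)
        com1 = fx.geometries[1].coords.mean(axis=0)
        first = out[0].coords.mean(axis=0)
        fifth = out[4].coords.mean(axis=0)
        assert np.linalg.norm(first - com0) < np.linalg.norm(first - com1)
        assert np.linalg.norm(fifth - com1) < np.linalg.norm(fifth - com0)

    def test_empty_seed_list_rejected(self):
        with pytest.raises(ValueError):
            generate_multi([], SamplerConfig(n_samples=5))


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs", [dict(ncycle=1), dict(nreset=0), dict(n_samples=0),
                   dict(temperature_K=-1.0)]
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SamplerConfig(**kwargs)
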