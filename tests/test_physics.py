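"""Forward physics: attenuation, simulation, calibration, mAs handling."""

import dataclasses

import numpy as np
import pytest

from ssbmd import phantoms, physics
from ssbmd.physics import (
    ENERGY_GRID_KEV,
    MU_RHO_CM2G,
    DENSITY_G_CM3,
    ConfigurationError,
    FittingError,
    attenuation_coefficient,
    calibrate_system,
    mas_normalize,
    monoenergetic_system,
    simulate_radiograph,
)


class TestAttenuation:
    def test_monotone_decrease_with_energy(self):
        assert attenuation_coefficient("soft", 60.0) < attenuation_coefficient("soft", 20.0)
        e = np.linspace(10, 60, 101)
        for material in ("soft", "bone"):
            mu = attenuation_coefficient(material, e)
            assert np.all(np.diff(mu) < 0)

    def test_bone_exceeds_soft_at_all_energies(self):
        e = np.linspace(10, 60, 101)
        assert np.all(attenuation_coefficient("bone", e) > attenuation_coefficient("soft", e))

    def test_interpolation_identity_at_grid_points(self):
        for material in ("soft", "bone"):
            expected = MU_RHO_CM2G[material] * DENSITY_G_CM3[material]
            got = attenuation_coefficient(material, ENERGY_GRID_KEV)
            assert np.allclose(got, expected, rtol=1e-12)

    def test_energy_out_of_range(self):
        with pytest.raises(ValueError):
            attenuation_coefficient("soft", 5.0)


class TestSimulate:
    def test_vacuum_limit(self, system):
        m = phantoms.make_slab_phantom(0.0, 1.0, (16, 16), system.pixel_pitch)
        r = simulate_radiograph(m, system, mas=2.0, noiseless=True)
        w, _, _ = system.spectral_terms()
        expected = 2.0 * w.sum()
        assert np.allclose(r.intensity, expected, rtol=1e-12)

    def test_monoenergetic_beer_lambert(self):
        # Single 40 keV bin, scatter off: closed-form exponential attenuation.
        sys40 = monoenergetic_system(
            40.0, pixel_pitch=0.15, scatter=physics.ScatterModel(s0=0.0)
        )
        m = phantoms.make_slab_phantom(4.0, 1.0, (8, 8), 0.15)
        r = simulate_radiograph(m, sys40, mas=2.0, noiseless=True)
        i0 = sys40.vacuum_intensity(2.0)
        mu = attenuation_coefficient("soft", 40.0)
        assert np.allclose(r.intensity, i0 * np.exp(-mu * 4.0), rtol=1e-12)

    def test_default_acquisition_metadata(self):
        # Default protocol: 60 kVp, 2 mAs, 24 cm x 12 cm field of view.
        system = physics.default_system(pixel_pitch=0.05)
        m = phantoms.make_slab_phantom(2.0, 1.0, (240, 480), 0.05)
        r = simulate_radiograph(m, system, mas=2.0, noiseless=True)
        assert r.kvp == 60.0
        assert r.mas == 2.0
        assert r.fov_cm == (12.0, 24.0)

    def test_pitch_mismatch_rejected(self, system):
        m = phantoms.make_slab_phantom(2.0, 1.0, (8, 8), 0.05)
        with pytest.raises(ConfigurationError):
            simulate_radiograph(m, system, mas=2.0)

    def test_primary_decreases_with_thickness_and_bone(self, system, rng):
        # Material ordering and Beer-Lambert monotonicity on random slabs.
        for _ in range(20):
            t = rng.uniform(0.5, 8.0)
            a = rng.uniform(0.1, 1.0)
            base = simulate_radiograph(
                phantoms.make_slab_phantom(t, a, (8, 8), system.pixel_pitch),
                system, mas=2.0, noiseless=True,
            ).intensity.mean()
            thicker = simulate_radiograph(
                phantoms.make_slab_phantom(t + 0.5, a, (8, 8), system.pixel_pitch),
                system, mas=2.0, noiseless=True,
            ).intensity.mean()
            bonier = simulate_radiograph(
                phantoms.make_slab_phantom(t, a * 0.8, (8, 8), system.pixel_pitch),
                system, mas=2.0, noiseless=True,
            ).intensity.mean()
            assert thicker < base
            assert bonier < base

    def test_poisson_consistency(self, system):
        # Mean of 500 seeded noisy images within 3 standard errors of the
        # noiseless expectation.
        m = phantoms.make_slab_phantom(4.0, 0.8, (12, 12), system.pixel_pitch)
        expected = simulate_radiograph(m, system, mas=2.0, noiseless=True).intensity
        acc = np.zeros_like(expected)
        n = 500
        for seed in range(n):
            acc += simulate_radiograph(m, system, mas=2.0, seed=seed).intensity
        mean = acc / n
        se = np.sqrt(expected / n)
        z = (mean - expected) / se
        assert np.abs(z.mean()) < 3.0
        assert (np.abs(z) > 4.5).mean() < 0.01

    def test_scatter_nonnegative_and_zero_without_s0(self):
        sys_off = monoenergetic_system(40.0, pixel_pitch=0.15,
                                       scatter=physics.ScatterModel(s0=0.0))
        sys_on = monoenergetic_system(40.0, pixel_pitch=0.15)
        m = phantoms.make_slab_phantom(4.0, 0.7, (24, 24), 0.15)
        off = simulate_radiograph(m, sys_off, 2.0, noiseless=True).intensity
        on = simulate_radiograph(m, sys_on, 2.0, noiseless=True).intensity
        assert np.all(on >= off)
        i0 = sys_off.vacuum_intensity(2.0)
        mu_eff = (attenuation_coefficient("soft", 40.0) * 0.7
                  + attenuation_coefficient("bone", 40.0) * 0.3)
        assert np.allclose(off, i0 * np.exp(-mu_eff * 4.0), rtol=1e-12)

    def test_signal_linear_in_mas(self, system):
        m = phantoms.make_slab_phantom(4.0, 0.8, (8, 8), system.pixel_pitch)
        totals = [
            simulate_radiograph(m, system, mas=mas, noiseless=True).intensity.sum()
            for mas in (1.0, 2.0, 4.0)
        ]
        assert totals[1] == pytest.approx(2 * totals[0], rel=1e-12)
        assert totals[2] == pytest.approx(4 * totals[0], rel=1e-12)

    def test_noise_deterministic_given_seed(self, system):
        m = phantoms.make_slab_phantom(4.0, 0.8, (8, 8), system.pixel_pitch)
        r1 = simulate_radiograph(m, system, 2.0, seed=9)
        r2 = simulate_radiograph(m, system, 2.0, seed=9)
        assert np.array_equal(r1.intensity, r2.intensity)


class TestMasNormalize:
    def test_identity(self, system):
        m = phantoms.make_slab_phantom(3.0, 0.9, (8, 8), system.pixel_pitch)
        r = simulate_radiograph(m, system, 2.0, noiseless=True)
        same = mas_normalize(r, 2.0)
        assert np.array_equal(same.intensity, r.intensity)

    def test_linearity_across_exposures(self, system):
        m = phantoms.make_slab_phantom(3.0, 0.9, (8, 8), system.pixel_pitch)
        r2 = simulate_radiograph(m, system, 2.0, noiseless=True)
        r4 = simulate_radiograph(m, system, 4.0, noiseless=True)
        n = mas_normalize(r4, 2.0)
        assert np.allclose(n.intensity, r2.intensity, rtol=1e-12)
        assert n.mas == 2.0

    def test_halving(self, system):
        m = phantoms.make_slab_phantom(3.0, 0.9, (8, 8), system.pixel_pitch)
        r = simulate_radiograph(m, system, 2.0, noiseless=True)
        half = mas_normalize(r, 1.0)
        assert np.allclose(half.intensity, r.intensity / 2.0, rtol=1e-12)

    def test_invalid_reference(self, system):
        m = phantoms.make_slab_phantom(3.0, 0.9, (8, 8), system.pixel_pitch)
        r = simulate_radiograph(m, system, 2.0, noiseless=True)
        with pytest.raises(ValueError):
            mas_normalize(r, 0.0)


@pytest.fixture(scope="module")
def wedge_exposure(system):
    wedge = phantoms.make_step_wedge(
        [(float(t), 1.0) for t in range(1, 9)], (40, 160), system.pixel_pitch
    )
    r = simulate_radiograph(wedge, system, 2.0, noiseless=True)
    return wedge, r


class TestCalibration:
    def test_self_calibration_fixed_point(self, system, wedge_exposure):
        wedge, r = wedge_exposure
        fit = calibrate_system([(r, wedge)], system)
        assert fit.gain == pytest.approx(system.gain, rel=1e-9)
        assert fit.scatter.s0 == pytest.approx(system.scatter.s0, abs=1e-9)
        assert fit.scatter.tau_cm == pytest.approx(system.scatter.tau_cm, rel=1e-9)
        assert fit.calibration.residual_rms < 1e-10

    def test_gain_recovery(self, system, wedge_exposure):
        wedge, _ = wedge_exposure
        truth = dataclasses.replace(system, gain=system.gain * 1.1)
        r = simulate_radiograph(wedge, truth, 2.0, noiseless=True)
        fit = calibrate_system([(r, wedge)], system)
        assert abs(fit.gain / truth.gain - 1.0) < 0.01

    def test_calibration_default_kvp(self, system):
        assert system.kvp == 60.0

    def test_degenerate_wedge_rejected(self, system):
        wedge = phantoms.make_step_wedge(
            [(2.0, 1.0), (2.0, 1.0)], (16, 32), system.pixel_pitch
        )
        r = simulate_radiograph(wedge, system, 2.0, noiseless=True)
        with pytest.raises(FittingError):
            calibrate_system([(r, wedge)], system)


def test_system_config_round_trip(tmp_path, system):
    path = str(tmp_path / "system.json")
    physics.save_system(path, system)
    back = physics.load_system(path)
    assert back.gain == system.gain
    assert back.kvp == system.kvp
    assert back.scatter == system.scatter
    assert np.allclose(back.spectrum.weights, system.spectrum.weights)
    m = phantoms.make_slab_phantom(3.0, 0.8, (8, 8), system.pixel_pitch)
    a = simulate_radiograph(m, system, 2.0, noiseless=True).intensity
    b = simulate_radiograph(m, back, 2.0, noiseless=True).intensity
    assert np.allclose(a, b, rtol=1e-12)


def test_radiograph_io_round_trip(tmp_path, system):
    m = phantoms.make_slab_phantom(4.0, 0.8, (16, 16), system.pixel_pitch)
    r = simulate_radiograph(m, system, 2.0, noiseless=True)
    path = str(tmp_path / "radiograph.png")
    physics.write_radiograph(path, r)
    back = physics.read_radiograph(path)
    assert back.kvp == r.kvp and back.mas == r.mas
    assert np.allclose(back.intensity, r.intensity, rtol=1e-4)
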