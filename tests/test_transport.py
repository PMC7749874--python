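"""Monte Carlo engine: source sampling, physics oracles, scan contracts."""

import numpy as np
import pytest
from scipy.integrate import quad

from oemdose.beam import BowtieFilter, Spectrum
from oemdose.errors import InvalidInputError
from oemdose.materials import ELECTRON_REST_KEV
from oemdose.oem import build_angular_profile
from oemdose.phantoms import VoxelPhantom
from oemdose.transport import (
    KEV_TO_MGY_G,
    CTGeometry,
    ScanProtocol,
    TransportEngine,
    free_air_kerma_per_photon,
    run_scan,
    sample_compton,
    sample_source_photons,
)


def kn_differential(eps, k):
    """Klein-Nishina differential cross-section per unit eps (unnormalized)."""
    cos_t = 1.0 - (1.0 - eps) / (k * eps)
    sin2 = 1.0 - cos_t**2
    return (1.0 / eps + eps) * (1.0 - eps * sin2 / (1.0 + eps**2))


def water_block(n=25, voxel_mm=4.0):
    return VoxelPhantom(np.zeros((n, n, n), dtype=np.float32), voxel_mm, name="water")


class TestSourceSampling:
    def test_weight_is_oem_output_on_central_ray(self, raw_spectrum80, rng):
        prof = build_angular_profile("front", 500)
        geom = CTGeometry(fov_mm=0.0, beam_width_mm=0.0)  # central ray only
        angles = rng.uniform(0.0, 360.0, 2000)
        _, _, _, w = sample_source_photons(
            rng, 2000, raw_spectrum80, BowtieFilter.flat(), geom, prof,
            gantry_angles_deg=angles,
        )
        np.testing.assert_allclose(w, prof.relative_output(angles), atol=1e-12)

    def test_oem_off_weights_are_bowtie_transmission(self, raw_spectrum80, rng):
        geom = CTGeometry()
        _, _, e, w = sample_source_photons(
            rng, 5000, raw_spectrum80, BowtieFilter.flat(), geom, None
        )
        np.testing.assert_allclose(w, 1.0, atol=1e-12)

    def test_sampled_energy_mean_matches_spectrum(self, raw_spectrum80, rng):
        n = 100_000
        e = raw_spectrum80.sample(rng, n)
        se = e.std(ddof=1) / np.sqrt(n)
        assert abs(e.mean() - raw_spectrum80.mean_energy_keV) < 3 * se

    def test_directions_unit_norm(self, raw_spectrum80, rng):
        _, d, _, _ = sample_source_photons(
            rng, 1000, raw_spectrum80, BowtieFilter.flat(), CTGeometry()
        )
        np.testing.assert_allclose(np.linalg.norm(d, axis=1), 1.0, atol=1e-12)


class TestComptonSampling:
    @pytest.mark.parametrize("energy", [60.0, 80.0])
    def test_mean_scattered_fraction_matches_quadrature(self, energy, rng):
        n = 100_000
        eps, cos_t = sample_compton(rng, np.full(n, energy))
        k = energy / ELECTRON_REST_KEV
        lo = 1.0 / (1.0 + 2.0 * k)
        num = quad(lambda e: e * kn_differential(e, k), lo, 1.0)[0]
        den = quad(lambda e: kn_differential(e, k), lo, 1.0)[0]
        se = eps.std(ddof=1) / np.sqrt(n)
        assert abs(eps.mean() - num / den) < 3 * se
        # kinematic consistency of the returned angle
        np.testing.assert_allclose(cos_t, 1.0 - (1.0 - eps) / (k * eps), atol=1e-12)


class TestTransport:
    def test_air_only_grid_deposits_nothing(self, rng):
        ph = VoxelPhantom(np.full((10, 10, 10), -1000.0, dtype=np.float32), 10.0)
        eng = TransportEngine(ph)
        n = 1000
        res = eng.run(
            np.tile([-200.0, 0.0, 0.0], (n, 1)), np.tile([1.0, 0.0, 0.0], (n, 1)),
            np.full(n, 60.0), np.ones(n), rng,
        )
        # air attenuation over ~10 cm is ~2e-4; essentially nothing deposits
        assert res["deposited_keV"] < 1e-3 * res["emitted_keV"]

    def test_primary_transmission_through_water(self, materials, rng):
        ph = water_block()
        eng = TransportEngine(ph)
        n = 100_000
        res = eng.run(
            np.tile([-200.0, 0.0, 0.0], (n, 1)), np.tile([1.0, 0.0, 0.0], (n, 1)),
            np.full(n, 60.0), np.ones(n), rng,
        )
        frac = 1.0 - res["interacted"].mean()
        expected = np.exp(-materials["water"].mu_at(60.0) * 10.0)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 3 * se

    def test_energy_conservation(self, cylinder, rng):
        eng = TransportEngine(cylinder)
        n = 20_000
        pos = np.tile([-300.0, 0.0, 0.0], (n, 1))
        d = np.tile([1.0, 0.0, 0.0], (n, 1))
        res = eng.run(pos, d, np.full(n, 50.0), np.ones(n), rng)
        assert 0.0 < res["deposited_keV"] <= res["emitted_keV"]

    def test_deterministic_for_seed(self, cylinder):
        eng = TransportEngine(cylinder)
        n = 5000
        args = (
            np.tile([-300.0, 0.0, 0.0], (n, 1)),
            np.tile([1.0, 0.0, 0.0], (n, 1)),
            np.full(n, 50.0),
            np.ones(n),
        )
        a = eng.run(*args, np.random.default_rng(99))
        b = eng.run(*args, np.random.default_rng(99))
        assert np.array_equal(a["edep_keV"], b["edep_keV"])


class TestFreeAirKerma:
    def test_pencil_beam_closed_form(self, materials):
        s = Spectrum.monoenergetic(40.0)
        geom = CTGeometry(fov_mm=0.0, beam_width_mm=0.0)
        kerma, _ = free_air_kerma_per_photon(s, geom, n_photons=20_000)
        r = 1.5  # cm, default scoring sphere
        expected = (
            40.0 * materials["air"].mu_en_rho_at(40.0)
            * 2.0 * r / (4.0 / 3.0 * np.pi * r**3) * KEV_TO_MGY_G
        )
        assert kerma == pytest.approx(expected, rel=1e-9)

    def test_linear_in_weight(self, raw_spectrum80):
        k1, _ = free_air_kerma_per_photon(raw_spectrum80, n_photons=50_000, seed=4)
        half = Spectrum(
            raw_spectrum80.energies_keV, raw_spectrum80.weights,
            raw_spectrum80.tube_voltage_kV,
        )
        k2, _ = free_air_kerma_per_photon(half, n_photons=50_000, seed=4)
        assert k1 == pytest.approx(k2)  # normalized spectra: same per-photon kerma


class TestRunScan:
    def test_requires_seed_and_photon_floor(self, cylinder):
        proto = ScanProtocol(80.0, (220.0,), 11.17)
        with pytest.raises(InvalidInputError):
            run_scan(cylinder, proto, None, 50_000, seed=None)
        with pytest.raises(InvalidInputError):
            run_scan(cylinder, proto, None, 100, seed=1)

    def test_dose_linear_in_mas(self, cylinder, spectrum80):
        base = dict(n_photons=20_000, seed=21, batches=2, spectrum=spectrum80)
        d1 = run_scan(cylinder, ScanProtocol(80.0, (100.0,), 11.17), None, **base)
        d2 = run_scan(cylinder, ScanProtocol(80.0, (200.0,), 11.17), None, **base)
        mask = cylinder.density > 0.5
        np.testing.assert_allclose(
            d2.dose_mGy[mask], 2.0 * d1.dose_mGy[mask], rtol=1e-9
        )

    def test_reproducible_grids(self, cylinder, spectrum80):
        proto = ScanProtocol(80.0, (220.0,), 11.17)
        a = run_scan(cylinder, proto, None, 20_000, seed=5, batches=2, spectrum=spectrum80)
        b = run_scan(cylinder, proto, None, 20_000, seed=5, batches=2, spectrum=spectrum80)
        assert np.array_equal(a.dose_mGy, b.dose_mGy)
        assert a.provenance["kerma_per_photon_mGy"] == b.provenance["kerma_per_photon_mGy"]

    def test_more_photons_reduce_uncertainty(self, cylinder, spectrum80):
        proto = ScanProtocol(80.0, (220.0,), 11.17)
        small = run_scan(cylinder, proto, None, 20_000, seed=31, batches=4, spectrum=spectrum80)
        large = run_scan(cylinder, proto, None, 80_000, seed=32, batches=4, spectrum=spectrum80)
        mask = cylinder.density > 0.5
        m_s, se_s = small.mean_over(mask)
        m_l, se_l = large.mean_over(mask)
        # means agree within combined 3 SE; variance drops with photon count
        assert abs(m_s - m_l) < 3 * np.hypot(se_s, se_l)
        assert se_l < se_s
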