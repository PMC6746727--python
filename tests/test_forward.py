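"""Projection geometry, polychromatic forward model and noise."""

import numpy as np
import pytest

from kesct.errors import DegenerateInputError, ValidationError
from kesct.phantom import (MuMap, PhantomSpec, Primitive, disc_phantom,
                           vessel_material)
from kesct.forward import (Geometry, Sinogram, absorption_image,
                           effective_pixel_size, line_integrals,
                           monochromatic_projection, photons_per_pixel,
                           polychromatic_projection, slab_transmission)
from kesct.spectrum import EnergyGrid, Spectrum

from conftest import make_geometry


def two_bin_spectrum(e1=32.0, e2=34.0, f1=3.0e9, f2=1.0e10):
    grid = EnergyGrid(bin_centers=np.array([e1, e2]), bin_width=e2 - e1)
    return Spectrum(grid=grid, fluence_rate=np.array([f1, f2]), label="two")


class TestEffectivePixel:
    def test_published_geometry(self):
        eff = effective_pixel_size(74.8, 15.3, 16.4)
        assert eff == pytest.approx(74.8 * 15.3 / 16.4, rel=1e-14)
        assert eff == pytest.approx(69.78, abs=0.005)
        assert round(eff, -1) == 70.0

    def test_unit_magnification(self):
        assert effective_pixel_size(74.8, 5.0, 5.0) == 74.8

    def test_inverse_proportionality(self):
        assert effective_pixel_size(74.8, 10.0, 40.0) == pytest.approx(
            effective_pixel_size(74.8, 10.0, 20.0) / 2.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            effective_pixel_size(-1.0, 15.3, 16.4)
        with pytest.raises(ValidationError):
            Geometry(angles_deg=np.array([0.0]), n_detector_bins=8,
                     source_sample_m=17.0)


class TestLineIntegrals:
    def test_zero_map_projects_to_zero(self):
        m = MuMap(values=np.zeros((64, 64)), energy_kev=33.0,
                  voxel_size_mm=0.1)
        geo = make_geometry(64, 0.1, [0.0, 45.0])
        assert np.all(line_integrals(m, geo) == 0.0)

    def test_disc_closed_form(self):
        radius, mu, vox = 8.0, 0.2, 0.07
        d = disc_phantom(radius, mu, grid_size=512, voxel_size_mm=vox)
        geo = make_geometry(512, vox, [0.0, 30.0, 77.0])
        sino = line_integrals(d, geo)
        s = (np.arange(512) - 512 // 2) * vox
        truth = 2 * mu * np.sqrt(np.maximum(radius**2 - s**2, 0.0))
        inside = np.abs(s) < 0.75 * radius
        for row in sino:
            rel = np.abs(row[inside] - truth[inside]) / truth[inside]
            assert np.sqrt(np.mean(rel**2)) < 0.01
        # central ray: 2 * mu * r
        assert sino[0, 512 // 2] == pytest.approx(2 * mu * radius, rel=0.01)
        # rays outside the disc
        assert np.all(sino[:, np.abs(s) > radius + 2 * vox] == 0.0)

    def test_rotating_map_permutes_angles(self):
        n = 65
        rng = np.random.default_rng(0)
        img = np.zeros((n, n))
        img[20:30, 10:25] = rng.uniform(0.1, 0.3, (10, 15))
        geo = make_geometry(n, 0.1, [0.0, 30.0, 60.0, 90.0])
        geo90 = make_geometry(n, 0.1, [90.0, 120.0, 150.0, 180.0])
        base = line_integrals(
            MuMap(values=img, energy_kev=33.0, voxel_size_mm=0.1), geo)
        rotated = line_integrals(
            MuMap(values=np.rot90(img).copy(), energy_kev=33.0,
                  voxel_size_mm=0.1), geo90)
        np.testing.assert_allclose(rotated, base, atol=1e-10)

    def test_geometry_mismatch_rejected(self):
        m = MuMap(values=np.zeros((64, 64)), energy_kev=33.0,
                  voxel_size_mm=0.2)
        geo = make_geometry(64, 0.1, [0.0])
        with pytest.raises(ValidationError):
            line_integrals(m, geo)


class TestPolychromatic:
    def test_vacuum_transmission_is_one(self):
        ph = PhantomSpec(grid_shape=(64, 64), voxel_size_mm=0.1,
                         primitives=())
        geo = make_geometry(64, 0.1, [0.0, 90.0])
        sino = polychromatic_projection(ph, two_bin_spectrum(), geo)
        np.testing.assert_allclose(sino.transmission, 1.0, atol=1e-12)

    def test_single_bin_reduces_to_beer_lambert(self, registry):
        w = registry.get("water")
        ph = PhantomSpec(grid_shape=(64, 64), voxel_size_mm=0.1,
                         primitives=(Primitive("ellipse", (0, 0), (2.5, 2.5),
                                               w, "water"),))
        geo = make_geometry(64, 0.1, [0.0, 40.0])
        mono = Spectrum(grid=EnergyGrid(bin_centers=np.array([33.0]),
                                        bin_width=0.025),
                        fluence_rate=np.array([1e9]), label="mono")
        sino = polychromatic_projection(ph, mono, geo)
        from kesct.phantom import render_mu_map
        expect = np.exp(-line_integrals(render_mu_map(ph, 33.0), geo))
        np.testing.assert_allclose(sino.transmission, expect, rtol=1e-12)

    def test_water_slab_two_bin_hand_sum(self, registry):
        """Independent two-bin oracle for the detector-weighted spectral
        average."""
        w = registry.get("water")
        s = two_bin_spectrum()
        d = 10.0  # mm
        t = slab_transmission(w, d, s, weighting="energy")
        mu1 = w.linear_attenuation(32.0)
        mu2 = w.linear_attenuation(34.0)
        w1, w2 = 32.0 * 3.0e9, 34.0 * 1.0e10
        hand = (w1 * np.exp(-mu1 * d) + w2 * np.exp(-mu2 * d)) / (w1 + w2)
        assert t == pytest.approx(hand, rel=1e-12)
        # photon-counting weighting drops the energy factors
        t_cnt = slab_transmission(w, d, s, weighting="counting")
        hand_cnt = (3.0e9 * np.exp(-mu1 * d) + 1.0e10 * np.exp(-mu2 * d)) / 1.3e10
        assert t_cnt == pytest.approx(hand_cnt, rel=1e-12)

    def test_beam_hardening_direction(self, spectrum_pair):
        """Through the edge-straddling unfiltered spectrum the effective mu
        of the iodinated vessel falls with path length; a monochromatic beam
        shows none."""
        unfiltered, _ = spectrum_pair
        vm = vessel_material()
        depths = np.array([0.5, 2.0, 5.0, 10.0])
        t = slab_transmission(vm, depths, unfiltered)
        mu_eff = -np.log(t) / depths
        assert np.all(np.diff(mu_eff) < 0)
        mono = Spectrum(grid=EnergyGrid(bin_centers=np.array([33.18]),
                                        bin_width=0.025),
                        fluence_rate=np.array([1e9]))
        t_mono = slab_transmission(vm, depths, mono)
        mu_mono = -np.log(t_mono) / depths
        np.testing.assert_allclose(mu_mono, mu_mono[0], rtol=1e-9)

    def test_filtered_beam_transmits_more_through_iodine(self, spectrum_pair):
        """Vessel-dominated rays: the filtered (below-edge) beam is less
        attenuated by iodine than the unfiltered one."""
        unfiltered, filtered = spectrum_pair
        vm = vessel_material()
        assert slab_transmission(vm, 3.0, filtered) > \
            slab_transmission(vm, 3.0, unfiltered)

    def test_zero_flux_degenerate(self):
        ph = PhantomSpec(grid_shape=(32, 32), voxel_size_mm=0.1,
                         primitives=())
        geo = make_geometry(32, 0.1, [0.0])
        dead = Spectrum(grid=EnergyGrid(bin_centers=np.array([33.0]),
                                        bin_width=0.025),
                        fluence_rate=np.array([0.0]))
        with pytest.raises(DegenerateInputError):
            polychromatic_projection(ph, dead, geo)


class TestNoise:
    def test_poisson_variance_matches_prediction(self):
        """Vacuum scan at >=1e4 counts/pixel: empirical transmission variance
        equals T/N0 within 5%."""
        ph = PhantomSpec(grid_shape=(64, 64), voxel_size_mm=0.1,
                         primitives=())
        geo = make_geometry(64, 0.1, np.arange(0.0, 180.0, 1.0))
        mono = Spectrum(grid=EnergyGrid(bin_centers=np.array([33.0]),
                                        bin_width=0.025),
                        fluence_rate=np.array([1.3e10]))
        exposure = 1.0
        n0 = photons_per_pixel(1.3e10, exposure, geo)
        assert n0 > 1e4
        sino = polychromatic_projection(ph, mono, geo, exposure_s=exposure,
                                        noise=True, seed=123,
                                        monochromatic=True)
        var = sino.transmission.var()
        assert var == pytest.approx(1.0 / n0, rel=0.05)

    def test_noise_deterministic_under_seed(self, desk_phantom):
        geo = make_geometry(256, 0.14, np.arange(0.0, 360.0, 12.0))
        mono = Spectrum(grid=EnergyGrid(bin_centers=np.array([33.18]),
                                        bin_width=0.025),
                        fluence_rate=np.array([1.3e10]))
        a = polychromatic_projection(desk_phantom, mono, geo, noise=True,
                                     seed=5, monochromatic=True)
        b = polychromatic_projection(desk_phantom, mono, geo, noise=True,
                                     seed=5, monochromatic=True)
        np.testing.assert_array_equal(a.transmission, b.transmission)


class TestAbsorption:
    def test_values(self):
        assert absorption_image(np.array([1.0]))[0] == 0.0
        assert absorption_image(np.array([0.044]))[0] == pytest.approx(0.956)

    def test_monotone_in_transmission(self):
        t = np.linspace(0.01, 1.0, 50)
        a = absorption_image(t)
        assert np.all(np.diff(a) < 0)

    def test_clipping(self):
        noisy = np.array([1.2, 0.5])
        assert absorption_image(noisy)[0] == 0.0
        assert absorption_image(noisy, clip=False)[0] == pytest.approx(-0.2)


def test_sinogram_round_trip(tmp_path, desk_phantom):
    geo = make_geometry(256, 0.14, np.arange(0.0, 360.0, 30.0))
    mono = Spectrum(grid=EnergyGrid(bin_centers=np.array([33.18]),
                                    bin_width=0.025),
                    fluence_rate=np.array([1.3e10]), label="unfiltered")
    sino = polychromatic_projection(desk_phantom, mono, geo, noise=True,
                                    seed=2, monochromatic=True)
    p = tmp_path / "sino.tif"
    sino.write(p)
    back = Sinogram.read(p)
    np.testing.assert_allclose(back.transmission, sino.transmission,
                               rtol=1e-6)
    assert back.scan_label == "unfiltered"
    assert back.mean_energy_kev == pytest.approx(33.18)
    assert back.seed == 2
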