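"""Source spectrum model, filtration and spectral summaries."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from kesct.errors import DegenerateInputError, ValidationError
from kesct.materials import IODINE_K_EDGE_KEV
from kesct.spectrum import (EnergyGrid, FilterSpec, SourceConfig, Spectrum,
                            above_edge_fraction, apply_filter,
                            compton_peak_energy, mean_energy, model_spectrum)


def delta_spectrum(energy=33.0, flux=1.0):
    grid = EnergyGrid(bin_centers=np.array([energy]), bin_width=0.025)
    return Spectrum(grid=grid, fluence_rate=np.array([flux]), label="delta")


class TestComptonKinematics:
    def test_gamma_one(self):
        assert compton_peak_energy(1.0, 1.0) == pytest.approx(0.004)

    def test_hand_arithmetic(self):
        # 4 * 83.75^2 * 1.2 eV = 33667.5 eV
        assert compton_peak_energy(83.75, 1.2) == pytest.approx(
            4 * 83.75**2 * 1.2 / 1000.0, rel=1e-14)

    def test_quadratic_scaling(self):
        full = compton_peak_energy(100.0, 1.2)
        half = compton_peak_energy(50.0, 1.2)
        assert half == pytest.approx(full / 4.0, rel=1e-14)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValidationError):
            compton_peak_energy(0.0, 1.0)
        with pytest.raises(ValidationError):
            compton_peak_energy(100.0, -1.0)


class TestModelSpectrum:
    def test_symmetric_without_tail(self):
        cfg = SourceConfig(tail_shape=0.0, mean_energy_target_kev=None)
        s = model_spectrum(cfg)
        assert mean_energy(s) == pytest.approx(cfg.peak_energy_kev,
                                               abs=s.grid.bin_width / 2)
        mode = s.energies[np.argmax(s.fluence_rate)]
        assert mode == pytest.approx(cfg.peak_energy_kev,
                                     abs=s.grid.bin_width)

    def test_default_calibration_hits_mean_target(self):
        s = model_spectrum(SourceConfig())
        assert mean_energy(s) == pytest.approx(33.18, abs=0.02)

    def test_total_flux_normalization(self):
        s = model_spectrum(SourceConfig())
        assert s.total_flux() == pytest.approx(1.3e10, rel=1e-9)

    def test_grid_must_cover_peak(self):
        small = EnergyGrid(bin_centers=np.arange(15.0, 30.0, 0.025),
                           bin_width=0.025)
        with pytest.raises(ValidationError):
            model_spectrum(SourceConfig(), grid=small)

    def test_bandwidth_bound_enforced(self):
        with pytest.raises(ValidationError):
            SourceConfig(fwhm_fraction=0.10)

    def test_unreachable_mean_target(self):
        with pytest.raises(ValidationError):
            model_spectrum(SourceConfig(tail_shape=0.1,
                                        mean_energy_target_kev=30.0))


class TestFilter:
    def test_zero_thickness_identity(self, registry, spectrum_pair):
        unfiltered, _ = spectrum_pair
        out = apply_filter(unfiltered, FilterSpec(registry.get("iodine"), 0.0))
        np.testing.assert_array_equal(out.fluence_rate,
                                      unfiltered.fluence_rate)

    def test_beer_lambert_multiplicativity(self, registry, spectrum_pair):
        unfiltered, _ = spectrum_pair
        iod = registry.get("iodine")
        half = FilterSpec(iod, 145.0)
        full = FilterSpec(iod, 290.0)
        twice = apply_filter(apply_filter(unfiltered, half), half)
        once = apply_filter(unfiltered, full)
        np.testing.assert_allclose(twice.fluence_rate, once.fluence_rate,
                                   rtol=1e-12)

    def test_filter_commutativity(self, registry, spectrum_pair):
        unfiltered, _ = spectrum_pair
        a = FilterSpec(registry.get("iodine"), 100.0)
        b = FilterSpec(registry.get("water"), 2000.0)
        ab = apply_filter(apply_filter(unfiltered, a), b)
        ba = apply_filter(apply_filter(unfiltered, b), a)
        # atol covers denormal bins in the far-suppressed tail
        np.testing.assert_allclose(ab.fluence_rate, ba.fluence_rate,
                                   rtol=1e-12, atol=1e-280)

    def test_filtering_never_increases_any_bin(self, spectrum_pair):
        unfiltered, filtered = spectrum_pair
        assert np.all(filtered.fluence_rate <= unfiltered.fluence_rate)

    def test_filtered_mean_strictly_below_unfiltered(self, spectrum_pair):
        unfiltered, filtered = spectrum_pair
        assert mean_energy(filtered) < mean_energy(unfiltered)

    def test_negative_thickness_rejected(self, registry):
        with pytest.raises(ValidationError):
            FilterSpec(registry.get("iodine"), -1.0)


class TestSummaries:
    def test_delta_spectrum_mean(self):
        assert mean_energy(delta_spectrum(33.0)) == 33.0

    def test_all_zero_spectrum_degenerate(self):
        s = delta_spectrum(33.0, flux=0.0)
        with pytest.raises(DegenerateInputError):
            mean_energy(s)

    def test_above_edge_identity_and_zero(self, spectrum_pair):
        unfiltered, _ = spectrum_pair
        assert above_edge_fraction(unfiltered, unfiltered) == pytest.approx(1.0)
        zero = Spectrum(grid=unfiltered.grid,
                        fluence_rate=np.zeros_like(unfiltered.fluence_rate))
        assert above_edge_fraction(unfiltered, zero) == 0.0

    def test_above_edge_requires_reference_support(self, spectrum_pair):
        unfiltered, _ = spectrum_pair
        with pytest.raises(DegenerateInputError):
            above_edge_fraction(unfiltered, unfiltered, edge_kev=59.9)

    def test_strong_above_edge_suppression(self, spectrum_pair):
        """The 290 um iodine filter removes the vast majority of above-edge
        intensity (fluence- and energy-weighted alike)."""
        unfiltered, filtered = spectrum_pair
        for weight in ("fluence", "energy"):
            frac = above_edge_fraction(unfiltered, filtered,
                                       IODINE_K_EDGE_KEV, weight=weight)
            assert 0.0 < frac < 0.05

    def test_csv_round_trip(self, spectrum_pair, tmp_path):
        unfiltered, _ = spectrum_pair
        p = tmp_path / "s.csv"
        unfiltered.to_csv(p)
        back = Spectrum.from_csv(p)
        np.testing.assert_allclose(back.fluence_rate,
                                   unfiltered.fluence_rate, rtol=1e-6)
        np.testing.assert_allclose(back.energies, unfiltered.energies,
                                   rtol=0, atol=1e-9)


@given(st.floats(min_value=20.0, max_value=34.9),
       st.floats(min_value=0.01, max_value=0.045))
def test_symmetric_model_mean_tracks_peak(peak, fw):
    cfg = SourceConfig(peak_energy_kev=peak, fwhm_fraction=fw,
                       tail_shape=0.0, mean_energy_target_kev=None)
    s = model_spectrum(cfg)
    assert mean_energy(s) == pytest.approx(peak, abs=s.grid.bin_width)
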