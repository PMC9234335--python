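"""Amide-I baseline, Gaussian deconvolution, binning and deltas."""

import numpy as np
import pytest

from specbind import (
    AmideBandSpec,
    FTIRSpectrum,
    SecondaryStructure,
    assign_structures,
    baseline_correct,
    deconvolve_amide1,
    gen_amide_spectrum,
    structure_delta,
)
from specbind.ftir import BandComponent, assign_center

CLASSES = ("beta_sheet", "random_coil", "alpha_helix", "beta_turn")


def band(center, area=1.0, sigma=6.0):
    return BandComponent(center=center, sigma=sigma, amplitude=area / (sigma * np.sqrt(2 * np.pi)),
                         area=area, assignment=assign_center(center))


class TestBaseline:
    def test_pure_ramp_maps_to_zero(self):
        w = np.arange(1595.0, 1706.0, 0.5)
        spec = FTIRSpectrum(w, 0.3 + 0.002 * (w - 1600.0))
        out = baseline_correct(spec)
        inside = (out.wavenumber >= 1600) & (out.wavenumber <= 1700)
        assert np.allclose(out.absorbance[inside], 0.0, atol=1e-12)

    def test_idempotent_on_corrected_input(self):
        spec = gen_amide_spectrum(AmideBandSpec(baseline_offset=0.1, baseline_slope=1e-3))
        once = baseline_correct(spec)
        twice = baseline_correct(once)
        assert np.allclose(once.absorbance, twice.absorbance, atol=1e-12)

    def test_removes_known_generator_baseline(self):
        clean = gen_amide_spectrum(AmideBandSpec())
        tilted = gen_amide_spectrum(AmideBandSpec(baseline_offset=0.2, baseline_slope=2e-3))
        a = baseline_correct(tilted).absorbance - baseline_correct(clean).absorbance
        assert np.allclose(a, 0.0, atol=1e-12)


class TestDeconvolution:
    def test_single_gaussian_recovered_exactly(self):
        spec = gen_amide_spectrum(
            AmideBandSpec(centers=(1655.0,), widths=(6.0,), area_fractions=(1.0,)),
            total_area=5.0,
        )
        comps = deconvolve_amide1(baseline_correct(spec))
        assert len(comps) == 1
        assert comps[0].center == pytest.approx(1655.0, abs=1e-3)
        assert comps[0].sigma == pytest.approx(6.0, rel=1e-3)
        assert comps[0].area == pytest.approx(5.0, rel=1e-3)

    def test_four_band_centers_recovered(self):
        comps = deconvolve_amide1(baseline_correct(gen_amide_spectrum(AmideBandSpec())))
        centers = [c.center for c in comps]
        assert len(comps) == 4
        for truth in (1620.0, 1645.0, 1655.0, 1675.0):
            assert min(abs(c - truth) for c in centers) <= 1.0

    def test_noise_free_fraction_round_trip(self):
        fractions = (0.42, 0.14, 0.24, 0.20)
        spec = gen_amide_spectrum(AmideBandSpec(area_fractions=fractions))
        structure = assign_structures(deconvolve_amide1(baseline_correct(spec)))
        for name, truth in zip(CLASSES, fractions):
            assert structure[name] == pytest.approx(100 * truth, abs=0.5)

    def test_scale_equivariance(self):
        spec = baseline_correct(gen_amide_spectrum(AmideBandSpec()))
        scaled = FTIRSpectrum(spec.wavenumber, spec.absorbance * 7.3)
        s1 = assign_structures(deconvolve_amide1(spec))
        s2 = assign_structures(deconvolve_amide1(scaled))
        for name in CLASSES:
            assert s1[name] == pytest.approx(s2[name], abs=1e-3)


class TestAssignment:
    def test_single_alpha_band(self):
        s = assign_structures([band(1655.0)])
        assert s["alpha_helix"] == 100.0

    def test_direct_binning_arithmetic(self):
        comps = [band(1620.0, 42.0), band(1645.0, 14.0), band(1655.0, 24.0),
                 band(1675.0, 20.0)]
        s = assign_structures(comps)
        assert s["beta_sheet"] == pytest.approx(42.0)
        assert s["random_coil"] == pytest.approx(14.0)
        assert s["alpha_helix"] == pytest.approx(24.0)
        assert s["beta_turn"] == pytest.approx(20.0)

    @pytest.mark.parametrize("center,expected", [
        (1639.9, "beta_sheet"), (1640.0, "random_coil"),
        (1650.9, "random_coil"), (1651.0, "alpha_helix"),
        (1660.9, "alpha_helix"), (1661.0, "beta_turn"),
        (1600.0, "beta_sheet"), (1700.0, "beta_turn"),
    ])
    def test_half_open_bin_boundaries(self, center, expected):
        assert assign_center(center) == expected

    def test_center_outside_window_refused(self):
        with pytest.raises(ValueError):
            assign_center(1710.0)

    def test_fractions_sum_to_100(self):
        s = assign_structures([band(1612.0, 3.7), band(1648.0, 0.9), band(1682.0, 2.2)])
        assert sum(s.fractions.values()) == pytest.approx(100.0, abs=1e-9)


class TestDelta:
    def _structure(self, values):
        return SecondaryStructure(fractions=dict(zip(CLASSES, values)))

    def test_identical_inputs_give_zero(self):
        s = self._structure((42.0, 14.0, 24.0, 20.0))
        assert all(v == 0.0 for v in structure_delta(s, s).values())

    def test_reported_style_alpha_helix_drop(self):
        free = self._structure((42.0, 14.0, 24.0, 20.0))
        complexed = self._structure((45.8, 14.4, 19.39, 20.41))
        delta = structure_delta(free, complexed)
        assert delta["alpha_helix"] == pytest.approx(-4.61)
        assert delta["beta_sheet"] == pytest.approx(3.80)

    def test_antisymmetry_and_zero_sum(self):
        a = self._structure((30.0, 25.0, 25.0, 20.0))
        b = self._structure((42.0, 14.0, 24.0, 20.0))
        d_ab = structure_delta(a, b)
        d_ba = structure_delta(b, a)
        for name in CLASSES:
            assert d_ab[name] == pytest.approx(-d_ba[name])
        assert sum(d_ab.values()) == pytest.approx(0.0, abs=1e-9)


def test_invalid_fractions_rejected():
    with pytest.raises(ValueError):
        SecondaryStructure(fractions={"beta_sheet": 120.0, "random_coil": -20.0,
                                      "alpha_helix": 0.0, "beta_turn": 0.0})
    with pytest.raises(ValueError):
        SecondaryStructure(fractions={"beta_sheet": 50.0, "random_coil": 10.0,
                                      "alpha_helix": 10.0, "beta_turn": 10.0})
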