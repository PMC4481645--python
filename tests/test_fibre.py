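import math

import numpy as np
import pytest

from wsilk.fibre import (
    Band,
    PolarizedSpectra,
    StressStrainCurve,
    baseline_correct,
    decompose_amide_I,
    fibre_area,
    iso_spectrum,
    orientation_ratio,
    smooth5,
    tensile_metrics,
)
from wsilk.io import XYTable
from wsilk.synthetic import gen_raman, gen_stress_strain

ANCHORS = [(1500, 1580), (1720, 1800)]
TWO_BANDS = (Band("alpha_helix", 1655.0), Band("beta_sheet", 1670.0))


def spectrum(y, x=None):
    if x is None:
        x = np.arange(1500.0, 1801.0)
    return XYTable(x, y, "wavenumber_cm-1")


class TestBaseline:
    def test_pure_cubic_removed(self):
        x = np.arange(1500.0, 1801.0)
        u = (x - 1500) / 300
        y = 3 + 2 * u - u**2 + 0.5 * u**3
        out = baseline_correct(spectrum(y), [(1500, 1800)])
        assert np.allclose(out.y, 0.0, atol=1e-10)

    def test_band_recovered_from_cubic_background(self):
        x = np.arange(1500.0, 1801.0)
        u = (x - 1500) / 300
        band = 2.0 * np.exp(-0.5 * ((x - 1655) / 10) ** 2)
        y = band + 5 - 3 * u + u**2
        out = baseline_correct(spectrum(y), ANCHORS)
        assert abs(np.trapezoid(out.y, x) - np.trapezoid(band, x)) < 0.01 * np.trapezoid(band, x)

    def test_zero_spectrum_stays_zero(self):
        out = baseline_correct(spectrum(np.zeros(301)), ANCHORS)
        assert np.allclose(out.y, 0.0)

    def test_too_few_anchors_rejected(self):
        with pytest.raises(ValueError):
            baseline_correct(spectrum(np.ones(301)), [(1500, 1502)])


class TestSmooth5:
    def test_constant_unchanged(self):
        out = smooth5(spectrum(np.full(301, 2.5)))
        assert np.allclose(out.y, 2.5)

    def test_spike_averaged_over_window(self):
        y = np.zeros(301)
        y[150] = 5.0
        out = smooth5(spectrum(y))
        assert out.y[150] == pytest.approx(1.0)

    def test_linear_ramp_unchanged_in_interior(self):
        y = np.linspace(0, 10, 301)
        out = smooth5(spectrum(y))
        assert np.allclose(out.y[2:-2], y[2:-2])


class TestIsoSpectrum:
    def test_identical_channels_pass_through(self):
        y = np.exp(-0.5 * ((np.arange(1500.0, 1801.0) - 1655) / 10) ** 2)
        s = spectrum(y)
        pol = PolarizedSpectra(xx=s, xz=s, zx=s, zz=s)
        assert np.allclose(iso_spectrum(pol).y, y)

    def test_linearity_under_scaling(self):
        pol = gen_raman(seed=3, orientation=0.4)
        scaled = PolarizedSpectra(
            xx=pol.xx.with_y(2 * pol.xx.y), xz=pol.xz.with_y(2 * pol.xz.y),
            zx=pol.zx.with_y(2 * pol.zx.y), zz=pol.zz.with_y(2 * pol.zz.y),
        )
        assert np.allclose(iso_spectrum(scaled).y, 2 * iso_spectrum(pol).y)

    def test_generator_inversion(self):
        pol0 = gen_raman(seed=3, orientation=0.0)
        truth = iso_spectrum(pol0).y
        pol = gen_raman(seed=3, orientation=0.5)
        recovered = iso_spectrum(pol).y
        scale = np.abs(truth).max()
        assert np.all(np.abs(recovered - truth) <= 0.02 * scale)

    def test_weights_must_sum_to_one(self):
        pol = gen_raman(seed=3)
        with pytest.raises(ValueError):
            iso_spectrum(pol, {"ZZ": 0.5, "XX": 0.5, "XZ": 0.5})


class TestAmideIDecomposition:
    def test_single_band_is_all_alpha(self):
        x = np.arange(1500.0, 1801.0)
        y = np.exp(-0.5 * ((x - 1655) / 10) ** 2)
        fractions = decompose_amide_I(spectrum(y), bands=TWO_BANDS)
        assert fractions["alpha_helix"] == pytest.approx(100.0, abs=0.5)

    def test_sixty_forty_split_recovered(self):
        pol = gen_raman(
            seed=1, bands=TWO_BANDS,
            fractions={"alpha_helix": 60.0, "beta_sheet": 40.0, "disorder": 0.0},
        )
        fractions = decompose_amide_I(iso_spectrum(pol), bands=TWO_BANDS)
        assert fractions["alpha_helix"] == pytest.approx(60.0, abs=2.0)
        assert fractions["beta_sheet"] == pytest.approx(40.0, abs=2.0)

    def test_fractions_sum_to_100(self):
        pol = gen_raman(seed=2)
        fractions = decompose_amide_I(iso_spectrum(pol))
        assert sum(fractions.values()) == pytest.approx(100.0)

    def test_band_order_permutation_invariant(self):
        pol = gen_raman(seed=1, bands=TWO_BANDS,
                        fractions={"alpha_helix": 70.0, "beta_sheet": 30.0})
        iso = iso_spectrum(pol)
        a = decompose_amide_I(iso, bands=TWO_BANDS)
        b = decompose_amide_I(iso, bands=TWO_BANDS[::-1])
        assert a["alpha_helix"] == pytest.approx(b["alpha_helix"], abs=0.5)

    def test_fixed_shape_fit_resolves_overlapped_table(self):
        # the default 4-band table is degenerate with floating shapes;
        # amplitude-only fitting recovers the generating fractions
        pol = gen_raman(seed=2, baseline_coeffs=(5.0, 2.0, -3.0, 1.0),
                        noise_sigma=0.002, orientation=0.2)
        proc = smooth5(baseline_correct(iso_spectrum(pol), ANCHORS))
        fractions = decompose_amide_I(proc, vary_centers=False, vary_widths=False)
        assert fractions["alpha_helix"] == pytest.approx(32.0, abs=2.0)
        assert fractions["beta_sheet"] == pytest.approx(28.0, abs=2.0)
        assert fractions["disorder"] == pytest.approx(40.0, abs=2.0)


class TestOrientation:
    def test_isotropic_when_channels_match(self):
        pol = gen_raman(seed=4, orientation=0.0)
        out = orientation_ratio(pol, 1655.0)
        assert out["R"] == pytest.approx(1.0)
        assert out["call"] == "isotropic"

    def test_generator_sign_matches_call(self):
        pol = gen_raman(seed=4, orientation=0.5)  # ZZ enhanced
        out = orientation_ratio(pol, 1655.0, aligned_when="less")
        assert out["R"] < 1.0
        assert out["call"] == "aligned along fibre axis"

    def test_zero_zz_rejected(self):
        x = np.arange(1600.0, 1701.0)
        zero = XYTable(x, np.zeros_like(x), "wavenumber_cm-1")
        ones = XYTable(x, np.ones_like(x), "wavenumber_cm-1")
        pol = PolarizedSpectra(xx=ones, xz=ones, zx=ones, zz=zero)
        with pytest.raises(ValueError):
            orientation_ratio(pol, 1655.0)


class TestFibreArea:
    def test_nine_identical_estimates(self):
        out = fibre_area([1.5] * 9)
        assert out["mean_diameter_um"] == pytest.approx(1.5)
        assert out["area_m2"] == pytest.approx(1.767e-12, rel=1e-3)

    def test_single_estimate(self):
        out = fibre_area([2.0])
        assert out["area_m2"] == pytest.approx(math.pi * 1e-12)

    def test_nonpositive_estimate_rejected(self):
        with pytest.raises(ValueError):
            fibre_area([1.5, -0.1])


class TestTensileMetrics:
    def test_linear_curve_closed_form(self):
        # σ = E·ε with E = 1 GPa to ε_b = 0.2: toughness = E·ε_b²/2 = 20 J/cm³
        strain = np.linspace(0, 0.2, 400)
        curve = StressStrainCurve(strain, 1000.0 * strain)
        out = tensile_metrics(curve)
        assert out["toughness_J_per_cm3"] == pytest.approx(20.0, rel=1e-6)
        assert out["youngs_modulus_GPa"] == pytest.approx(1.0, rel=1e-9)
        assert out["breaking_strain"] == pytest.approx(0.2)
        assert out["breaking_strength_MPa"] == pytest.approx(200.0)

    def test_breaking_strength_is_max_stress(self):
        curve = gen_stress_strain(seed=0)
        out = tensile_metrics(curve)
        assert out["breaking_strength_MPa"] == pytest.approx(curve.stress.max())

    def test_toughness_grid_refinement(self):
        coarse = gen_stress_strain(seed=0, n_points=100)
        fine = gen_stress_strain(seed=0, n_points=1000)
        t1 = tensile_metrics(coarse)["toughness_J_per_cm3"]
        t2 = tensile_metrics(fine)["toughness_J_per_cm3"]
        assert abs(t2 - t1) / t1 < 0.005

    def test_generator_modulus_round_trip(self):
        curve = gen_stress_strain(seed=0, E_GPa=1.7, yield_strain=0.05)
        out = tensile_metrics(curve)
        assert out["youngs_modulus_GPa"] == pytest.approx(1.7, rel=1e-3)
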