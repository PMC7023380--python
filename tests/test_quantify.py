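import numpy as np
import pytest
from scipy import stats

from coffee_screener.analytes import DEFAULT_ANALYTES, OMC_NOISE_WINDOW, OMC_WINDOW
from coffee_screener.errors import (ConfigurationError, InvalidParameterError,
                                    SpectrumRangeError)
from coffee_screener.quantify import (IntegrationResult, area_to_solution_concentration,
                                      correct_omc_area, integrate_window,
                                      matched_calibration, quantify_sample,
                                      solution_to_content)
from coffee_screener.simulate import (CALIBRATION_LEVELS_MG_L, SimulationSettings,
                                      simulate_spectrum)
from coffee_screener.spectra import Spectrum
from conftest import window_area


def lorentzian_spectrum(desk, center=3.155, area=1.0, fwhm_ppm=0.002,
                        baseline=None, n=8192, span=(2.8, 3.5)):
    """Synthetic single-peak spectrum on a local descending axis."""
    x = np.linspace(span[1], span[0], n)
    g = fwhm_ppm / 2.0
    y = (area / np.pi) * g / ((x - center) ** 2 + g ** 2)
    if baseline is not None:
        y = y + baseline(x)
    return Spectrum(y, x, desk)


class TestIntegrateWindow:
    def test_zero_spectrum_zero_area(self, desk):
        spec = Spectrum(np.zeros(4096), np.linspace(4.0, 3.0, 4096), desk)
        for method in ("linefit", "sum"):
            assert integrate_window(spec, (3.2, 3.6), method=method).raw_area == 0.0

    def test_linefit_recovers_known_area_and_matches_sum(self, desk):
        # narrow peak fully inside the window: tails negligible
        spec = lorentzian_spectrum(desk, area=2.5, fwhm_ppm=0.002)
        window = (3.105, 3.205)
        fit = integrate_window(spec, window, method="linefit")
        sm = integrate_window(spec, window, method="sum")
        assert fit.raw_area == pytest.approx(2.5, rel=0.01)
        assert abs(fit.raw_area - sm.raw_area) / 2.5 < 0.02

    def test_linefit_unbiased_on_ramp_where_sum_is_biased(self, desk):
        ramp = lambda x: 40.0 * (x - 3.1)
        spec = lorentzian_spectrum(desk, area=1.0, baseline=ramp)
        window = (3.105, 3.205)
        fit = integrate_window(spec, window, method="linefit")
        sm = integrate_window(spec, window, method="sum")
        assert fit.raw_area == pytest.approx(1.0, rel=0.01)
        assert abs(sm.raw_area - 1.0) > 0.1  # naive sum carries the ramp area

    def test_narrow_window_rejected(self, desk):
        spec = lorentzian_spectrum(desk, n=64, span=(0.0, 10.0))
        with pytest.raises(InvalidParameterError):
            integrate_window(spec, (3.15, 3.16))

    def test_window_outside_axis_rejected(self, desk):
        spec = lorentzian_spectrum(desk)
        with pytest.raises(SpectrumRangeError):
            integrate_window(spec, (8.0, 9.0))

    def test_unknown_method_rejected(self, desk):
        spec = lorentzian_spectrum(desk)
        with pytest.raises(InvalidParameterError):
            integrate_window(spec, (3.1, 3.2), method="simpson")

    def test_fit_quality_reported(self, desk, noiseless):
        spec, _ = simulate_spectrum({"OMC": 100.0}, settings=noiseless, params=desk)
        res = integrate_window(spec, OMC_WINDOW)
        assert res.fit_quality < 1e-3  # noiseless model data fit to numerics


class TestOmcCorrection:
    def test_no_interference_keeps_area(self, desk, noiseless):
        spec, truth = simulate_spectrum({"OMC": 150.0}, settings=noiseless, params=desk)
        res = correct_omc_area(spec)
        assert res.corrected_area == pytest.approx(truth["area_ppm"]["OMC"], rel=0.01)

    def test_flat_interference_cancels_exactly(self, desk, noiseless):
        """Equal-width windows: a flat offset contributes identically to both."""
        spec, truth = simulate_spectrum({"OMC": 150.0}, settings=noiseless, params=desk)
        flat = spec.copy()
        flat.intensities = flat.intensities + 5.0  # flat interference everywhere
        res = correct_omc_area(flat)
        width_omc = OMC_WINDOW[1] - OMC_WINDOW[0]
        width_ref = OMC_NOISE_WINDOW[1] - OMC_NOISE_WINDOW[0]
        assert width_omc == pytest.approx(width_ref)
        assert res.corrected_area == pytest.approx(truth["area_ppm"]["OMC"], rel=0.01)
        assert res.raw_area > res.corrected_area  # raw carries the offset

    def test_interference_only_clips_to_zero(self, desk):
        settings = SimulationSettings(interference_amplitude=2.0)
        conc = {name: 0.0 for name in DEFAULT_ANALYTES}
        spec, _ = simulate_spectrum(conc, settings=settings, params=desk)
        res = correct_omc_area(spec)
        assert res.corrected_area >= 0.0
        assert res.corrected_area < 0.05 * res.raw_area

    def test_correction_beats_no_correction_on_robusta(self, desk, cal_us):
        """With robusta-level interference the corrected OMC estimate is closer
        to truth than the uncorrected window total, on every replicate."""
        settings = SimulationSettings(noise_sd=0.05, interference_amplitude=2.0)
        analyte = DEFAULT_ANALYTES["OMC"]
        for seed in range(8):
            rng = np.random.default_rng(seed)
            spec, _ = simulate_spectrum({"OMC": 100.0}, settings=settings,
                                        params=desk, rng=rng)
            corr = correct_omc_area(spec)
            unc = integrate_window(spec, OMC_WINDOW)
            unc_total = IntegrationResult("OMC", unc.raw_area + unc.baseline_area,
                                          unc.raw_area + unc.baseline_area, 0.0,
                                          OMC_WINDOW)
            err_corr = abs(area_to_solution_concentration(corr, analyte, cal_us) - 100.0)
            err_unc = abs(area_to_solution_concentration(unc_total, analyte, cal_us) - 100.0)
            assert err_corr < err_unc


class TestConcentrationConversion:
    def test_zero_area_zero_concentration(self, cal_us):
        res = IntegrationResult("OMC", 0.0, 0.0, 0.0, OMC_WINDOW)
        assert area_to_solution_concentration(res, DEFAULT_ANALYTES["OMC"], cal_us) == 0.0

    def test_linearity_in_area(self, cal_us):
        a = DEFAULT_ANALYTES["kahweol"]
        c1 = area_to_solution_concentration(
            IntegrationResult("kahweol", 1.0, 1.0, 0.0, a.window_ppm), a, cal_us)
        c2 = area_to_solution_concentration(
            IntegrationResult("kahweol", 2.0, 2.0, 0.0, a.window_ppm), a, cal_us)
        assert c2 == pytest.approx(2.0 * c1)

    def test_missing_calibration_rejected(self):
        res = IntegrationResult("OMC", 1.0, 1.0, 0.0, OMC_WINDOW)
        with pytest.raises(ConfigurationError):
            area_to_solution_concentration(res, DEFAULT_ANALYTES["OMC"], None)

    def test_simulator_inverse_identity(self, desk, noiseless, cal_us):
        """cal.factor = 1/k_device makes quantification the exact inverse of
        the signal model."""
        spec, _ = simulate_spectrum({"HMF": 77.0}, settings=noiseless, params=desk)
        a = DEFAULT_ANALYTES["HMF"]
        res = integrate_window(spec, a.window_ppm, analyte="HMF")
        c = area_to_solution_concentration(res, a, cal_us)
        assert c == pytest.approx(77.0, rel=0.01)


class TestContentConversion:
    @pytest.mark.parametrize("c_mg_L, factor, expected", [
        (1.0, 1.0, 7.5),        # lower working-range bound
        (1000.0, 1.0, 7500.0),  # upper working-range bound
        (750.0, 1.0, 5625.0),   # upper linearity bound
        (100.0, 6.0, 4500.0),   # caffeine with the empirical factor 6
    ])
    def test_conversion_values(self, c_mg_L, factor, expected):
        assert solution_to_content(c_mg_L, recalculation_factor=factor) == \
            pytest.approx(expected)

    def test_nonpositive_mass_or_volume_rejected(self):
        with pytest.raises(InvalidParameterError):
            solution_to_content(1.0, sample_mass_g=0.0)
        with pytest.raises(InvalidParameterError):
            solution_to_content(1.0, extract_volume_mL=-1.0)


class TestQuantifySample:
    def test_blank_flags_below_lod(self, desk, noiseless, cal_us):
        conc = {name: 0.0 for name in DEFAULT_ANALYTES}
        spec, _ = simulate_spectrum(conc, settings=noiseless, params=desk)
        limits = {name: 10.0 for name in DEFAULT_ANALYTES}
        results = quantify_sample(spec, cal=cal_us, limits=limits)
        for q in results:
            assert q.content_mg_kg == pytest.approx(0.0, abs=1.0)
            assert "below_lod" in q.flags

    def test_noiseless_roundtrip_within_2_percent(self, desk, five_conc, cal_us):
        settings = SimulationSettings(caffeine_dissolved_fraction=1.0 / 6.0)
        spec, _ = simulate_spectrum(five_conc, settings=settings, params=desk)
        results = {q.analyte: q for q in quantify_sample(spec, cal=cal_us)}
        for name, conc in five_conc.items():
            nominal = conc * 7.5  # factor 6 restores nominal caffeine content
            assert results[name].content_mg_kg == pytest.approx(nominal, rel=0.02), name

    def test_interference_only_omc_near_zero(self, desk, cal_us):
        settings = SimulationSettings(interference_amplitude=2.0)
        conc = {name: 0.0 for name in DEFAULT_ANALYTES}
        spec, _ = simulate_spectrum(conc, settings=settings, params=desk)
        results = {q.analyte: q for q in quantify_sample(spec, cal=cal_us)}
        omc_uncorrected = integrate_window(spec, OMC_WINDOW)
        uncorrected_total = omc_uncorrected.raw_area + omc_uncorrected.baseline_area
        assert uncorrected_total > 0.05  # interference alone inflates the window
        assert results["OMC"].content_mg_kg < 50.0  # corrected stays low

    def test_per_analyte_failure_does_not_abort(self, desk, cal_us):
        # axis covering only part of the analytes: the rest error out per-analyte
        x = np.linspace(6.0, 2.0, 8192)
        spec = Spectrum(np.zeros_like(x), x, desk)
        results = {q.analyte: q for q in quantify_sample(spec, cal=cal_us)}
        assert len(results) == 5
        assert np.isnan(results["HMF"].content_mg_kg)  # window off-axis
        assert results["kahweol"].content_mg_kg == 0.0  # window on-axis


def test_end_to_end_linearity_noiseless(desk, cal_us):
    """Quantified content vs truth over the 10 levels: slope 1, R^2 > 0.999."""
    settings = SimulationSettings()
    for name in ("OMC", "HMF"):
        measured = []
        for level in CALIBRATION_LEVELS_MG_L:
            spec, _ = simulate_spectrum({name: level}, settings=settings, params=desk)
            q = {r.analyte: r for r in quantify_sample(spec, cal=cal_us)}[name]
            measured.append(q.content_mg_kg)
        truth_content = np.array(CALIBRATION_LEVELS_MG_L) * 7.5
        res = stats.linregress(truth_content, measured)
        assert res.slope == pytest.approx(1.0, abs=0.02)
        assert res.rvalue ** 2 > 0.999
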