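"""From processed spectrum to analyte content.

The chain is: window line-fit integration (Lorentzians plus a local linear
baseline), the interference correction for OMC, conversion of normalized
area to solution concentration through the per-device eretic factor
(PULCON-style external calibration), and conversion to content per kg of
coffee via the extraction stoichiometry (200 mg beans in 1.5 mL solvent,
hence 7.5 mg/kg per mg/L) times the analyte's recalculation factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .analytes import DEFAULT_ANALYTES, OMC_NOISE_WINDOW, OMC_WINDOW, AnalyteDefinition
from .errors import ConfigurationError, InvalidParameterError, SpectrumRangeError
from .simulate import K_DEVICE
from .spectra import Spectrum

__all__ = [
    "IntegrationResult", "QuantificationResult", "EreticCalibration",
    "matched_calibration", "integrate_window", "correct_omc_area",
    "area_to_solution_concentration", "solution_to_content", "quantify_sample",
    "measure_simulated_design", "DEFAULT_SAMPLE_MASS_G", "DEFAULT_EXTRACT_VOLUME_ML",
]

DEFAULT_SAMPLE_MASS_G = 0.200
DEFAULT_EXTRACT_VOLUME_ML = 1.5


@dataclass
class IntegrationResult:
    """Outcome of integrating one ppm window."""

    analyte: str
    raw_area: float
    corrected_area: float
    fit_quality: float
    window_used: tuple[float, float]
    baseline_area: float = 0.0
    flags: list[str] = field(default_factory=list)


@dataclass
class QuantificationResult:
    """Final per-analyte result of one sample."""

    analyte: str
    concentration_solution_mg_L: float
    content_mg_kg: float
    eretic_factor_used: float
    flags: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class EreticCalibration:
    """External concentration calibration of one spectrometer.

    ``factor`` converts a proton-normalized spectral area into molarity
    (mol/L per intensity*ppm); it is the single calibration degree of
    freedom and absorbs every instrument constant.
    """

    factor: float
    reference_description: str = ""
    device_preset: str = ""

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise InvalidParameterError("eretic factor must be positive")


def matched_calibration(device: str) -> EreticCalibration:
    """The calibration matched to the simulator's device constant."""
    if device not in K_DEVICE:
        raise ConfigurationError(f"no device constant for {device!r}")
    return EreticCalibration(1.0 / K_DEVICE[device],
                             reference_description="simulator-matched",
                             device_preset=device)


def _with_exact_bounds(x: np.ndarray, y: np.ndarray, lo: float,
                       hi: float) -> tuple[np.ndarray, np.ndarray]:
    """Extend (ascending) samples with interpolated ordinates at lo and hi so
    the trapezoid covers the requested window span exactly."""
    xs = [lo, *x[(x > lo) & (x < hi)], hi]
    return np.interp(np.asarray(xs), x, y), np.asarray(xs)


def _lorentzians_plus_line(x: np.ndarray, theta: np.ndarray, k: int) -> np.ndarray:
    y = theta[3 * k] + theta[3 * k + 1] * (x - x.mean())
    for j in range(k):
        h, x0, g = theta[3 * j], theta[3 * j + 1], theta[3 * j + 2]
        y = y + h * g * g / ((x - x0) ** 2 + g * g)
    return y


def integrate_window(spectrum: Spectrum, window: tuple[float, float],
                     method: str = "linefit", n_peaks: int = 1,
                     analyte: str = "") -> IntegrationResult:
    """Integrate a ppm window by Lorentzian line fitting or trapezoid sum.

    ``linefit`` fits ``n_peaks`` Lorentzians plus a local linear baseline and
    reports the sum of the analytic Lorentzian areas (pi * height * hwhm),
    which extrapolates the tails the finite window cuts off. ``sum`` is the
    plain trapezoidal integral of the window and serves as the brute-force
    reference. On non-convergence the line fit falls back to the sum with a
    flag.
    """
    lo, hi = sorted(window)
    sl = spectrum.window_slice(lo, hi)
    x = spectrum.ppm_axis[sl][::-1]  # ascending for fitting
    y = np.asarray(spectrum.intensities[sl], dtype=float)[::-1]
    if x.size < 8:
        raise InvalidParameterError(
            f"window ({lo}, {hi}) contains only {x.size} points (need >= 8)")
    if method == "sum":
        area = float(np.trapezoid(*_with_exact_bounds(x, y, lo, hi)))
        return IntegrationResult(analyte, area, area, 0.0, (lo, hi))
    if method != "linefit":
        raise InvalidParameterError(f"unknown integration method {method!r}")

    signal_norm = float(np.linalg.norm(y))
    if signal_norm == 0.0:
        return IntegrationResult(analyte, 0.0, 0.0, 0.0, (lo, hi))

    span = hi - lo
    theta0, lower, upper = [], [], []
    order = np.argsort(y)[::-1]
    for j in range(n_peaks):
        x0 = float(x[order[j % x.size]])
        h0 = max(float(y[order[j % x.size]]), 1e-12)
        theta0 += [h0, x0, span / 20.0]
        lower += [0.0, lo, span / 1e4]
        upper += [np.inf, hi, 5.0 * span]
    slope0 = (y[-1] - y[0]) / span
    theta0 += [float(np.median(y)), slope0]
    lower += [-np.inf, -np.inf]
    upper += [np.inf, np.inf]

    def resid(theta: np.ndarray) -> np.ndarray:
        return _lorentzians_plus_line(x, theta, n_peaks) - y

    fit = least_squares(resid, np.asarray(theta0), bounds=(lower, upper),
                        method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
                        max_nfev=4000)
    quality = float(np.linalg.norm(fit.fun)) / signal_norm
    if not fit.success or not np.all(np.isfinite(fit.x)):
        area = float(np.trapezoid(y, x))
        return IntegrationResult(analyte, area, area, quality, (lo, hi),
                                 flags=["linefit_fallback_sum"])
    area = float(sum(np.pi * fit.x[3 * j] * fit.x[3 * j + 2] for j in range(n_peaks)))
    # integral of the fitted local baseline c + m (x - x.mean()) over the window
    c0, m0 = fit.x[3 * n_peaks], fit.x[3 * n_peaks + 1]
    xm = float(x.mean())
    base_area = float(c0 * (hi - lo) + 0.5 * m0 * ((hi - xm) ** 2 - (lo - xm) ** 2))
    return IntegrationResult(analyte, area, area, quality, (lo, hi),
                             baseline_area=base_area)


def correct_omc_area(spectrum: Spectrum, method: str = "linefit") -> IntegrationResult:
    """OMC area with the fatty-acid interference subtracted.

    The matrix background that inflates the OMC window (3.125-3.185 ppm)
    also fills the equal-width window just next to it (3.04-3.10 ppm),
    which contains no analyte signal; subtracting the latter integral from
    the former cancels any locally flat interference exactly. For the line
    fit the raw OMC area is the window total (Lorentzian plus fitted local
    baseline), since the baseline there *is* the interference being
    subtracted. Negative differences clip to zero with a flag. The
    reference window is a plain integral (there is no line to fit in it).
    """
    omc = integrate_window(spectrum, OMC_WINDOW, method=method, analyte="OMC")
    noise = integrate_window(spectrum, OMC_NOISE_WINDOW, method="sum", analyte="OMC")
    raw = omc.raw_area + omc.baseline_area
    corrected = raw - noise.raw_area
    flags = list(omc.flags) + ["omc_interference_corrected"]
    if corrected < 0:
        corrected = 0.0
        flags.append("corrected_area_clipped")
    return IntegrationResult("OMC", raw, corrected, omc.fit_quality,
                             OMC_WINDOW, flags=flags)


def area_to_solution_concentration(result: IntegrationResult,
                                   analyte: AnalyteDefinition,
                                   cal: EreticCalibration | None) -> float:
    """Eretic quantification: area -> mg/L in the measuring solution.

    c = (A / n_protons) * factor * M * 1000, i.e. the proton-normalized
    area times the eretic factor gives molarity, scaled to mg/L.
    """
    if cal is None:
        raise ConfigurationError("eretic calibration required for quantification")
    if result.corrected_area < 0:
        raise InvalidParameterError("corrected area must be >= 0")
    return (result.corrected_area / analyte.n_protons) * cal.factor \
        * analyte.molar_mass_g_mol * 1000.0


def solution_to_content(c_mg_L: float, sample_mass_g: float = DEFAULT_SAMPLE_MASS_G,
                        extract_volume_mL: float = DEFAULT_EXTRACT_VOLUME_ML,
                        recalculation_factor: float = 1.0) -> float:
    """Solution concentration -> content per kg of ground coffee.

    content = c * (V/m) * recalculation_factor; with the default 200 mg in
    1.5 mL this is 7.5 mg/kg per mg/L. The recalculation factor is 6 for
    caffeine (restricted CDCl3 solubility) and 1 otherwise.
    """
    if sample_mass_g <= 0 or extract_volume_mL <= 0:
        raise InvalidParameterError("sample mass and extract volume must be positive")
    return c_mg_L * (extract_volume_mL / 1000.0) / (sample_mass_g / 1000.0) \
        * recalculation_factor


def quantify_sample(spectrum: Spectrum,
                    analytes: dict[str, AnalyteDefinition] | None = None,
                    cal: EreticCalibration | None = None,
                    limits: dict[str, float] | None = None,
                    method: str = "linefit",
                    sample_mass_g: float = DEFAULT_SAMPLE_MASS_G,
                    extract_volume_mL: float = DEFAULT_EXTRACT_VOLUME_ML,
                    ) -> list[QuantificationResult]:
    """Quantify all analytes of one processed spectrum.

    OMC goes through the interference correction; every analyte is
    converted with the eretic factor and its own recalculation factor.
    ``limits`` optionally maps analyte name to a detection limit in mg/kg
    to set below-LOD flags. A failure in one analyte is recorded as a
    flagged zero-content result and does not abort the others.
    """
    analytes = analytes or DEFAULT_ANALYTES
    if cal is None and spectrum.params.device in K_DEVICE:
        cal = matched_calibration(spectrum.params.device)
    results: list[QuantificationResult] = []
    for name, a in analytes.items():
        try:
            if name == "OMC":
                integ = correct_omc_area(spectrum, method=method)
            else:
                integ = integrate_window(spectrum, a.window_ppm, method=method,
                                         analyte=name)
                if integ.corrected_area < 0:
                    integ.corrected_area = 0.0
                    integ.flags.append("corrected_area_clipped")
            c = area_to_solution_concentration(integ, a, cal)
            content = solution_to_content(c, sample_mass_g, extract_volume_mL,
                                          a.recalculation_factor)
            flags = list(integ.flags)
            if limits is not None and name in limits and content < limits[name]:
                flags.append("below_lod")
            results.append(QuantificationResult(name, c, content,
                                                cal.factor, flags))
        except (SpectrumRangeError, InvalidParameterError, ConfigurationError) as exc:
            results.append(QuantificationResult(name, float("nan"), float("nan"),
                                                cal.factor if cal else float("nan"),
                                                flags=[f"error: {exc}"]))
    return results


def measure_simulated_design(measurements, analytes=None, method: str = "linefit"):
    """Quantify every spectrum of a simulated factorial study.

    Returns the tidy per-(measurement, analyte) table the validation module
    consumes: columns analyte, matrix, device, shaking_min, array_index,
    spiked_mg_kg, measured_mg_kg, is_blank. The spiked content equivalent
    is level (mg/L) times the 7.5 mg/kg-per-mg/L extraction conversion.
    """
    import pandas as pd

    analytes = analytes or DEFAULT_ANALYTES
    conversion = DEFAULT_EXTRACT_VOLUME_ML / 1000.0 / (DEFAULT_SAMPLE_MASS_G / 1000.0)
    rows = []
    for m in measurements:
        cal = matched_calibration(m.cell.device)
        for q in quantify_sample(m.spectrum, analytes, cal, method=method):
            rows.append({
                "analyte": q.analyte,
                "matrix": m.cell.coffee_type,
                "device": m.cell.device,
                "shaking_min": m.cell.shaking_min,
                "array_index": m.cell.array_index,
                "spiked_mg_kg": m.level_mg_L * conversion,
                "measured_mg_kg": q.content_mg_kg,
                "is_blank": m.is_blank,
            })
    return pd.DataFrame(rows)
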