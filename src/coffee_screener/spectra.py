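"""1D proton NMR data model and processing chain.

The processing conventions follow routine high-resolution liquid-state
practice on 400 MHz instruments: a complex free induction decay (FID) of
``TD/2`` points sampled at dwell time ``1/SW``, exponential apodization
quoted as a line broadening in Hz, zero-filled FFT to the real-spectrum
size ``SI``, automatic zero/first-order phasing, and an asymmetric
least-squares baseline. Chemical-shift axes are stored descending
(high field left), the standard NMR display convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.optimize import minimize
from scipy.sparse.linalg import spsolve

from .errors import InvalidParameterError

__all__ = [
    "AcquisitionParameters",
    "FreeInductionDecay",
    "Spectrum",
    "ULTRASHIELD",
    "ASCEND",
    "DEVICE_PRESETS",
    "desk_params",
    "build_ppm_axis",
    "compute_acquisition_time",
    "apodize_exponential",
    "transform_to_spectrum",
    "phase_correct",
    "baseline_correct",
    "process_fid",
]


@dataclass(frozen=True)
class AcquisitionParameters:
    """Acquisition and processing parameters of a 1D proton experiment.

    Attributes use the customary Bruker-style parameter names in the
    docstrings: TD (time-domain points), SW (spectral width), NS/DS
    (scans/dummy scans), D1 (relaxation delay), AQ (acquisition time),
    SI (real spectrum size), RG (receiver gain), LB (line broadening).
    """

    time_domain_points: int = 131072
    spectral_width_hz: float = 8223.68
    spectral_width_ppm: float = 20.5503
    scans: int = 64
    dummy_scans: int = 2
    relaxation_delay_s: float = 30.0
    real_spectrum_size: int = 262144
    receiver_gain: float = 45.2
    temperature_k: float = 300.0
    line_broadening_hz: float = 0.30
    device: str = "UltraShield"

    def __post_init__(self) -> None:
        for name in ("time_domain_points", "scans", "real_spectrum_size"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.dummy_scans < 0:
            raise InvalidParameterError("dummy_scans must be >= 0")
        for name in ("spectral_width_hz", "spectral_width_ppm", "temperature_k"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.line_broadening_hz < 0:
            raise InvalidParameterError("line_broadening_hz must be >= 0")

    @property
    def carrier_frequency_mhz(self) -> float:
        """Spectrometer proton frequency implied by SW in Hz versus ppm."""
        return self.spectral_width_hz / self.spectral_width_ppm

    @property
    def acquisition_time_s(self) -> float:
        """AQ = TD / (2 SW) for the complex (TD/2-point) FID convention."""
        return compute_acquisition_time(self)

    @property
    def dwell_time_s(self) -> float:
        return 1.0 / self.spectral_width_hz

    @property
    def n_complex_points(self) -> int:
        return self.time_domain_points // 2

    def validate_consistency(self, aq_tol_s: float = 0.01, sw_tol_hz: float = 0.1) -> None:
        """Check the AQ/SW bookkeeping identities.

        ``AQ = TD/(2 SW)`` and ``SW_hz = SW_ppm * carrier_MHz`` must hold;
        the second is an identity here because the carrier is derived, but
        it guards externally supplied parameter sets.
        """
        aq = self.time_domain_points / (2.0 * self.spectral_width_hz)
        if abs(aq - self.acquisition_time_s) > aq_tol_s:
            raise InvalidParameterError("AQ inconsistent with TD and SW")
        sw = self.spectral_width_ppm * self.carrier_frequency_mhz
        if abs(sw - self.spectral_width_hz) > sw_tol_hz:
            raise InvalidParameterError("SW(Hz) inconsistent with SW(ppm) and carrier")


#: 400 MHz AVANCE Ultra Shield dialect.
ULTRASHIELD = AcquisitionParameters(
    spectral_width_hz=8223.68, spectral_width_ppm=20.5503, device="UltraShield"
)
#: 400 MHz Ascend dialect (marginally different SW calibration).
ASCEND = AcquisitionParameters(
    spectral_width_hz=8223.69, spectral_width_ppm=20.5617, device="Ascend"
)

DEVICE_PRESETS: dict[str, AcquisitionParameters] = {
    "UltraShield": ULTRASHIELD,
    "Ascend": ASCEND,
}


def desk_params(device: str = "UltraShield", time_domain_points: int = 16384,
                real_spectrum_size: int = 65536) -> AcquisitionParameters:
    """A reduced-size parameter set for simulation and testing.

    Keeps the spectral width, line broadening and all per-device constants
    of the full-size preset but shrinks TD/SI so that spectra are cheap to
    generate and fit; frequency resolution SW/SI stays well below the
    narrowest integration window.
    """
    base = DEVICE_PRESETS[device]
    return replace(base, time_domain_points=time_domain_points,
                   real_spectrum_size=real_spectrum_size)


@dataclass
class FreeInductionDecay:
    """Complex time-domain signal plus its acquisition parameters."""

    values: np.ndarray
    dwell_time_s: float
    params: AcquisitionParameters

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.ndim != 1:
            raise InvalidParameterError("FID must be one-dimensional")
        if self.dwell_time_s <= 0:
            raise InvalidParameterError("dwell_time_s must be positive")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dwell_time_s


@dataclass
class Spectrum:
    """Frequency-domain spectrum on a descending ppm axis.

    ``intensities`` may be complex between Fourier transform and phase
    correction; processed spectra are real.
    """

    intensities: np.ndarray
    ppm_axis: np.ndarray
    params: AcquisitionParameters
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        self.ppm_axis = np.asarray(self.ppm_axis, dtype=float)
        if self.intensities.shape != self.ppm_axis.shape:
            raise InvalidParameterError(
                "intensities and ppm_axis must have equal length"
            )
        d = np.diff(self.ppm_axis)
        if self.ppm_axis.size >= 2 and not (np.all(d < 0) or np.all(d > 0)):
            raise InvalidParameterError("ppm_axis must be strictly monotonic")
        if self.ppm_axis.size >= 2 and d[0] > 0:
            # normalise to the descending display convention
            self.ppm_axis = self.ppm_axis[::-1].copy()
            self.intensities = self.intensities[::-1].copy()

    @property
    def is_complex(self) -> bool:
        return np.iscomplexobj(self.intensities)

    def window_slice(self, low_ppm: float, high_ppm: float) -> slice:
        """Index slice covering ``[low, high]`` ppm on the descending axis."""
        from .errors import SpectrumRangeError

        lo, hi = sorted((low_ppm, high_ppm))
        ax = self.ppm_axis
        if hi > ax[0] or lo < ax[-1]:
            raise SpectrumRangeError(
                f"window ({lo}, {hi}) ppm outside axis [{ax[-1]:.3f}, {ax[0]:.3f}]"
            )
        start = int(np.searchsorted(-ax, -hi, side="left"))
        stop = int(np.searchsorted(-ax, -lo, side="right"))
        return slice(start, stop)

    def copy(self) -> "Spectrum":
        return Spectrum(self.intensities.copy(), self.ppm_axis.copy(),
                        self.params, self.label, dict(self.meta))


def build_ppm_axis(params: AcquisitionParameters, center_ppm: float) -> np.ndarray:
    """Equally spaced descending ppm axis of ``SI`` points.

    The grid matches the FFT bin layout used by :func:`transform_to_spectrum`:
    point ``i`` sits at ``center + SW/2 - i * SW/SI``.
    """
    si = params.real_spectrum_size
    if si < 2:
        raise InvalidParameterError("real_spectrum_size must be >= 2")
    if params.carrier_frequency_mhz <= 0:
        raise InvalidParameterError("carrier frequency must be positive")
    sw = params.spectral_width_ppm
    return center_ppm + sw / 2.0 - np.arange(si) * (sw / si)


def compute_acquisition_time(params: AcquisitionParameters) -> float:
    """AQ in seconds: ``TD / (2 SW)`` (complex-pair sampling)."""
    if params.time_domain_points <= 0 or params.spectral_width_hz <= 0:
        raise InvalidParameterError("TD and SW must be positive")
    return params.time_domain_points / (2.0 * params.spectral_width_hz)


def apodize_exponential(fid: FreeInductionDecay, lb_hz: float | None = None) -> FreeInductionDecay:
    """Multiply the FID by ``exp(-pi * LB * t)``.

    This is the standard exponential window: it adds exactly ``LB`` Hz to
    the Lorentzian full width at half maximum of every line.
    """
    if lb_hz is None:
        lb_hz = fid.params.line_broadening_hz
    if lb_hz < 0:
        raise InvalidParameterError("line broadening must be >= 0")
    window = np.exp(-np.pi * lb_hz * fid.times_s)
    return FreeInductionDecay(fid.values * window, fid.dwell_time_s, fid.params)


def transform_to_spectrum(fid: FreeInductionDecay, zero_fill_to: int | None = None,
                          center_ppm: float = 5.0) -> Spectrum:
    """Zero-filled FFT of the FID onto a descending ppm axis.

    The first FID point is halved (trapezoid-consistent DC handling) and the
    transform is scaled by the dwell time so that spectral areas in Hz
    approximate the continuous-Fourier areas of the time-domain model. The
    result is complex; :func:`phase_correct` takes the real part.
    """
    n = fid.values.size
    if zero_fill_to is None:
        zero_fill_to = fid.params.real_spectrum_size
    if zero_fill_to < n:
        raise InvalidParameterError("zero_fill_to must be >= number of FID points")
    buf = np.zeros(zero_fill_to, dtype=complex)
    buf[:n] = fid.values
    buf[0] *= 0.5
    spec = np.fft.fft(buf) * fid.dwell_time_s
    freqs = np.fft.fftfreq(zero_fill_to, d=fid.dwell_time_s)
    if zero_fill_to % 2 == 0:
        freqs[zero_fill_to // 2] = abs(freqs[zero_fill_to // 2])  # Nyquist as +SW/2
    order = np.argsort(-freqs, kind="stable")
    params = replace(fid.params, real_spectrum_size=zero_fill_to)
    axis = build_ppm_axis(params, center_ppm)
    return Spectrum(spec[order], axis, params)


def _apply_phase(values: np.ndarray, ph0: float, ph1: float) -> np.ndarray:
    n = values.size
    ramp = np.arange(n) / n - 0.5
    return values * np.exp(1j * (ph0 + ph1 * ramp))


def _negative_penalty(values: np.ndarray, ph: np.ndarray) -> float:
    real = _apply_phase(values, ph[0], ph[1]).real
    neg = real[real < 0]
    return float(np.sum(neg * neg))


def phase_correct(spectrum: Spectrum) -> Spectrum:
    """Automatic zero/first-order phase correction.

    The phase pair is chosen to minimise the integrated squared negative
    intensity, a simple automatic criterion that drives all lines of a
    well-behaved 1D spectrum into positive absorption. A coarse zero-order
    grid search seeds a Nelder-Mead refinement of both orders. Returns a
    real spectrum; the applied phases are stored in ``meta``.
    """
    values = np.asarray(spectrum.intensities, dtype=complex)
    # coarse zero-order scan
    grid = np.linspace(-np.pi, np.pi, 73, endpoint=False)
    pen = [_negative_penalty(values, np.array([p, 0.0])) for p in grid]
    ph0_0 = grid[int(np.argmin(pen))]
    best = None
    for ph1_0 in (0.0, -1.0, 1.0):
        res = minimize(lambda p: _negative_penalty(values, p),
                       x0=np.array([ph0_0, ph1_0]), method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    ph0, ph1 = best.x
    out = spectrum.copy()
    out.intensities = _apply_phase(values, ph0, ph1).real
    out.meta["phase0_rad"] = float(ph0)
    out.meta["phase1_rad"] = float(ph1)
    return out


def baseline_correct(spectrum: Spectrum, lam: float | None = None, p: float = 0.001,
                     n_iter: int = 20) -> Spectrum:
    """Asymmetric least-squares (Whittaker) baseline estimation.

    Fits a stiff smooth curve that hugs the signal-free points (asymmetry
    weight ``p`` pushes the curve below positive peaks) and subtracts it.
    ``lam`` controls stiffness and scales with the fourth power of the
    number of points so the default behaves alike at any zero-fill level.
    """
    y = np.asarray(spectrum.intensities, dtype=float)
    n = y.size
    if n < 10:
        raise InvalidParameterError("spectrum too short for baseline estimation")
    if lam is None:
        lam = 0.3 * (n / 100.0) ** 4  # stiffness ∝ n^4: same curvature scale at any SI
    d = sparse.diags([1.0, -2.0, 1.0], [0, -1, -2], shape=(n, n - 2))
    dtd = lam * (d @ d.T)
    w = np.ones(n)
    z = y
    for _ in range(n_iter):
        ws = sparse.diags(w)
        z = spsolve((ws + dtd).tocsc(), w * y)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    out = spectrum.copy()
    out.intensities = y - z
    out.meta["baseline_corrected"] = True
    return out


def process_fid(fid: FreeInductionDecay, center_ppm: float = 5.0,
                lb_hz: float | None = None, zero_fill_to: int | None = None,
                baseline: bool = True) -> Spectrum:
    """Full processing chain: apodize, FFT, autophase, baseline."""
    spec = transform_to_spectrum(apodize_exponential(fid, lb_hz),
                                 zero_fill_to, center_ppm)
    spec = phase_correct(spec)
    if baseline:
        spec = baseline_correct(spec)
    return spec
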