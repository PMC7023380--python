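"""Reading and writing spectra.

Two text dialects are supported:

* the package's own tabular format — two tab-separated columns (ppm,
  intensity) preceded by ``#`` header lines carrying the acquisition
  parameters as ``key=value`` pairs; lossless round trip;
* a minimal JCAMP-DX subset, read-only — ``##XYDATA=(X++(Y..Y))`` tables
  in plain (AFFN) form with XFACTOR/YFACTOR/FIRSTX/LASTX/NPOINTS, which is
  what common converters emit for processed 1D spectra.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .errors import SpectrumParseError, UnsupportedFormatError
from .spectra import AcquisitionParameters, Spectrum

__all__ = ["read_spectrum", "write_spectrum"]

_PARAM_FIELDS = ("time_domain_points", "spectral_width_hz", "spectral_width_ppm",
                 "scans", "dummy_scans", "relaxation_delay_s", "real_spectrum_size",
                 "receiver_gain", "temperature_k", "line_broadening_hz", "device")
_INT_FIELDS = {"time_domain_points", "scans", "dummy_scans", "real_spectrum_size"}


def write_spectrum(spectrum: Spectrum, path: str | Path, format: str = "tsv") -> None:
    """Write a spectrum in the tabular dialect (full float precision)."""
    if format != "tsv":
        raise UnsupportedFormatError(f"unsupported write format {format!r}")
    path = Path(path)
    lines = ["# coffee-screener spectrum v1", f"# label={spectrum.label}"]
    for name in _PARAM_FIELDS:
        lines.append(f"# {name}={getattr(spectrum.params, name)}")
    for ppm, inten in zip(spectrum.ppm_axis, np.real(spectrum.intensities)):
        lines.append(f"{float(ppm)!r}\t{float(inten)!r}")
    path.write_text("\n".join(lines) + "\n")


def read_spectrum(path: str | Path, format: str | None = None) -> Spectrum:
    """Read a spectrum file; the dialect is sniffed unless given.

    ``format`` may be ``"tsv"`` or ``"jcamp"``.
    """
    path = Path(path)
    text = path.read_text()
    if format is None:
        format = "jcamp" if text.lstrip().startswith("##") else "tsv"
    if format == "tsv":
        return _read_tabular(text, path)
    if format == "jcamp":
        return _read_jcamp(text, path)
    raise UnsupportedFormatError(f"unsupported read format {format!r}")


def _read_tabular(text: str, path: Path) -> Spectrum:
    header: dict[str, str] = {}
    ppm: list[float] = []
    inten: list[float] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                header[key.strip()] = value.strip()
            continue
        parts = line.split()
        if len(parts) != 2:
            raise SpectrumParseError(
                f"{path}:{lineno}: expected two columns, got {len(parts)}")
        try:
            ppm.append(float(parts[0]))
            inten.append(float(parts[1]))
        except ValueError as exc:
            raise SpectrumParseError(f"{path}:{lineno}: {exc}") from None
    if not ppm:
        raise SpectrumParseError(f"{path}: no data rows")
    kwargs = {}
    for name in _PARAM_FIELDS:
        if name in header:
            if name == "device":
                kwargs[name] = header[name]
            elif name in _INT_FIELDS:
                kwargs[name] = int(header[name])
            else:
                kwargs[name] = float(header[name])
    try:
        params = AcquisitionParameters(**kwargs)
    except Exception as exc:
        raise SpectrumParseError(f"{path}: bad acquisition parameters: {exc}") from None
    return Spectrum(np.asarray(inten), np.asarray(ppm), params,
                    label=header.get("label", path.stem))


def _read_jcamp(text: str, path: Path) -> Spectrum:
    fields: dict[str, str] = {}
    data_lines: list[str] = []
    in_data = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = re.sub(r"[\s_-]", "", key).upper()
            if key == "XYDATA":
                if "(X++(Y..Y))" not in value.replace(" ", ""):
                    raise SpectrumParseError(
                        f"{path}:{lineno}: only (X++(Y..Y)) XYDATA supported")
                in_data = True
                continue
            if key == "END":
                in_data = False
                continue
            fields[key] = value.strip()
            in_data = False
        elif in_data:
            data_lines.append(line)
    if not data_lines:
        raise SpectrumParseError(f"{path}: no XYDATA table found")
    yfac = float(fields.get("YFACTOR", 1.0))
    try:
        firstx = float(fields["FIRSTX"])
        lastx = float(fields["LASTX"])
    except KeyError as exc:
        raise SpectrumParseError(f"{path}: missing ##{exc.args[0]}") from None
    npoints = int(float(fields.get("NPOINTS", 0)))
    ys: list[float] = []
    for line in data_lines:
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            raise SpectrumParseError(f"{path}: malformed XYDATA line {line!r}")
        ys.extend(yfac * float(p) for p in parts[1:])
    if npoints and len(ys) != npoints:
        raise SpectrumParseError(
            f"{path}: NPOINTS={npoints} but {len(ys)} ordinates parsed")
    n = len(ys)
    # XFACTOR applies to the X column entries; FIRSTX/LASTX are already scaled
    axis = np.linspace(firstx, lastx, n)
    sw_ppm = abs(firstx - lastx) * n / max(n - 1, 1)
    params = AcquisitionParameters(real_spectrum_size=n,
                                   spectral_width_ppm=sw_ppm,
                                   spectral_width_hz=sw_ppm * 400.0,
                                   device=fields.get("SPECTROMETERDATASYSTEM",
                                                     "unknown"))
    return Spectrum(np.asarray(ys), axis, params,
                    label=fields.get("TITLE", path.stem))
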