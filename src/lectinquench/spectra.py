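"""Spectrum containers, CSV I/O and peak metrics.

Emission spectra are plain (wavelength, intensity) traces carrying optional
titration / denaturation metadata; a :class:`TitrationSeries` groups the
ligand-free reference spectrum (F0) with the ligand-titrated spectra recorded
at one temperature.  Peak location is refined with a three-point parabolic
vertex so that the reported emission maximum (lambda_max) does not depend on
the underlying band shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "SpectrumParseError",
    "EmissionSpectrum",
    "TitrationSeries",
    "CDSpectrum",
    "PeakMetrics",
    "read_spectrum",
    "write_spectrum",
    "peak_metrics",
    "intensity_at",
    "resample",
]


class ValidationError(ValueError):
    """Raised when a spectrum violates a structural invariant."""


class SpectrumParseError(ValueError):
    """Raised on malformed spectrum files; names the offending line."""


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    return arr


@dataclass(frozen=True)
class EmissionSpectrum:
    """A single emission trace: wavelengths (nm) and intensities (a.u.).

    ``meta`` may carry ``temperature_K``, ``quencher_M``, ``urea_M`` and
    ``replicate``; absent keys simply mean the quantity does not apply.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    meta: Mapping = field(default_factory=dict)

    def __post_init__(self):
        wl = _as_float_array(self.wavelengths, "wavelengths")
        it = _as_float_array(self.intensities, "intensities")
        if wl.size != it.size:
            raise ValidationError(
                f"length mismatch: {wl.size} wavelengths vs {it.size} intensities"
            )
        if wl.size < 5:
            raise ValidationError("a spectrum needs at least 5 points")
        if np.any(wl < 0):
            raise ValidationError("negative wavelengths")
        if np.any(np.diff(wl) <= 0):
            raise ValidationError("wavelengths must be strictly increasing")
        wl.setflags(write=False)
        it.setflags(write=False)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", it)
        object.__setattr__(self, "meta", dict(self.meta))

    @property
    def temperature_K(self):
        return self.meta.get("temperature_K")

    @property
    def quencher_M(self):
        return self.meta.get("quencher_M")

    @property
    def urea_M(self):
        return self.meta.get("urea_M")


@dataclass(frozen=True)
class TitrationSeries:
    """F0 spectrum plus quencher-titrated spectra at one temperature."""

    f0: EmissionSpectrum
    points: tuple  # of (quencher_M, EmissionSpectrum)
    temperature_K: float

    def __post_init__(self):
        pts = tuple((float(q), s) for q, s in self.points)
        qs = np.array([q for q, _ in pts])
        if qs.size and np.any(np.diff(qs) <= 0):
            raise ValidationError("quencher concentrations must be strictly increasing")
        if qs.size and np.any(qs <= 0):
            raise ValidationError("quencher concentrations must be positive")
        grid = self.f0.wavelengths
        for _, s in pts:
            if s.wavelengths.shape != grid.shape or not np.array_equal(s.wavelengths, grid):
                raise ValidationError("all spectra in a series must share one wavelength grid")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "temperature_K", float(self.temperature_K))

    @property
    def quencher_M(self) -> np.ndarray:
        return np.array([q for q, _ in self.points])


@dataclass(frozen=True)
class CDSpectrum:
    """Far-UV circular dichroism trace (ellipticity in mdeg by convention).

    ``protein_conc_M``, ``path_cm`` and ``n_residues`` enable conversion to
    mean residue ellipticity; they may be None for raw traces.
    """

    wavelengths: np.ndarray
    signal: np.ndarray
    protein_conc_M: float | None = None
    path_cm: float | None = None
    n_residues: int | None = None
    meta: Mapping = field(default_factory=dict)

    def __post_init__(self):
        wl = _as_float_array(self.wavelengths, "wavelengths")
        sg = _as_float_array(self.signal, "signal")
        if wl.size != sg.size:
            raise ValidationError("length mismatch between wavelengths and signal")
        if np.any(np.diff(wl) <= 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if self.path_cm is not None and self.path_cm <= 0:
            raise ValidationError("path length must be positive")
        wl.setflags(write=False)
        sg.setflags(write=False)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "signal", sg)
        object.__setattr__(self, "meta", dict(self.meta))


@dataclass(frozen=True)
class PeakMetrics:
    """Emission-peak position and height; ``at_edge`` flags maxima on the scan boundary."""

    lambda_max: float
    i_max: float
    at_edge: bool = False


def read_spectrum(path, dialect: str = "csv", meta: Mapping | None = None) -> EmissionSpectrum:
    """Read a two-column numeric table (wavelength_nm, intensity).

    A single non-numeric header line is tolerated; malformed data rows raise
    :class:`SpectrumParseError` naming the 1-based line number.
    """
    if dialect not in ("csv", "whitespace"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = "," if dialect == "csv" else None
    wl, it = [], []
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        fields = line.split(sep)
        try:
            x, y = float(fields[0]), float(fields[1])
        except (ValueError, IndexError):
            if lineno == 1 and not wl:  # optional header
                continue
            raise SpectrumParseError(f"{path}: malformed row at line {lineno}: {line!r}")
        wl.append(x)
        it.append(y)
    return EmissionSpectrum(np.array(wl), np.array(it), meta=dict(meta or {}))


def write_spectrum(spectrum: EmissionSpectrum, path, header: bool = True) -> None:
    """Write a spectrum as a two-column CSV; full float precision (round-trip safe)."""
    with open(path, "w") as fh:
        if header:
            fh.write("wavelength_nm,intensity\n")
        for x, y in zip(spectrum.wavelengths, spectrum.intensities):
            fh.write(f"{float(x)!r},{float(y)!r}\n")


def peak_metrics(spectrum: EmissionSpectrum, method: str = "quadratic") -> PeakMetrics:
    """Locate the emission maximum.

    ``grid_max`` returns the brightest sample.  ``quadratic`` (default) fits
    a parabola through that sample and its two neighbours and returns the
    vertex, clamped to the neighbour interval; a maximum on the scan edge
    falls back to the grid value with ``at_edge=True``.
    """
    wl, it = spectrum.wavelengths, spectrum.intensities
    i = int(np.argmax(it))
    if i == 0 or i == it.size - 1:
        return PeakMetrics(float(wl[i]), float(it[i]), at_edge=True)
    if method == "grid_max":
        return PeakMetrics(float(wl[i]), float(it[i]))
    if method != "quadratic":
        raise ValueError(f"unknown method {method!r}")
    x = wl[i - 1 : i + 2] - wl[i]  # centred for numerical conditioning
    y = it[i - 1 : i + 2]
    a, b, c = np.polyfit(x, y, 2)
    if a == 0:  # flat triple: keep the grid point
        return PeakMetrics(float(wl[i]), float(it[i]))
    uv = float(np.clip(-b / (2 * a), x[0], x[-1]))
    yv = float(np.polyval([a, b, c], uv))
    return PeakMetrics(float(wl[i] + uv), yv)


def intensity_at(spectrum, wavelength: float) -> float:
    """Linearly interpolated intensity at ``wavelength`` (nm); exact at grid nodes."""
    wl = spectrum.wavelengths
    if wavelength < wl[0] or wavelength > wl[-1]:
        raise ValueError(
            f"wavelength {wavelength} nm outside scanned range [{wl[0]}, {wl[-1]}]"
        )
    y = spectrum.intensities if hasattr(spectrum, "intensities") else spectrum.signal
    return float(np.interp(wavelength, wl, y))


def band_integral(spectrum: EmissionSpectrum) -> float:
    """Trapezoidal integral of intensity over the scanned band."""
    return float(np.trapezoid(spectrum.intensities, spectrum.wavelengths))


def resample(spectrum: EmissionSpectrum, new_grid: Sequence[float]) -> EmissionSpectrum:
    """Linear resampling onto ``new_grid``; never applied implicitly anywhere."""
    grid = np.asarray(new_grid, dtype=float)
    if grid[0] < spectrum.wavelengths[0] or grid[-1] > spectrum.wavelengths[-1]:
        raise ValueError("new grid extends beyond the scanned range")
    vals = np.interp(grid, spectrum.wavelengths, spectrum.intensities)
    return EmissionSpectrum(grid, vals, meta=dict(spectrum.meta))
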