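"""Spectral data type and CSV I/O.

Every quantity in the package that varies with wavelength — reflectance,
irradiance, receptor sensitivity, ocular-media transmission — is carried as a
:class:`Spectrum`: a non-negative function tabulated on a strictly increasing
integer-nanometre grid. The working grid is 400–700 nm at 1 nm; visible-band
photography passes roughly 420–680 nm and both modelled fish predators lack
UV-sensitive cones, so a 400–700 nm support covers every peak sensitivity and
the ocular cutoff with margin. All spectral integrals use the trapezoid rule;
resampling is linear interpolation.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_GRID",
    "Spectrum",
    "resample",
    "read_spectra_csv",
    "write_spectra_csv",
    "d65",
]

#: Default working grid: 400–700 nm inclusive, 1 nm step.
DEFAULT_GRID = np.arange(400, 701, dtype=float)

WAVELENGTH_COLUMN = "wavelength_nm"


@dataclass(frozen=True)
class Spectrum:
    """A wavelength-indexed non-negative function.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing wavelengths in nanometres.
    values
        Non-negative, finite values. Units depend on role: reflectance and
        transmission are fractions in [0, 1]; irradiance and sensitivity are
        relative (absolute scale cancels downstream).
    name
        Optional label, used for CSV column headers.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or vals.ndim != 1 or wl.size != vals.size:
            raise ValueError("wavelengths and values must be 1-D and equal length")
        if wl.size < 2:
            raise ValueError("a spectrum needs at least two samples")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(vals)):
            raise ValueError("spectrum values must be finite")
        if np.any(vals < 0):
            raise ValueError("spectrum values must be non-negative")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)

    def __eq__(self, other: object) -> bool:  # arrays break the default
        if not isinstance(other, Spectrum):
            return NotImplemented
        return np.array_equal(self.wavelengths_nm, other.wavelengths_nm) and np.array_equal(
            self.values, other.values
        )

    def resample(self, grid: np.ndarray) -> "Spectrum":
        return resample(self, grid)

    def integral(self) -> float:
        """Trapezoid-rule integral over the spectrum's own grid."""
        return float(np.trapezoid(self.values, self.wavelengths_nm))


def resample(spec: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linearly interpolate ``spec`` onto ``grid``.

    The target grid must lie within the source support; requests outside it
    raise with the overhanging range named, rather than silently extrapolating.
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = spec.wavelengths_nm[0], spec.wavelengths_nm[-1]
    if grid[0] < lo or grid[-1] > hi:
        raise ValueError(
            f"target grid [{grid[0]:g}, {grid[-1]:g}] nm overhangs source "
            f"support [{lo:g}, {hi:g}] nm"
        )
    values = np.interp(grid, spec.wavelengths_nm, spec.values)
    return Spectrum(grid, values, name=spec.name)


def read_spectra_csv(path) -> list[Spectrum]:
    """Read named spectra from a wide CSV (``wavelength_nm`` + one column each).

    Rejects files without a wavelength column, non-monotone wavelengths and
    negative values, naming the offending row.
    """
    df = pd.read_csv(path)
    if WAVELENGTH_COLUMN not in df.columns:
        raise ValueError(f"no wavelength column ({WAVELENGTH_COLUMN!r}) in {path}")
    wl = df[WAVELENGTH_COLUMN].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(wl) <= 0)[0]
    if bad.size:
        raise ValueError(f"non-monotone wavelengths at row {int(bad[0]) + 1}")
    spectra = []
    for col in df.columns:
        if col == WAVELENGTH_COLUMN:
            continue
        vals = df[col].to_numpy(dtype=float)
        neg = np.nonzero(vals < 0)[0]
        if neg.size:
            raise ValueError(f"negative value in column {col!r} at row {int(neg[0])}")
        spectra.append(Spectrum(wl, vals, name=str(col)))
    if not spectra:
        raise ValueError(f"no spectrum columns in {path}")
    return spectra


def write_spectra_csv(path, spectra: list[Spectrum]) -> None:
    """Write spectra sharing one grid to a wide CSV (inverse of the reader)."""
    if not spectra:
        raise ValueError("nothing to write")
    wl = spectra[0].wavelengths_nm
    for s in spectra[1:]:
        if not np.array_equal(s.wavelengths_nm, wl):
            raise ValueError("all spectra must share one wavelength grid")
    data = {WAVELENGTH_COLUMN: wl}
    for i, s in enumerate(spectra):
        data[s.name or f"spectrum_{i}"] = s.values
    pd.DataFrame(data).to_csv(path, index=False)


def d65(grid: np.ndarray | None = None) -> Spectrum:
    """The CIE D65 daylight illuminant (relative spectral power).

    Shipped as the standard 10-nm table over 400–700 nm and interpolated to
    the requested grid (default: the 1-nm working grid).
    """
    ref = importlib.resources.files("prawnvision.data") / "d65.csv"
    with importlib.resources.as_file(ref) as p:
        spec = read_spectra_csv(p)[0]
    return resample(spec, DEFAULT_GRID if grid is None else grid)
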