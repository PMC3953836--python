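"""Reflectance-spectrum I/O and preprocessing.

Spectra are held as wavelength-indexed arrays. The analysis grid is a fixed
1-nm grid from 300 to 700 nm inclusive (401 points); all downstream
integration assumes this grid (or any other common grid shared by every
curve entering a calculation).

Reflectance is stored internally as a unitless fraction. Files recorded in
percent are divided by 100 on read.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GRID_MIN",
    "GRID_MAX",
    "GRID_STEP",
    "WAVELENGTH_GRID",
    "ReflectanceSpectrum",
    "read_spectra",
    "write_spectra",
    "average_replicates",
    "process_spectrum",
]

GRID_MIN = 300.0
GRID_MAX = 700.0
GRID_STEP = 1.0

#: The common analysis grid: 300..700 nm in 1-nm steps (401 points).
WAVELENGTH_GRID = np.arange(GRID_MIN, GRID_MAX + GRID_STEP / 2, GRID_STEP)


@dataclass(frozen=True)
class ReflectanceSpectrum:
    """A single spectral curve: reflectance (or sensitivity, or irradiance)
    as a function of wavelength in nm.

    Parameters
    ----------
    wavelengths : array-like
        Strictly increasing wavelengths in nm.
    reflectance : array-like
        One value per wavelength. Raw instrument reads may contain small
        negative values; :func:`process_spectrum` removes them.
    label : str
        Species / surface / channel identifier.
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        refl = np.asarray(self.reflectance, dtype=float)
        if wl.ndim != 1 or refl.ndim != 1:
            raise ValueError("wavelengths and reflectance must be 1-D")
        if wl.size != refl.size:
            raise ValueError(
                f"length mismatch: {wl.size} wavelengths vs {refl.size} values"
            )
        if wl.size == 0:
            raise ValueError("empty spectrum")
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(refl)):
            raise ValueError("non-finite values in spectrum")
        if wl.size > 1 and not np.all(np.diff(wl) > 0):
            raise ValueError(f"wavelengths not strictly increasing ({self.label!r})")
        wl.setflags(write=False)
        refl.setflags(write=False)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "reflectance", refl)

    def __len__(self) -> int:
        return self.wavelengths.size

    def trim(self, lo: float = GRID_MIN, hi: float = GRID_MAX) -> "ReflectanceSpectrum":
        """Restrict to wavelengths in [lo, hi]."""
        mask = (self.wavelengths >= lo) & (self.wavelengths <= hi)
        if not mask.any():
            raise ValueError(
                f"spectrum {self.label!r} has no data in [{lo}, {hi}] nm"
            )
        return replace(
            self, wavelengths=self.wavelengths[mask], reflectance=self.reflectance[mask]
        )

    def resample(self, grid: np.ndarray = WAVELENGTH_GRID) -> "ReflectanceSpectrum":
        """Linear interpolation onto ``grid``.

        The target grid must lie within the measured range (no
        extrapolation).
        """
        grid = np.asarray(grid, dtype=float)
        if grid[0] < self.wavelengths[0] - 1e-9 or grid[-1] > self.wavelengths[-1] + 1e-9:
            raise ValueError(
                f"grid [{grid[0]}, {grid[-1]}] extends beyond measured range "
                f"[{self.wavelengths[0]}, {self.wavelengths[-1]}] for {self.label!r}"
            )
        return replace(
            self,
            wavelengths=grid,
            reflectance=np.interp(grid, self.wavelengths, self.reflectance),
        )

    def on_grid(self, grid: np.ndarray = WAVELENGTH_GRID) -> bool:
        return self.wavelengths.size == np.asarray(grid).size and np.allclose(
            self.wavelengths, grid
        )


def read_spectra(
    path: str | Path | io.IOBase,
    unit: str = "fraction",
    lo: float = GRID_MIN,
    hi: float = GRID_MAX,
) -> list[ReflectanceSpectrum]:
    """Read a wide CSV of spectra: first column wavelength (nm), one column
    per measurement.

    Rows outside [lo, hi] nm are dropped. ``unit='percent'`` divides values
    by 100 so that internal reflectance is always a fraction.
    """
    if unit not in ("fraction", "percent"):
        raise ValueError(f"unit must be 'fraction' or 'percent', got {unit!r}")
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty spectra file: {path}") from None
    if df.shape[0] == 0:
        raise ValueError(f"spectra file has no rows: {path}")
    if df.shape[1] < 2:
        raise ValueError("need a wavelength column plus at least one measurement column")
    values = df.apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        raise ValueError("non-numeric cells in spectra file")
    wl = values.iloc[:, 0].to_numpy(dtype=float)
    if not np.all(np.diff(wl) > 0):
        raise ValueError("wavelength column not strictly increasing")
    scale = 0.01 if unit == "percent" else 1.0
    out = []
    for col in values.columns[1:]:
        s = ReflectanceSpectrum(wl, values[col].to_numpy(dtype=float) * scale, str(col))
        out.append(s.trim(lo, hi))
    return out


def write_spectra(
    spectra: Sequence[ReflectanceSpectrum],
    path: str | Path,
    wavelength_column: str = "wavelength_nm",
) -> None:
    """Write spectra sharing one grid as a wide CSV (inverse of
    :func:`read_spectra`)."""
    if not spectra:
        raise ValueError("no spectra to write")
    grid = spectra[0].wavelengths
    for s in spectra[1:]:
        if not s.on_grid(grid):
            raise ValueError("spectra are not on a common grid; resample first")
    df = pd.DataFrame({wavelength_column: grid})
    for s in spectra:
        df[s.label] = s.reflectance
    df.to_csv(path, index=False)


def average_replicates(
    spectra: Sequence[ReflectanceSpectrum], label: str | None = None
) -> ReflectanceSpectrum:
    """Pointwise arithmetic mean of replicate spectra on a common grid.

    Raises if the grids differ (resample first); the label of the first
    replicate is inherited unless ``label`` is given.
    """
    if len(spectra) == 0:
        raise ValueError("no spectra to average")
    grid = spectra[0].wavelengths
    for s in spectra[1:]:
        if not s.on_grid(grid):
            raise ValueError(
                f"replicate {s.label!r} is not on the grid of {spectra[0].label!r}; "
                "resample first"
            )
    mean = np.mean([s.reflectance for s in spectra], axis=0)
    return ReflectanceSpectrum(grid, mean, label if label is not None else spectra[0].label)


def _loess(x: np.ndarray, y: np.ndarray, span: float, degree: int = 2) -> np.ndarray:
    """Local polynomial regression with a tricube kernel over a fractional
    span of nearest neighbours."""
    n = x.size
    k = int(np.ceil(span * n))
    k = min(n, max(k, degree + 2))
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argpartition(d, k - 1)[:k]
        dmax = d[idx].max()
        if dmax <= 0:
            out[i] = y[i]
            continue
        w = (1.0 - (d[idx] / dmax) ** 3) ** 3
        w = np.maximum(w, 1e-9)  # keep the design matrix full rank at the edge
        coeffs = np.polyfit(x[idx] - x[i], y[idx], degree, w=np.sqrt(w))
        out[i] = coeffs[-1]
    return out


def process_spectrum(
    s: ReflectanceSpectrum,
    span: float = 0.25,
    step: float = GRID_STEP,
    negatives: str = "clip",
    lo: float = GRID_MIN,
    hi: float = GRID_MAX,
) -> ReflectanceSpectrum:
    """Smooth, remove negative values, and resample onto the fixed grid.

    Steps, in order: degree-2 local regression with fractional ``span``;
    negative-value removal (``'clip'`` sets them to zero, ``'offset'`` adds
    a constant so the minimum becomes zero); linear resampling to an evenly
    spaced grid from ``lo`` to ``hi`` with ``step`` nm spacing.
    """
    if not (0 < span <= 1):
        raise ValueError(f"span must be in (0, 1], got {span}")
    if negatives not in ("clip", "offset"):
        raise ValueError(f"negatives must be 'clip' or 'offset', got {negatives!r}")
    n_steps = (hi - lo) / step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(f"step {step} does not divide the range [{lo}, {hi}]")
    s = s.trim(lo, hi)
    smoothed = _loess(s.wavelengths, s.reflectance, span)
    if negatives == "clip":
        cleaned = np.maximum(smoothed, 0.0)
    else:
        m = smoothed.min()
        cleaned = smoothed - m if m < 0 else smoothed
    grid = np.arange(lo, hi + step / 2, step)
    return ReflectanceSpectrum(s.wavelengths, cleaned, s.label).resample(grid)
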