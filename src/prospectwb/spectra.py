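"""Spectral grid handling shared by all modules.

Leaf optical properties are handled on a fixed 1-nm working grid
(400-2200 nm by default, 1801 points).  Instrument spectra sampled on
coarser or irregular grids are linearly interpolated onto it once, at
load time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WorkingGrid",
    "Spectrum",
    "DEFAULT_GRID",
    "CoverageError",
    "resample_to_grid",
    "band_mean",
]

#: Tolerance above 1.0 allowed for calibrated measured reflectance (noise).
CALIBRATION_EPS = 0.05

#: Physical support of the instrument.
WAVELENGTH_MIN = 350.0
WAVELENGTH_MAX = 2500.0


class CoverageError(ValueError):
    """Raised when a spectrum does not span the requested wavelength range."""


@dataclass(frozen=True)
class WorkingGrid:
    """Regular wavelength grid, in nanometres."""

    start: float = 400.0
    stop: float = 2200.0
    step: float = 1.0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError(f"grid step must be > 0, got {self.step}")
        if self.stop <= self.start:
            raise ValueError("grid stop must exceed start")

    @property
    def wavelengths(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.step)) + 1
        return self.start + self.step * np.arange(n)

    @property
    def n_points(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1


DEFAULT_GRID = WorkingGrid()


@dataclass
class Spectrum:
    """A sampled spectrum: wavelengths (nm) and dimensionless values.

    ``calibrated=True`` (the default) means values are reflectance or
    transmittance fractions and must lie in [0, 1 + 0.05]; raw detector
    signals are stored with ``calibrated=False`` and are only required
    to be finite and non-negative.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    calibrated: bool = True
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.ndim != 1 or self.values.ndim != 1:
            raise ValueError("wavelengths and values must be 1-D")
        if self.wavelengths.shape != self.values.shape:
            raise ValueError(
                f"length mismatch: {self.wavelengths.size} wavelengths, "
                f"{self.values.size} values"
            )
        if self.wavelengths.size < 1:
            raise ValueError("spectrum is empty")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if (
            self.wavelengths[0] < WAVELENGTH_MIN
            or self.wavelengths[-1] > WAVELENGTH_MAX
        ):
            raise ValueError(
                "wavelengths must lie within "
                f"[{WAVELENGTH_MIN:g}, {WAVELENGTH_MAX:g}] nm"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum values must be finite")
        if self.calibrated and (
            np.any(self.values < 0.0)
            or np.any(self.values > 1.0 + CALIBRATION_EPS)
        ):
            raise ValueError(
                "calibrated values must lie in [0, 1.05]; "
                "use calibrated=False for raw signals"
            )

    def __len__(self) -> int:
        return self.values.size

    def value_at(self, wavelength: float) -> float:
        """Value at the grid point nearest to ``wavelength``."""
        self._check_support(wavelength, wavelength)
        i = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        return float(self.values[i])

    def _check_support(self, lo: float, hi: float) -> None:
        if lo < self.wavelengths[0] or hi > self.wavelengths[-1]:
            raise CoverageError(
                f"requested range [{lo:g}, {hi:g}] nm outside spectrum "
                f"support [{self.wavelengths[0]:g}, {self.wavelengths[-1]:g}] nm"
            )

    def on_grid(self, grid: WorkingGrid) -> bool:
        gw = grid.wavelengths
        return self.wavelengths.size == gw.size and np.allclose(
            self.wavelengths, gw
        )


def resample_to_grid(s: Spectrum, grid: WorkingGrid = DEFAULT_GRID) -> Spectrum:
    """Linearly interpolate a spectrum onto the working grid.

    The input must span the full grid; no extrapolation is performed.
    Resampling a spectrum already on the grid returns identical values.
    """
    gw = grid.wavelengths
    s._check_support(gw[0], gw[-1])
    if s.on_grid(grid):
        return Spectrum(gw, s.values.copy(), calibrated=s.calibrated, name=s.name)
    vals = np.interp(gw, s.wavelengths, s.values)
    return Spectrum(gw, vals, calibrated=s.calibrated, name=s.name)


def band_mean(s: Spectrum, lo: float, hi: float) -> float:
    """Mean of the spectrum over [lo, hi] nm inclusive.

    A degenerate band (lo == hi) returns the nearest-grid value, which
    is how single-wavelength terms of vegetation indices are read.
    """
    if lo > hi:
        raise ValueError(f"band limits reversed: {lo} > {hi}")
    s._check_support(lo, hi)
    if lo == hi:
        return s.value_at(lo)
    mask = (s.wavelengths >= lo) & (s.wavelengths <= hi)
    if not np.any(mask):
        # band narrower than the local sampling: fall back to nearest point
        return s.value_at(0.5 * (lo + hi))
    return float(np.mean(s.values[mask]))
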