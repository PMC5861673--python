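"""Coupling of the leaf volume, its surfaces and the white background.

The measured system is, from top to bottom: upper leaf surface
(wavelength-independent reflectivity ``rsurf``, transmissivity
``1 - rsurf``, no absorption), leaf volume (R_leaf, T_leaf from the
plate model with transparent external boundaries), lower leaf surface
(same ``rsurf``) and the Teflon white background R_wb(lambda).  The
three coupling steps sum the multiple reflections between successive
pairs in closed form, and a fraction ``fwb`` of the beam may hit the
background directly beside the leaf.
"""

from __future__ import annotations

import numpy as np

from .coefficients import CoefficientSet
from .prospect import LeafParams, _volume_values, leaf_volume_rt, validate_params
from .spectra import DEFAULT_GRID, Spectrum, WorkingGrid

__all__ = [
    "flat_background",
    "validate_background",
    "surface_over_background",
    "leaf_on_background",
    "system_reflectance",
]


def flat_background(
    grid: WorkingGrid = DEFAULT_GRID, reflectance: float = 0.99
) -> Spectrum:
    """Spectrally flat white background (default synthetic Teflon, 0.99)."""
    if not 0.0 < reflectance <= 1.0:
        raise ValueError("background reflectance must lie in (0, 1]")
    wl = grid.wavelengths
    return Spectrum(wl, np.full_like(wl, reflectance), name="R_wb")


def validate_background(bg: Spectrum, grid: WorkingGrid = DEFAULT_GRID) -> None:
    if not bg.on_grid(grid):
        raise ValueError("background spectrum must be on the working grid")
    if np.any(bg.values <= 0.0) or np.any(bg.values > 1.0):
        raise ValueError("background reflectance must lie in (0, 1]")


def _couple(r_top: np.ndarray, t_top: np.ndarray, r_below: np.ndarray):
    """Reflectance of a non-absorbing-free composite: layer with
    (r_top, t_top) above a substrate of reflectance r_below, all
    inter-reflections summed: r_top + r_below * t_top^2 / (1 - r_top*r_below)
    for a symmetric layer."""
    denom = 1.0 - r_top * r_below
    if np.any(denom <= 0.0):
        raise FloatingPointError("divergent surface-background bounce series")
    return r_top + r_below * t_top ** 2 / denom


def surface_over_background(rsurf: float, r_wb: Spectrum) -> Spectrum:
    """Reflectance of the lower leaf surface lying on the white background:

        R_surf_wb = rsurf + R_wb (1 - rsurf)^2 / (1 - rsurf R_wb)
    """
    if not 0.0 <= rsurf < 1.0:
        raise ValueError("rsurf must lie in [0, 1)")
    vals = _couple(
        np.full_like(r_wb.values, rsurf), 1.0 - rsurf, r_wb.values
    )
    return Spectrum(r_wb.wavelengths, np.clip(vals, 0.0, 1.0), name="R_surf_wb")


def leaf_on_background(
    r_leaf: Spectrum,
    t_leaf: Spectrum,
    r_surf_wb: Spectrum,
    rsurf: float,
) -> Spectrum:
    """Two-stage composition of the leaf volume over the backed lower
    surface, then the upper surface over that:

        R_bue_wb  = R_leaf + R_surf_wb T_leaf^2 / (1 - R_leaf R_surf_wb)
        R_leaf_wb = rsurf + R_bue_wb (1 - rsurf)^2 / (1 - rsurf R_bue_wb)
    """
    if not 0.0 <= rsurf < 1.0:
        raise ValueError("rsurf must lie in [0, 1)")
    wl = r_leaf.wavelengths
    for s in (t_leaf, r_surf_wb):
        if s.values.shape != r_leaf.values.shape or not np.allclose(
            s.wavelengths, wl
        ):
            raise ValueError("inputs must share one wavelength grid")
    r_bue = _couple(r_leaf.values, t_leaf.values, r_surf_wb.values)
    r_out = _couple(np.full_like(r_bue, rsurf), 1.0 - rsurf, r_bue)
    return Spectrum(wl, np.clip(r_out, 0.0, 1.0), name="R_leaf_wb")


def _system_values(
    p: LeafParams,
    coeffs: CoefficientSet,
    bg_values: np.ndarray,
    internal_interfaces: bool = True,
) -> np.ndarray:
    """Unvalidated array core of :func:`system_reflectance` (hot path)."""
    r_leaf, t_leaf = _volume_values(p, coeffs, internal_interfaces)
    r_surf_wb = _couple(p.rsurf, 1.0 - p.rsurf, bg_values)
    r_bue = _couple(r_leaf, t_leaf, r_surf_wb)
    r_leaf_wb = _couple(p.rsurf, 1.0 - p.rsurf, r_bue)
    return np.clip(bg_values * p.fwb + (1.0 - p.fwb) * r_leaf_wb, 0.0, 1.0)


def system_reflectance(
    p: LeafParams,
    coeffs: CoefficientSet,
    bg: Spectrum,
    brown: bool = False,
    internal_interfaces: bool = True,
) -> Spectrum:
    """Full forward simulation of the measured white-background
    reflectance:

        R = R_wb * fwb + (1 - fwb) * R_leaf_wb
    """
    validate_params(p, coeffs.version, brown)
    if bg.values.shape != coeffs.wavelengths.shape or not np.allclose(
        bg.wavelengths, coeffs.wavelengths
    ):
        raise ValueError("background must be on the coefficient grid")
    vals = _system_values(p, coeffs, bg.values, internal_interfaces)
    return Spectrum(bg.wavelengths, vals, name="R_system")
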