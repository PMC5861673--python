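"""Specific absorption coefficients and refractive index per model version.

Four versions of the plate model are supported; they differ in how the
chlorophyllian pigments are separated and in their coefficient tables:

========  ==========================================  ==================
version   pigment separation                          constituents
========  ==========================================  ==================
P3        pooled chlorophyll a+b + carotenoids        cabc
P4        pooled chlorophyll a+b + carotenoids        cabc
P5        chlorophyll a+b and carotenoids split       cab, cc
PD        + anthocyanins                              cab, cc, canth
========  ==========================================  ==================

Water (``cw``, cm^2/mg), dry matter (``cm``, cm^2/mg) and brown pigments
(``cbp``, relative units for a dimensionless content) are common to all
versions.  Brown-pigment absorption follows the usual convention of a
smooth exponential decay from the blue into the near infrared.

The bundled tables returned by :func:`synthetic_coefficients` are
*synthetic*: smooth Gaussian band models placed at the known absorption
features of each constituent, with realistic magnitudes (e.g. the water
coefficient reproduces the order of magnitude of liquid-water absorption
at 1450 and 1940 nm).  They are not the published calibrations; real
tables can be supplied as CSV via :func:`load_coefficients_csv` with
columns ``wavelength_nm, n, sac_cab, sac_cc, sac_canth, sac_cbp,
sac_cw, sac_cm`` (or ``sac_cabc`` for pooled versions).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from typing import Mapping

import numpy as np
import pandas as pd

from .spectra import DEFAULT_GRID, Spectrum, WorkingGrid, resample_to_grid

__all__ = [
    "Version",
    "CoefficientSet",
    "synthetic_coefficients",
    "load_coefficients_csv",
    "save_coefficients_csv",
    "parse_variant",
    "VARIANTS",
]


class Version(str, Enum):
    P3 = "P3"
    P4 = "P4"
    P5 = "P5"
    PD = "PD"


#: the eight model variants: each version with and without brown pigments
VARIANTS = ("P3", "P3b", "P4", "P4b", "P5", "P5b", "PD", "PDb")

#: pigment constituents required per version (besides cw, cm, cbp)
PIGMENTS_BY_VERSION: Mapping[Version, tuple[str, ...]] = {
    Version.P3: ("cabc",),
    Version.P4: ("cabc",),
    Version.P5: ("cab", "cc"),
    Version.PD: ("cab", "cc", "canth"),
}

_COMMON = ("cw", "cm", "cbp")


def parse_variant(name: str) -> tuple[Version, bool]:
    """Split a variant name like ``'PDb'`` into (version, brown flag)."""
    if name not in VARIANTS:
        raise ValueError(f"unknown variant {name!r}; expected one of {VARIANTS}")
    brown = name.endswith("b")
    return Version(name[:-1] if brown else name), brown


@dataclass
class CoefficientSet:
    """Refractive index and specific absorption coefficients on a grid.

    Units: pigments cm^2/ug, water and dry matter cm^2/mg, brown
    pigments relative (dimensionless content).
    """

    version: Version
    wavelengths: np.ndarray
    refractive_index: np.ndarray
    sac: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.refractive_index = np.asarray(self.refractive_index, dtype=float)
        n_pts = self.wavelengths.size
        if self.refractive_index.shape != (n_pts,):
            raise ValueError("refractive index not on the working grid")
        if np.any(self.refractive_index < 1.0) or np.any(
            self.refractive_index > 1.7
        ):
            raise ValueError("refractive index must lie in [1.0, 1.7]")
        required = set(PIGMENTS_BY_VERSION[self.version]) | set(_COMMON)
        missing = required - set(self.sac)
        if missing:
            raise ValueError(
                f"version {self.version.value} requires coefficients for "
                f"{sorted(missing)}"
            )
        for key, table in self.sac.items():
            table = np.asarray(table, dtype=float)
            if table.shape != (n_pts,):
                raise ValueError(f"coefficient {key!r} not on the working grid")
            if np.any(table < 0):
                raise ValueError(f"coefficient {key!r} has negative values")
            self.sac[key] = table

    @property
    def constituents(self) -> tuple[str, ...]:
        return PIGMENTS_BY_VERSION[self.version] + _COMMON


def _gauss(wl: np.ndarray, center: float, width: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((wl - center) / width) ** 2)


def _pigment_cab(wl: np.ndarray, scale: float) -> np.ndarray:
    # Soret band in the blue and the red absorption maximum of Chl a+b;
    # the red-band tail extends into the red edge (690-720 nm).
    return scale * (
        _gauss(wl, 430.0, 30.0, 0.055)
        + _gauss(wl, 663.0, 25.0, 0.045)
        + _gauss(wl, 580.0, 60.0, 0.008)
    )


def _pigment_cc(wl: np.ndarray, scale: float) -> np.ndarray:
    # carotenoid absorption confined to the blue-green
    return scale * (
        _gauss(wl, 450.0, 18.0, 0.045)
        + _gauss(wl, 478.0, 16.0, 0.035)
        + _gauss(wl, 425.0, 20.0, 0.020)
    )


def _pigment_canth(wl: np.ndarray) -> np.ndarray:
    # anthocyanin green absorption maximum
    return _gauss(wl, 547.0, 28.0, 0.040)


def _brown(wl: np.ndarray) -> np.ndarray:
    # senescence polyphenols: strong in the blue, negligible beyond ~1000 nm
    return 0.8 * np.exp(-(wl - 400.0) / 140.0)


def _water(wl: np.ndarray) -> np.ndarray:
    # liquid-water overtone/combination bands; cm^2/mg (1 mg/cm^2 of water
    # is a 10-um equivalent water thickness)
    return (
        _gauss(wl, 970.0, 35.0, 0.0005)
        + _gauss(wl, 1200.0, 55.0, 0.0025)
        + _gauss(wl, 1450.0, 60.0, 0.030)
        + _gauss(wl, 1790.0, 80.0, 0.012)
        + _gauss(wl, 1940.0, 90.0, 0.115)
        + _gauss(wl, 2500.0, 250.0, 0.080)
    )


def _dry_matter(wl: np.ndarray) -> np.ndarray:
    # weak, broad absorption rising beyond the visible with cellulose/
    # protein features near 1720 and 2100 nm
    base = 0.0015 / (1.0 + np.exp(-(wl - 900.0) / 60.0))
    return (
        base
        + _gauss(wl, 1720.0, 60.0, 0.006)
        + _gauss(wl, 2100.0, 100.0, 0.008)
        + _gauss(wl, 1540.0, 80.0, 0.003)
    )


# per-version tweaks so that the four versions are similar but not identical
_VERSION_STYLE = {
    Version.P3: dict(pig_scale=1.00, water_scale=1.00, n0=1.46, n1=0.11),
    Version.P4: dict(pig_scale=0.95, water_scale=1.05, n0=1.46, n1=0.11),
    Version.P5: dict(pig_scale=1.00, water_scale=1.05, n0=1.46, n1=0.11),
    Version.PD: dict(pig_scale=0.97, water_scale=1.02, n0=1.44, n1=0.09),
}


@lru_cache(maxsize=None)
def _synthetic_cached(version: Version, start: float, stop: float, step: float):
    grid = WorkingGrid(start, stop, step)
    wl = grid.wavelengths
    style = _VERSION_STYLE[version]
    x = (wl - wl[0]) / (wl[-1] - wl[0])
    refr = style["n0"] - style["n1"] * x

    sac: dict[str, np.ndarray] = {
        "cw": style["water_scale"] * _water(wl),
        "cm": _dry_matter(wl),
        "cbp": _brown(wl),
    }
    if version in (Version.P3, Version.P4):
        # pooled chlorophyllian pigments: chlorophyll shape plus a
        # carotenoid contribution at the mean Cab/Cc ratio of ~5
        sac["cabc"] = _pigment_cab(wl, style["pig_scale"]) + 0.18 * _pigment_cc(
            wl, style["pig_scale"]
        )
    else:
        sac["cab"] = _pigment_cab(wl, style["pig_scale"])
        sac["cc"] = _pigment_cc(wl, style["pig_scale"])
        if version is Version.PD:
            sac["canth"] = _pigment_canth(wl)
    return wl, refr, sac


def synthetic_coefficients(
    version: Version | str, grid: WorkingGrid = DEFAULT_GRID
) -> CoefficientSet:
    """Synthetic coefficient set for a model version (see module docstring).

    Deterministic, generated in closed form on the requested grid; the
    same object contents are returned for repeated calls.
    """
    if isinstance(version, str):
        version = Version(version)
    wl, refr, sac = _synthetic_cached(version, grid.start, grid.stop, grid.step)
    return CoefficientSet(
        version=version,
        wavelengths=wl.copy(),
        refractive_index=refr.copy(),
        sac={k: v.copy() for k, v in sac.items()},
    )


_CSV_COLUMNS = {
    "cab": "sac_cab",
    "cc": "sac_cc",
    "cabc": "sac_cabc",
    "canth": "sac_canth",
    "cbp": "sac_cbp",
    "cw": "sac_cw",
    "cm": "sac_cm",
}


def load_coefficients_csv(
    path, version: Version | str, grid: WorkingGrid = DEFAULT_GRID
) -> CoefficientSet:
    """Load a coefficient table from CSV and resample it onto the grid.

    The file must cover the full grid.  For the pooled versions (P3/P4)
    a ``sac_cabc`` column is used if present, otherwise ``sac_cab`` is
    taken as the pooled coefficient.
    """
    if isinstance(version, str):
        version = Version(version)
    df = pd.read_csv(path)
    if "wavelength_nm" not in df.columns:
        raise ValueError("coefficient CSV needs a 'wavelength_nm' column")
    if "n" not in df.columns:
        raise ValueError("coefficient CSV needs a refractive-index column 'n'")
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    order = np.argsort(wl)
    df = df.iloc[order]
    wl = wl[order]

    def _col(name: str) -> np.ndarray:
        raw = Spectrum(wl, df[name].to_numpy(dtype=float), calibrated=False)
        return resample_to_grid(raw, grid).values

    refr = _col("n")
    sac: dict[str, np.ndarray] = {}
    for key in PIGMENTS_BY_VERSION[version] + _COMMON:
        col = _CSV_COLUMNS[key]
        if col not in df.columns and key == "cabc" and "sac_cab" in df.columns:
            col = "sac_cab"
        if col not in df.columns:
            raise ValueError(
                f"coefficient CSV is missing column {col!r} required by "
                f"version {version.value}"
            )
        sac[key] = _col(col)
    return CoefficientSet(
        version=version,
        wavelengths=grid.wavelengths,
        refractive_index=refr,
        sac=sac,
    )


def save_coefficients_csv(coeffs: CoefficientSet, path) -> None:
    """Write a coefficient set in the CSV layout read by the loader."""
    data = {"wavelength_nm": coeffs.wavelengths, "n": coeffs.refractive_index}
    for key, table in coeffs.sac.items():
        data[_CSV_COLUMNS[key]] = table
    pd.DataFrame(data).to_csv(path, index=False)
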