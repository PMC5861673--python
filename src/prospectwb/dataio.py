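"""Dataset layout, measurement equations and tabular I/O.

The experiment's data layout is a workbook (or an equivalent CSV
bundle, one file per sheet) with sheets::

    description
    reflectance_Chl                 pigment-subset leaves
    reflectance_Cw_Cm               water/dry-matter-subset leaves
    reflectance of white background

Each reflectance sheet is a wide table whose first column is
``wavelength_nm`` and whose remaining columns are leaves (header = leaf
id).  Rows whose first cell is not a number carry per-leaf metadata
(sample_id, stage, cultivar, modality) and the destructive contents
(Cab/Cc or Cabc in ug/cm^2 on the pigment sheet; Cw/Cm in mg/cm^2 on
the other).  The background sheet has two columns, ``wavelength_nm``
and ``reflectance``.

Also implemented here: the destructive content equations
(Cm = M_dry/S, Cw = (M_fresh - M_dry)/S) and the conversion of raw
spectrometer signals into the directional-hemispherical reflectance
factor using the before/after reference panel scans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import DEFAULT_GRID, Spectrum, WorkingGrid, resample_to_grid

__all__ = [
    "STAGES",
    "LeafSample",
    "destructive_contents",
    "dhrf_from_signals",
    "read_dataset",
    "write_dataset",
]

logger = logging.getLogger(__name__)

STAGES = ("two_nodes_april", "grain_filling_june")

_META_TEXT = ("sample_id", "stage", "cultivar", "modality")
_META_PIGMENT = ("Cab", "Cc", "Cabc")
_META_WATER = ("Cw", "Cm")

SHEET_PIGMENT = "reflectance_Chl"
SHEET_WATER = "reflectance_Cw_Cm"
SHEET_BACKGROUND = "reflectance of white background"
SHEET_DESCRIPTION = "description"


@dataclass
class LeafSample:
    """One leaf: identifiers, measured spectrum, destructive contents.

    ``destructive`` holds exactly one subset: pigment contents
    (``Cab``/``Cc`` and/or ``Cabc``, ug/cm^2) or water/dry matter
    (``Cw``/``Cm``, mg/cm^2).
    """

    sample_id: str
    stage: str
    cultivar: str
    modality: str
    leaf_id: str
    spectrum: Spectrum
    destructive: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(
                f"unknown stage {self.stage!r}; expected one of {STAGES}"
            )
        has_pig = any(k in self.destructive for k in _META_PIGMENT)
        has_wat = any(k in self.destructive for k in _META_WATER)
        if has_pig and has_wat:
            raise ValueError(
                "a leaf carries either pigment or water/dry-matter "
                "destructive values, not both"
            )
        for key, val in self.destructive.items():
            if val < 0:
                raise ValueError(f"destructive {key} must be >= 0")

    @property
    def subset(self) -> str:
        if any(k in self.destructive for k in _META_PIGMENT):
            return "pigment"
        if any(k in self.destructive for k in _META_WATER):
            return "water"
        return "none"


def destructive_contents(
    m_fresh: float, m_dry: float, area: float
) -> tuple[float, float]:
    """Dry matter and water contents from leaf masses (mg) and area (cm^2):

        Cm = M_dry / S        Cw = (M_fresh - M_dry) / S

    Returns (Cm, Cw) in mg/cm^2.
    """
    if area <= 0:
        raise ValueError("leaf area must be positive")
    if m_dry < 0 or m_fresh < m_dry:
        raise ValueError("need M_fresh >= M_dry >= 0")
    return m_dry / area, (m_fresh - m_dry) / area


def dhrf_from_signals(
    s_leaf: Spectrum,
    s_ref_bef: Spectrum,
    s_ref_aft: Spectrum,
    dhrf_ref: Spectrum,
) -> Spectrum:
    """Directional-hemispherical reflectance factor from raw signals:

        DHRF = 2 S_leaf / (S_ref_bef + S_ref_aft) * DHRF_ref

    using the reference-panel scans taken before and after the series.
    Values above 1.05 are reported and clipped.
    """
    wl = s_leaf.wavelengths
    for s in (s_ref_bef, s_ref_aft, dhrf_ref):
        if s.values.shape != wl.shape or not np.allclose(s.wavelengths, wl):
            raise ValueError("all signals must share one wavelength grid")
    ref_sum = s_ref_bef.values + s_ref_aft.values
    if np.any(ref_sum <= 0):
        raise ValueError("reference signals must be positive")
    vals = 2.0 * s_leaf.values / ref_sum * dhrf_ref.values
    n_over = int(np.sum(vals > 1.05))
    if n_over:
        logger.warning(
            "DHRF exceeds 1.05 at %d wavelengths; clipping", n_over
        )
        vals = np.minimum(vals, 1.05)
    return Spectrum(wl, np.clip(vals, 0.0, None), name="DHRF_leaf")


# ---------------------------------------------------------------------------
# wide-table (de)serialization


def _exact_floats(series: pd.Series) -> np.ndarray:
    """Convert a (possibly mixed-type) column with Python's correctly
    rounded float parsing so CSV round-trips preserve full precision;
    unparseable cells become NaN."""
    out = np.empty(len(series))
    for i, v in enumerate(series.to_numpy()):
        try:
            out[i] = float(v)
        except (TypeError, ValueError):
            out[i] = np.nan
    return out


def _samples_to_frame(samples: list[LeafSample]) -> pd.DataFrame:
    wl = samples[0].spectrum.wavelengths
    meta_keys = list(_META_TEXT) + sorted(
        {k for s in samples for k in s.destructive}
    )
    data: dict[str, list] = {"wavelength_nm": meta_keys + list(wl)}
    for s in samples:
        if s.spectrum.values.shape != wl.shape or not np.allclose(
            s.spectrum.wavelengths, wl
        ):
            raise ValueError("all leaves must share one wavelength grid")
        meta = {
            "sample_id": s.sample_id,
            "stage": s.stage,
            "cultivar": s.cultivar,
            "modality": s.modality,
            **s.destructive,
        }
        data[str(s.leaf_id)] = [meta.get(k, "") for k in meta_keys] + list(
            s.spectrum.values
        )
    return pd.DataFrame(data)


def _frame_to_samples(
    df: pd.DataFrame, sheet: str, grid: WorkingGrid
) -> list[LeafSample]:
    if df.columns[0] != "wavelength_nm":
        raise ValueError(
            f"sheet {sheet!r}: first column must be 'wavelength_nm', "
            f"got {df.columns[0]!r}"
        )
    first = df.iloc[:, 0].astype(str)
    numeric = pd.Series(_exact_floats(first), index=df.index)
    meta_rows = df[numeric.isna()]
    spec_rows = df[numeric.notna()]
    wl = numeric[numeric.notna()].to_numpy(dtype=float)
    if wl.size < 2:
        raise ValueError(f"sheet {sheet!r}: no wavelength rows found")
    if np.any(np.diff(wl) <= 0):
        raise ValueError(
            f"sheet {sheet!r}: wavelength column must be strictly increasing"
        )
    meta_index = meta_rows.iloc[:, 0].astype(str).to_numpy()

    samples: list[LeafSample] = []
    for leaf_id in df.columns[1:]:
        meta = dict(zip(meta_index, meta_rows[leaf_id]))
        values = _exact_floats(spec_rows[leaf_id])
        if np.any(~np.isfinite(values)):
            logger.warning(
                "sheet %r: leaf %r has non-numeric reflectance; skipped",
                sheet, leaf_id,
            )
            continue
        destructive = {}
        for key in _META_PIGMENT + _META_WATER:
            raw = meta.get(key, "")
            if raw != "" and not pd.isna(raw):
                destructive[key] = float(raw)
        try:
            spec = resample_to_grid(Spectrum(wl, values), grid)
            samples.append(
                LeafSample(
                    sample_id=str(meta.get("sample_id", "")),
                    stage=str(meta.get("stage", "")),
                    cultivar=str(meta.get("cultivar", "")),
                    modality=str(meta.get("modality", "")),
                    leaf_id=str(leaf_id),
                    spectrum=spec,
                    destructive=destructive,
                )
            )
        except ValueError as err:
            logger.warning(
                "sheet %r: leaf %r rejected (%s); skipped", sheet, leaf_id, err
            )
    return samples


def _background_frame(bg: Spectrum) -> pd.DataFrame:
    return pd.DataFrame(
        {"wavelength_nm": bg.wavelengths, "reflectance": bg.values}
    )


def _frame_to_background(df: pd.DataFrame, grid: WorkingGrid) -> Spectrum:
    for col in ("wavelength_nm", "reflectance"):
        if col not in df.columns:
            raise ValueError(f"background sheet is missing column {col!r}")
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    if np.any(np.diff(wl) <= 0):
        raise ValueError("background wavelengths must be strictly increasing")
    raw = Spectrum(wl, df["reflectance"].to_numpy(dtype=float), name="R_wb")
    return resample_to_grid(raw, grid)


def write_dataset(
    samples: list[LeafSample],
    background: Spectrum,
    path,
    description: str = "synthetic white-background leaf reflectance dataset",
) -> None:
    """Write samples + background as an ``.xlsx`` workbook or, for any
    other path, a directory bundle of CSV files (one per sheet)."""
    pigment = [s for s in samples if s.subset == "pigment"]
    water = [s for s in samples if s.subset != "pigment"]
    if not pigment or not water:
        # keep both sheets present even if one subset is empty-ish
        logger.warning("one destructive subset is empty")
    desc = pd.DataFrame({"description": [description]})
    frames = {
        SHEET_DESCRIPTION: desc,
        SHEET_PIGMENT: _samples_to_frame(pigment) if pigment else pd.DataFrame(
            {"wavelength_nm": []}
        ),
        SHEET_WATER: _samples_to_frame(water) if water else pd.DataFrame(
            {"wavelength_nm": []}
        ),
        SHEET_BACKGROUND: _background_frame(background),
    }
    path = Path(path)
    if path.suffix.lower() == ".xlsx":
        with pd.ExcelWriter(path, engine="openpyxl") as writer:
            for sheet, frame in frames.items():
                frame.to_excel(writer, sheet_name=sheet[:31], index=False)
    else:
        path.mkdir(parents=True, exist_ok=True)
        for sheet, frame in frames.items():
            frame.to_csv(path / f"{sheet.replace(' ', '_')}.csv", index=False)


def read_dataset(
    path, grid: WorkingGrid = DEFAULT_GRID
) -> tuple[list[LeafSample], Spectrum]:
    """Read a workbook or CSV bundle written in the documented layout.

    Returns (samples, background); spectra are resampled onto ``grid``.
    Leaves with corrupted spectra are skipped with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".xlsx":
        book = pd.read_excel(path, sheet_name=None)
        def _sheet(name: str) -> pd.DataFrame:
            key = name[:31]
            if key not in book:
                raise ValueError(f"workbook is missing sheet {name!r}")
            return book[key]
    else:
        def _sheet(name: str) -> pd.DataFrame:
            f = path / f"{name.replace(' ', '_')}.csv"
            if not f.exists():
                raise ValueError(f"bundle is missing sheet file {f.name!r}")
            return pd.read_csv(f)

    samples = _frame_to_samples(_sheet(SHEET_PIGMENT), SHEET_PIGMENT, grid)
    samples += _frame_to_samples(_sheet(SHEET_WATER), SHEET_WATER, grid)
    background = _frame_to_background(_sheet(SHEET_BACKGROUND), grid)
    logger.info("read %d leaves (%d pigment, %d water subset)",
                len(samples),
                sum(s.subset == "pigment" for s in samples),
                sum(s.subset == "water" for s in samples))
    return samples, background
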