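"""Vegetation indices and their empirical calibration.

Four indices are implemented, two tracking the pooled chlorophyllian
pigment content (Cabc) and two tracking water content (Cw):

=====  ======  =========================================  ==========
name   target  formula                                    calibration
=====  ======  =========================================  ==========
Dx4    Cabc    S(850)/S(710) - 1                          linear
CIre   Cabc    mean R 760-800 / mean R 690-710 - 1        linear
SRw    Cw      R(1300)/R(1450)                            linear
NDw    Cw      (R(1062)-R(1393))/(R(1062)+R(1393))        quadratic
=====  ======  =========================================  ==========

Dx4 was designed on leaf transmittance; here all indices are evaluated
on the white-background reflectance spectrum, whose absorption features
behave like those of transmittance-enhanced optical paths.  Band ranges
are band means; single wavelengths are nearest-grid samples.
Calibration regresses content on index by least squares (degree 1 or 2)
and is validated by leave-one-out.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .spectra import Spectrum, band_mean

__all__ = [
    "VI_NAMES",
    "VIDefinition",
    "CalibrationModel",
    "vi_definition",
    "compute_vi",
    "calibrate_vi",
    "loo_evaluate",
    "save_calibration",
    "load_calibration",
]


@dataclass(frozen=True)
class VIDefinition:
    name: str
    target: str           # "cabc" or "cw"
    degree: int           # polynomial degree of the calibration


_DEFINITIONS = {
    "Dx4": VIDefinition("Dx4", "cabc", 1),
    "CIre": VIDefinition("CIre", "cabc", 1),
    "SRw": VIDefinition("SRw", "cw", 1),
    "NDw": VIDefinition("NDw", "cw", 2),
}

VI_NAMES = tuple(_DEFINITIONS)


def vi_definition(name: str) -> VIDefinition:
    try:
        return _DEFINITIONS[name]
    except KeyError:
        raise ValueError(f"unknown vegetation index {name!r}") from None


def compute_vi(s: Spectrum, name: str) -> float:
    """Evaluate one index on a spectrum covering its bands."""
    vi = vi_definition(name).name
    if vi == "Dx4":
        denom = s.value_at(710.0)
        if denom == 0.0:
            raise ZeroDivisionError("Dx4 undefined: zero signal at 710 nm")
        return s.value_at(850.0) / denom - 1.0
    if vi == "CIre":
        denom = band_mean(s, 690.0, 710.0)
        if denom == 0.0:
            raise ZeroDivisionError("CIre undefined: zero red-edge band")
        return band_mean(s, 760.0, 800.0) / denom - 1.0
    if vi == "SRw":
        denom = s.value_at(1450.0)
        if denom == 0.0:
            raise ZeroDivisionError("SRw undefined: zero signal at 1450 nm")
        return s.value_at(1300.0) / denom
    # NDw
    a = s.value_at(1062.0)
    b = s.value_at(1393.0)
    if a + b == 0.0:
        raise ZeroDivisionError("NDw undefined: zero band sum")
    return (a - b) / (a + b)


@dataclass
class CalibrationModel:
    """Polynomial map from index value to biochemical content."""

    vi: VIDefinition
    coefficients: np.ndarray   # numpy polyval order (highest degree first)
    loo_r2: float = float("nan")
    loo_rmse: float = float("nan")

    def predict(self, index_values) -> np.ndarray:
        return np.polyval(self.coefficients, np.asarray(index_values, float))


def _fit(indices: np.ndarray, contents: np.ndarray, degree: int) -> np.ndarray:
    if np.ptp(indices) == 0.0:
        raise ValueError("degenerate design: all index values are equal")
    return np.polyfit(indices, contents, degree)


def calibrate_vi(indices, contents, name: str) -> CalibrationModel:
    """Least-squares fit of content on index (degree per index type)."""
    d = vi_definition(name)
    x = np.asarray(indices, dtype=float)
    y = np.asarray(contents, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("indices and contents must be equal-length vectors")
    if x.size < d.degree + 2:
        raise ValueError("too few points to calibrate")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("indices and contents must be finite")
    coefs = _fit(x, y, d.degree)
    model = CalibrationModel(vi=d, coefficients=coefs)
    try:
        model.loo_r2, model.loo_rmse = loo_evaluate(x, y, name)
    except ValueError:
        pass  # too few points for LOO; keep NaN diagnostics
    return model


def loo_evaluate(indices, contents, name: str) -> tuple[float, float]:
    """Leave-one-out validation: refit without each point, predict it,
    and score the held-out predictions (squared Pearson r and RMSE)."""
    d = vi_definition(name)
    x = np.asarray(indices, dtype=float)
    y = np.asarray(contents, dtype=float)
    n = x.size
    if n < 5:
        raise ValueError("leave-one-out needs at least 5 points")
    preds = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        coefs = _fit(x[keep], y[keep], d.degree)
        preds[i] = np.polyval(coefs, x[i])
    if np.ptp(y) == 0.0 or np.ptp(preds) == 0.0:
        raise ValueError("zero variance: r^2 undefined")
    r = np.corrcoef(y, preds)[0, 1]
    rmse = float(np.sqrt(np.mean((preds - y) ** 2)))
    return float(r ** 2), rmse


def save_calibration(model: CalibrationModel, path) -> None:
    payload = {
        "vi": model.vi.name,
        "target": model.vi.target,
        "degree": model.vi.degree,
        "coefficients": list(map(float, model.coefficients)),
        "loo_r2": model.loo_r2,
        "loo_rmse": model.loo_rmse,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)


def load_calibration(path) -> CalibrationModel:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return CalibrationModel(
        vi=vi_definition(payload["vi"]),
        coefficients=np.asarray(payload["coefficients"], dtype=float),
        loo_r2=float(payload["loo_r2"]),
        loo_rmse=float(payload["loo_rmse"]),
    )
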