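"""Agreement metrics between estimated and destructively measured
contents, plus spectral-fit diagnostics.

Conventions:

* r^2 is the squared Pearson correlation on the raw pairs,
* slope is the least-squares slope of estimated on measured,
* bias = mean(measured) - mean(estimated),
* "corrected RMSE" removes the systematic linear deviation: the OLS fit
  estimated = a*measured + b is inverted ((estimated - b)/a) before the
  RMSE is recomputed; a slope-only (through-origin) correction is
  available by flag,
* rRMSE expresses the corrected RMSE as a percentage of the mean
  measured value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .spectra import Spectrum

__all__ = [
    "MetricReport",
    "agreement_metrics",
    "rmse_corr",
    "rrmse",
    "SpectralDiagnostics",
    "spectral_fit_diagnostics",
]


@dataclass
class MetricReport:
    variable: str
    method: str
    r2: float
    spearman_rho: float
    rmse: float
    rmse_corr: float
    slope: float
    bias: float
    rrmse_pct: float
    n: int


def _paired(measured, estimated) -> tuple[np.ndarray, np.ndarray]:
    m = np.asarray(measured, dtype=float)
    e = np.asarray(estimated, dtype=float)
    if m.shape != e.shape or m.ndim != 1:
        raise ValueError("measured and estimated must be equal-length vectors")
    if m.size < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.all(np.isfinite(m)) and np.all(np.isfinite(e))):
        raise ValueError("inputs must be finite")
    return m, e


def rmse_corr(measured, estimated, through_origin: bool = False):
    """Slope(-and-offset)-corrected RMSE.

    Fits estimated = a*measured (+ b), maps estimates back through the
    inverse fit and returns (corrected RMSE, a).
    """
    m, e = _paired(measured, estimated)
    if through_origin:
        denom = float(np.dot(m, m))
        if denom == 0.0:
            raise ValueError("through-origin slope undefined: zero measured")
        a = float(np.dot(m, e)) / denom
        b = 0.0
    else:
        if np.ptp(m) == 0.0:
            raise ValueError("zero variance in measured values")
        a, b = np.polyfit(m, e, 1)
    if abs(a) < 1e-12:
        raise ValueError("non-invertible correction: slope ~ 0")
    corrected = (e - b) / a
    return float(np.sqrt(np.mean((corrected - m) ** 2))), float(a)


def rrmse(rmse_value: float, measured_mean: float) -> float:
    """Relative RMSE in percent of the mean measured content."""
    if measured_mean <= 0:
        raise ValueError("mean measured content must be positive")
    return 100.0 * rmse_value / measured_mean


def agreement_metrics(
    measured, estimated, variable: str = "", method: str = ""
) -> MetricReport:
    """All Table-style agreement metrics for one variable and method."""
    m, e = _paired(measured, estimated)
    if np.ptp(m) == 0.0 or np.ptp(e) == 0.0:
        raise ValueError("zero variance: correlation undefined")
    r = stats.pearsonr(m, e).statistic
    rho = stats.spearmanr(m, e).statistic
    rmse = float(np.sqrt(np.mean((e - m) ** 2)))
    rc, slope = rmse_corr(m, e)
    bias = float(np.mean(m) - np.mean(e))
    return MetricReport(
        variable=variable,
        method=method,
        r2=float(r ** 2),
        spearman_rho=float(rho),
        rmse=rmse,
        rmse_corr=rc,
        slope=slope,
        bias=bias,
        rrmse_pct=rrmse(rc, float(np.mean(m))),
        n=m.size,
    )


@dataclass
class SpectralDiagnostics:
    """Per-sample RMSE distribution and per-wavelength RMSE curve."""

    wavelengths: np.ndarray
    per_sample_rmse: np.ndarray
    per_wavelength_rmse: np.ndarray

    def panel(self, lo: float, hi: float):
        """Sub-curve over [lo, hi] nm (e.g. 400-1000 or 1000-2200)."""
        mask = (self.wavelengths >= lo) & (self.wavelengths <= hi)
        return self.wavelengths[mask], self.per_wavelength_rmse[mask]


def spectral_fit_diagnostics(
    measured: list[Spectrum], fitted: list[Spectrum]
) -> SpectralDiagnostics:
    """Misfit diagnostics over paired measured/fitted spectra: one RMSE
    per sample (across wavelengths) and one per wavelength (across
    samples)."""
    if len(measured) != len(fitted) or not measured:
        raise ValueError("need equally many measured and fitted spectra")
    wl = measured[0].wavelengths
    for s in measured + fitted:
        if s.values.shape != wl.shape or not np.allclose(s.wavelengths, wl):
            raise ValueError("all spectra must share one wavelength grid")
    diffs = np.array(
        [f.values - m.values for m, f in zip(measured, fitted)]
    )
    return SpectralDiagnostics(
        wavelengths=wl.copy(),
        per_sample_rmse=np.sqrt(np.mean(diffs ** 2, axis=1)),
        per_wavelength_rmse=np.sqrt(np.mean(diffs ** 2, axis=0)),
    )
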