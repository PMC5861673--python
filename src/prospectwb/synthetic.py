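"""Synthetic leaf datasets with known ground truth.

Parameter vectors are drawn uniformly within the inversion bounds
(the defaults of :mod:`prospectwb.inversion`), optionally with the
observed chlorophyll-carotenoid coupling (Cc = Cab/ratio + jitter,
ratio ~ 5) for the versions that separate the two pigments.  Spectra
are forward-simulated over the white background and perturbed with
additive i.i.d. Gaussian noise on reflectance (default sigma = 0.005,
the order of magnitude of typical spectral fit residuals), truncated
to [0, 1].  A single integer seed controls all randomness.

What this emulates: the spectral consequences of biochemical variation
plus instrument noise.  What it does not: detector splice artifacts,
senescence-specific residual structure, or destructive-measurement
error (ground-truth contents are exact).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coefficients import CoefficientSet, Version, synthetic_coefficients
from .dataio import STAGES, LeafSample
from .inversion import DEFAULT_BOUNDS
from .prospect import LeafParams, active_variables
from .spectra import DEFAULT_GRID, Spectrum, WorkingGrid
from .whitebg import flat_background, system_reflectance

__all__ = ["SimulationSpec", "sample_params", "generate_dataset",
           "wheat_ranges"]

_CULTIVARS = ("Apache", "Caphorn", "Soissons", "Hysun", "Isildur", "Biensur")


def wheat_ranges() -> dict[str, tuple[float, float]]:
    """Parameter ranges of field-grown wheat leaves measured over the
    white background.

    Unlike the wide inversion bounds (which must admit any leaf), these
    are the conditions of the wheat study itself: dry matter varies very
    little (about 4-6 mg/cm^2), water spans roughly 8-25 mg/cm^2,
    pigments run from senescent to dark green, the leaf covers most of
    the illuminated port (small ``fwb``), and structure/surface
    parameters sit in the narrow range retrieved for wheat.  Use these
    when a simulation should look like the experiment rather than
    exercise the full inversion domain; the narrow dry-matter range is
    what makes Cm the least constrained content.
    """
    return {
        "cabc": (5.0, 90.0),
        "cab": (4.0, 75.0),
        "cc": (1.0, 16.0),
        "canth": (0.0, 2.0),
        "cm": (4.0, 6.0),
        "cw": (8.0, 25.0),
        "cbp": (0.0, 0.3),
        "n": (1.2, 1.8),
        "rsurf": (0.01, 0.1),
        "fwb": (0.0, 0.15),
    }


@dataclass
class SimulationSpec:
    """Configuration of one synthetic dataset."""

    n_leaves: int = 50
    version: Version = Version.PD
    brown: bool = False
    parameter_ranges: dict[str, tuple[float, float]] = field(
        default_factory=dict
    )
    noise_sigma: float = 0.005
    couple_pigments: bool = True
    pigment_ratio: float = 5.0
    pigment_jitter: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.version, str):
            self.version = Version(self.version)
        if self.n_leaves < 1:
            raise ValueError("n_leaves must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        ranges = dict(DEFAULT_BOUNDS)
        for name, (lo, hi) in self.parameter_ranges.items():
            dlo, dhi = DEFAULT_BOUNDS[name]
            if lo < dlo or hi > dhi or lo > hi:
                raise ValueError(
                    f"range for {name} must lie within the bounds "
                    f"({dlo}, {dhi})"
                )
            ranges[name] = (lo, hi)
        self.parameter_ranges = ranges

    @property
    def active(self) -> tuple[str, ...]:
        return active_variables(self.version, self.brown)


def sample_params(spec: SimulationSpec) -> list[LeafParams]:
    """Uniform parameter draws within the configured ranges
    (deterministic for a given seed)."""
    rng = np.random.default_rng(spec.seed)
    return _sample_params(spec, rng)


def _sample_params(spec: SimulationSpec, rng: np.random.Generator):
    draws: list[LeafParams] = []
    split = spec.version in (Version.P5, Version.PD)
    for _ in range(spec.n_leaves):
        values: dict[str, float] = {}
        for name in spec.active:
            lo, hi = spec.parameter_ranges[name]
            values[name] = float(rng.uniform(lo, hi))
        if split and spec.couple_pigments:
            lo, hi = spec.parameter_ranges["cc"]
            cc = values["cab"] / spec.pigment_ratio + float(
                rng.normal(0.0, spec.pigment_jitter)
            )
            values["cc"] = float(np.clip(cc, max(lo, 0.0), hi))
        draws.append(LeafParams(**values))
    return draws


def generate_dataset(
    spec: SimulationSpec,
    coeffs: CoefficientSet | None = None,
    bg: Spectrum | None = None,
    grid: WorkingGrid = DEFAULT_GRID,
) -> tuple[list[LeafSample], list[LeafParams]]:
    """Forward-simulate a dataset of LeafSamples plus its ground truth.

    Leaves alternate between the pigment and the water/dry-matter
    destructive subsets, mirroring the 3+3 sampling design; the
    destructive values are the exact ground-truth contents.
    """
    if coeffs is None:
        coeffs = synthetic_coefficients(spec.version, grid)
    if bg is None:
        bg = flat_background(grid)
    rng = np.random.default_rng(spec.seed)
    truths = _sample_params(spec, rng)

    split = spec.version in (Version.P5, Version.PD)
    samples: list[LeafSample] = []
    for i, p in enumerate(truths):
        sim = system_reflectance(p, coeffs, bg, brown=spec.brown)
        values = sim.values
        if spec.noise_sigma > 0:
            values = values + rng.normal(0.0, spec.noise_sigma, values.shape)
            values = np.clip(values, 0.0, 1.0)
        if i % 2 == 0:
            destructive = (
                {"Cab": p.cab, "Cc": p.cc, "Cabc": p.cab + p.cc}
                if split
                else {"Cabc": p.cabc}
            )
        else:
            destructive = {"Cw": p.cw, "Cm": p.cm}
        samples.append(
            LeafSample(
                sample_id=f"S{i // 6:03d}",
                stage=STAGES[0] if i < spec.n_leaves // 2 else STAGES[1],
                cultivar=_CULTIVARS[i % len(_CULTIVARS)],
                modality=f"N{i % 3 + 1}D{i % 2 + 1}",
                leaf_id=f"L{i:04d}",
                spectrum=Spectrum(sim.wavelengths, values),
                destructive=destructive,
            )
        )
    return samples, truths
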