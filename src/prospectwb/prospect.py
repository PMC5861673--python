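"""Generalized plate (Stokes N-layer) leaf radiative transfer.

The leaf volume is modelled as N identical homogeneous elementary
layers.  Each layer absorbs according to the sum of its constituents'
specific absorption coefficients weighted by content (per layer, i.e.
divided by N) and scatters at the dielectric interfaces between layers.
For the white-background measurement configuration the two *external*
boundaries of the volume are taken as perfectly transmitting: the
directional surface reflectivity is handled outside the volume by the
wavelength-independent ``rsurf`` parameter (see :mod:`prospectwb.whitebg`).

Non-integer N is supported through the closed-form Stokes solution, and
the output is continuous across integer N.  Setting
``internal_interfaces=False`` removes the inter-layer interfaces as well,
leaving a purely absorbing stack (R=0, T=tau**N) for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields

import numpy as np
from scipy.special import exp1

from .coefficients import CoefficientSet, Version
from .spectra import Spectrum

__all__ = [
    "LeafParams",
    "active_variables",
    "validate_params",
    "tav",
    "layer_transmission",
    "absorption_coefficient",
    "absorption_spectrum",
    "add_layers",
    "plate_rt",
    "stokes_extension",
    "leaf_volume_rt",
]

#: variable ordering used for bound tables and optimizer vectors
CANONICAL_ORDER = (
    "cc", "cab", "cabc", "canth", "cm", "cw", "cbp", "n", "rsurf", "fwb",
)

_CONTENT_FIELDS = ("cab", "cc", "cabc", "canth", "cbp", "cw", "cm")


@dataclass
class LeafParams:
    """State vector of the leaf model.

    Contents: ``cab``, ``cc``, ``cabc``, ``canth`` in ug/cm^2, ``cw`` and
    ``cm`` in mg/cm^2, ``cbp`` dimensionless.  ``n`` is the mesophyll
    structure parameter (>= 1, real-valued), ``rsurf`` the wavelength-
    independent surface reflectivity and ``fwb`` the directly illuminated
    white-background fraction.  Fields inactive for a given version are
    kept at zero.
    """

    cab: float = 0.0
    cc: float = 0.0
    cabc: float = 0.0
    canth: float = 0.0
    cbp: float = 0.0
    cw: float = 0.0
    cm: float = 0.0
    n: float = 1.5
    rsurf: float = 0.0
    fwb: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in dc_fields(self)}


def active_variables(version: Version, brown: bool) -> tuple[str, ...]:
    """Free variables of the inversion for (version, brown-pigment flag)."""
    if version in (Version.P3, Version.P4):
        pigments = ("cabc",)
    elif version is Version.P5:
        pigments = ("cc", "cab")
    else:
        pigments = ("cc", "cab", "canth")
    active = set(pigments) | {"cm", "cw", "n", "rsurf", "fwb"}
    if brown:
        active.add("cbp")
    return tuple(v for v in CANONICAL_ORDER if v in active)


def validate_params(p: LeafParams, version: Version, brown: bool) -> None:
    """Check ranges and that variables outside the active set are zero."""
    for name in _CONTENT_FIELDS:
        if getattr(p, name) < 0:
            raise ValueError(f"content {name} must be >= 0")
    if p.n < 1.0:
        raise ValueError("structure parameter n must be >= 1")
    if not 0.0 <= p.rsurf < 1.0:
        raise ValueError("rsurf must lie in [0, 1)")
    if not 0.0 <= p.fwb <= 1.0:
        raise ValueError("fwb must lie in [0, 1]")
    active = set(active_variables(version, brown))
    for name in _CONTENT_FIELDS:
        if name not in active and getattr(p, name) != 0.0:
            raise ValueError(
                f"{name} is inactive for {version.value}"
                f"{'b' if brown else ''} and must be zero"
            )


# ---------------------------------------------------------------------------
# interface transmissivity and elementary-layer transmission


def tav(theta_deg: float, n) -> np.ndarray:
    """Transmissivity of a dielectric interface for light incident from
    vacuum within a cone of half-angle ``theta_deg``, averaged over the
    cone (Fresnel coefficients integrated over incidence angle).

    ``tav(90, n)`` is the diffuse (hemispherical) transmissivity used
    for inter-layer interfaces.
    """
    n = np.asarray(n, dtype=float)
    if np.any(n < 1.0):
        raise ValueError("refractive index must be >= 1")
    if not 0.0 < theta_deg <= 90.0:
        raise ValueError("incidence half-angle must be in (0, 90] degrees")
    n2 = n ** 2
    npl = n2 + 1.0
    nm = n2 - 1.0
    a = (n + 1.0) ** 2 / 2.0
    k = -((n2 - 1.0) ** 2) / 4.0
    sa = np.sin(np.deg2rad(theta_deg))

    b2 = sa ** 2 - npl / 2.0
    if theta_deg == 90.0:
        b = -b2  # b1 = 0
    else:
        b = np.sqrt(b2 ** 2 + k) - b2
    b3 = b ** 3
    a3 = a ** 3
    ts = (k ** 2 / (6.0 * b3) + k / b - b / 2.0) - (
        k ** 2 / (6.0 * a3) + k / a - a / 2.0
    )
    tp1 = -2.0 * n2 * (b - a) / npl ** 2
    tp2 = -2.0 * n2 * npl * np.log(b / a) / nm ** 2
    tp3 = n2 * (1.0 / b - 1.0 / a) / 2.0
    tp4 = (
        16.0
        * n2 ** 2
        * (n2 ** 2 + 1.0)
        * np.log((2.0 * npl * b - nm ** 2) / (2.0 * npl * a - nm ** 2))
        / (npl ** 3 * nm ** 2)
    )
    tp5 = (
        16.0
        * n2 ** 3
        * (1.0 / (2.0 * npl * b - nm ** 2) - 1.0 / (2.0 * npl * a - nm ** 2))
        / npl ** 3
    )
    tp = tp1 + tp2 + tp3 + tp4 + tp5
    return (ts + tp) / (2.0 * sa ** 2)


def layer_transmission(k) -> np.ndarray:
    """Transmission of isotropic flux through one elementary layer of
    absorption optical depth ``k``:

        tau(k) = (1 - k) exp(-k) + k^2 E1(k)

    with tau(0) = 1 and tau strictly decreasing towards 0.
    """
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise ValueError("absorption coefficient must be >= 0")
    # at k = 0 the second term vanishes exactly, so no branch is needed
    tau = (1.0 - k) * np.exp(-k) + k ** 2 * exp1(np.maximum(k, 1e-300))
    return np.clip(tau, 0.0, 1.0)


def absorption_coefficient(p: LeafParams, coeffs: CoefficientSet) -> np.ndarray:
    """Per-elementary-layer absorption: sum of the specific absorption
    coefficients weighted by content, divided by the number of layers N."""
    k = np.zeros_like(coeffs.wavelengths)
    for name in coeffs.constituents:
        content = getattr(p, name)
        if content:
            k = k + coeffs.sac[name] * content
    return k / p.n


def absorption_spectrum(
    p: LeafParams, coeffs: CoefficientSet, brown: bool = False
) -> Spectrum:
    """Absorption coefficient of one elementary layer as a Spectrum."""
    validate_params(p, coeffs.version, brown)
    k = absorption_coefficient(p, coeffs)
    return Spectrum(coeffs.wavelengths, k, calibrated=False, name="k")


# ---------------------------------------------------------------------------
# layer algebra

def add_layers(top, bottom):
    """Compose two layers by summing all inter-layer multiple reflections.

    Layers are (Rf, Tf, Rb, Tb) tuples of scalars or arrays: reflectance
    and transmittance for front (from above) and back (from below)
    incidence.  Returns the composite 4-tuple.
    """
    rf_a, tf_a, rb_a, tb_a = (np.asarray(x, dtype=float) for x in top)
    rf_b, tf_b, rb_b, tb_b = (np.asarray(x, dtype=float) for x in bottom)
    d = 1.0 - rb_a * rf_b
    if np.any(d <= 0.0):
        raise FloatingPointError("divergent inter-layer reflection series")
    rf = rf_a + tf_a * rf_b * tb_a / d
    tf = tf_a * tf_b / d
    rb = rb_b + tb_b * rb_a * tf_b / d
    tb = tb_b * tb_a / d
    return rf, tf, rb, tb


def _interface(t_exterior, n, from_above: bool):
    """Dielectric interface as a 4-tuple layer.

    ``t_exterior`` is the transmissivity seen from the vacuum side; from
    inside the medium it is ``t_exterior / n**2``.  ``t_exterior == 1``
    denotes an absent (fully transparent) boundary.  ``from_above`` tells
    whether the vacuum side faces up (entry interface) or down (exit).
    """
    t_ext = np.asarray(t_exterior, dtype=float)
    n = np.asarray(n, dtype=float)
    t_int = np.where(t_ext >= 1.0, 1.0, t_ext / n ** 2)
    r_ext = 1.0 - np.where(t_ext >= 1.0, 1.0, t_ext)
    r_int = 1.0 - t_int
    if from_above:
        return r_ext, t_ext, r_int, t_int
    return r_int, t_int, r_ext, t_ext


def plate_rt(tau, n, t_in, t_out):
    """Reflectance and transmittance of one absorbing plate.

    The plate has internal (isotropic-flux) transmission ``tau`` and is
    bounded by interfaces whose exterior-side transmissivities are
    ``t_in`` (top) and ``t_out`` (bottom); the corresponding interior-
    side transmissivities follow the dielectric relation t/n^2 except
    for fully transparent boundaries (t == 1).  All internal bounces are
    summed in closed form.  Returns (R1, T1) for incidence from above.
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0) or np.any(tau > 1):
        raise ValueError("tau must lie in [0, 1]")
    for t in (t_in, t_out):
        if np.any(np.asarray(t) < 0) or np.any(np.asarray(t) > 1):
            raise ValueError("interface transmissivities must lie in [0, 1]")
    top = _interface(t_in, n, from_above=True)
    slab = (np.zeros_like(tau), tau, np.zeros_like(tau), tau)
    bottom = _interface(t_out, n, from_above=False)
    rf, tf, _, _ = add_layers(add_layers(top, slab), bottom)
    return rf, tf


def _stokes_layers(r, t, m):
    """Closed-form Stokes solution for a pile of ``m`` identical
    symmetric layers (R=r, T=t each); ``m`` is real and >= 0."""
    r = np.asarray(r, dtype=float)
    t = np.asarray(t, dtype=float)
    r, t = np.broadcast_arrays(r, t)
    if m < 0:
        raise ValueError("layer count must be >= 0")
    if m == 0:
        return np.zeros_like(r), np.ones_like(t)

    R = np.empty_like(r)
    T = np.empty_like(t)

    conservative = (1.0 - r - t) < 1e-9
    dead = (~conservative) & (t < 1e-12)
    tiny_r = (~conservative) & (~dead) & (r < 1e-12)
    normal = ~(conservative | dead | tiny_r)

    # conservative layers: flux resistance adds linearly
    tc = t[conservative]
    Tm = tc / (tc + (1.0 - tc) * m)
    T[conservative] = Tm
    R[conservative] = 1.0 - Tm

    # opaque layers: nothing transmitted, first layer's reflectance seen
    R[dead] = r[dead]
    T[dead] = 0.0

    # negligible single-layer reflectance: first-order geometric series
    rr, tt = r[tiny_r], t[tiny_r]
    T[tiny_r] = tt ** m
    R[tiny_r] = rr * (1.0 - tt ** (2.0 * m)) / np.maximum(1.0 - tt ** 2, 1e-30)

    rr, tt = r[normal], t[normal]
    d2 = (1 + rr + tt) * (1 + rr - tt) * (1 - rr + tt) * (1 - rr - tt)
    D = np.sqrt(np.maximum(d2, 0.0))
    a = (1.0 + rr ** 2 - tt ** 2 + D) / (2.0 * rr)
    b = (1.0 - rr ** 2 + tt ** 2 + D) / (2.0 * tt)
    bm = b ** m
    bm2 = bm ** 2
    a2 = a ** 2
    denom = a2 * bm2 - 1.0
    R[normal] = a * (bm2 - 1.0) / denom
    T[normal] = bm * (a2 - 1.0) / denom

    return np.clip(R, 0.0, 1.0), np.clip(T, 0.0, 1.0)


def stokes_extension(r1, t1, n_layers: float):
    """Reflectance/transmittance of ``n_layers`` identical layers
    stacked on each other, each with single-layer values (r1, t1).

    ``n_layers`` is real-valued and >= 1; the degenerate dark layer
    (r1 = t1 = 0) yields (0, 0).
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    r1 = np.asarray(r1, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    if np.any(r1 < 0) or np.any(t1 < 0) or np.any(r1 + t1 > 1.0 + 1e-12):
        raise ValueError("need r1, t1 >= 0 and r1 + t1 <= 1")
    return _stokes_layers(r1, t1, float(n_layers))


def _interface_pair(coeffs: CoefficientSet):
    """Reflectance/transmittance of the exit+entry dielectric interface
    pair between consecutive elementary layers (diffuse flux, tav(90)).
    Cached on the coefficient set: it depends only on n(lambda)."""
    cached = getattr(coeffs, "_pair_cache", None)
    if cached is not None:
        return cached
    n_refr = coeffs.refractive_index
    t12 = tav(90.0, n_refr)
    t21 = t12 / n_refr ** 2
    r12 = 1.0 - t12
    r21 = 1.0 - t21
    d = 1.0 - r12 * r12
    t_pair = t21 * t12 / d
    r_pair = r21 + t21 * r12 * t12 / d
    coeffs._pair_cache = (r_pair, t_pair)
    return r_pair, t_pair


def _volume_values(
    p: LeafParams, coeffs: CoefficientSet, internal_interfaces: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Unvalidated array core of :func:`leaf_volume_rt` (hot path)."""
    k = absorption_coefficient(p, coeffs)
    tau = layer_transmission(k)
    if not internal_interfaces:
        return np.zeros_like(tau), tau ** p.n
    r_pair, t_pair = _interface_pair(coeffs)
    # symmetric repeated unit: half-slab | pair | half-slab
    r_m, t_m = _stokes_layers(tau * r_pair, tau * t_pair, p.n - 1.0)
    return tau * r_m, tau * t_m


def leaf_volume_rt(
    p: LeafParams,
    coeffs: CoefficientSet,
    brown: bool = False,
    internal_interfaces: bool = True,
) -> tuple[Spectrum, Spectrum]:
    """Leaf-volume reflectance and transmittance with transparent
    external boundaries.

    The N-layer stack is decomposed exactly as
    ``half-slab | [interface-pair + slab]^(N-1) | half-slab``:
    the repeated unit is symmetric, so the closed-form Stokes solution
    applies for real N and the result is continuous in N.  With
    ``internal_interfaces=False`` the stack is purely absorbing.
    """
    validate_params(p, coeffs.version, brown)
    r_leaf, t_leaf = _volume_values(p, coeffs, internal_interfaces)
    wl = coeffs.wavelengths
    return (
        Spectrum(wl, np.clip(r_leaf, 0.0, 1.0), name="R_leaf"),
        Spectrum(wl, np.clip(t_leaf, 0.0, 1.0), name="T_leaf"),
    )
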