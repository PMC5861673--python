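"""Retrieve leaf biochemistry from one noisy white-background spectrum
by bounded three-start inversion, and compare with the known truth."""

import numpy as np

from prospectwb import (
    InversionConfig,
    LeafParams,
    Spectrum,
    flat_background,
    invert_spectrum,
    synthetic_coefficients,
    system_reflectance,
)

rng = np.random.default_rng(42)
coeffs = synthetic_coefficients("PD")
background = flat_background()

truth = LeafParams(cab=45.0, cc=9.0, canth=0.5, cw=17.0, cm=5.0,
                   n=1.5, rsurf=0.04, fwb=0.03)
clean = system_reflectance(truth, coeffs, background)
noisy = Spectrum(
    clean.wavelengths,
    np.clip(clean.values + rng.normal(0, 0.005, clean.values.shape), 0, 1),
)

cfg = InversionConfig(version="PD", brown=False)
result = invert_spectrum(noisy, cfg, coeffs, background)
est = result.estimate

print("variable      truth   estimate   spread over 3 starts")
for name in cfg.active:
    print(f"{name:>8}   {getattr(truth, name):8.3f}   "
          f"{getattr(est, name):8.3f}   {result.spread[name]:.2e}")
print(f"\nspectral fit RMSE: {result.fit_rmse:.4f} "
      f"(noise level was 0.005)")
print(
    "Pigments and water are recovered to within a few percent from a\n"
    "single noisy spectrum; dry matter (cm) is the least constrained\n"
    "because its absorption is weak and overlapped by water."
)
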