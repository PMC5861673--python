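# Methods

## The leaf model

The leaf volume is a pile of N identical homogeneous elementary layers
(generalized plate model). One layer is characterized by:

* an absorption optical depth `k(λ) = Σᵢ Kᵢ(λ)·Cᵢ / N`, the sum of the
  constituents' specific absorption coefficients weighted by their
  area-based contents and shared among the N layers;
* the isotropic-flux transmission `τ(k) = (1−k)e⁻ᵏ + k²E₁(k)` (E₁ the
  exponential integral), the exact angular integral of Beer extinction
  over a hemisphere of directions;
* dielectric interfaces with diffuse transmissivity `t₁₂ = tav(90°, n)`
  (Fresnel coefficients averaged over the incidence hemisphere, closed
  form validated in the tests against numerical quadrature) and
  `t₂₁ = t₁₂/n²` from inside the medium.

Model versions P3 and P4 treat chlorophyll a+b and carotenoids as one
pooled constituent (C_abc); P5 splits them; PD adds anthocyanins. Each
version optionally includes brown pigments (senescence polyphenols), a
dimensionless content absorbing in the blue with an exponential decay
into the near infrared — the convention in which the bundled table is
expressed.

### White-background adaptation

In this measurement geometry the leaf surface is described by a single
wavelength-independent reflectivity `rsurf`, identical for both faces,
with transmissivity `1 − rsurf` and no absorption; the volume's external
boundaries are therefore made perfectly transmitting while the internal
inter-layer interfaces keep their dielectric behaviour. The original
model's incidence-solid-angle surface treatment is deliberately not
implemented.

Removing only the outer boundaries from a Stokes pile is done exactly by
the decomposition

    volume = half-slab | [interface-pair + slab]^(N−1) | half-slab

where "interface-pair" is the exit+entry dielectric pair between
consecutive layers and "slab" a pure absorber (τ). The repeated unit is
symmetric, so the classic closed-form Stokes solution applies for
real-valued N (retrieved wheat values are ~1.4–1.65) and the output is
continuous across integer N. Because the literature leaves open whether
internal interfaces should survive the surface-stripping, a fully
interface-free stack (R = 0, T = τᴺ) is switchable with
`internal_interfaces=False` for sensitivity checks.

The measured system composes, in closed form (all multiple reflections
summed): lower surface on the background, volume on that, upper surface
on that, and finally linear mixing with the background fraction `fwb`
directly hit by the beam. One printed form of the upper-surface step
writes the surface reflectivity with a wavelength argument; it is
implemented as a scalar, consistent with the stated assumption of
spectral independence. Directional-hemispherical and bi-hemispherical
quantities are treated as equal throughout.

## Coefficient tables

The bundled tables are **synthetic**: sums of Gaussian bands placed at
the known absorption features (chlorophyll 430/663 nm, carotenoids
450/478 nm, anthocyanins 547 nm, water 970/1200/1450/1790/1940 nm, dry
matter 1720/2100 nm over a weak logistic baseline) with magnitudes that
reproduce realistic optical depths (e.g. the water coefficient at
1450 nm corresponds to liquid-water absorption for a 10 µm equivalent
water thickness per mg/cm²). The four versions differ by small scale
factors and refractive-index curves so that version dispatch is
exercised. Consequences: all tests and the acceptance study are
self-contained and dataset-free, but absolute retrieval biases caused by
imperfect published calibrations (a central finding on real data) cannot
arise here — the forward and inverse models share the same coefficients.
Real calibrations can be loaded from CSV and used everywhere the
synthetic ones are.

## Inversion

Free variables per version: `[cabc, cm, cw, n, rsurf, fwb]` for P3/P4,
with `cab, cc` replacing `cabc` for P5 and adding `canth` for PD;
`cbp` joins for the brown variants. Bounds and the three fixed starting
points (defaults, editable on `InversionConfig`):

| variable | min | max | start 1 | start 2 | start 3 | units |
|---|---|---|---|---|---|---|
| cc    | 0    | 80  | 10   | 5    | 50    | µg/cm² |
| cab   | 0    | 140 | 50   | 20   | 80    | µg/cm² |
| cabc  | 0    | 140 | 60   | 20   | 90    | µg/cm² |
| canth | 0    | 20  | 5    | 1    | 10    | µg/cm² |
| cm    | 1    | 50  | 1    | 8    | 40    | mg/cm² |
| cw    | 1    | 30  | 25   | 1.5  | 18    | mg/cm² |
| cbp   | 0    | 1   | 0.01 | 0.2  | 0.001 | – |
| n     | 1.01 | 3.5 | 1.4  | 2.0  | 1.1   | – |
| rsurf | 0    | 0.5 | 0.05 | 0.1  | 0.01  | – |
| fwb   | 0    | 1   | 0.01 | 0.2  | 0.1   | – |

The cost is the root-mean-square spectral misfit over 400–2200 nm with
the conventional 1/1800 divisor (the 1-nm grid holds 1801 points; the
constant rescales J without moving the minimizer, and is kept as
printed). Minimization uses a bounded trust-region reflective
least-squares solver on the residual vector: local, deterministic and
descending, like the interior-point scalar minimization it replaces, but
far better conditioned near a perfect fit, where the gradient of the
square-root cost degenerates. Tolerances: 1e-10 on cost and step, at
most 500 iterations per start. The reported estimate is the per-variable
arithmetic mean of the three solutions (so a start trapped in a side
minimum is visible in the per-variable `spread` diagnostic), and
per-start convergence flags are kept. Batch inversion can work per leaf
or per sample (replicate spectra averaged first); per-leaf is the
default.

## Synthetic data

`SimulationSpec` draws parameter vectors uniformly within the inversion
bounds by default — the full domain the optimizer must cover — with an
optional chlorophyll–carotenoid coupling (cc = cab/5 + 1 µg/cm² Gaussian
jitter, truncated at zero) for the split versions, mirroring the strong
correlation observed in wheat. Spectra receive additive i.i.d. Gaussian
reflectance noise, default σ = 0.005, truncated to [0, 1]; a single
integer seed controls everything.

`wheat_ranges()` is the narrower, field-wheat scenario: dry matter 4–6
mg/cm² (its natural variability in such an experiment is tiny), water
8–25 mg/cm², pigments from senescent to dark green, N 1.2–1.8, small
surface reflectivity and background fraction. The generator emulates
biochemical variation plus instrument noise; it does not emulate
detector-splice artifacts, destructive-measurement error, coefficient-
calibration bias, or pigment clumping — so passing round-trip tests
demonstrate the correctness and conditioning of the estimator, not its
field accuracy.

The background defaults to a spectrally flat 0.99 synthetic Teflon
curve; a measured background (dataset sheet or two-column CSV) overrides
it.

## Evaluation conventions

r² is squared Pearson correlation on the raw pairs (a linear correction
leaves it unchanged); slope is OLS of estimated on measured; bias is
mean(measured) − mean(estimated). "Corrected RMSE" inverts the OLS
slope-and-offset fit before recomputing the RMSE; a slope-only
(through-origin) variant is available by flag since both readings of a
"slope correction" are defensible. rRMSE is the corrected RMSE as a
percentage of the mean measured value. Pigment metrics use the
pigment-destructive leaf subset, water/dry-matter metrics the other,
matching the 3+3 destructive sampling design.

Vegetation indices: band ranges (R₇₆₀₋₈₀₀, R₆₉₀₋₇₁₀) are band means;
single wavelengths nearest-grid samples. Dx4, designed on transmittance,
is evaluated on the white-background reflectance spectrum, which behaves
like a path-doubled transmittance. Calibrations regress content on index
(prediction of content is the use case), linear except quadratic for
NDw, and are scored by leave-one-out.

## Numerical choices

* Stokes closed form branches: conservative layers (1 − r − t < 1e-9)
  use the exact flux-resistance limit T_m = t/(t + (1−t)m); opaque
  layers (t < 1e-12) return (r, 0); near-zero reflectance uses the
  first-order geometric series. Branch thresholds keep the result
  continuous to ~1e-9, below every tolerance used.
* τ(k) is clipped to [0, 1] against rounding; E₁ is evaluated at
  max(k, 1e-300) so k = 0 is exact without a branch.
* Interpolation onto the 400–2200 nm, 1-nm working grid is linear
  (reflectance spectra are smooth at this scale); no extrapolation, no
  smoothing or splice correction.
* Coupling denominators (1 − R·R′) are guarded although they cannot
  vanish for valid inputs.
* Forward outputs are clipped to [0, 1] after composition to absorb
  last-ulp excursions.

## Problem sizes

The test suite inverts 50 noiseless leaves for each of the four versions
(recovery medians are at numerical precision), 50 noisy leaves for the
dry-matter conditioning check, and smaller sets elsewhere; the
acceptance script uses 40 leaves per experiment and 60 for the
vegetation-index pipeline. One inversion (three starts, ~1800 residuals,
6–9 free variables) takes well under a second.

## Known limitations

* Synthetic coefficient tables (above): no coefficient-bias effects.
* `rsurf` and `fwb` partly compensate each other (both brighten the
  system); they are effective parameters and their retrieved values
  should be compared between treatments, not read anatomically.
* Dry matter is intrinsically weakly constrained when its variability is
  small — the honest behaviour, quantified rather than hidden.
* No fluorescence, no surface BRDF, no background translucency or
  leaf–background air gap.
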