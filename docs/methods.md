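# Methods

This note documents the models implemented in `mosqnir`, the choices
made where the underlying physics or published procedure left the design
open, and what the synthetic-data experiments do and do not establish.

## Optical constants

* **Chitin dispersion.** `n_chi(λ) = n_inf + C/λ²` with `n_inf = 1.517`
  and `C = 8800 nm²`. Strictly decreasing in wavelength, limit 1.517;
  both coefficients are configurable through `OpticalConstants`.
* **Water absorption.** An embedded table of ~50 literature-style
  anchor values for pure liquid water (cm⁻¹, converted to µm⁻¹) spanning
  850–2500 nm is densified at import to a 5 nm grid by monotone PCHIP
  interpolation in log-coefficient; `mu_water` interpolates that grid
  linearly and raises outside the span. The table reproduces the
  qualitative structure that matters to the fits — the absorption bands
  near 1450 nm and 1940 nm and the window around 1200 nm — but is not a
  certified copy of any single published dataset. Because generator and
  fitter share the same table, recovery experiments are exact with
  respect to it.
* **Melanin absorption.** Broadband eumelanin absorption in the
  near-infrared is approximated as an exponential decay
  `µ_mel(λ) = µ_ref·exp(−β(λ−λ_ref))` with defaults
  `µ_ref = 0.01 µm⁻¹ at λ_ref = 1000 nm`, `β = 0.0062 nm⁻¹`. The
  *absolute* scale of near-infrared melanin absorption is a convention:
  fitted melanin pathlengths are comparable only within one constants
  configuration. All µ are in µm⁻¹ so that pathlength (µm) × µ is a
  dimensionless absorbance.

## Wing thin-film model

The fringe function `F(λ,d)` uses the normal-incidence Fresnel
reflectance of the air/chitin step and the interference phase
`2πd·n_chi(λ)/λ`. With a single fringe period inside a 900–2500 nm
window, the spectral exponent `k` of the general model is not
identifiable and is fixed at 0, reducing the model to the affine form
`(a·F + b)/2`; the general-`k` form is retained in the forward model
only. Reported `a`, `b` keep the convention in which the modulation
depth is `a/(a+b)`.

**Resonances.** `resonant_wavelengths` solves
`λ = 2d·n_chi(λ)(m−½)⁻¹·sqrt(1 − sin²θ/n²)` as a fixed point (tolerance
10⁻⁶ nm, ≤100 iterations; the square-root factor is dropped at normal
incidence). This is the *constructive-interference condition*: the
wavelength where the phase term `sin²φ` is maximal. The full fringe
function peaks a few nanometres short of it (4–17 nm over
d ∈ [100, 500] nm), because the Fresnel prefactor grows toward shorter
wavelengths and tilts the fringe. Tests therefore validate the closed
form against a brute-force scan of the fringe with the Fresnel factor
frozen, which isolates the phase maximum the formula describes.

**Fitting.** The thickness axis is multimodal (fringe-mode ambiguity),
so `fit_wing` profiles thickness on a 100–500 nm grid in 5 nm steps —
amplitude and bias are linear given `d` and solved per grid point — and
polishes the best three candidates with bounded trust-region least
squares (`d ∈ [50, 600] nm`, `a, b ∈ [0, 3]`); ties favour the smaller
thickness. 95 % CIs are t-quantile × standard errors from the
linearized covariance `s²(JᵀJ)⁻¹`. Seeded simulations at SNR 100:1 show
the interval for `d` covering truth at ~96 % over 200 replicates.

## Body model

Two-stage procedure: the spectrally flat specular reflectance is first
estimated as `median_λ |R_copol − R_depol|`, subtracted from the
co-polarized channel, and the four diffuse parameters
(`D_half`, `α`, `ℓ_H2O`, `ℓ_mel`) are then fitted independently per
channel (the de-polarized channel without subtraction, since gloss is
polarization-preserving). Bounds: `D_half ∈ [100, 5000] nm`,
`α ∈ [0, 10]`, `ℓ ∈ [0, 1000] µm`. The non-negativity bound on `α` is a
convention; a negative tilt is physically conceivable but never needed
on the data this models. Starts come from a 3⁴ grid of interior points;
all 81 are scored by SSE and the best six are polished with bounded
least squares — on every test problem this finds the same optimum as
polishing all starts at a fraction of the cost. A fit is flagged
*indeterminate* when any diffuse parameter's 95 % CI lower bound touches
zero, which is also how melanin-free specimens announce themselves
(≥ 80 % of noisy melanin-free replicates carry the flag).

Wavelengths above 1600 nm are excluded by default: the visible-extended
InGaAs instrument class this emulates lacks second-order rejection at
the long end.

The white-spot short-pass model `1/(1+(λ/D_half)^α)` is fitted the same
way with two parameters.

## Aspect harmonics

Per band, ordinary least squares on the design `{1, −cos ψ, −cos 2ψ}`.
On the default full-circle 15°-step grid the design columns are
orthogonal, so the `k0` estimate equals the plain angle average and
in-span data are recovered to machine precision. Bands are fitted
independently — the near-constancy of elongation and asymmetry across
bands is a finding to be observed, not a constraint to be imposed. The
SVD variance decomposition is computed on the raw (uncentered) matrix
and uses squared singular values; uncentered analysis is what makes the
dominant mean-like spectral component visible as a large first fraction.

## Synthetic data: what it emulates, and what it does not

Generators reproduce the instrument geometries: 288 bands over
900–2500 nm for wings, 382 bands over 900–1600 nm for bodies and spots,
24 yaw angles × 7 shortwave-infrared laser bands (1000–1640 nm) for
aspect scans, and 33 µm/pixel cubes for the imaging pipeline. Noise is
additive Gaussian, homoscedastic per spectrum, with
`σ = mean(signal)/SNR`; default SNRs are 100:1 (wings, de-polarized
bodies, spots) and 50:1 (co-polarized bodies). Real spectra additionally
carry band-correlated calibration structure, heteroscedastic shot noise,
and specimen heterogeneity that the generators do not model; passing
recovery tests therefore demonstrates correctness and calibration of the
estimators under the stated noise model, not instrument-level accuracy
on real animals.

Default generator parameters are the population medians of the system
being emulated: wing thickness 174 nm with fringe contrast 0.9; specular
offset 3 %; co-polarized pathlengths 51 µm (water) and 25 µm (melanin),
de-polarized 61/32 µm; spot cut 1215 nm with steepness 4.2. The
scatterance parameters are not published as medians; `D_half = 330 nm`
follows from the reported ±90 nm ≈ 27 % relative confidence, and
`α = 1.0` is a typical shortwave-infrared tissue scattering tilt. With
these defaults the median explanation grade over a simulated 82-specimen
study (both polarization channels at their instrument SNRs) is ~0.96;
the co-polarized channel alone, at SNR 50:1 and with the mild spectral
contrast these parameters produce, sits near 0.94.

By default `gen_body_spectra` gives both polarization channels the same
diffuse parameters, so the specular estimator inverts exactly on
noiseless output; the de-polarized population medians enter via
`DEPOL_MEDIANS` (used by `gen_population` and passed explicitly where a
co/de contrast is wanted). Population draws are lognormal with the
requested median and relative IQR (`σ_log = asinh(IQR/2)/z₀.₇₅`),
keeping every physical parameter positive.

All generators are pure functions of their arguments including the
seed; `numpy.random.default_rng` sequences (e.g. `[seed, i]`) give one
independent stream per replicate.

## Numerical conventions and edge cases

* Quantiles: linear interpolation (type 7) throughout.
* Allometric exponents: OLS on the log–log scale with t-intervals.
* `r = 0` (ideal mirror) in the directional-scattering lobe
  `cos(θ)^(1/r)` is a delta function and raises rather than evaluates.
* Dual-band ratios guard the denominator at 10⁻⁹ and raise on
  degenerate films.
* Spectra tables are written with 12 significant digits (round-trip
  lossless well past the 9-digit contract); readers reject missing
  columns, non-numeric cells and malformed ENVI headers rather than
  coercing.
* ENVI dialect: BSQ/BIL/BIP, little-endian, uint16/float32; row-major,
  0-based pixels; bands ascending in wavelength. Background statistics
  for masking come from the outer 2-pixel frame of the band-mean image
  (specimens are mounted against a dark border); the threshold rule is
  a stand-in validated on synthetic cubes only.

## Problem sizes

The recovery experiments run 100 wing spectra, 200 polarized pairs per
channel, 82 specular pairs and 100 spot spectra — enough that the
Monte-Carlo error of a median is far below each comparison tolerance,
while a full run of the acceptance script stays under a minute on one
CPU.

## Known limitations

* Single-fringe wing spectra cannot constrain thickness heterogeneity
  (the general `k`, `λ0` machinery is forward-only here).
* No radiative-transfer or Monte-Carlo photon transport; the thin-slab
  closed form is the model, by design.
* The melanin scale convention makes `ℓ_mel` comparable only within one
  constants configuration.
* Aspect modelling covers yaw only; pitch/roll dependence and
  higher-order spherical harmonics are out of scope.
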