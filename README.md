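# mosqnir

Near-infrared reflectance models of mosquito wings and bodies, with
fitters that turn spectra into **metric tissue parameters**: wing
membrane thickness in nanometres, and equivalent water/melanin
absorption pathlengths in micrometres.

Optical sensors and entomological lidars classify disease vectors by the
light they scatter. This package implements the physical forward models
behind those signals and the inverse problems that recover their
parameters, together with a synthetic-data generator that emulates the
instruments involved, so every fitted quantity can be exercised by
parameter recovery on a desk.

## Models

**Wing membranes** act as a chitin thin film (index
`n_chi = 1.517 + 8800 nm²/λ²`) between air interfaces. The reflectance
fringe is

```
F(λ,d) = 4R sin²(2πd·n_chi/λ) / ((1−R)² + 4R sin²(2πd·n_chi/λ)),
R = ((1−n_chi)/(1+n_chi))²
```

and a measured spectrum is fitted as `(a·F(λ,d) + b)/2`, yielding the
thickness `d`, the modulation depth `a/(a+b)`, and the resonant
backscatter wavelengths `λ_m = 2 d n_chi / (m − ½)`.

**Bodies** are thin, poorly scattering tissue in the shortwave infrared
(ballistic light transport), so the Kubelka–Munk thin-slab limit applies:

```
R_body(λ) = R_spec + S/(1 + S + A),
S(λ) = (D_half/λ)^α,
A(λ) = ℓ_H2O·µ_H2O(λ) + ℓ_mel·µ_mel(λ)
```

`R_spec` is estimated first as the median co/de-polarized difference,
then the four diffuse parameters are fitted per polarization channel.
The white abdominal spots of *Aedes aegypti* follow a short-pass curve
`1/(1 + (λ/D_half)^α)`.

**Aspect scans** (backscatter cross-section vs. yaw ψ, head at 0°) are
described by three polar harmonics
`σ(λ,ψ) = k0 − k1·cos ψ − k2·cos 2ψ`, giving elongation `k2/(k2+k0)` and
head/tail asymmetry `k1/(k1+k0)`; an uncentered SVD quantifies how
aspect-stable the spectrum is.

## Worked example

```
$ python examples/wing_thickness.py
recovered thickness : 174.4 (+/- 0.9) nm
modulation depth    : 0.902
explanation grade   : R2_adj = 0.9946
m=1 resonance       : 1063.9 nm
```

One noisy 288-band spectrum (900–2500 nm, SNR 100:1) of a 174 nm
membrane is inverted to the thickness within a sub-nanometre confidence
interval; the fringe contrast is 90 % and the first interference mode
sits near 1064 nm — which is why single-band sensors at common laser
lines are so sensitive to membrane thickness.

```
$ python examples/body_pathlengths.py
specular reflectance: 3.4 %
co-pol: water  55.1 (+/- 6.8) um, melanin  24.5 (+/- 2.9) um, R2_adj 0.938
de-pol: water  60.2 (+/- 2.8) um, melanin  32.2 (+/- 1.4) um, R2_adj 0.986
```

The fitted pathlengths are micrometres of pure chromophore equivalent to
the observed absorbance; de-polarized light travels deeper paths and
shows larger pathlengths. Other examples cover the white-spot short-pass
fit, aspect harmonics/SVD, the full hyperspectral cube pipeline
(calibration → masking → extraction → fit), and population-level
summaries with allometric exponents.

A thin CLI mirrors the library (`mosqnir fit-wing|fit-body|fit-spot|
fit-aspect|simulate|calibrate|segment|extract-spectrum|summarize`).

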