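"""Fit the short-pass model of the white abdominal spots of Aedes aegypti.

The spots look white in the visible but dim toward the infrared because
their scattering nanostructures are sub-wavelength there.  The reflectance
follows 1 / (1 + (lambda / D_half)^alpha); the cut wavelength D_half marks
where reflectance has fallen to one half.
"""

from mosqnir import fit_spot
from mosqnir import simulate as sim

spectrum = sim.gen_spot_spectrum(d_half_nm=1215.0, alpha=4.2, snr=100.0, seed=0)
fit = fit_spot(spectrum)

print(f"cut wavelength D1/2 : {fit.d_half_nm:.0f} (+/- {fit.ci95_d_half_nm:.0f}) nm")
print(f"steepness alpha     : {fit.alpha:.2f} (+/- {fit.ci95_alpha:.2f})")
print(f"explanation grade   : R2_adj = {fit.r2_adj:.4f}")
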