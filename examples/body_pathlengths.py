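"""Extract water and melanin pathlengths from polarized body spectra.

Generates one synthetic polarized pair (382 bands, 900-1600 nm; SNR 50:1
co-polarized, 100:1 de-polarized) with distinct diffuse parameters per
channel, then fits the specular offset and the four-parameter diffuse
model to each channel.
"""

from mosqnir import fit_body
from mosqnir import simulate as sim

pair = sim.gen_body_spectra(
    r_spec=0.03,
    ell_h2o_um=51.0,
    ell_mel_um=25.0,
    depol_params={"ell_h2o_um": 61.0, "ell_mel_um": 32.0},
    seed=0,
)
co, de = fit_body(pair)

print(f"specular reflectance: {100 * co.r_spec:.1f} %")
for fit in (co, de):
    print(
        f"{fit.polarization}-pol: water {fit.ell_h2o_um:5.1f} "
        f"(+/- {fit.ci95['ell_h2o_um']:.1f}) um, "
        f"melanin {fit.ell_mel_um:5.1f} (+/- {fit.ci95['ell_mel_um']:.1f}) um, "
        f"R2_adj {fit.r2_adj:.3f}"
    )

# The pathlengths are metric: micrometres of pure chromophore that would
# produce the observed absorbance.  De-polarized light interrogates deeper,
# multiply-scattered paths, hence the larger pathlengths on that channel.
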