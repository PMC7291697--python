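"""Forward model: reflectance of marrow-like tissue seen by the two-fiber probe.

Builds a cancellous-bone composition, computes its diffuse reflectance
spectrum, and shows how added hemoglobin darkens the visible band while
leaving the NIR fat/water bands almost untouched.
"""

import dataclasses

import numpy as np

from drsfit import InstrumentConfig, TissueComposition, forward_reflectance, load_default_chromophores

inst = InstrumentConfig()  # 1.042 mm fiber separation, 450-1600 nm
chrom = load_default_chromophores()

marrow = TissueComposition(
    hb_gl=13.0, hbo2_gl=30.3,          # ~29% blood content
    fat_vol_frac=0.251, water_vol_frac=0.699,  # fat fraction ~26%
    scatter_amp_800=15.9, scatter_slope=1.0,
)
spec = forward_reflectance(marrow, inst, chrom)
bloodier = forward_reflectance(dataclasses.replace(marrow, hbo2_gl=60.0), inst, chrom)

wl = spec.grid.wavelengths_nm
for probe_nm in (550, 800, 930, 1200, 1450):
    i = int(np.argmin(np.abs(wl - probe_nm)))
    drop = 100 * (1 - bloodier.reflectance[i] / spec.reflectance[i])
    print(f"{probe_nm:5d} nm  R = {spec.reflectance[i]:.4e}   +30 g/l HbO2 -> {drop:5.1f}% darker")

print(
    "\nHemoglobin absorbs in the 450-600 nm Q-band region, so extra blood "
    "suppresses the visible reflectance by orders of magnitude more than the "
    "NIR, where the fat (930/1211 nm) and water (975/1450 nm) bands dominate."
)
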