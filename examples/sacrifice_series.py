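"""Perfusion decay: fat fraction stays stable while blood drains.

Simulates the 70-minute post-sacrifice recording at reduced sampling, fits
spectra at a few time points, and quantifies the 1200-nm-normalized spectral
overlap in the NIR versus the hemoglobin band.
"""

import numpy as np

from drsfit import (
    InstrumentConfig,
    SacrificeConfig,
    fit_spectrum,
    forward_reflectance,
    generate_sacrifice_series,
    load_default_chromophores,
    normalize_at,
)

inst = InstrumentConfig()
chrom = load_default_chromophores()
sc = SacrificeConfig(n_samples=60)

series = generate_sacrifice_series(sc, inst, chrom, seed=0)
print(f"{'t (min)':>8}{'blood truth':>12}{'blood fit':>10}{'fat frac truth':>15}{'fat frac fit':>13}")
for m in series[:: len(series) // 5][:6]:
    fit = fit_spectrum(m.spectrum, inst, chrom)
    blood_t, _, ff_t = sc.truth_at(m.time_s)
    print(
        f"{m.time_s / 60:>8.1f}{blood_t:>12.1f}{fit.blood_content_pct:>10.1f}"
        f"{ff_t:>15.1f}{fit.fat_fraction_pct:>13.1f}"
    )

s0 = normalize_at(forward_reflectance(sc.composition_at(0.0), inst, chrom))
sT = normalize_at(forward_reflectance(sc.composition_at(sc.duration_s), inst, chrom))
wl = s0.grid.wavelengths_nm
rel = np.abs(sT.reflectance - s0.reflectance) / s0.reflectance
nir = (wl >= 1000) & (wl <= 1600)
vis = (wl >= 530) & (wl <= 580)
print(
    f"\n1200 nm-normalized start/end spectra: max relative change "
    f"{100 * rel[nir].max():.0f}% in 1000-1600 nm vs "
    f"{100 * rel[vis].max():.0f}% in the 530-580 nm hemoglobin band."
)
print(
    "Blood content halves while the fat fraction drifts by ~3 pp: the breach "
    "signal is robust to perfusion changes."
)
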