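"""Inverse fit: recover tissue physiology from one noisy spectrum.

Simulates a measurement of cancellous bone at the default instrument noise
and fits it back, printing truth vs estimate with 95% confidence
half-widths for the two clinically used parameters.
"""

from drsfit import (
    InstrumentConfig,
    TissueComposition,
    add_instrument_noise,
    blood_content,
    fat_fraction,
    fit_spectrum,
    forward_reflectance,
    load_default_chromophores,
)

inst = InstrumentConfig()
chrom = load_default_chromophores()

truth = TissueComposition(
    hb_gl=13.0, hbo2_gl=30.3, fat_vol_frac=0.251, water_vol_frac=0.699,
    scatter_amp_800=15.9, scatter_slope=1.0,
)
spec = add_instrument_noise(forward_reflectance(truth, inst, chrom), inst, seed=7)
fit = fit_spectrum(spec, inst, chrom)

print(f"converged: {fit.converged} ({fit.n_iter} function evaluations)")
print(f"{'parameter':<22}{'truth':>9}{'fitted':>9}{'95% CI':>9}")
rows = [
    ("blood content (%)", blood_content(truth), fit.blood_content_pct, fit.ci95["blood_content_pct"]),
    ("fat fraction (%)", fat_fraction(truth.fat_vol_frac, truth.water_vol_frac),
     fit.fat_fraction_pct, fit.ci95["fat_fraction_pct"]),
    ("fat content (%)", 100 * truth.fat_vol_frac, fit.fat_content_pct, fit.ci95["fat_content_pct"]),
    ("water content (%)", 100 * truth.water_vol_frac, fit.water_content_pct, fit.ci95["water_content_pct"]),
    ("mu_s'(800) (cm^-1)", truth.scatter_amp_800, fit.scatter_amp_800, fit.ci95["scatter_amp_800"]),
]
for name, t, est, ci in rows:
    print(f"{name:<22}{t:>9.2f}{est:>9.2f}  +-{ci:.2f}")

print(
    "\nEach half-width comes from the residual-variance covariance at the "
    "optimum; the fat-fraction interval of ~2 pp is the signal-quality level "
    "at which a cancellous-to-cortical drop (26% -> ~0%) is unmistakable."
)
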