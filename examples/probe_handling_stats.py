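"""Probe-handling conditions: blood shifts, fat fraction does not.

Simulates the three handling conditions (low pressure, high pressure,
retracted), fits all spectra and reproduces the study's significance
pattern with Wilcoxon rank-sum tests at alpha = 0.01, plus the
confidence-interval quality range.
"""

import numpy as np

from drsfit import (
    FitOptions,
    HandlingCondition,
    InstrumentConfig,
    Zone,
    ZoneCompositionModel,
    add_instrument_noise,
    ci_range_summary,
    fit_spectrum,
    forward_reflectance,
    load_default_chromophores,
    sample_zone_composition,
    wilcoxon_rank_sum,
)

inst = InstrumentConfig()
chrom = load_default_chromophores()
model = ZoneCompositionModel()
rng = np.random.default_rng(5)

fits = {c: [] for c in HandlingCondition}
for condition in HandlingCondition:
    for _ in range(20):
        comp = sample_zone_composition(Zone.CANCELLOUS, condition, model, rng)
        spec = add_instrument_noise(forward_reflectance(comp, inst, chrom), inst, rng)
        fits[condition].append(fit_spectrum(spec, inst, chrom, FitOptions(n_starts=1)))

def values(condition, param):
    return [getattr(f, param) for f in fits[condition]]

lo, hi, re = HandlingCondition.LOW_PRESSURE, HandlingCondition.HIGH_PRESSURE, HandlingCondition.RETRACTED
pressure_blood = values(lo, "blood_content_pct") + values(hi, "blood_content_pct")
for name, a, b in [
    ("blood: retracted vs pressure", values(re, "blood_content_pct"), pressure_blood),
    ("blood: low vs high pressure", values(lo, "blood_content_pct"), values(hi, "blood_content_pct")),
    ("fat fraction: low vs high pressure", values(lo, "fat_fraction_pct"), values(hi, "fat_fraction_pct")),
    ("fat fraction: retracted vs low", values(re, "fat_fraction_pct"), values(lo, "fat_fraction_pct")),
]:
    t = wilcoxon_rank_sum(a, b)
    print(f"{name:<38} p = {t.p_value:.4f}  significant at 0.01: {t.significant}")

all_fits = [f for group in fits.values() for f in group if f.converged]
lo_ci, hi_ci = ci_range_summary(all_fits)
print(f"\nfat-fraction 95% CI half-widths: {lo_ci:.1f}-{hi_ci:.1f} pp across conditions")
print(
    "Retraction pools blood at the probe tip (blood up, fat fraction down); "
    "contact pressure shifts blood but leaves the fat fraction unchanged, and "
    "the CI range shows measurement quality is condition-independent."
)
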