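# drsfit

Diffuse reflectance spectroscopy (DRS) analysis for cortical-breach
detection during pedicle-screw placement.

During spinal-fusion surgery a probe (Jamshidi needle / optical K-wire) is
advanced through the vertebral pedicle. Cancellous bone is marrow-rich —
high fat fraction — while the cortical shell and everything beyond it are
not; a fiber-optic probe measuring diffuse reflectance at its tip can
therefore warn of an impending cortical breach as the **fat fraction**
Fat/(Fat+Water)×100 collapses. `drsfit` implements the full analysis chain
for this setting, for researchers working on optical surgical guidance:

- a physics-based forward model: four-chromophore absorption
  (Hb, HbO₂, fat, water) plus power-law scattering
  µs′(λ) = a·(λ/800)⁻ᵇ, propagated through the steady-state
  diffusion-dipole reflectance R(ρ) at the two-fiber separation
  ρ = 1.042 mm over 450–1600 nm;
- a bounded least-squares inverse fit recovering the composition with
  delta-method 95 % confidence intervals (blood content = 100·(Hb+HbO₂)/150 g/l,
  fat fraction, µs′(800));
- a synthetic-experiment generator reproducing the study conditions:
  insertions across tissue zones (cancellous / pre-cortical / cortical /
  breach), three probe-handling conditions (low pressure, high pressure,
  retracted), and a 70-min post-sacrifice perfusion-decay recording;
- the breach-detection pipeline (zone labelling, per-zone median[min–max]
  summaries, fat-fraction drop detector, 1200 nm spectral normalization);
- the study's statistical toolbox (Jarque–Bera, exact/approximate Wilcoxon
  rank-sum, OLS R², CI-range reporting) at α = 0.01.

The packaged chromophore curves are synthetic literature-style tables (see
`docs/methods.md` and `src/drsfit/data/provenance.yaml`); the package is
self-consistent but not a source of reference optical properties.

## Worked example

```python
from drsfit import (InstrumentConfig, TissueComposition, add_instrument_noise,
                    fit_spectrum, forward_reflectance, load_default_chromophores)

inst = InstrumentConfig()                 # 1.042 mm fibers, 2% relative noise
chrom = load_default_chromophores()
truth = TissueComposition(hb_gl=13.0, hbo2_gl=30.3,          # 28.9% blood
                          fat_vol_frac=0.251, water_vol_frac=0.699,  # 26.4% fat fraction
                          scatter_amp_800=15.9, scatter_slope=1.0)
spec = add_instrument_noise(forward_reflectance(truth, inst, chrom), inst, seed=7)
fit = fit_spectrum(spec, inst, chrom)
print(fit.blood_content_pct, fit.fat_fraction_pct, fit.ci95["fat_fraction_pct"])
```

Running `python examples/fit_single_spectrum.py` (the same computation with
a full table) prints:

```
converged: True (9 function evaluations)
parameter                 truth   fitted   95% CI
blood content (%)         28.87    28.86  +-0.03
fat fraction (%)          26.42    26.59  +-1.67
fat content (%)           25.10    25.31  +-2.12
water content (%)         69.90    69.89  +-0.23
mu_s'(800) (cm^-1)        15.90    15.94  +-0.09
```

The fitted fat fraction recovers the marrow truth to a fraction of its
~1.7 pp confidence half-width — the precision at which the cancellous→
cortical drop (≈26 % → ≈0 %) is an unmistakable breach warning. The other
`examples/` scripts walk through the forward model, insertion simulation,
breach detection, the perfusion-decay series and the probe-handling
statistics, each printing a short interpretation of its numbers.

A thin CLI mirrors the library:
`drsfit simulate|fit|label|detect|stats|run --help`.

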