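# Methods

`drsfit` models and analyzes two-fiber diffuse reflectance spectroscopy
(DRS) measurements for cortical-breach detection during pedicle-screw
placement. This note records the model, its assumptions, the tunable
parameters, and the design decisions taken where the problem was genuinely
open.

## Forward model

Tissue is described by four chromophores and a power-law scattering
spectrum:

- `hb_gl`, `hbo2_gl` — deoxy-/oxy-hemoglobin concentration (g/l),
- `fat_vol_frac`, `water_vol_frac` — volume fractions of lipid and water,
- `scatter_amp_800` — reduced scattering µs′ at 800 nm (cm⁻¹),
- `scatter_slope` — exponent *b* of µs′(λ) = a·(λ/800)⁻ᵇ.

Bulk absorption is the linear mixture
µa(λ) = c_Hb ε_Hb(λ) + c_HbO₂ ε_HbO₂(λ) + f_fat µa,fat(λ) + f_wat µa,wat(λ).

Reflectance at source–detector separation ρ uses the steady-state
diffusion-dipole (extrapolated-boundary) solution for a pencil beam: an
isotropic source at depth z₀ = 1/(µa+µs′) and its negative image at
z₀ + 2z_b, with z_b = 2AD, D = 1/(3(µa+µs′)), µ_eff = √(3µa(µa+µs′)):

R(ρ) = (1/4π) Σᵢ zᵢ (µ_eff + 1/rᵢ) exp(−µ_eff rᵢ)/rᵢ² ,  rᵢ = √(zᵢ² + ρ²).

The boundary constant A comes from the empirical Fresnel-mismatch
polynomial r_d = −1.440 n⁻² + 0.710 n⁻¹ + 0.668 + 0.0636 n with tissue
index n = 1.4, giving A ≈ 3.25. All transport arithmetic is in cm/cm⁻¹;
millimetres appear only at the API surface. The default fiber separation is
1.042 mm (the instrument's engineering value; a 1.024 mm variant circulates
in summaries of the same probe — the parameter is configurable).

Assumptions: semi-infinite homogeneous medium, calibrated reflectance in
(white/dark referencing is assumed done upstream), no fluorescence, and
diffusion validity. In the hemoglobin Q-bands of blood-rich tissue
µa ≫ µs′, where diffusion theory is a poor photon-transport approximation;
because the same expression serves as generator and fit model the package
remains self-consistent, but absolute visible-band reflectances should not
be read as transport-accurate.

## Chromophore tables

The packaged absorption curves (`drsfit/data/*_synthetic.csv`, 400–1700 nm,
2 nm) are **synthetic**: log-space PCHIP interpolants through hand-chosen
anchors reproducing the qualitative band structure of the real
chromophores (hemoglobin Soret/Q bands; lipid CH-overtones near 930, 1211,
1400 nm; water OH-overtones near 975, 1197, 1450 nm). Hemoglobin anchors
are molar extinctions converted to per-(g/l) with a molar mass of
64 500 g/mol. They are not reference optical-property data; see
`data/provenance.yaml`. Interpolation onto instrument grids is linear and
extrapolation outside 400–1700 nm is refused.

## Inverse fit

Six parameters are fitted per spectrum with bounded trust-region-reflective
least squares: (hb, hbo2, tw, φ, a, b) where tw = fat+water volume and φ is
the fat share, so fat = tw·φ and the clinical fat fraction is 100·φ. This
keeps the nonnegativity and total-volume constraints inside a box and makes
the breach statistic a fitted parameter. DRS "content" estimates can exceed
a strict volume budget (fat 41.5 % alongside water ≈ 75 % is a typical
marrow reading), so tw is capped at 1.5 rather than 1.0.

- Residuals default to log space, r = log R_model − log R_meas: under
  multiplicative (relative) instrument noise these are homoscedastic, which
  both stabilizes the fit across the ~4 decades of spectral dynamic range
  and makes the residual-variance covariance estimate, and hence the
  confidence intervals, calibrated. Plain reflectance residuals with
  per-band mean scaling are available as `weighting="band_scaled"`.
- Multistart: lipid-rich, blood-rich and water-rich initializations
  (best objective wins). Noisy single-spectrum fits are well behaved with
  one start; the default is 3.
- The analytic Jacobian is derived from the dipole formula (chain rule over
  µa and µs′) and is verified against finite differences in the test suite.
- `converged` is False whenever the selected solution stopped on the
  evaluation budget instead of a tolerance.

Derived physiology: blood content = 100·(hb+hbo2)/150 g/l (may exceed
100 %), fat fraction = 100·fat/(fat+water) (0 % with a flag when
fat+water = 0).

### Confidence intervals

Parameter covariance is s²(JᵀJ)⁻¹ at the optimum with
s² = ‖r‖²/(n−p); derived quantities get first-order (delta-method)
intervals, and half-widths use the Gaussian 95 % quantile 1.959964.
Rank-deficient Jacobians yield infinite half-widths along unidentifiable
directions rather than an exception. Monte-Carlo calibration at the default
noise gives empirical coverage of ~93–95 % for the fat fraction — the mild
undercoverage expected of first-order intervals on a nonlinear model — and
the delta-method half-width agrees with a parametric bootstrap to well
within 20 %.

## Instrument and noise model

Two spectrometers (visible 450–1100 nm, NIR 900–1600 nm, 1 nm default
step) are stitched into one 450–1600 nm spectrum with a single switch at
1000 nm: visible samples below, NIR above. Measurement noise is
multiplicative Gaussian with per-band relative σ plus an optional additive
floor; negatives are clipped (and counted). The default relative σ of 2 %
was calibrated so that single-spectrum fat-fraction CI half-widths fall in
the experimentally observed 1.5–3.6 pp range; at this level they span
roughly 1.2–2.6 pp across probe-handling conditions.

## Synthetic experiments

The generator reproduces the study conditions, not any deposited data.

Per-zone blood content and fat fraction are drawn from **two-piece uniform**
distributions (median, min, max): a fair coin selects the lower or upper
limb, so the population median equals the configured median exactly while
respecting the truncation. Defaults are the reported per-zone statistics:

| zone       | blood % (med [min–max]) | fat fraction % (med [min–max]) |
|------------|-------------------------|--------------------------------|
| cancellous | 28.9 [21.4–51.3]        | 26.4 [11.9–50.0]               |
| pre-cortical | 28.8 [21.0–100]       | 5.3 [0–17.3]                   |
| cortical   | 19.4 [18.9–20.5]        | 0.0 [0–0.1]                    |
| breach     | 48.9 [48.1–49.6]        | 11.2 [10.9–11.4]               |

The wide upper limb of the pre-cortical blood distribution supplies the
observed heavy right tail. Scattering amplitude is uniform on
14.6–17.2 cm⁻¹ and the slope uniform on 0.8–1.2. Two free choices close
the map from (blood %, fat fraction %) to a full composition: combined
fat+water volume 0.95 and hemoglobin oxygen saturation 0.70 — mid-range
values for perfused marrow; neither is identifiable from the summary
statistics being emulated.

Probe handling is modelled as composition change: high pressure scales the
blood distribution by 0.8 (pressure expels blood), retraction scales blood
by 1.6 and fat fraction by 0.6 (a blood pool fills the vacated cavity).
Each position yields 10 spectra per condition; the default experiment is 6
insertions with a {2,1,1,2,2,1} position split (9 positions, 270 spectra)
whose depth templates cover all four zones.

The sacrifice series interpolates blood 18.9→8.1 %, fat content
41.5→37.7 % and fat fraction 35.5→32.3 % over 70 min with an
endpoint-matched exponential, decay(t) = (e^(−t/τ)−e^(−T/τ))/(1−e^(−T/τ)),
τ = T/3 by default (the decay shape is not constrained by the summary
endpoints; it is pluggable). 2020 samples by default.

Depths are signed distances to the inner cortical wall (negative inside);
zone geometry is cancellous (−∞,−3), pre-cortical [−3,0), cortical
[0,t_c), breach [t_c, t_c+3] with configurable cortical thickness t_c
(default 1 mm); beyond the breach band the labeller raises.

## Breach detection

Per-position fitted fat fraction is compared against a running median
baseline of positions called safe so far (the first position anchors it —
insertions start in cancellous bone). `impending_breach` requires the fat
fraction below an absolute threshold (default 10 pp) *and* below
(1−0.5)× baseline; a simultaneous blood surge above 40 % instead flags
`retracted_suspect`, or `breached` when an impending call already occurred
earlier in the trajectory. High blood + low fat fraction is genuinely
ambiguous between retraction and a completed breach; the sequence context
is the only discriminator used. Thresholds were fixed on the synthetic
generator; on all-cancellous trajectories at default noise the false
impending-breach rate is below 1 % of positions.

## Statistics

- Jarque–Bera with classical biased moment estimators,
  JB = n/6·(S² + K²/4), p from χ²(2); constant samples and n < 8 are
  errors.
- Wilcoxon rank-sum: exact enumeration of all C(n, n_x) group assignments
  (midranks for ties) when n_x+n_y ≤ 12, otherwise a tie-corrected normal
  approximation with continuity correction. The approximation agrees with
  the exact path to <0.02 in p for tie-free samples near the crossover
  size; heavy ties at very small n can produce discrepancies up to ~0.1
  near p = 1, which the exact path avoids.
- R² is the squared Pearson correlation (equal to OLS R² with intercept).
- `ci_range_summary` reports the min/max CI half-width over a set of fits,
  the study's per-measurement signal-quality summary.
- All tests are two-sided with α = 0.01 by default.

## Problem sizes

Monte-Carlo checks use: 2000 replicates for CI coverage, 300–1000
replicates per zone-median recovery, a 200-sample sacrifice series (last 10
fitted), 50 noiseless round-trip compositions, and 100 random triples for
the formula oracle. These sizes put the Monte-Carlo error comfortably
inside each tolerance while keeping the default suite quick on one CPU.

## Limitations

- The chromophore tables are synthetic stand-ins; absolute fitted
  concentrations are only meaningful within this package's closed loop.
  Swapping in digitized reference spectra is a drop-in replacement
  (same CSV schema).
- Generator and fitter share one forward model, so recovery tests
  demonstrate the inverse machinery and its statistics, not robustness to
  model mismatch (real probes add fiber-coupling drift, inner-filter
  effects, inhomogeneous sampling volumes).
- The diffusion approximation degrades where µa ≳ µs′ (visible band of
  blood-rich tissue).
- Probe-handling effects are composition changes only; no biomechanics.
- Oxygen saturation is fixed, not fitted or decayed, and no additional
  absorbers (beta-carotene, met-Hb, collagen) are modelled; the chromophore
  set is the natural extension point.
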