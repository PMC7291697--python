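schema: drsfit-chromophore-provenance-1
status: synthetic
note: >
  These absorption tables are synthetic stand-ins for digitized literature
  chromophore spectra.  Each curve is a PCHIP interpolant (in log space)
  through hand-picked anchor points chosen to reproduce the qualitative band
  structure of the real chromophores: oxy-/deoxy-hemoglobin Soret and Q bands
  in the visible, the lipid CH-overtone bands near 930, 1211 and 1400 nm, and
  the water OH-overtone bands near 975, 1197 and 1450 nm.  They are generated
  by scripts/make_chromophore_tables.py and are self-consistent within this
  package (simulator and fitter share them); they must not be used as
  reference optical-property data.
support_nm: [400, 1700]
step_nm: 2
units:
  hb: cm^-1 per g/l
  hbo2: cm^-1 per g/l
  fat: cm^-1 (pure substance, weight by volume fraction)
  water: cm^-1 (pure substance, weight by volume fraction)
hemoglobin_molar_mass_g_per_mol: 64500
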