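"""Breach detection along an insertion crossing the cortical boundary.

Simulates a trajectory from cancellous bone through the pre-cortical zone
into the cortex, fits each position's spectra, and runs the fat-fraction
breach detector.
"""

import numpy as np

from drsfit import (
    InsertionGeometry,
    InstrumentConfig,
    ZoneCompositionModel,
    detect_breach_values,
    fit_spectrum,
    generate_insertion,
    load_default_chromophores,
)
from drsfit.synthetic import HandlingCondition

inst = InstrumentConfig()
chrom = load_default_chromophores()
model = ZoneCompositionModel()

geometry = InsertionGeometry((-8.0, -5.0, -1.5, 0.5))  # two cancellous, PCZ, cortical
traj = generate_insertion(
    model, geometry, inst, chrom, seed=11,
    conditions=[HandlingCondition.LOW_PRESSURE], n_per_condition=5,
)

ff_pos, blood_pos = [], []
for depth in traj.position_depths:
    fits = [
        fit_spectrum(m.spectrum, inst, chrom)
        for m in traj.measurements
        if m.depth_mm == depth
    ]
    ff_pos.append(float(np.median([f.fat_fraction_pct for f in fits])))
    blood_pos.append(float(np.median([f.blood_content_pct for f in fits])))

print(f"{'depth (mm)':>11}{'fat frac (%)':>14}{'blood (%)':>11}   call")
for depth, call in zip(traj.position_depths, detect_breach_values(ff_pos, blood_pos)):
    print(f"{depth:>+11.1f}{call.fat_fraction_pct:>14.1f}{call.blood_content_pct:>11.1f}   {call.call.value}")

print(
    "\nThe fat fraction collapses as the probe leaves marrow-rich cancellous "
    "bone; a drop below 10 pp that more than halves the cancellous baseline "
    "raises impending_breach before the cortex is perforated."
)
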