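"""Regenerate the synthetic chromophore absorption tables shipped in drsfit/data.

The packaged curves are *synthetic*: smooth monotone (PCHIP-in-log-space)
interpolants through hand-picked anchor points that reproduce the qualitative
band structure of published tissue-chromophore spectra — hemoglobin Soret/Q
bands in the visible, the lipid CH-overtone bands near 930/1211/1400 nm and
the water OH-overtone bands near 975/1197/1450 nm.  They are internally
consistent (the same tables drive both the simulator and the fitter) but are
not digitizations of any published dataset.

Units:
  hb / hbo2  : specific absorption, cm^-1 per (g/l) of hemoglobin
  fat / water: absorption of the pure substance, cm^-1 (volume-fraction weight)

Run from the repository root:  python scripts/make_chromophore_tables.py
"""

from __future__ import annotations

import pathlib

import numpy as np
from scipy.interpolate import PchipInterpolator

OUT = pathlib.Path(__file__).resolve().parents[1] / "src" / "drsfit" / "data"

GRID = np.arange(400.0, 1701.0, 2.0)

# molar mass of hemoglobin (g/mol) used to convert molar extinction to per-g/l
HB_MOLAR_MASS = 64500.0
LN10 = np.log(10.0)

# (wavelength_nm, molar extinction M^-1 cm^-1)
HBO2_EPS = [
    (400, 220000), (420, 450000), (450, 62000), (480, 27000), (500, 20000),
    (520, 27000), (542, 57000), (560, 9500), (577, 56000), (590, 15000),
    (600, 3200), (620, 1000), (650, 420), (700, 290), (750, 518),
    (800, 816), (850, 1058), (900, 1198), (950, 1200), (1000, 1080),
    (1100, 900), (1200, 700), (1300, 600), (1400, 550), (1500, 500),
    (1600, 470), (1700, 450),
]
HB_EPS = [
    (400, 250000), (430, 530000), (450, 110000), (480, 27000), (500, 20200),
    (520, 24000), (540, 47000), (555, 53412), (577, 39000), (600, 14600),
    (630, 5000), (660, 3227), (700, 1794), (730, 1500), (760, 1670),
    (800, 820), (850, 690), (900, 730), (950, 550), (1000, 430),
    (1100, 370), (1200, 320), (1300, 280), (1400, 250), (1500, 230),
    (1600, 215), (1700, 200),
]
# (wavelength_nm, mu_a cm^-1 of the pure substance)
WATER_MUA = [
    (400, 0.00058), (450, 0.00030), (500, 0.00026), (550, 0.00048),
    (600, 0.0023), (650, 0.0032), (700, 0.0060), (730, 0.019),
    (760, 0.026), (800, 0.020), (850, 0.043), (900, 0.068),
    (940, 0.27), (975, 0.50), (1000, 0.36), (1050, 0.13),
    (1100, 0.17), (1150, 0.70), (1197, 1.05), (1250, 0.88),
    (1300, 1.15), (1350, 2.80), (1400, 13.0), (1450, 29.0),
    (1500, 22.0), (1550, 13.0), (1600, 6.7), (1650, 5.2), (1700, 6.0),
]
FAT_MUA = [
    (400, 0.10), (450, 0.05), (500, 0.02), (550, 0.010), (600, 0.006),
    (650, 0.005), (700, 0.005), (760, 0.007), (800, 0.008), (850, 0.012),
    (900, 0.06), (930, 0.30), (960, 0.10), (1000, 0.08), (1040, 0.22),
    (1080, 0.10), (1150, 0.40), (1211, 1.40), (1250, 0.55), (1300, 0.32),
    (1350, 0.50), (1395, 1.05), (1415, 1.25), (1450, 0.85), (1500, 0.50),
    (1550, 0.48), (1600, 0.45), (1650, 0.80), (1700, 2.20),
]


def _interp_log(anchors: list[tuple[float, float]]) -> np.ndarray:
    wl = np.array([a[0] for a in anchors], dtype=float)
    val = np.array([a[1] for a in anchors], dtype=float)
    f = PchipInterpolator(wl, np.log(val))
    return np.exp(f(GRID))


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    curves = {
        "hbo2": _interp_log(HBO2_EPS) * LN10 / HB_MOLAR_MASS,
        "hb": _interp_log(HB_EPS) * LN10 / HB_MOLAR_MASS,
        "water": _interp_log(WATER_MUA),
        "fat": _interp_log(FAT_MUA),
    }
    for name, mua in curves.items():
        path = OUT / f"{name}_synthetic.csv"
        with open(path, "w") as fh:
            fh.write("# synthetic chromophore absorption table, see provenance.yaml\n")
            fh.write("wavelength_nm,specific_absorption\n")
            for w, v in zip(GRID, mua):
                fh.write(f"{w:.1f},{v:.6e}\n")
        print(f"wrote {path} ({path.stat().st_size} bytes)")


if __name__ == "__main__":
    main()
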