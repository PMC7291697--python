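"""Loading of the packaged chromophore absorption tables.

The tables under ``drsfit/data`` are synthetic literature-style curves (see
``data/provenance.yaml``): smooth interpolants with the qualitative band
structure of hemoglobin, fat and water, shared by the simulator and the
fitter so the package is self-consistent.
"""

from __future__ import annotations

import functools
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .model import CHROMOPHORES, Band, ChromophoreSet, WavelengthGrid

_FILES = {name: f"{name}_synthetic.csv" for name in CHROMOPHORES}


def _data_path(filename: str):
    return resources.files("drsfit").joinpath("data").joinpath(filename)


@functools.lru_cache(maxsize=1)
def load_default_chromophores() -> ChromophoreSet:
    """Read the packaged tables (400–1700 nm, 2 nm step) into a ChromophoreSet."""
    curves: dict[str, np.ndarray] = {}
    grid_wl: np.ndarray | None = None
    for name, fname in _FILES.items():
        with resources.as_file(_data_path(fname)) as path:
            tab = pd.read_csv(path, comment="#")
        if list(tab.columns) != ["wavelength_nm", "specific_absorption"]:
            raise ValueError(f"unexpected columns in {fname}: {list(tab.columns)}")
        wl = tab["wavelength_nm"].to_numpy(dtype=float)
        if grid_wl is None:
            grid_wl = wl
        elif not np.array_equal(grid_wl, wl):
            raise ValueError("chromophore tables are not on a common grid")
        curves[name] = tab["specific_absorption"].to_numpy(dtype=float)
    with resources.as_file(_data_path("provenance.yaml")) as path:
        provenance = yaml.safe_load(path.read_text())
    grid = WavelengthGrid(grid_wl, Band.COMBINED)
    return ChromophoreSet(grid, curves, provenance)
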