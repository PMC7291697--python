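"""File formats, run configuration and the end-to-end pipeline runner.

Spectrum files are plain CSV with a ``wavelength_nm,reflectance`` header
preceded by ``# key: value`` metadata comment lines.  Simulated datasets are
directories of spectrum CSVs with a ``manifest.json`` carrying geometry,
seeds and ground truths; the sacrifice series is one long CSV with a
``time_s`` column.  Run configuration round-trips through YAML.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .chromophores import load_default_chromophores
from .fit import FitOptions, FitResult, fit_spectrum
from .model import Band, InstrumentConfig, Spectrum, WavelengthGrid
from .pipeline import (
    BreachConfig,
    detect_breach_values,
    summarize_zones,
)
from .stats import DEFAULT_ALPHA, ci_range_summary, wilcoxon_rank_sum
from .synthetic import (
    DEFAULT_POSITION_SPLIT,
    HandlingCondition,
    InsertionTrajectory,
    ProbeMeasurement,
    ZoneCompositionModel,
    generate_dataset,
)

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "stitch_spectra",
    "write_insertion_dataset",
    "write_sacrifice_csv",
    "RunConfig",
    "run_pipeline",
]

_HEADER = "wavelength_nm,reflectance"


def write_spectrum(path: str | pathlib.Path, spec: Spectrum) -> None:
    """Write a spectrum CSV: ``# key: value`` metadata lines, then the data."""
    path = pathlib.Path(path)
    with open(path, "w") as fh:
        fh.write(f"# band: {spec.grid.band.value}\n")
        for key, value in spec.meta.items():
            fh.write(f"# {key}: {value}\n")
        fh.write(_HEADER + "\n")
        for wl, r in zip(spec.grid.wavelengths_nm, spec.reflectance):
            fh.write(f"{wl:.4f},{r:.12e}\n")


def read_spectrum(path: str | pathlib.Path) -> Spectrum:
    """Read a spectrum CSV written by :func:`write_spectrum`.

    Rejects files without the expected header or with non-monotone
    wavelengths.  Metadata values are parsed with YAML scalars.
    """
    path = pathlib.Path(path)
    meta: dict[str, object] = {}
    header_line = None
    rows_start = 0
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        s = line.strip()
        if s.startswith("#"):
            body = s.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = yaml.safe_load(value.strip())
            continue
        header_line = s
        rows_start = i + 1
        break
    if header_line != _HEADER:
        raise ValueError(f"missing or malformed header in {path}: expected {_HEADER!r}")
    data = np.loadtxt(lines[rows_start:], delimiter=",", ndmin=2)
    band = Band(meta.pop("band", "combined"))
    grid = WavelengthGrid(data[:, 0], band)  # raises on non-monotone wavelengths
    return Spectrum(grid, data[:, 1], meta)


def stitch_spectra(visible: Spectrum, nir: Spectrum, stitch_nm: float = 1000.0) -> Spectrum:
    """Combine the two spectrometer bands into one spectrum: visible samples
    below the stitch point, NIR samples at and above it."""
    wl_v = visible.grid.wavelengths_nm
    wl_n = nir.grid.wavelengths_nm
    keep_v = wl_v < stitch_nm
    keep_n = wl_n >= stitch_nm
    if not keep_v.any() or not keep_n.any():
        raise ValueError("bands do not bracket the stitch point")
    wl = np.concatenate([wl_v[keep_v], wl_n[keep_n]])
    refl = np.concatenate([visible.reflectance[keep_v], nir.reflectance[keep_n]])
    meta = {**dict(nir.meta), **dict(visible.meta), "stitch_nm": stitch_nm}
    return Spectrum(WavelengthGrid(wl, Band.COMBINED), refl, meta)


def _comp_dict(comp) -> dict:
    return {
        "hb_gl": comp.hb_gl,
        "hbo2_gl": comp.hbo2_gl,
        "fat_vol_frac": comp.fat_vol_frac,
        "water_vol_frac": comp.water_vol_frac,
        "scatter_amp_800": comp.scatter_amp_800,
        "scatter_slope": comp.scatter_slope,
    }


def write_insertion_dataset(traj: InsertionTrajectory, outdir: str | pathlib.Path) -> pathlib.Path:
    """One directory per insertion: per-measurement spectrum CSVs plus a
    manifest.json with geometry and ground truths."""
    outdir = pathlib.Path(outdir) / traj.insertion_id
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, m in enumerate(traj.measurements):
        fname = f"m{i:03d}.csv"
        write_spectrum(outdir / fname, m.spectrum)
        entries.append(
            {
                "file": fname,
                "depth_mm": m.depth_mm,
                "zone": m.zone_true.value,
                "condition": m.condition.value,
                "time_s": m.time_s,
                "truth": _comp_dict(m.truth),
            }
        )
    manifest = {
        "insertion_id": traj.insertion_id,
        "cortical_boundary_depth_mm": traj.cortical_boundary_depth_mm,
        "measurements": entries,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return outdir


def write_sacrifice_csv(measurements: tuple[ProbeMeasurement, ...], path: str | pathlib.Path) -> None:
    """Long-format CSV of the sacrifice recording: time_s, wavelength_nm, reflectance."""
    frames = []
    for m in measurements:
        frames.append(
            pd.DataFrame(
                {
                    "time_s": m.time_s,
                    "wavelength_nm": m.spectrum.grid.wavelengths_nm,
                    "reflectance": m.spectrum.reflectance,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run configuration


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one end-to-end pipeline run."""

    schema_version: int = 1
    seed: int = 0
    instrument: InstrumentConfig = field(default_factory=InstrumentConfig)
    zone_model: ZoneCompositionModel = field(default_factory=ZoneCompositionModel)
    fit_options: FitOptions = field(default_factory=FitOptions)
    breach: BreachConfig = field(default_factory=BreachConfig)
    positions_per_insertion: tuple[int, ...] = DEFAULT_POSITION_SPLIT
    n_per_condition: int = 10
    alpha: float = DEFAULT_ALPHA

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        zm = d["zone_model"]
        for key in ("blood", "fat_fraction"):
            zm[key] = {zone.value: stat for zone, stat in zm[key].items()}
        return d

    def to_yaml(self, path: str | pathlib.Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        from .synthetic import Zone, ZoneStat

        d = dict(d)
        if "instrument" in d:
            d["instrument"] = InstrumentConfig(**d["instrument"])
        if "zone_model" in d:
            zm = dict(d["zone_model"])
            for key in ("blood", "fat_fraction"):
                zm[key] = {Zone(z): ZoneStat(**s) if isinstance(s, dict) else ZoneStat(*s)
                           for z, s in zm[key].items()}
            for key in ("scatter_amp_range", "scatter_slope_range"):
                zm[key] = tuple(zm[key])
            d["zone_model"] = ZoneCompositionModel(**zm)
        if "fit_options" in d:
            d["fit_options"] = FitOptions(**d["fit_options"])
        if "breach" in d:
            d["breach"] = BreachConfig(**d["breach"])
        if "positions_per_insertion" in d:
            d["positions_per_insertion"] = tuple(d["positions_per_insertion"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | pathlib.Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _fit_measurements(measurements, config: RunConfig, chrom) -> list[FitResult]:
    return [
        fit_spectrum(m.spectrum, config.instrument, chrom, config.fit_options)
        for m in measurements
    ]


def run_pipeline(config: RunConfig, out_dir: str | pathlib.Path | None = None) -> dict:
    """Simulate, fit, label, summarize and test: the full analysis chain.

    Returns (and optionally writes as report.json) a fully deterministic
    report keyed by the config seed: per-zone summaries of the low-pressure
    fits, probe-handling condition comparisons, fat-fraction CI-quality
    ranges and per-insertion breach calls.
    """
    chrom = load_default_chromophores()
    report: dict = {
        "schema_version": config.schema_version,
        "seed": config.seed,
        "n_insertions": len(config.positions_per_insertion),
    }
    if not config.positions_per_insertion:
        warnings.warn("config defines zero insertions: empty report", RuntimeWarning)
        report["empty"] = True
        return report

    trajectories = generate_dataset(
        config.zone_model,
        config.instrument,
        chrom,
        seed=config.seed,
        positions_per_insertion=config.positions_per_insertion,
        n_per_condition=config.n_per_condition,
    )

    all_fits: list[FitResult] = []
    all_meas: list[ProbeMeasurement] = []
    breach_calls = {}
    for traj in trajectories:
        fits = _fit_measurements(traj.measurements, config, chrom)
        all_fits.extend(fits)
        all_meas.extend(traj.measurements)
        # per-position medians over the pressure conditions drive the detector
        ff_pos, blood_pos = [], []
        for depth in traj.position_depths:
            sel = [
                f
                for f, m in zip(fits, traj.measurements)
                if m.depth_mm == depth and m.condition != HandlingCondition.RETRACTED
            ]
            ff_pos.append(float(np.median([f.fat_fraction_pct for f in sel])))
            blood_pos.append(float(np.median([f.blood_content_pct for f in sel])))
        if len(ff_pos) >= 2:
            calls = detect_breach_values(ff_pos, blood_pos, config.breach)
            breach_calls[traj.insertion_id] = [
                {"index": c.index, "call": c.call.value, "drop_pp": c.drop_pp} for c in calls
            ]

    low = [f for f, m in zip(all_fits, all_meas) if m.condition == HandlingCondition.LOW_PRESSURE]
    low_zones = [m.zone_true for m in all_meas if m.condition == HandlingCondition.LOW_PRESSURE]
    summaries = summarize_zones(low, low_zones)
    report["zone_summaries"] = [
        {"zone": s.zone.value, "n": s.n, **{k: dict(zip(("median", "min", "max"), v)) for k, v in s.stats.items()}}
        for s in summaries
    ]

    def pool(condition: HandlingCondition, param: str) -> list[float]:
        return [
            getattr(f, param)
            for f, m in zip(all_fits, all_meas)
            if m.condition == condition
        ]

    comparisons = {}
    lo_b, hi_b, re_b = (pool(c, "blood_content_pct") for c in HandlingCondition)
    lo_f, hi_f = (pool(c, "fat_fraction_pct") for c in (HandlingCondition.LOW_PRESSURE, HandlingCondition.HIGH_PRESSURE))
    re_f = pool(HandlingCondition.RETRACTED, "fat_fraction_pct")
    for name, (a, b) in {
        "blood_retracted_vs_low": (re_b, lo_b),
        "blood_retracted_vs_high": (re_b, hi_b),
        "blood_low_vs_high": (lo_b, hi_b),
        "fat_fraction_low_vs_high": (lo_f, hi_f),
        "fat_fraction_retracted_vs_low": (re_f, lo_f),
    }.items():
        if min(len(a), len(b)) < 3:
            comparisons[name] = {"skipped": "needs n >= 3 per group"}
            continue
        t = wilcoxon_rank_sum(a, b, alpha=config.alpha)
        comparisons[name] = {
            "statistic": t.statistic,
            "p_value": t.p_value,
            "significant": t.significant,
            "n": [t.n_x, t.n_y],
        }
    report["condition_comparisons"] = comparisons

    converged = [f for f in all_fits if f.converged]
    report["fat_fraction_ci_range_pp"] = list(ci_range_summary(converged))
    report["n_spectra"] = len(all_fits)
    report["n_converged"] = len(converged)
    report["breach_calls"] = breach_calls

    if out_dir is not None:
        out_dir = pathlib.Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
    return report
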