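"""In-silico replicas of the three probe experiments.

Generates ground-truthed spectra datasets for
  * stepwise insertions across tissue zones (cancellous / pre-cortical /
    cortical / breach) with three probe-handling conditions per position,
  * the continuous post-sacrifice recording in the vertebral body center,
where every measurement carries its generating TissueComposition, so fitted
parameters can be scored against truth.

Per-zone blood content and fat fraction are drawn from two-piece uniform
distributions parameterized by (median, min, max): a fair coin picks the
lower or upper limb, so the population median equals the configured median
exactly while the min/max truncation is respected.  Probe-handling effects
are modelled as composition changes — retraction mixes a blood pool into the
probed volume (blood up, fat fraction down), high contact pressure expels
blood relative to low pressure.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .fit import BLOOD_REFERENCE_GL
from .model import (
    ChromophoreSet,
    InstrumentConfig,
    Spectrum,
    TissueComposition,
    add_instrument_noise,
    forward_reflectance,
)

__all__ = [
    "Zone",
    "HandlingCondition",
    "ZoneStat",
    "ZoneCompositionModel",
    "InsertionGeometry",
    "ProbeMeasurement",
    "InsertionTrajectory",
    "SacrificeConfig",
    "sample_zone_composition",
    "generate_insertion",
    "generate_dataset",
    "generate_sacrifice_series",
    "DEFAULT_POSITION_SPLIT",
]


class Zone(str, enum.Enum):
    CANCELLOUS = "cancellous"
    PCZ = "pcz"
    CORTICAL = "cortical"
    BREACH = "breach"


class HandlingCondition(str, enum.Enum):
    LOW_PRESSURE = "low_pressure"    # 1.2 +/- 0.3 N/mm^2 axial pressure
    HIGH_PRESSURE = "high_pressure"  # 6.1 +/- 0.5 N/mm^2
    RETRACTED = "retracted"          # probe pulled back 1-2 mm


@dataclass(frozen=True)
class ZoneStat:
    """(median, min, max) of one parameter in one zone."""

    median: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if not self.min <= self.median <= self.max:
            raise ValueError("require min <= median <= max")

    def scale(self, factor: float, lo: float = 0.0, hi: float = 100.0) -> "ZoneStat":
        vals = sorted(np.clip([v * factor for v in (self.min, self.median, self.max)], lo, hi))
        return ZoneStat(median=vals[1], min=vals[0], max=vals[2])


def _sample_two_piece(rng: np.random.Generator, stat: ZoneStat) -> float:
    """Two-piece uniform draw whose population median is stat.median."""
    if rng.uniform() < 0.5:
        return stat.min + (stat.median - stat.min) * rng.uniform()
    return stat.median + (stat.max - stat.median) * rng.uniform()


@dataclass(frozen=True)
class ZoneCompositionModel:
    """Per-zone composition distributions plus probe-handling modifiers.

    Blood content and fat fraction are in percent; scattering amplitude in
    cm^-1.  ``fat_water_total`` is the combined fat+water volume fraction of
    the probed volume, and ``oxygen_saturation`` splits total hemoglobin into
    HbO2 and Hb.
    """

    blood: Mapping[Zone, ZoneStat] = field(
        default_factory=lambda: {
            Zone.CANCELLOUS: ZoneStat(28.9, 21.4, 51.3),
            Zone.PCZ: ZoneStat(28.8, 21.0, 100.0),
            Zone.CORTICAL: ZoneStat(19.4, 18.9, 20.5),
            Zone.BREACH: ZoneStat(48.9, 48.1, 49.6),
        }
    )
    fat_fraction: Mapping[Zone, ZoneStat] = field(
        default_factory=lambda: {
            Zone.CANCELLOUS: ZoneStat(26.4, 11.9, 50.0),
            Zone.PCZ: ZoneStat(5.3, 0.0, 17.3),
            Zone.CORTICAL: ZoneStat(0.0, 0.0, 0.1),
            Zone.BREACH: ZoneStat(11.2, 10.9, 11.4),
        }
    )
    scatter_amp_range: tuple[float, float] = (14.6, 17.2)
    scatter_slope_range: tuple[float, float] = (0.8, 1.2)
    fat_water_total: float = 0.95
    oxygen_saturation: float = 0.7
    high_pressure_blood_scale: float = 0.8
    retracted_blood_scale: float = 1.6
    retracted_fat_fraction_scale: float = 0.6

    def condition_stats(self, zone: Zone, condition: HandlingCondition) -> tuple[ZoneStat, ZoneStat]:
        """(blood, fat-fraction) distributions for a zone under a handling condition."""
        if zone not in self.blood:
            raise ValueError(f"unknown zone: {zone!r}")
        blood = self.blood[zone]
        ff = self.fat_fraction[zone]
        if condition is HandlingCondition.HIGH_PRESSURE:
            blood = blood.scale(self.high_pressure_blood_scale)
        elif condition is HandlingCondition.RETRACTED:
            blood = blood.scale(self.retracted_blood_scale)
            ff = ff.scale(self.retracted_fat_fraction_scale)
        return blood, ff

    def composition_from(self, blood_pct: float, fat_fraction_pct: float,
                         scatter_amp: float, scatter_slope: float) -> TissueComposition:
        thb = BLOOD_REFERENCE_GL * blood_pct / 100.0
        fat = self.fat_water_total * fat_fraction_pct / 100.0
        return TissueComposition(
            hb_gl=(1.0 - self.oxygen_saturation) * thb,
            hbo2_gl=self.oxygen_saturation * thb,
            fat_vol_frac=fat,
            water_vol_frac=self.fat_water_total - fat,
            scatter_amp_800=scatter_amp,
            scatter_slope=scatter_slope,
        )


def sample_zone_composition(
    zone: Zone,
    condition: HandlingCondition,
    model: ZoneCompositionModel,
    seed: int | np.random.Generator,
) -> TissueComposition:
    """Draw one ground-truth composition for a zone under a handling condition."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    blood_stat, ff_stat = model.condition_stats(zone, condition)
    blood = _sample_two_piece(rng, blood_stat)
    ff = _sample_two_piece(rng, ff_stat)
    amp = rng.uniform(*model.scatter_amp_range)
    slope = rng.uniform(*model.scatter_slope_range)
    return model.composition_from(blood, ff, amp, slope)


@dataclass(frozen=True)
class InsertionGeometry:
    """Measurement depths of one insertion, relative to the cortical boundary.

    ``position_depths_mm`` are signed distances to the inner cortical wall:
    negative inside cancellous bone, positive toward/beyond the cortex.  They
    must be nondecreasing (the probe only advances between positions).
    """

    position_depths_mm: tuple[float, ...] = (-8.0, -4.0)
    cortical_boundary_depth_mm: float = 30.0
    cortical_thickness_mm: float = 1.0

    def __post_init__(self) -> None:
        d = np.asarray(self.position_depths_mm, float)
        if d.size == 0:
            raise ValueError("geometry needs at least one measurement position")
        if np.any(np.diff(d) < 0):
            raise ValueError("position depths must be nondecreasing along the insertion")

    @staticmethod
    def default_depths(n_positions: int) -> tuple[float, ...]:
        standard = (-8.0, -4.0, -1.5, 0.5, 2.0)
        if not 1 <= n_positions <= len(standard):
            raise ValueError(f"n_positions must be in [1, {len(standard)}]")
        return standard[:n_positions]


@dataclass(frozen=True)
class ProbeMeasurement:
    spectrum: Spectrum
    depth_mm: float  # signed distance to the cortical boundary (negative inside)
    zone_true: Zone
    condition: HandlingCondition
    time_s: float
    truth: TissueComposition


@dataclass(frozen=True)
class InsertionTrajectory:
    measurements: tuple[ProbeMeasurement, ...]
    cortical_boundary_depth_mm: float
    insertion_id: str

    def __post_init__(self) -> None:
        depths = [m.depth_mm for m in self.measurements]
        if np.any(np.diff(depths) < 0):
            raise ValueError("measurement depths must be nondecreasing")

    @property
    def position_depths(self) -> tuple[float, ...]:
        seen: list[float] = []
        for m in self.measurements:
            if not seen or m.depth_mm != seen[-1]:
                seen.append(m.depth_mm)
        return tuple(seen)


#: positions per insertion splitting 9 positions over 6 insertions, so the
#: default dataset holds 9 x 3 x 10 = 270 spectra
DEFAULT_POSITION_SPLIT = (2, 1, 1, 2, 2, 1)

#: per-insertion depth templates matching DEFAULT_POSITION_SPLIT; together the
#: nine positions cover all four zones (cancellous, pre-cortical, cortical,
#: breach) the way a mixed set of safe and breaching insertions would
_DEPTH_TEMPLATES = (
    (-8.0, -1.5),
    (-8.0,),
    (-1.5,),
    (-8.0, 0.5),
    (-5.0, 1.5),
    (1.5,),
)


def default_insertion_depths(index: int, n_positions: int) -> tuple[float, ...]:
    """Depth template of insertion ``index``; falls back to the generic
    monotone depth ladder when the requested position count differs."""
    template = _DEPTH_TEMPLATES[index % len(_DEPTH_TEMPLATES)]
    if len(template) == n_positions:
        return template
    return InsertionGeometry.default_depths(n_positions)


def generate_insertion(
    model: ZoneCompositionModel,
    geometry: InsertionGeometry,
    inst: InstrumentConfig,
    chrom: ChromophoreSet,
    seed: int,
    conditions: Sequence[HandlingCondition] = tuple(HandlingCondition),
    n_per_condition: int = 10,
    insertion_id: str = "insertion-0",
    noise: bool = True,
) -> InsertionTrajectory:
    """Simulate one insertion: at every position, ``n_per_condition`` spectra
    per handling condition (default 3 x 10 = 30), each with its own sampled
    ground-truth composition."""
    from .pipeline import label_zone

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    grid = inst.combined_grid()
    measurements: list[ProbeMeasurement] = []
    t = 0.0
    for depth in geometry.position_depths_mm:
        zone = label_zone(depth, cortical_thickness_mm=geometry.cortical_thickness_mm)
        for condition in conditions:
            for _ in range(n_per_condition):
                truth = sample_zone_composition(zone, condition, model, rng)
                spec = forward_reflectance(
                    truth, inst, chrom, grid=grid,
                    meta={
                        "insertion_id": insertion_id,
                        "depth_mm": depth,
                        "zone": zone.value,
                        "condition": condition.value,
                        "time_s": t,
                    },
                )
                if noise:
                    spec = add_instrument_noise(spec, inst, rng)
                measurements.append(
                    ProbeMeasurement(spec, depth, zone, condition, t, truth)
                )
                t += 1.0
    return InsertionTrajectory(tuple(measurements), geometry.cortical_boundary_depth_mm, insertion_id)


def generate_dataset(
    model: ZoneCompositionModel,
    inst: InstrumentConfig,
    chrom: ChromophoreSet,
    seed: int,
    positions_per_insertion: Sequence[int] = DEFAULT_POSITION_SPLIT,
    n_per_condition: int = 10,
    conditions: Sequence[HandlingCondition] = tuple(HandlingCondition),
    noise: bool = True,
) -> list[InsertionTrajectory]:
    """Simulate the default multi-insertion experiment (270 spectra with the
    default 6-insertion split)."""
    seeds = np.random.SeedSequence(seed).spawn(len(positions_per_insertion))
    out = []
    for i, (n_pos, child) in enumerate(zip(positions_per_insertion, seeds)):
        geometry = InsertionGeometry(default_insertion_depths(i, n_pos))
        out.append(
            generate_insertion(
                model, geometry, inst, chrom,
                seed=int(child.generate_state(1)[0] % (2**31)),
                conditions=conditions,
                n_per_condition=n_per_condition,
                insertion_id=f"insertion-{i}",
                noise=noise,
            )
        )
    return out


@dataclass(frozen=True)
class SacrificeConfig:
    """Endpoint-matched decay model of the post-sacrifice recording.

    Blood content decays from ``blood_start`` to ``blood_end`` percent over
    ``duration_s`` while fat content and fat fraction drift slowly; each
    trajectory follows the normalized exponential
    ``decay(t) = (exp(-t/tau) - exp(-T/tau)) / (1 - exp(-T/tau))`` which is 1
    at t = 0 and 0 at t = T, so the configured endpoints are hit exactly.
    """

    duration_s: float = 70.0 * 60.0
    n_samples: int = 2020
    blood_start_pct: float = 18.9
    blood_end_pct: float = 8.1
    fat_start_pct: float = 41.5
    fat_end_pct: float = 37.7
    fat_fraction_start_pct: float = 35.5
    fat_fraction_end_pct: float = 32.3
    tau_s: float | None = None  # default duration/3
    scatter_amp_800: float = 15.9
    scatter_slope: float = 1.0
    oxygen_saturation: float = 0.7

    def _decay(self, t: np.ndarray | float) -> np.ndarray | float:
        tau = self.tau_s if self.tau_s is not None else self.duration_s / 3.0
        et = np.exp(-np.asarray(t, float) / tau)
        eT = np.exp(-self.duration_s / tau)
        return (et - eT) / (1.0 - eT)

    def truth_at(self, t: float) -> tuple[float, float, float]:
        """Noiseless (blood %, fat content %, fat fraction %) at time t."""
        d = float(self._decay(t))
        blood = self.blood_end_pct + (self.blood_start_pct - self.blood_end_pct) * d
        fat = self.fat_end_pct + (self.fat_start_pct - self.fat_end_pct) * d
        ff = self.fat_fraction_end_pct + (self.fat_fraction_start_pct - self.fat_fraction_end_pct) * d
        return blood, fat, ff

    def composition_at(self, t: float) -> TissueComposition:
        blood, fat_pct, ff = self.truth_at(t)
        thb = BLOOD_REFERENCE_GL * blood / 100.0
        fat = fat_pct / 100.0
        water = fat * (100.0 - ff) / ff
        return TissueComposition(
            hb_gl=(1.0 - self.oxygen_saturation) * thb,
            hbo2_gl=self.oxygen_saturation * thb,
            fat_vol_frac=fat,
            water_vol_frac=water,
            scatter_amp_800=self.scatter_amp_800,
            scatter_slope=self.scatter_slope,
        )


def generate_sacrifice_series(
    config: SacrificeConfig,
    inst: InstrumentConfig,
    chrom: ChromophoreSet,
    seed: int,
    noise: bool = True,
) -> tuple[ProbeMeasurement, ...]:
    """Simulate the continuous recording in the vertebral-body center while
    perfusion decays after sacrifice.  Returns time-ordered measurements; the
    probe sits deep in cancellous bone (depth -8 mm) throughout."""
    if config.duration_s <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    grid = inst.combined_grid()
    times = np.linspace(0.0, config.duration_s, config.n_samples)
    out = []
    for t in times:
        truth = config.composition_at(float(t))
        spec = forward_reflectance(truth, inst, chrom, grid=grid, meta={"time_s": float(t)})
        if noise:
            spec = add_instrument_noise(spec, inst, rng)
        out.append(ProbeMeasurement(spec, -8.0, Zone.CANCELLOUS, HandlingCondition.LOW_PRESSURE, float(t), truth))
    return tuple(out)
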