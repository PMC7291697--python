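"""Breach-detection analysis: zone labelling, per-zone summaries, the
fat-fraction breach signal, and 1200-nm spectral normalization.

Zone geometry is defined relative to the inner cortical wall (signed depth,
negative inside cancellous bone):

    cancellous   depth < -3 mm
    pre-cortical -3 mm <= depth < 0 (the 3 mm early-warning band)
    cortical     0 <= depth < cortical thickness (default 1 mm)
    breach       the first 3 mm past the cortex

The breach signal is the drop of fitted fat fraction below a running
cancellous baseline; a simultaneous blood surge instead flags a probable
probe retraction (blood pooling in the vacated cavity).
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .fit import FitResult
from .model import Spectrum
from .synthetic import Zone

__all__ = [
    "BreachCallType",
    "BreachCall",
    "BreachConfig",
    "ZoneSummary",
    "label_zone",
    "summarize_zones",
    "detect_breach_signal",
    "detect_breach_values",
    "normalize_at",
]

PCZ_WIDTH_MM = 3.0
BREACH_WIDTH_MM = 3.0

#: parameters summarized per zone (attribute names of FitResult)
SUMMARY_PARAMS = ("blood_content_pct", "fat_fraction_pct", "scatter_amp_800")


def label_zone(depth_mm: float, cortical_thickness_mm: float = 1.0) -> Zone:
    """Map a signed distance to the cortical boundary onto a tissue zone.

    Raises beyond ``cortical_thickness + 3`` mm outside: the probe has left
    the defined breach zone.
    """
    if not math.isfinite(depth_mm):
        raise ValueError("depth must be finite")
    if depth_mm < -PCZ_WIDTH_MM:
        return Zone.CANCELLOUS
    if depth_mm < 0.0:
        return Zone.PCZ
    if depth_mm < cortical_thickness_mm:
        return Zone.CORTICAL
    if depth_mm <= cortical_thickness_mm + BREACH_WIDTH_MM:
        return Zone.BREACH
    raise ValueError(
        f"depth {depth_mm:.2f} mm is beyond the defined breach zone "
        f"(> {cortical_thickness_mm + BREACH_WIDTH_MM:.1f} mm outside)"
    )


@dataclass(frozen=True)
class ZoneSummary:
    """Median/min/max of the fitted physiology within one zone."""

    zone: Zone
    n: int
    stats: Mapping[str, tuple[float, float, float]]  # param -> (median, min, max)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("zone summary requires n >= 1")
        for name, (med, lo, hi) in self.stats.items():
            if not lo <= med <= hi:
                raise ValueError(f"{name}: min <= median <= max violated")


def summarize_zones(fits: Sequence[FitResult], zones: Sequence[Zone]) -> list[ZoneSummary]:
    """Per-zone median [min, max] of blood content, fat fraction and
    scattering amplitude, in anatomical zone order.  Zones with no fits are
    omitted with a warning."""
    if len(fits) != len(zones):
        raise ValueError("fits and zones must have equal length")
    out: list[ZoneSummary] = []
    for zone in Zone:
        values = [f for f, z in zip(fits, zones) if z == zone]
        if not values:
            warnings.warn(f"no measurements in zone {zone.value}; omitted", RuntimeWarning)
            continue
        stats = {}
        for param in SUMMARY_PARAMS:
            arr = np.array([getattr(f, param) for f in values], dtype=float)
            stats[param] = (float(np.median(arr)), float(arr.min()), float(arr.max()))
        out.append(ZoneSummary(zone=zone, n=len(values), stats=stats))
    return out


class BreachCallType(str, enum.Enum):
    ADVANCE_SAFE = "advance_safe"
    IMPENDING_BREACH = "impending_breach"
    BREACHED = "breached"
    RETRACTED_SUSPECT = "retracted_suspect"


@dataclass(frozen=True)
class BreachConfig:
    """Operating thresholds of the breach-signal detector.

    abs_threshold_pp    fat fraction below this absolute level (pp) is
                        breach-suspicious
    rel_drop            additionally require a drop below (1 - rel_drop) x
                        the running cancellous baseline
    blood_threshold_pct blood content above this with a simultaneous
                        fat-fraction drop flags a retraction (or, after an
                        impending-breach call, a completed breach)
    """

    abs_threshold_pp: float = 10.0
    rel_drop: float = 0.5
    blood_threshold_pct: float = 40.0


@dataclass(frozen=True)
class BreachCall:
    index: int
    fat_fraction_pct: float
    blood_content_pct: float
    drop_pp: float  # baseline minus observed fat fraction
    call: BreachCallType


def detect_breach_values(
    fat_fraction_pct: Sequence[float],
    blood_content_pct: Sequence[float],
    config: BreachConfig | None = None,
) -> list[BreachCall]:
    """Classify an ordered per-position trajectory of (fat fraction, blood).

    The baseline is the running median of positions called safe so far; the
    first position anchors it (insertions start in cancellous bone).
    """
    config = config or BreachConfig()
    ff = np.asarray(fat_fraction_pct, dtype=float)
    blood = np.asarray(blood_content_pct, dtype=float)
    if ff.size != blood.size:
        raise ValueError("fat fraction and blood sequences must have equal length")
    if ff.size < 2:
        raise ValueError("breach detection requires >= 2 positions")
    if np.all(np.isnan(ff)):
        raise ValueError("all fat fractions are NaN")

    calls: list[BreachCall] = []
    baseline_vals: list[float] = []
    prior_impending = False
    for i, (f, b) in enumerate(zip(ff, blood)):
        baseline = float(np.median(baseline_vals)) if baseline_vals else float(f)
        drop = baseline - float(f)
        rel_hit = f < (1.0 - config.rel_drop) * baseline
        if b > config.blood_threshold_pct and rel_hit:
            call = BreachCallType.BREACHED if prior_impending else BreachCallType.RETRACTED_SUSPECT
        elif f < config.abs_threshold_pp and rel_hit:
            call = BreachCallType.IMPENDING_BREACH
            prior_impending = True
        else:
            call = BreachCallType.ADVANCE_SAFE
            baseline_vals.append(float(f))
        calls.append(BreachCall(i, float(f), float(b), drop, call))
    return calls


def detect_breach_signal(fits: Sequence[FitResult], config: BreachConfig | None = None) -> list[BreachCall]:
    """Breach calls from an ordered sequence of per-position fits."""
    return detect_breach_values(
        [f.fat_fraction_pct for f in fits],
        [f.blood_content_pct for f in fits],
        config,
    )


def normalize_at(spec: Spectrum, wavelength_nm: float = 1200.0) -> Spectrum:
    """Scale a spectrum to unit reflectance at the anchor wavelength.

    Shape-preserving (all ratios between wavelengths unchanged) and
    idempotent; used to compare perfusion states independently of overall
    intensity.  The anchor value is linearly interpolated if the grid does
    not sample it exactly.
    """
    if not spec.grid.covers(wavelength_nm):
        raise ValueError(f"grid does not cover the anchor wavelength {wavelength_nm} nm")
    anchor = float(np.interp(wavelength_nm, spec.grid.wavelengths_nm, spec.reflectance))
    if anchor <= 0:
        raise ValueError("reflectance at the anchor wavelength must be > 0")
    meta = dict(spec.meta)
    meta["normalized_at_nm"] = wavelength_nm
    return Spectrum(spec.grid, spec.reflectance / anchor, meta)
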