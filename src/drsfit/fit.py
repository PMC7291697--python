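"""Inversion of measured reflectance spectra into tissue composition.

A bounded trust-region-reflective least-squares fit recovers six parameters
from one spectrum: Hb and HbO2 concentration (g/l), the combined fat+water
volume, the fat share of that volume, the reduced-scattering amplitude at
800 nm and the scattering power-law slope.  Fitting the fat *share* directly
(rather than independent fat and water volumes) keeps the physical
constraint fat + water <= cap inside a box, and makes the clinically used
fat fraction Fat/(Fat+Water)*100 a fitted parameter with a directly
propagated confidence interval.

Confidence intervals follow the standard nonlinear-regression error
propagation: the parameter covariance is the residual variance times
(J^T J)^-1 at the optimum, and derived quantities (blood content, fat
fraction) get first-order (delta-method) intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .model import (
    MAX_FAT_WATER_TOTAL,
    SCATTER_REF_NM,
    ChromophoreSet,
    InstrumentConfig,
    Spectrum,
    TissueComposition,
    _diffusion_reflectance_grad,
)

__all__ = [
    "FitOptions",
    "FitResult",
    "fit_spectrum",
    "blood_content",
    "fat_fraction",
    "confidence_intervals",
]

#: reference total hemoglobin of normal human blood (g/l); blood content is
#: total hemoglobin expressed as a percentage of this value
BLOOD_REFERENCE_GL = 150.0

#: two-sided 95% Gaussian quantile
Z95 = 1.959964

_PARAM_NAMES = ("hb_gl", "hbo2_gl", "fat_water_total", "fat_share", "scatter_amp_800", "scatter_slope")

_LOWER = np.array([0.0, 0.0, 0.0, 0.0, 0.5, 0.0])
_UPPER = np.array([300.0, 300.0, MAX_FAT_WATER_TOTAL, 1.0, 60.0, 4.0])

# lipid-rich / blood-rich / water-rich starting points (multistart)
_STARTS = (
    np.array([0.5, 1.0, 0.9, 0.6, 16.0, 1.0]),
    np.array([15.0, 35.0, 0.9, 0.25, 16.0, 1.0]),
    np.array([3.0, 7.0, 1.0, 0.05, 16.0, 1.0]),
)

_MUA_FLOOR = 1e-9


def blood_content(comp: TissueComposition, reference_gl: float = BLOOD_REFERENCE_GL) -> float:
    """Total hemoglobin (Hb + HbO2) as a percentage of normal blood (150 g/l).

    Values above 100% are possible (blood-pooled measurement volumes).
    """
    return 100.0 * (comp.hb_gl + comp.hbo2_gl) / reference_gl


def fat_fraction(fat: float, water: float) -> float:
    """Fat fraction Fat/(Fat+Water)*100, the breach-detection statistic.

    Invariant under common rescaling of fat and water.  The degenerate input
    fat = water = 0 returns 0.0 with a RuntimeWarning rather than NaN, so
    pipelines stay total.
    """
    if fat < 0 or water < 0:
        raise ValueError("fat and water must be >= 0")
    total = fat + water
    if total == 0:
        warnings.warn("fat + water = 0: fat fraction undefined, returning 0", RuntimeWarning)
        return 0.0
    return 100.0 * fat / total


@dataclass(frozen=True)
class FitOptions:
    """Tunables of the spectral fit.

    weighting   'log' (homoscedastic under relative noise; default) or
                'band_scaled' (plain reflectance residuals scaled by the
                per-band mean of the data)
    n_starts    number of multistart initializations (<= 3 canonical starts)
    """

    weighting: str = "log"
    n_starts: int = 3
    max_nfev: int = 400
    xtol: float = 1e-12
    ftol: float = 1e-12
    gtol: float = 1e-12

    def __post_init__(self) -> None:
        if self.weighting not in ("log", "band_scaled"):
            raise ValueError("weighting must be 'log' or 'band_scaled'")
        if not 1 <= self.n_starts <= len(_STARTS):
            raise ValueError(f"n_starts must be in [1, {len(_STARTS)}]")


@dataclass(frozen=True)
class FitResult:
    """Fitted composition, derived physiology, uncertainty and diagnostics."""

    composition: TissueComposition
    blood_content_pct: float
    fat_fraction_pct: float
    fat_content_pct: float
    water_content_pct: float
    scatter_amp_800: float
    covariance: np.ndarray
    ci95: Mapping[str, float]
    residual_norm: float
    fitted_spectrum: Spectrum
    converged: bool
    n_iter: int
    degenerate_fat_water: bool = False
    weighting: str = "log"
    param_names: Sequence[str] = field(default=_PARAM_NAMES)

    def to_dict(self) -> dict:
        """JSON-serializable summary (parameters, CIs, diagnostics)."""
        c = self.composition
        return {
            "composition": {
                "hb_gl": float(c.hb_gl),
                "hbo2_gl": float(c.hbo2_gl),
                "fat_vol_frac": float(c.fat_vol_frac),
                "water_vol_frac": float(c.water_vol_frac),
                "scatter_amp_800": float(c.scatter_amp_800),
                "scatter_slope": float(c.scatter_slope),
            },
            "blood_content_pct": float(self.blood_content_pct),
            "fat_fraction_pct": float(self.fat_fraction_pct),
            "fat_content_pct": float(self.fat_content_pct),
            "water_content_pct": float(self.water_content_pct),
            "ci95": {k: (None if not np.isfinite(v) else float(v)) for k, v in self.ci95.items()},
            "residual_norm": float(self.residual_norm),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "degenerate_fat_water": bool(self.degenerate_fat_water),
            "weighting": self.weighting,
        }


class _Objective:
    """Weighted residuals and analytic Jacobian for one spectrum."""

    def __init__(self, spec: Spectrum, inst: InstrumentConfig, chrom: ChromophoreSet, options: FitOptions):
        y = spec.reflectance
        if np.any(~np.isfinite(y)):
            raise ValueError("spectrum contains NaN/inf reflectance")
        self.wl = spec.grid.wavelengths_nm
        self.K = chrom.on_grid(spec.grid).matrix  # (n, 4): hb, hbo2, fat, water
        self.lwl = np.log(self.wl / SCATTER_REF_NM)
        self.rho_cm = inst.fiber_separation_cm
        self.y = y
        self.options = options
        if options.weighting == "log":
            if np.any(y <= 0):
                raise ValueError("log weighting requires strictly positive reflectance")
            self.log_y = np.log(y)
        else:
            vis = self.wl < inst.stitch_nm
            scale = np.empty_like(y)
            for mask in (vis, ~vis):
                if mask.any():
                    scale[mask] = np.mean(y[mask])
            if np.any(scale <= 0):
                raise ValueError("band scaling requires positive band-mean reflectance")
            self.scale = scale
        self._cache_x: tuple | None = None
        self._cache: tuple[np.ndarray, np.ndarray] | None = None

    def _model(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        hb, hbo2, tw, phi, amp, slope = x
        conc = np.array([hb, hbo2, tw * phi, tw * (1.0 - phi)])
        mua = self.K @ conc
        np.maximum(mua, _MUA_FLOOR, out=mua)
        musp = amp * np.exp(-slope * self.lwl)
        R, dR_da, dR_ds = _diffusion_reflectance_grad(mua, musp, self.rho_cm)
        # chain rule onto the six fit parameters
        dmua = np.column_stack(
            [
                self.K[:, 0],
                self.K[:, 1],
                self.K[:, 2] * phi + self.K[:, 3] * (1.0 - phi),
                tw * (self.K[:, 2] - self.K[:, 3]),
                np.zeros_like(mua),
                np.zeros_like(mua),
            ]
        )
        dmusp = np.column_stack(
            [
                np.zeros_like(musp),
                np.zeros_like(musp),
                np.zeros_like(musp),
                np.zeros_like(musp),
                musp / amp,
                -musp * self.lwl,
            ]
        )
        J_R = dR_da[:, None] * dmua + dR_ds[:, None] * dmusp
        if self.options.weighting == "log":
            r = np.log(R) - self.log_y
            J = J_R / R[:, None]
        else:
            r = (R - self.y) / self.scale
            J = J_R / self.scale[:, None]
        return r, J

    def _eval(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        key = tuple(x)
        if self._cache_x != key:
            self._cache = self._model(np.asarray(x, float))
            self._cache_x = key
        return self._cache

    def residuals(self, x: np.ndarray) -> np.ndarray:
        return self._eval(x)[0]

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        return self._eval(x)[1]


def _covariance_and_cis(J: np.ndarray, r: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, dict]:
    """Parameter covariance s^2 (J^T J)^-1 via SVD, with delta-method CIs.

    Rank-deficient Jacobians yield infinite half-widths along unidentifiable
    directions instead of raising.
    """
    n, p = J.shape
    dof = max(n - p, 1)
    s2 = float(r @ r) / dof
    U, sv, Vt = np.linalg.svd(J, full_matrices=False)
    tol = sv[0] * 1e-10 if sv[0] > 0 else np.inf
    rank = int(np.sum(sv > tol))
    inv_sv2 = np.zeros_like(sv)
    inv_sv2[:rank] = 1.0 / sv[:rank] ** 2
    cov = s2 * (Vt.T * inv_sv2) @ Vt
    null = Vt[rank:]  # directions with no information

    def half_width(grad: np.ndarray) -> float:
        if null.size and np.any(np.abs(null @ grad) > 1e-8 * max(np.linalg.norm(grad), 1.0)):
            return float("inf")
        var = float(grad @ cov @ grad)
        return Z95 * float(np.sqrt(max(var, 0.0)))

    hb, hbo2, tw, phi, amp, slope = x
    e = np.eye(p)
    ci = {
        "hb_gl": half_width(e[0]),
        "hbo2_gl": half_width(e[1]),
        "blood_content_pct": half_width(np.array([100 / BLOOD_REFERENCE_GL, 100 / BLOOD_REFERENCE_GL, 0, 0, 0, 0])),
        "fat_fraction_pct": half_width(np.array([0, 0, 0, 100.0, 0, 0])),
        "fat_content_pct": half_width(np.array([0, 0, 100.0 * phi, 100.0 * tw, 0, 0])),
        "water_content_pct": half_width(np.array([0, 0, 100.0 * (1 - phi), -100.0 * tw, 0, 0])),
        "scatter_amp_800": half_width(e[4]),
        "scatter_slope": half_width(e[5]),
    }
    return cov, ci


def fit_spectrum(
    spec: Spectrum,
    inst: InstrumentConfig,
    chrom: ChromophoreSet,
    options: FitOptions | None = None,
) -> FitResult:
    """Fit one calibrated reflectance spectrum to the diffusion forward model.

    Multistart bounded least squares (lipid-rich, blood-rich and water-rich
    initializations); the lowest-objective solution is returned.  The
    ``converged`` flag is honest: it is False whenever the selected start
    stopped on the evaluation budget rather than on a tolerance.
    """
    options = options or FitOptions()
    wl = spec.grid.wavelengths_nm
    if wl[0] > 600.0 or wl[-1] < 1000.0:
        warnings.warn(
            "spectrum does not cover both the blood-sensitive (450-600 nm) and "
            "fat/water-sensitive (>1000 nm) regions; the fit may be poorly constrained",
            RuntimeWarning,
        )
    obj = _Objective(spec, inst, chrom, options)

    best = None
    for x0 in _STARTS[: options.n_starts]:
        res = least_squares(
            obj.residuals,
            x0,
            jac=obj.jacobian,
            bounds=(_LOWER, _UPPER),
            method="trf",
            x_scale=np.array([10.0, 10.0, 0.3, 0.3, 5.0, 0.5]),
            xtol=options.xtol,
            ftol=options.ftol,
            gtol=options.gtol,
            max_nfev=options.max_nfev,
        )
        if best is None or res.cost < best.cost:
            best = res

    hb, hbo2, tw, phi, amp, slope = best.x
    fat = tw * phi
    water = tw * (1.0 - phi)
    comp = TissueComposition(
        hb_gl=hb, hbo2_gl=hbo2, fat_vol_frac=fat, water_vol_frac=water,
        scatter_amp_800=amp, scatter_slope=slope,
    )
    degenerate = bool(tw == 0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ff = fat_fraction(fat, water)
    cov, ci = _covariance_and_cis(obj.jacobian(best.x), best.fun, best.x)

    from .model import forward_reflectance

    fitted = forward_reflectance(comp, inst, chrom, grid=spec.grid, meta={"fitted": True})
    return FitResult(
        composition=comp,
        blood_content_pct=blood_content(comp),
        fat_fraction_pct=ff,
        fat_content_pct=100.0 * fat,
        water_content_pct=100.0 * water,
        scatter_amp_800=amp,
        covariance=cov,
        ci95=ci,
        residual_norm=float(np.linalg.norm(best.fun)),
        fitted_spectrum=fitted,
        converged=bool(best.status > 0),
        n_iter=int(best.nfev),
        degenerate_fat_water=degenerate,
        weighting=options.weighting,
    )


def confidence_intervals(
    fit: FitResult,
    spec: Spectrum,
    inst: InstrumentConfig,
    chrom: ChromophoreSet,
    options: FitOptions | None = None,
) -> dict:
    """Recompute the 95% CI half-widths of ``fit`` on ``spec``.

    Standalone entry point for the error-propagation step: rebuilds the
    weighted Jacobian and residuals at the fitted parameters and applies the
    covariance + delta-method machinery.  Requires a converged fit.
    """
    if not fit.converged:
        raise ValueError("confidence intervals require a converged fit")
    options = options or FitOptions(weighting=fit.weighting)
    obj = _Objective(spec, inst, chrom, options)
    c = fit.composition
    tw = c.fat_vol_frac + c.water_vol_frac
    phi = c.fat_vol_frac / tw if tw > 0 else 0.0
    x = np.array([c.hb_gl, c.hbo2_gl, tw, phi, c.scatter_amp_800, c.scatter_slope])
    _, ci = _covariance_and_cis(obj.jacobian(x), obj.residuals(x), x)
    return ci
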