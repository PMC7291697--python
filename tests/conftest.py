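import numpy as np
import pytest

from drsfit import (
    FitResult,
    InstrumentConfig,
    Spectrum,
    TissueComposition,
    WavelengthGrid,
    ZoneCompositionModel,
    load_default_chromophores,
)


@pytest.fixture(scope="session")
def chrom():
    return load_default_chromophores()


@pytest.fixture(scope="session")
def inst():
    return InstrumentConfig()


@pytest.fixture(scope="session")
def zone_model():
    return ZoneCompositionModel()


@pytest.fixture(scope="session")
def typical_comp():
    """Marrow-like composition in the middle of the cancellous ranges."""
    return TissueComposition(
        hb_gl=13.0,
        hbo2_gl=30.3,
        fat_vol_frac=0.251,
        water_vol_frac=0.699,
        scatter_amp_800=15.9,
        scatter_slope=1.0,
    )


def make_fit_result(blood_pct=25.0, ff_pct=26.0, amp=15.9, ci_ff=2.0, converged=True):
    """Minimal FitResult stand-in for pipeline/stats plumbing tests."""
    thb = 150.0 * blood_pct / 100.0
    fat = 0.95 * ff_pct / 100.0
    comp = TissueComposition(
        hb_gl=0.3 * thb, hbo2_gl=0.7 * thb,
        fat_vol_frac=fat, water_vol_frac=0.95 - fat,
        scatter_amp_800=amp, scatter_slope=1.0,
    )
    grid = WavelengthGrid(np.array([450.0, 1000.0, 1600.0]))
    spec = Spectrum(grid, np.ones(3))
    return FitResult(
        composition=comp,
        blood_content_pct=blood_pct,
        fat_fraction_pct=ff_pct,
        fat_content_pct=100 * fat,
        water_content_pct=100 * (0.95 - fat),
        scatter_amp_800=amp,
        covariance=np.zeros((6, 6)),
        ci95={"fat_fraction_pct": ci_ff, "blood_content_pct": ci_ff / 2},
        residual_norm=0.0,
        fitted_spectrum=spec,
        converged=converged,
        n_iter=1,
    )
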