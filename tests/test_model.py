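"""Forward-model unit and property tests: absorption linearity, the
scattering power law, diffusion reflectance physics and the noise model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drsfit import (
    InstrumentConfig,
    Spectrum,
    TissueComposition,
    WavelengthGrid,
    absorption_coefficient,
    add_instrument_noise,
    diffusion_reflectance,
    forward_reflectance,
    reduced_scattering,
)
from drsfit.model import boundary_constant

conc_st = st.floats(min_value=0.0, max_value=50.0)
# doubled compositions must stay under the fat+water cap
frac_st = st.floats(min_value=0.0, max_value=0.37)


class TestWavelengthGrid:
    def test_rejects_non_monotone(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            WavelengthGrid(np.array([450.0, 449.0, 451.0]))

    def test_combined_spans_full_range(self):
        g = WavelengthGrid.combined()
        assert g.wavelengths_nm[0] == 450.0 and g.wavelengths_nm[-1] == 1600.0


class TestAbsorption:
    def test_empty_tissue_is_transparent(self, chrom):
        comp = TissueComposition(scatter_amp_800=16.0)
        grid = WavelengthGrid.combined(step=50.0)
        assert np.all(absorption_coefficient(comp, grid, chrom) == 0.0)

    @given(hb=conc_st, hbo2=conc_st, fat=frac_st, water=frac_st)
    @settings(max_examples=25, deadline=None)
    def test_doubling_concentrations_doubles_mua(self, chrom_module, hb, hbo2, fat, water):
        grid = WavelengthGrid.combined(step=100.0)
        comp = TissueComposition(hb, hbo2, fat, water, 16.0, 1.0)
        mua = absorption_coefficient(comp, grid, chrom_module)
        mua2 = absorption_coefficient(comp.scaled(2.0), grid, chrom_module)
        np.testing.assert_allclose(mua2, 2.0 * mua, rtol=1e-12)

    def test_pure_water_matches_embedded_table(self, chrom):
        """Water-only tissue reproduces the packaged water curve by lookup."""
        from importlib import resources

        table = pd.read_csv(
            resources.files("drsfit").joinpath("data").joinpath("water_synthetic.csv"),
            comment="#",
        )
        pick = table.iloc[[50, 300, 600]]  # three tabulated wavelengths
        grid = WavelengthGrid(pick["wavelength_nm"].to_numpy())
        comp = TissueComposition(water_vol_frac=1.0, scatter_amp_800=16.0)
        mua = absorption_coefficient(comp, grid, chrom)
        np.testing.assert_allclose(mua, pick["specific_absorption"].to_numpy(), rtol=1e-9)

    def test_outside_support_raises(self, chrom):
        grid = WavelengthGrid(np.array([300.0, 500.0]))
        comp = TissueComposition(water_vol_frac=0.5, scatter_amp_800=16.0)
        with pytest.raises(ValueError, match="outside chromophore support"):
            absorption_coefficient(comp, grid, chrom)


@pytest.fixture(scope="module")
def chrom_module():
    from drsfit import load_default_chromophores

    return load_default_chromophores()


class TestReducedScattering:
    @given(
        amp=st.floats(min_value=1.0, max_value=40.0),
        slope=st.floats(min_value=0.0, max_value=3.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_amplitude_at_800_exact(self, amp, slope):
        grid = WavelengthGrid(np.array([450.0, 800.0, 1600.0]))
        comp = TissueComposition(scatter_amp_800=amp, scatter_slope=slope)
        musp = reduced_scattering(comp, grid)
        assert musp[1] == pytest.approx(amp, abs=0.0, rel=1e-15)

    def test_zero_slope_flat(self):
        grid = WavelengthGrid.combined(step=100.0)
        comp = TissueComposition(scatter_amp_800=12.5, scatter_slope=0.0)
        assert np.all(reduced_scattering(comp, grid) == 12.5)

    def test_power_law_closed_form(self):
        grid = WavelengthGrid(np.array([800.0, 1600.0]))
        comp = TissueComposition(scatter_amp_800=16.0, scatter_slope=1.0)
        assert reduced_scattering(comp, grid)[1] == pytest.approx(8.0, rel=1e-14)

    def test_nonpositive_amplitude_rejected(self):
        with pytest.raises(ValueError):
            TissueComposition(scatter_amp_800=0.0)


def oracle_dipole_reflectance(mua, musp, rho, n=1.4):
    """Independent re-derivation of the diffusion dipole, written from the
    photon-dose form R = 1/4pi * sum_i z_i (mueff + 1/r_i) exp(-mueff r_i)/r_i^2
    with explicit intermediate quantities (no vectorized shortcuts)."""
    import math

    rd = -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n
    A = (1 + rd) / (1 - rd)
    transport = mua + musp
    source_depth = 1.0 / transport
    diffusion_len = math.sqrt(3.0 * mua * (mua + musp))
    extrapolation = 2.0 * A / (3.0 * transport)
    image_depth = source_depth + 2.0 * extrapolation
    total = 0.0
    for depth in (source_depth, image_depth):
        dist = math.sqrt(depth * depth + rho * rho)
        total += depth * (diffusion_len + 1.0 / dist) * math.exp(-diffusion_len * dist) / dist**2
    return total / (4.0 * math.pi)


class TestDiffusionReflectance:
    def test_matches_independent_oracle_on_random_triples(self):
        rng = np.random.default_rng(1234)
        for _ in range(100):
            mua = rng.uniform(0.01, 50.0)
            musp = rng.uniform(5.0, 30.0)
            rho = rng.uniform(0.05, 0.3)
            got = float(diffusion_reflectance(np.array([mua]), np.array([musp]), rho)[0])
            want = oracle_dipole_reflectance(mua, musp, rho)
            assert got == pytest.approx(want, rel=1e-10)

    def test_boundary_constant_near_known_value(self):
        # A ~ 3.25 for tissue-air mismatch at n = 1.4
        assert boundary_constant(1.4) == pytest.approx(3.25, abs=0.01)

    def test_more_hemoglobin_less_reflectance(self, inst, chrom, typical_comp):
        import dataclasses

        lo = dataclasses.replace(typical_comp, hb_gl=0.0)
        hi = dataclasses.replace(typical_comp, hb_gl=1.0)
        r_lo = forward_reflectance(lo, inst, chrom).reflectance
        r_hi = forward_reflectance(hi, inst, chrom).reflectance
        grid = inst.combined_grid().wavelengths_nm
        strong = (grid > 500) & (grid < 600)  # Hb Q-band region
        assert np.all(r_hi[strong] < r_lo[strong])

    @given(
        hb=st.floats(min_value=0.5, max_value=40.0),
        fat=st.floats(min_value=0.05, max_value=0.5),
    )
    @settings(max_examples=10, deadline=None)
    def test_monotone_in_each_chromophore(self, inst, chrom_module, hb, fat):
        comp = TissueComposition(hb, 10.0, fat, 0.6, 16.0, 1.0)
        base = forward_reflectance(comp, inst, chrom_module, grid=WavelengthGrid.combined(step=25.0))
        import dataclasses

        for bump in (
            {"hb_gl": hb + 1},
            {"fat_vol_frac": fat + 0.05},
            {"water_vol_frac": 0.7},
        ):
            more = dataclasses.replace(comp, **bump)
            r = forward_reflectance(more, inst, chrom_module, grid=base.grid)
            assert np.all(r.reflectance <= base.reflectance)
            assert np.any(r.reflectance < base.reflectance)

    def test_larger_fiber_separation_darker(self, inst, chrom, typical_comp):
        near = InstrumentConfig(fiber_separation_mm=0.5)
        r_near = forward_reflectance(typical_comp, near, chrom).reflectance
        r_far = forward_reflectance(typical_comp, inst, chrom).reflectance
        assert np.all(r_far < r_near)

    def test_zero_optics_error_not_nan(self):
        with pytest.raises(ValueError, match="undefined"):
            diffusion_reflectance(np.array([0.0]), np.array([0.0]), 0.1)

    def test_gradients_match_finite_differences(self):
        from drsfit.model import _diffusion_reflectance_grad

        mua = np.array([0.05, 0.8, 7.0, 60.0])
        musp = np.array([22.0, 16.0, 14.0, 10.0])
        rho = 0.1042
        _, da, ds = _diffusion_reflectance_grad(mua, musp, rho)
        eps = 1e-7
        da_fd = (diffusion_reflectance(mua + eps, musp, rho) - diffusion_reflectance(mua - eps, musp, rho)) / (2 * eps)
        ds_fd = (diffusion_reflectance(mua, musp + eps, rho) - diffusion_reflectance(mua, musp - eps, rho)) / (2 * eps)
        np.testing.assert_allclose(da, da_fd, rtol=1e-5)
        np.testing.assert_allclose(ds, ds_fd, rtol=1e-5)


class TestInstrumentNoise:
    def test_zero_noise_is_identity(self, chrom, typical_comp):
        quiet = InstrumentConfig(noise_rel_visible=0.0, noise_rel_nir=0.0, noise_add=0.0)
        spec = forward_reflectance(typical_comp, quiet, chrom)
        noisy = add_instrument_noise(spec, quiet, seed=0)
        np.testing.assert_array_equal(noisy.reflectance, spec.reflectance)

    def test_seed_reproducibility(self, inst, chrom, typical_comp):
        spec = forward_reflectance(typical_comp, inst, chrom)
        a = add_instrument_noise(spec, inst, seed=7)
        b = add_instrument_noise(spec, inst, seed=7)
        np.testing.assert_array_equal(a.reflectance, b.reflectance)

    def test_noise_is_unbiased(self, inst, chrom):
        grid = WavelengthGrid(np.array([1190.0, 1200.0, 1210.0]))
        spec = Spectrum(grid, np.array([0.4, 0.5, 0.6]))
        rng = np.random.default_rng(99)
        draws = np.array(
            [add_instrument_noise(spec, inst, rng).reflectance[1] for _ in range(10_000)]
        )
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - 0.5) < 3 * se
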