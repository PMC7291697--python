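"""Statistical-toolbox tests: Jarque-Bera, exact and approximate rank-sum
comparisons, OLS R^2 and the CI-quality range summary."""

import math
from itertools import combinations

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from drsfit import (
    InstrumentConfig,
    add_instrument_noise,
    ci_range_summary,
    fit_spectrum,
    forward_reflectance,
    jarque_bera,
    linear_r2,
    wilcoxon_rank_sum,
)
from conftest import make_fit_result


class TestJarqueBera:
    def test_zero_skew_zero_kurtosis_sample(self):
        # symmetric four-spike sample constructed so the excess kurtosis
        # vanishes: a = 1 + sqrt(2), b = 1, plus four zeros (n = 8)
        a = 1 + math.sqrt(2)
        sample = [a, -a, 1.0, -1.0, 0.0, 0.0, 0.0, 0.0]
        result = jarque_bera(sample)
        assert result.statistic == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == pytest.approx(1.0)

    def test_matches_scipy_reference(self):
        sample = np.arange(1.0, 21.0)
        ours = jarque_bera(sample)
        ref_stat, ref_p = sps.jarque_bera(sample)
        assert ours.statistic == pytest.approx(float(ref_stat), rel=1e-12)
        assert ours.p_value == pytest.approx(float(ref_p), rel=1e-9)

    @given(
        shift=st.floats(min_value=-100, max_value=100),
        scale=st.floats(min_value=0.01, max_value=100),
    )
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance(self, shift, scale):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        a = jarque_bera(x).statistic
        b = jarque_bera(scale * x + shift).statistic
        assert b == pytest.approx(a, rel=1e-8, abs=1e-8)

    def test_type_one_error_rate(self):
        rng = np.random.default_rng(7)
        rejections = sum(
            jarque_bera(rng.normal(size=50), alpha=0.05).significant for _ in range(1000)
        )
        assert 30 <= rejections <= 70

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            jarque_bera([2.0] * 10)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="n >= 8"):
            jarque_bera([1.0, 2.0, 3.0])


def brute_force_ranksum_p(x, y):
    """Independent enumeration oracle: two-sided p from the deviation of the
    x rank sum over all equally likely group assignments."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    nx, n = len(x), len(pooled)
    mu = nx * (n + 1) / 2
    obs = abs(ranks[:nx].sum() - mu)
    hits = total = 0
    for assignment in combinations(range(n), nx):
        total += 1
        if abs(ranks[list(assignment)].sum() - mu) >= obs - 1e-9:
            hits += 1
    return hits / total


class TestWilcoxonRankSum:
    def test_identical_groups_p_one(self):
        result = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert result.p_value == pytest.approx(1.0)
        assert result.method == "ranksum_exact"

    def test_separated_groups_exact_p(self):
        result = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert result.p_value == pytest.approx(0.1)

    @given(
        nx=st.integers(min_value=3, max_value=5),
        ny=st.integers(min_value=3, max_value=5),
        data=st.data(),
    )
    @settings(max_examples=40, deadline=None)
    def test_exact_path_equals_brute_force(self, nx, ny, data):
        vals = st.integers(min_value=0, max_value=6)  # small range forces ties
        x = np.array(data.draw(st.lists(vals, min_size=nx, max_size=nx)), float)
        y = np.array(data.draw(st.lists(vals, min_size=ny, max_size=ny)), float)
        result = wilcoxon_rank_sum(x, y)
        assert result.method == "ranksum_exact"
        assert result.p_value == pytest.approx(brute_force_ranksum_p(x, y))

    def test_normal_approximation_close_to_exact(self):
        from drsfit.stats import _ranksum_exact, _ranksum_normal

        rng = np.random.default_rng(11)
        for _ in range(100):
            x = rng.normal(size=rng.integers(5, 7))
            y = rng.normal(size=rng.integers(5, 7))
            _, p_exact = _ranksum_exact(x, y)
            _, p_norm = _ranksum_normal(x, y)
            assert abs(p_exact - p_norm) < 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0, 2.0, 3.0])


class TestLinearR2:
    def test_collinear_is_one(self):
        x = np.arange(10.0)
        assert linear_r2(x, 3 * x - 2) == pytest.approx(1.0)

    def test_independent_near_zero(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=4000)
        y = rng.permutation(x)
        assert linear_r2(x, y) < 0.01

    def test_five_point_normal_equations_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.1, 3.9, 6.2, 8.1, 9.8])
        # oracle: explicit OLS via the normal equations, R^2 = 1 - SSR/SST
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        ssr = float(np.sum((y - X @ beta) ** 2))
        sst = float(np.sum((y - y.mean()) ** 2))
        assert linear_r2(x, y) == pytest.approx(1 - ssr / sst, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            linear_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCiRangeSummary:
    def test_single_fit_degenerate(self):
        fit = make_fit_result(ci_ff=2.5)
        assert ci_range_summary([fit]) == (2.5, 2.5)

    def test_unconverged_rejected(self):
        with pytest.raises(ValueError, match="converged"):
            ci_range_summary([make_fit_result(converged=False)])

    def test_fit_ci_range_brackets_study_range(self, zone_model, chrom, inst):
        """Fitted fat-fraction CI half-widths across probe-handling conditions
        stay within the plausible 1.0-4.5 pp bracket around the observed
        1.5-3.6 pp study range."""
        from drsfit import HandlingCondition, Zone, sample_zone_composition

        rng = np.random.default_rng(17)
        fits = []
        for condition in (HandlingCondition.LOW_PRESSURE, HandlingCondition.HIGH_PRESSURE):
            for _ in range(10):
                comp = sample_zone_composition(Zone.CANCELLOUS, condition, zone_model, rng)
                spec = add_instrument_noise(forward_reflectance(comp, inst, chrom), inst, rng)
                fits.append(fit_spectrum(spec, inst, chrom))
        lo, hi = ci_range_summary([f for f in fits if f.converged])
        assert 1.0 <= lo <= hi <= 4.5

    def test_halving_noise_shrinks_both_endpoints(self, chrom, typical_comp):
        ranges = []
        for sigma in (0.02, 0.01):
            inst_s = InstrumentConfig(noise_rel_visible=sigma, noise_rel_nir=sigma)
            fits = []
            for seed in range(5):
                spec = add_instrument_noise(forward_reflectance(typical_comp, inst_s, chrom), inst_s, seed)
                fits.append(fit_spectrum(spec, inst_s, chrom))
            ranges.append(ci_range_summary(fits))
        assert ranges[1][0] < ranges[0][0]
        assert ranges[1][1] < ranges[0][1]
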