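"""Unit and property tests for the MF-DFA estimator."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from mfgait import mfdfa as M
from mfgait.synthetic import gen_binomial_cascade


def naive_fq(profile, s, q, order=1, policy="forward_only"):
    """Independent double-loop re-implementation of F_q(s)."""
    n = len(profile)
    L = n // s
    starts = [v * s for v in range(L)]
    if policy == "bidirectional":
        starts += [n - (v + 1) * s for v in range(L)]
    f2 = []
    for st0 in starts:
        w = profile[st0 : st0 + s]
        j = np.arange(1, s + 1, dtype=float)
        coef = np.polyfit(j, w, order)
        resid = w - np.polyval(coef, j)
        f2.append(np.mean(resid**2))
    f2 = np.array(f2)
    if q == 0:
        return np.exp(0.5 * np.mean(np.log(f2)))
    return np.mean(f2 ** (q / 2)) ** (1 / q)


class TestProfile:
    def test_constant_series_maps_to_zeros(self):
        assert np.allclose(M.build_profile([5.0, 5, 5, 5]), 0.0)

    def test_hand_computed_example(self):
        np.testing.assert_allclose(M.build_profile([1.0, 2, 3]), [-1, -1, 0])

    @given(arrays(float, st.integers(2, 200),
                  elements=st.floats(-1e6, 1e6, allow_nan=False)))
    def test_profile_ends_at_zero(self, x):
        prof = M.build_profile(x)
        tol = 1e-9 * len(x) * max(1.0, np.max(np.abs(x)))
        assert abs(prof[-1]) <= tol

    def test_non_finite_input_names_index(self):
        with pytest.raises(ValueError, match="index 2"):
            M.build_profile([1.0, 2.0, np.nan, 4.0])


class TestLocalDetrend:
    def test_linear_profile_has_zero_residuals(self):
        prof = 3.0 * np.arange(50) + 2.0
        f2 = M.local_detrend_covariances(prof, 10, order=1)
        assert np.allclose(f2, 0.0, atol=1e-18)

    def test_alternating_profile_matches_brute_force(self):
        prof = np.array([0.0, 1, 0, 1, 0, 1])
        f2 = M.local_detrend_covariances(prof, 3, order=1)
        assert len(f2) == 2
        assert f2[0] == pytest.approx(f2[1])  # symmetry of the two windows
        for v, f in enumerate(f2):
            w = prof[v * 3 : (v + 1) * 3]
            coef = np.polyfit(np.arange(1, 4, dtype=float), w, 1)
            resid = w - np.polyval(coef, np.arange(1, 4, dtype=float))
            assert f == pytest.approx(np.mean(resid**2), rel=1e-12)

    def test_window_count_floor_division(self):
        prof = np.random.default_rng(0).normal(size=100)
        assert len(M.local_detrend_covariances(prof, 30)) == 3

    @pytest.mark.parametrize("s,expected", [(10, 20), (33, 6), (50, 4)])
    def test_bidirectional_doubles_window_count(self, s, expected):
        prof = np.random.default_rng(1).normal(size=100)
        assert len(M.local_detrend_covariances(prof, s, policy="bidirectional")) == expected

    def test_scale_larger_than_series_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            M.local_detrend_covariances(np.zeros(10), 11)


class TestFluctuationFunction:
    @pytest.mark.parametrize("q", [-4.0, -1.0, 0.0, 0.5, 2.0, 4.0])
    def test_constant_windows_collapse_to_sqrt(self, q):
        assert M.fluctuation_function(np.full(7, 9.0), q) == pytest.approx(3.0)

    def test_rms_example(self):
        # q = 2 reduces to the RMS of sqrt(F^2): sqrt((1 + 4) / 2)
        assert M.fluctuation_function(np.array([1.0, 4.0]), 2.0) == pytest.approx(
            np.sqrt(2.5), rel=1e-12
        )

    @given(
        arrays(float, st.integers(2, 30), elements=st.floats(1e-6, 1e6)),
        st.lists(st.integers(-20, 20).map(lambda k: k / 4.0), min_size=2, max_size=6,
                 unique=True),
    )
    def test_power_mean_monotone_in_q(self, f2, qs):
        vals = [M.fluctuation_function(f2, q) for q in sorted(qs)]
        assert all(b >= a * (1 - 1e-9) for a, b in zip(vals, vals[1:]))

    def test_zero_window_with_negative_q(self):
        f2 = np.array([0.0, 1.0, 4.0])
        with pytest.raises(ValueError, match="zero residual"):
            M.fluctuation_function(f2, -2.0)
        excl = M.fluctuation_function(f2, -2.0, zero_policy="exclude")
        assert excl == pytest.approx(np.mean([1.0, 4.0 ** -1]) ** -0.5)
        floored = M.fluctuation_function(f2, -2.0, zero_policy="floor", zero_floor=1e-15)
        assert floored < excl

    @pytest.mark.parametrize("q", [-3.0, -1.0, 0.0, 1.0, 2.5])
    @pytest.mark.parametrize("s", [8, 16])
    def test_oracle_equivalence_small_series(self, q, s):
        rng = np.random.default_rng(42)
        for _ in range(5):
            x = rng.normal(size=64)
            prof = M.build_profile(x)
            f2 = M.local_detrend_covariances(prof, s)
            ours = M.fluctuation_function(f2, q)
            theirs = naive_fq(prof, s, q)
            assert ours == pytest.approx(theirs, rel=1e-12)


class TestHurstAndSpectrum:
    def _surface(self, h, scale_fn=lambda s, q: 1.0):
        scales = np.array([16, 32, 64, 128, 256])
        q = M.default_q_grid()
        vals = np.array([[scale_fn(s, qq) * s ** h for s in scales] for qq in q])
        return M.FluctuationSurface(vals, scales, q, np.zeros(5, int), np.zeros(5, int))

    def test_exact_power_law_recovered(self):
        hc = M.estimate_hurst(self._surface(0.5))
        assert np.allclose(hc.h, 0.5) and np.allclose(hc.fit_r2, 1.0)

    def test_multiplicative_constant_absorbed(self):
        hc = M.estimate_hurst(self._surface(0.8, scale_fn=lambda s, q: 3.0))
        assert np.allclose(hc.h, 0.8)

    def test_too_few_scales_raises(self):
        surf = self._surface(0.5)
        surf.scales = surf.scales[:2]
        surf.values = surf.values[:, :2]
        with pytest.raises(ValueError, match="3 scales"):
            M.estimate_hurst(surf)

    def test_monofractal_legendre(self):
        q = M.default_q_grid()
        hc = M.HurstCurve(q, np.full(q.size, 0.6), np.ones(q.size))
        spec = M.legendre_spectrum(hc)
        assert np.allclose(spec.tau, q * 0.6 - 1)
        assert np.allclose(spec.alpha, 0.6)
        assert np.allclose(spec.f_alpha, 1.0)

    def test_f_at_q0_is_one(self):
        # tau(0) = -1 forces f(alpha(0)) = 1
        c = gen_binomial_cascade(0.7, 12)
        res = M.run_mfdfa(c, M.default_config(len(c)))
        i0 = np.flatnonzero(res.spectrum.q_grid == 0.0)[0]
        assert res.spectrum.f_alpha[i0] == pytest.approx(1.0, abs=1e-9)

    def test_alpha_non_increasing_for_cascade(self):
        c = gen_binomial_cascade(0.7, 12)
        res = M.run_mfdfa(c, M.default_config(len(c)))
        assert np.all(np.diff(res.spectrum.alpha) <= 1e-9)


class TestSummary:
    def _spec(self, alpha, f):
        q = np.arange(len(alpha), dtype=float)
        return M.SingularitySpectrum(q, np.zeros_like(q), np.array(alpha), np.array(f))

    def test_symmetric_spectrum_gives_zero(self):
        s = M.summarize_spectrum(self._spec([0.4, 0.6, 0.8], [0.5, 1.0, 0.5]))
        assert s.d_alpha == pytest.approx(0.0)

    def test_asymmetric_example(self):
        s = M.summarize_spectrum(self._spec([0.4, 0.6, 1.0], [0.5, 1.0, 0.5]))
        assert s.delta_alpha == pytest.approx(0.6)
        assert s.alpha_0 == pytest.approx(0.6)
        assert s.d_alpha == pytest.approx(0.2)  # 0.4 - 0.2

    def test_monofractal_flagged(self):
        s = M.summarize_spectrum(self._spec([0.5, 0.5, 0.5], [1.0, 1.0, 1.0]))
        assert s.monofractal and s.delta_alpha == 0 and s.d_alpha == 0 and s.delta_f == 0

    def test_literal_formula_variant(self):
        spec = self._spec([0.4, 0.6, 1.0], [0.5, 1.0, 0.5])
        lit = M.summarize_spectrum(spec, d_alpha_formula="literal")
        assert lit.d_alpha == pytest.approx(abs(1.0 - 0.6) - 0.4 - 0.6)


class TestRunMfdfa:
    def test_deterministic(self):
        x = np.random.default_rng(3).normal(size=1024)
        cfg = M.default_config(1024)
        a = M.run_mfdfa(x, cfg)
        b = M.run_mfdfa(x.copy(), cfg)
        assert np.array_equal(a.surface.values, b.surface.values)
        assert a.summary.d_alpha == b.summary.d_alpha

    def test_uniform_cascade_narrower_than_skewed(self):
        cfg = M.default_config(4096)
        w_uniform = M.run_mfdfa(
            gen_binomial_cascade(0.5, 12) + 1e-9 * np.random.default_rng(0).normal(size=4096),
            cfg,
        ).summary.delta_alpha
        w_skewed = M.run_mfdfa(gen_binomial_cascade(0.7, 12), cfg).summary.delta_alpha
        assert w_uniform < w_skewed

    def test_stage_name_attached_to_errors(self):
        with pytest.raises(ValueError, match=r"\[profile\]"):
            M.run_mfdfa(np.arange(40.0), M.default_config(512))

    def test_scale_count_conservation(self):
        x = np.random.default_rng(5).normal(size=1000)
        for policy, factor in (("forward_only", 1), ("bidirectional", 2)):
            cfg = M.default_config(1000, segmentation_policy=policy)
            res = M.run_mfdfa(x, cfg)
            expect = factor * (1000 // cfg.scales)
            assert np.array_equal(res.surface.segment_counts, expect)
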