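import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aggrekin.kinetics import (
    FitError,
    GrowthCurve,
    detect_termination,
    fit_single_rate,
    fit_two_phase,
    summarize_condition,
    welch_t_test,
)


def piecewise(t, r1, r2, tc, a0=1000.0):
    t = np.asarray(t, float)
    return a0 + np.where(t <= tc, r1 * t, r1 * tc + r2 * (t - tc))


def brute_force_two_phase(t, y):
    """Independent oracle: exhaustive changepoint scan, free least squares."""
    best = None
    for i in range(2, len(t) - 2):
        tc = t[i]
        X = np.column_stack([np.ones_like(t), t, np.maximum(t - tc, 0.0)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(np.sum((y - X @ beta) ** 2))
        if best is None or sse < best[0] - 1e-12:
            best = (sse, tc, beta[1], beta[1] + beta[2])
    return best


class TestGrowthCurve:
    def test_validation(self):
        with pytest.raises(ValueError):
            GrowthCurve(np.array([0.0, 1.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            GrowthCurve(np.array([1.0, 0.5]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            GrowthCurve(np.array([0.0, 1.0]), np.array([2.0, 1.0]))


class TestFitSingleRate:
    def test_exact_line(self):
        t = np.arange(0.0, 3600.0, 300.0)
        curve = GrowthCurve(t, 1000.0 + 29_211.0 * t)
        fit = fit_single_rate(curve)
        assert fit.rates["rx"] == pytest.approx(29_211.0, rel=1e-9)

    def test_constant_curve_rate_zero(self):
        t = np.arange(0.0, 3000.0, 300.0)
        curve = GrowthCurve(t, np.full(len(t), 500.0))
        assert fit_single_rate(curve).rates["rx"] == 0.0

    def test_too_few_points(self):
        curve = GrowthCurve(np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        with pytest.raises(FitError):
            fit_single_rate(curve)

    def test_window_restriction(self):
        t = np.arange(0.0, 6000.0, 300.0)
        y = piecewise(t, 1000.0, 0.0, 3000.0)
        fit = fit_single_rate(GrowthCurve(t, y), window=(0.0, 3000.0))
        assert fit.rates["rx"] == pytest.approx(1000.0, rel=1e-9)

    def test_custom_naming(self):
        t = np.arange(0.0, 3000.0, 300.0)
        fit = fit_single_rate(
            GrowthCurve(t, 10.0 + 5.0 * t), archetype="small", rate_name="r"
        )
        assert fit.archetype == "small" and "r" in fit.rates


class TestFitTwoPhase:
    def test_exact_recovery(self):
        t = np.arange(0.0, 10_000.0, 250.0)
        y = piecewise(t, 1599.0, 8073.0, 5000.0)
        fit = fit_two_phase(GrowthCurve(t, y), use_growth_window=False)
        assert not fit.degenerate
        assert fit.rates["r1"] == pytest.approx(1599.0, rel=1e-9)
        assert fit.rates["r2"] == pytest.approx(8073.0, rel=1e-9)
        assert fit.changepoint_s == pytest.approx(5000.0)

    def test_pure_line_degenerate(self):
        t = np.arange(0.0, 3000.0, 100.0)
        fit = fit_two_phase(GrowthCurve(t, 10.0 + 3.0 * t), use_growth_window=False)
        assert fit.degenerate
        assert fit.rates["r1"] == fit.rates["r2"] == pytest.approx(3.0)

    def test_too_few_points(self):
        t = np.arange(0.0, 5.0)
        with pytest.raises(FitError):
            fit_two_phase(GrowthCurve(t, t))

    def test_matches_brute_force_oracle_on_noisy_curves(self):
        rng = np.random.default_rng(3)
        for trial in range(20):
            n = int(rng.integers(12, 200))
            t = np.sort(rng.uniform(0, 10_000, n))
            t = np.unique(t)
            if len(t) < 12:
                continue
            tc = rng.uniform(t[4], t[-5])
            r1, r2 = rng.uniform(100, 5000, 2)
            y = piecewise(t, r1, r2, tc)
            y = np.maximum.accumulate(y + rng.normal(0, 1.0, len(t)))
            fit = fit_two_phase(
                GrowthCurve(t, y), use_growth_window=False, min_improvement=0.0
            )
            sse_o, tc_o, r1_o, r2_o = brute_force_two_phase(t, y)
            assert fit.changepoint_s == pytest.approx(tc_o)
            assert fit.rates["r1"] == pytest.approx(max(r1_o, 0.0), rel=1e-6, abs=1e-9)
            assert fit.rates["r2"] == pytest.approx(max(r2_o, 0.0), rel=1e-6, abs=1e-9)

    def test_changepoint_strictly_interior(self):
        t = np.arange(0.0, 5000.0, 100.0)
        y = piecewise(t, 100.0, 900.0, 2500.0)
        fit = fit_two_phase(GrowthCurve(t, y), use_growth_window=False)
        assert t[0] < fit.changepoint_s < t[-1]


class TestDetectTermination:
    def test_flat_after_t_term(self):
        t = np.arange(0.0, 12_000.0, 300.0)
        y = piecewise(t, 1170.0, 0.0, 7620.0)
        term = detect_termination(GrowthCurve(t, y), plateau_window_s=1200.0)
        assert term == pytest.approx(7620.0, abs=600.0)

    def test_linear_curve_never_terminates(self):
        t = np.arange(0.0, 6000.0, 300.0)
        term = detect_termination(GrowthCurve(t, 10.0 + 2.0 * t), 1200.0)
        assert term is None

    def test_all_flat_terminates_at_start(self):
        t = np.arange(0.0, 6000.0, 300.0)
        term = detect_termination(GrowthCurve(t, np.full(len(t), 7.0)), 1200.0)
        assert term == t[0]

    def test_window_validation(self):
        t = np.arange(0.0, 600.0, 300.0)
        with pytest.raises(ValueError):
            detect_termination(GrowthCurve(t, t), plateau_window_s=10_000.0)


class TestWelch:
    def test_identical_samples(self):
        t, p = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_zero_variance_equal_means(self):
        t, p = welch_t_test([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_closed_form_oracle(self):
        # independent oracle: Welch statistic and Satterthwaite df by hand
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 3.0, 4.0, 5.0])
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t_expected = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        from scipy import stats

        p_expected = 2 * stats.t.sf(abs(t_expected), df)
        t_obs, p_obs = welch_t_test(a, b)
        assert t_obs == pytest.approx(t_expected)  # -1.0954
        assert p_obs == pytest.approx(p_expected)  # 0.3153
        assert df == pytest.approx(6.0)

    def test_antisymmetry(self):
        a = [1.0, 2.0, 3.0]
        b = [4.0, 5.0, 7.0]
        t1, p1 = welch_t_test(a, b)
        t2, p2 = welch_t_test(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])


class TestSummarize:
    def one_fit(self, archetype, **rates):
        from aggrekin.kinetics import RateFit

        return RateFit(archetype=archetype, rates=rates)

    def test_mean_and_se(self):
        fits = [self.one_fit("isotropic", rx=v) for v in (1.0, 2.0, 3.0)]
        summary = summarize_condition(fits, "control")
        row = summary.table.query("rate_name == 'rx'").iloc[0]
        assert row["mean_rate_nm2_per_s"] == pytest.approx(2.0)
        assert row["se_nm2_per_s"] == pytest.approx(1.0 / np.sqrt(3.0))  # 0.577

    def test_single_fit_flagged(self):
        summary = summarize_condition([self.one_fit("small", r=5.0)], "c")
        row = summary.table.query("rate_name == 'r'").iloc[0]
        assert row["n"] == 1 and row["se_nm2_per_s"] == 0.0 and row["single_fit"]

    def test_empty_archetypes_reported(self):
        summary = summarize_condition([], "c")
        assert set(summary.table["archetype"]) == {"anisotropic", "isotropic", "small"}
        assert (summary.table["n"] == 0).all()

    def test_n_structure_conserved(self):
        # condition-level n-structure like 39 anisotropic / 16 isotropic / 2 small
        fits = (
            [self.one_fit("anisotropic", r1=1.0, r2=2.0)] * 39
            + [self.one_fit("isotropic", rx=3.0)] * 16
            + [self.one_fit("small", r=0.5)] * 2
        )
        summary = summarize_condition(fits, "control")
        per = summary.table.drop_duplicates("archetype").set_index("archetype")["n"]
        assert per["anisotropic"] == 39
        assert per["isotropic"] == 16
        assert per["small"] == 2
        assert summary.n_total() == len(fits)

    @given(
        ns=st.tuples(
            st.integers(0, 8), st.integers(0, 8), st.integers(0, 8)
        )
    )
    @settings(max_examples=20, deadline=None)
    def test_n_conservation_property(self, ns):
        na, ni, nsm = ns
        fits = (
            [self.one_fit("anisotropic", r1=1.0, r2=2.0)] * na
            + [self.one_fit("isotropic", rx=3.0)] * ni
            + [self.one_fit("small", r=0.5)] * nsm
        )
        assert summarize_condition(fits, "x").n_total() == len(fits)
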