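import numpy as np
import pandas as pd
import pytest

from aggrekin.simulate import (
    GrowthModel,
    ImagingModel,
    InvalidConfigError,
    simulate_aggregate,
    simulate_field_of_view,
    simulate_turbidity,
    turbidity_sigmoid,
)
from aggrekin.turbidity import estimate_lag


def imaging(**kw):
    base = dict(seed=11, n_frames=120, binding_rate_per_area=5e-6)
    base.update(kw)
    return ImagingModel(**base)


class TestGrowthModel:
    def test_invalid_configs(self):
        with pytest.raises(InvalidConfigError):
            GrowthModel("isotropic", rx=-1.0)
        with pytest.raises(InvalidConfigError):
            GrowthModel("anisotropic", r1=1.0, r2=1.0, t_switch=0.0)
        with pytest.raises(InvalidConfigError):
            GrowthModel("small", r_small=1.0, t_term=-5.0)
        with pytest.raises(InvalidConfigError):
            GrowthModel("bogus")
        with pytest.raises(InvalidConfigError):
            ImagingModel(n_frames=0)

    def test_isotropic_true_area_is_closed_form(self):
        # final area = pi r0^2 + rx * t
        m = GrowthModel("isotropic", rx=29_211.0, nucleus_radius=400.0)
        expected = np.pi * 400.0**2 + 29_211.0 * 3600.0
        assert m.true_area(3600.0) == pytest.approx(expected)
        # polygon oracle: the footprint's shapely area matches the law
        assert m.footprint(3600.0).area == pytest.approx(expected, rel=1e-3)

    def test_anisotropic_footprint_area_tracks_law(self):
        m = GrowthModel(
            "anisotropic", r1=1500.0, r2=6000.0, t_switch=2000.0, nucleus_radius=400.0
        )
        for t in (0.0, 500.0, 2000.0, 3000.0, 6000.0):
            assert m.footprint(t).area == pytest.approx(
                float(m.true_area(t)), rel=2e-3
            )

    def test_small_area_constant_after_termination(self):
        m = GrowthModel("small", r_small=1170.0, t_term=7620.0)
        a_term = float(m.true_area(7620.0))
        assert float(m.true_area(8000.0)) == a_term
        assert float(m.true_area(12_000.0)) == a_term

    def test_isotropic_slope_recovers_rx_within_2pct(self):
        m = GrowthModel("isotropic", rx=4000.0)
        t = np.linspace(0, 7200, 240)
        slope = np.polyfit(t, m.true_area(t), 1)[0]
        assert slope == pytest.approx(4000.0, rel=0.02)


class TestSimulateAggregate:
    def test_zero_growth_stays_at_origin(self):
        m = GrowthModel("isotropic", rx=0.0, nucleus_radius=400.0)
        table, _ = simulate_aggregate(m, imaging(), origin=(20_000.0, 20_000.0))
        r = np.linalg.norm(table.xy - [20_000.0, 20_000.0], axis=1)
        sigma = 20.0
        assert np.all(r <= 400.0 + 5 * sigma)
        assert np.mean(r <= 400.0 + 3 * sigma) > 0.95

    def test_small_events_rare_after_termination(self):
        m = GrowthModel("small", r_small=900.0, t_term=1800.0)
        table, _ = simulate_aggregate(m, imaging(n_frames=240), (20_000.0, 20_000.0))
        t = table.times_s
        pre_rate = (t <= 1800.0).sum() / 1800.0
        post_rate = (t > 1800.0).sum() / (240 * 30.0 - 1800.0)
        assert post_rate < 0.2 * pre_rate

    def test_nonpositive_frames_invalid(self):
        with pytest.raises(InvalidConfigError):
            ImagingModel(n_frames=-3)


class TestSimulateFieldOfView:
    def test_empty_mix_only_false_positives(self):
        table, truth = simulate_field_of_view(
            [], imaging(false_positive_rate=3.0)
        )
        assert len(table) > 0
        assert np.all(truth.aggregate_ids == 0)

    def test_distant_aggregates_are_disjoint(self):
        big = imaging(fov_size_nm=(100_000.0, 100_000.0), false_positive_rate=0.0)
        mix = [
            (GrowthModel("isotropic", rx=2000.0), (10_000.0, 10_000.0)),
            (GrowthModel("isotropic", rx=2000.0), (90_000.0, 90_000.0)),
        ]
        table, truth = simulate_field_of_view(mix, big)
        xy1 = table.xy[truth.aggregate_ids == 1]
        xy2 = table.xy[truth.aggregate_ids == 2]
        from scipy.spatial import cKDTree

        assert cKDTree(xy1).query(xy2, k=1)[0].min() > 10_000.0

    def test_determinism(self):
        mix = [(GrowthModel("isotropic", rx=2000.0), (20_000.0, 20_000.0))]
        t1, g1 = simulate_field_of_view(mix, imaging(false_positive_rate=1.0))
        t2, g2 = simulate_field_of_view(mix, imaging(false_positive_rate=1.0))
        pd.testing.assert_frame_equal(t1.data, t2.data)
        np.testing.assert_array_equal(g1.aggregate_ids, g2.aggregate_ids)

    def test_seed_changes_output(self):
        mix = [(GrowthModel("isotropic", rx=2000.0), (20_000.0, 20_000.0))]
        t1, _ = simulate_field_of_view(mix, imaging(seed=1))
        t2, _ = simulate_field_of_view(mix, imaging(seed=2))
        assert not t1.data.equals(t2.data)

    def test_event_count_conservation(self, benchmark_fov):
        table, truth = benchmark_fov
        non_noise = int((truth.aggregate_ids > 0).sum())
        assert non_noise == sum(
            truth.n_events(k) for k in truth.models
        )
        assert len(table) == non_noise + int((truth.aggregate_ids == 0).sum())

    def test_origin_outside_fov_rejected(self):
        mix = [(GrowthModel("isotropic", rx=0.0), (-5.0, 0.0))]
        with pytest.raises(InvalidConfigError):
            simulate_field_of_view(mix, imaging())

    def test_anisotropy_of_phase1_footprint(self):
        m = GrowthModel(
            "anisotropic", r1=1500.0, r2=6000.0, t_switch=3600.0, aspect_ratio_phase1=4.0
        )
        table, truth = simulate_aggregate(
            m, imaging(n_frames=120), (20_000.0, 20_000.0)
        )
        xy = table.xy[table.times_s > 2400.0]  # late phase 1
        ev = np.linalg.eigvalsh(np.cov(xy.T))
        assert np.sqrt(ev[1] / ev[0]) >= 4.0 - 1.5

    def test_isotropic_footprint_is_round(self, isotropic_acquisition):
        table, _ = isotropic_acquisition
        ev = np.linalg.eigvalsh(np.cov(table.xy.T))
        assert np.sqrt(ev[1] / ev[0]) == pytest.approx(1.0, abs=0.15)


class TestSimulateTurbidity:
    t_grid = np.arange(0.0, 600.0, 10.0)

    def test_noiseless_replicates_identical(self):
        d = simulate_turbidity(100.0, 0.08, 1.0, 0.0, self.t_grid, 3, seed=0)
        wide = d.pivot_table(index="time_min", columns="replicate", values="absorbance")
        assert np.allclose(wide[1], wide[2])
        assert np.allclose(wide[1], wide[3])

    def test_negative_plateau_invalid(self):
        with pytest.raises(InvalidConfigError):
            simulate_turbidity(100.0, 0.08, -1.0, 0.0, self.t_grid, 3)

    def test_zero_lag_boundary(self):
        d = simulate_turbidity(0.0, 0.08, 1.0, 0.0, self.t_grid, 1, seed=0)
        lag = estimate_lag(d["time_min"].to_numpy(), d["absorbance"].to_numpy())
        assert lag < 15.0

    def test_tangent_lag_of_generating_sigmoid(self):
        # closed-form oracle: steepest tangent of the logistic meets the
        # baseline at t0 - 2/k; the generator sets t0 = lag + 2/k.
        k, lag = 0.08, 160.0
        t0 = lag + 2.0 / k
        y = turbidity_sigmoid(self.t_grid, lag, k, 1.0)
        slope_max = 1.0 * k / 4.0
        tangent_zero = t0 - (1.0 / 2.0) / slope_max
        assert tangent_zero == pytest.approx(lag)
        est = estimate_lag(self.t_grid, y)
        assert est == pytest.approx(lag, abs=10.0)  # one grid step

    def test_replicate_count_validation(self):
        with pytest.raises(InvalidConfigError):
            simulate_turbidity(100.0, 0.08, 1.0, 0.0, self.t_grid, 0)
        with pytest.raises(InvalidConfigError):
            simulate_turbidity(100.0, 0.08, 1.0, 0.0, [10.0, 5.0], 2)
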