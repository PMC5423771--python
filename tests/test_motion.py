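"""Motion statistics: path length, speed, MSD, D, classes, modality."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import svtrack as sv
from svtrack.motion import (
    MSDCurve, apparent_d_floor, classify_length, classify_modality,
    compute_msd, estimate_d, max_speed, path_length, speed_length_correlation,
    summarize_tracks,
)
from svtrack.simulate import MotionModel

from _oracles import brute_force_msd


def track_df(pos, track_id=0):
    pos = np.asarray(pos, float)
    if pos.shape[1] == 2:
        pos = np.column_stack([pos, np.zeros(len(pos))])
    return pd.DataFrame({"track_id": track_id, "frame": np.arange(len(pos)),
                         "x_um": pos[:, 0], "y_um": pos[:, 1], "z_um": pos[:, 2]})


class TestPathAndSpeed:
    def test_stationary_track_has_zero_length_and_speed(self):
        pos = np.zeros((5, 2))
        assert path_length(pos) == 0.0
        assert max_speed(pos, 1.0) == 0.0

    def test_straight_run_arithmetic(self):
        pos = np.column_stack([np.arange(9) * 0.5, np.zeros(9)])
        assert path_length(pos) == pytest.approx(4.0)
        assert max_speed(pos, 1.0) == pytest.approx(0.5)

    def test_square_path_length_counts_full_perimeter(self):
        pos = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]], float)
        assert path_length(pos) == pytest.approx(4.0)
        # net displacement is zero although the path is 4 µm
        assert np.allclose(pos[0], pos[-1])

    def test_gate_limited_jump_gives_gate_speed(self):
        pos = np.array([[0, 0], [0.8, 0]], float)
        assert max_speed(pos, 1.0) == pytest.approx(0.8)

    def test_single_point_track_rejected(self):
        with pytest.raises(ValueError):
            path_length(np.zeros((1, 2)))
        with pytest.raises(ValueError):
            max_speed(np.zeros((1, 2)), 1.0)

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            max_speed(np.zeros((3, 2)), 0.0)


class TestMSD:
    def test_ballistic_track_msd_is_v_squared_tau_squared(self):
        v = 0.3
        pos = np.column_stack([np.arange(20) * v, np.zeros(20)])
        msd = compute_msd([pos], dt=1.0)
        np.testing.assert_allclose(msd.msd, (v * msd.lags) ** 2, atol=1e-12)

    def test_stationary_track_msd_is_zero(self):
        msd = compute_msd([np.zeros((10, 2))], dt=1.0)
        assert np.all(msd.msd == 0.0)
        assert msd.msd[0] == 0.0

    def test_pair_counts_non_increasing(self):
        rng = np.random.default_rng(0)
        msd = compute_msd([rng.normal(0, 1, (15, 2))], dt=1.0)
        assert np.all(np.diff(msd.n_pairs) <= 0)

    def test_vectorized_msd_equals_brute_force_pair_loop(self):
        """Oracle equivalence on 50 random tracks of up to 20 points."""
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(3, 21))
            pos = rng.normal(0, 0.5, (n, 2))
            msd = compute_msd([pos], dt=1.0)
            want, counts = brute_force_msd(pos, n - 1)
            np.testing.assert_allclose(msd.msd, want, rtol=1e-12, atol=1e-15)
            np.testing.assert_array_equal(msd.n_pairs, counts)

    def test_ensemble_pools_pairs_across_tracks(self):
        rng = np.random.default_rng(2)
        tracks = [rng.normal(0, 0.3, (int(rng.integers(6, 15)), 2)) for _ in range(5)]
        msd = compute_msd(tracks, dt=1.0)
        # pooled MSD at lag 1 equals the pair-weighted mean of per-track MSDs
        num = den = 0.0
        for pos in tracks:
            m, c = brute_force_msd(pos, 1)
            num += m[1] * c[1]
            den += c[1]
        assert msd.msd[1] == pytest.approx(num / den, rel=1e-12)


class TestEstimateD:
    def test_exact_2d_line_recovers_d(self):
        lags = np.arange(0, 6, dtype=float)
        curve = MSDCurve(lags, 4 * 0.05 * lags, np.full(6, 100), d=2)
        fit = estimate_d(curve)
        assert fit.d_coef == pytest.approx(0.05, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_exact_3d_line_recovers_d(self):
        lags = np.arange(0, 6, dtype=float)
        curve = MSDCurve(lags, 6 * 0.01 * lags, np.full(6, 100), d=3)
        assert estimate_d(curve).d_coef == pytest.approx(0.01, abs=1e-12)

    def test_negative_slope_clamped_to_zero_with_flag(self):
        lags = np.arange(0, 5, dtype=float)
        curve = MSDCurve(lags, 0.1 - 0.01 * lags, np.full(5, 10), d=2)
        fit = estimate_d(curve)
        assert fit.d_coef == 0.0
        assert fit.clamped

    def test_immobile_spots_with_noise_reproduce_apparent_floor(self):
        """σ_loc = 0.045 µm ⇒ MSD plateau 4σ² ≈ 0.0081 µm², the D floor
        reported for fixed terminals and beads."""
        from svtrack.experiments import noise_floor

        out = noise_floor(sigma_loc=0.045, seed=3)
        assert out["intercept"] == pytest.approx(4 * 0.045**2, rel=0.10)
        assert out["apparent_d"] == pytest.approx(0.008, abs=0.002)
        assert out["slope_d"] == pytest.approx(0.0, abs=5e-4)


class TestClassification:
    @pytest.mark.parametrize("length,cls", [
        (1.5, "S"), (0.0, "S"), (2.0, "M"), (3.9, "M"), (4.0, "L"), (6.0, "L"),
    ])
    def test_length_class_boundaries_half_open(self, length, cls):
        assert classify_length(length) == cls

    def test_ballistic_track_is_facilitated(self):
        pos = np.column_stack([np.arange(30) * 0.3, np.zeros(30)])
        label, alpha = classify_modality(pos, dt=1.0)
        assert label == "active_facilitated"
        assert alpha == pytest.approx(2.0, abs=0.01)

    def test_confined_track_is_impeded(self):
        # diffusion trapped in a 0.1 µm box: MSD saturates, alpha < 0.7
        rng = np.random.default_rng(4)
        pos = rng.uniform(0, 0.1, (40, 2))
        label, alpha = classify_modality(pos, dt=1.0)
        assert label == "active_impeded"
        assert alpha < 0.7

    def test_degenerate_track_flagged_impeded(self):
        label, alpha = classify_modality(np.zeros((10, 2)), dt=1.0)
        assert label == "active_impeded"
        assert np.isnan(alpha)

    def test_brownian_ensemble_mostly_classified_diffusive(self):
        m = MotionModel(d_free=0.03, active_fraction=0.0, switch_rates=(),
                        p_init_passive=(0.0, 1.0, 0.0))
        truth = sv.simulate_tracks(None, m, 200, 60, 1.0, seed=5)
        summ = summarize_tracks(truth.to_dataframe(), 1.0)
        frac_diffusive = (summ["modality"] == "diffusive").mean()
        assert frac_diffusive >= 0.8


class TestCorrelationAndDimensionality:
    def test_perfectly_proportional_gives_r_one(self):
        df = pd.DataFrame({"path_length": [1.0, 2.0, 3.0],
                           "max_speed": [0.1, 0.2, 0.3]})
        assert speed_length_correlation(df) == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        df = pd.DataFrame({"path_length": [1.0, 1.0, 1.0],
                           "max_speed": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError):
            speed_length_correlation(df)

    def test_active_mixture_correlates_speed_with_length(self, chain_geometry):
        truth = sv.simulate_tracks(chain_geometry, MotionModel(), 250, 30, 1.0, seed=6)
        summ = summarize_tracks(truth.to_dataframe(), 1.0)
        assert speed_length_correlation(summ) > 0.5

    def test_homogeneous_slow_population_weakens_correlation(self, chain_geometry):
        # with runs disabled and a single slow motion state, speed variation
        # is mostly localization noise and the length-speed coupling drops
        # below the active-mixture level
        m = MotionModel(d_free=0.0005, d_tethered=0.0005, active_fraction=0.0,
                        switch_rates=(), p_init_passive=(0.0, 1.0, 0.0))
        truth = sv.simulate_tracks(chain_geometry, m, 250, 30, 1.0, seed=7)
        df = truth.to_dataframe()
        rng = np.random.default_rng(9)
        df[["x_um", "y_um"]] += rng.normal(0, 0.03, (len(df), 2))
        summ = summarize_tracks(df, 1.0)
        assert speed_length_correlation(summ) < 0.5

    def test_2d_projection_and_3d_give_same_d_for_isotropic_motion(self):
        m = MotionModel(d_free=0.02, active_fraction=0.0, switch_rates=(),
                        p_init_passive=(0.0, 1.0, 0.0))
        truth = sv.simulate_tracks(None, m, 200, 30, 1.0, seed=8, ndim=3,
                                   z_halfdepth=50.0)
        df = truth.to_dataframe()
        d2 = estimate_d(compute_msd(df, 1.0, d=2)).d_coef
        d3 = estimate_d(compute_msd(df, 1.0, d=3)).d_coef
        assert d2 / d3 == pytest.approx(1.0, abs=0.1)


@given(st.floats(min_value=0.0, max_value=50.0))
def test_every_length_gets_exactly_one_class(length):
    assert classify_length(length) in {"S", "M", "L"}


def test_apparent_floor_requires_nonzero_lag():
    curve = MSDCurve(np.array([0.0]), np.array([0.0]), np.array([5]), d=2)
    with pytest.raises(ValueError):
        apparent_d_floor(curve)
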