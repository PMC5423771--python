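"""Region assignment, displacement direction, colocalization, AZ recruitment."""

import numpy as np
import pandas as pd
import pytest

import svtrack as sv
from svtrack.regions import (
    assign_tracks, az_recruitment, direction_proportions, pearson_colocalization,
)
from svtrack.simulate import MotionModel


def df_from_tracks(track_points):
    rows = []
    for tid, pts in track_points.items():
        for f, (x, y) in enumerate(pts):
            rows.append((tid, f, x, y, 0.0))
    return pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um", "z_um"])


class TestAssignTracks:
    def test_track_inside_one_swelling(self, chain_geometry):
        c0 = chain_geometry.swellings[0][0]
        tracks = df_from_tracks({0: [(c0[0], c0[1])] * 6})
        out = assign_tracks(tracks, chain_geometry)
        assert out.loc[0, "region"] == "swelling"
        assert out.loc[0, "occ_swelling"] == 1.0

    def test_majority_rule_labels_finger(self, chain_geometry):
        (p0, p1, _) = chain_geometry.fingers[0]
        mid = ((p0[0] + p1[0]) / 2, (p0[1] + p1[1]) / 2)
        c0 = chain_geometry.swellings[0][0]
        pts = [mid] * 7 + [c0] * 3
        out = assign_tracks(df_from_tracks({0: pts}), chain_geometry)
        assert out.loc[0, "region"] == "finger"
        assert out.loc[0, "occ_finger"] == pytest.approx(0.7)

    def test_occupancies_sum_to_one(self, chain_geometry):
        rng = np.random.default_rng(0)
        pts = [tuple(p) for p in rng.uniform(0, 10, (12, 2))]
        out = assign_tracks(df_from_tracks({0: pts}), chain_geometry)
        total = out[["occ_swelling", "occ_finger", "occ_outside"]].sum(axis=1)
        assert np.allclose(total, 1.0)

    def test_track_outside_mask_labeled_outside(self, chain_geometry):
        w, h = chain_geometry.fov
        out = assign_tracks(df_from_tracks({0: [(w - 0.01, h - 0.01)] * 5}),
                            chain_geometry)
        assert out.loc[0, "region"] == "outside"

    def test_imposed_region_d_ordering_recovered(self, chain_geometry):
        """Faster diffusion planted in fingers is recovered per region."""
        rng = np.random.default_rng(1)
        d_swell, d_finger = 0.004, 0.012

        def diffusing_tracks(center, d, ids):
            m = MotionModel(d_free=d, active_fraction=0.0, switch_rates=(),
                            p_init_passive=(0.0, 1.0, 0.0))
            truth = sv.simulate_tracks(None, m, len(ids), 20, 1.0,
                                       seed=int(rng.integers(2**31)))
            df = truth.to_dataframe()
            # recenter each short track on the target region
            for k, tid in enumerate(df["track_id"].unique()):
                sel = df["track_id"] == tid
                df.loc[sel, ["x_um", "y_um"]] -= df.loc[sel, ["x_um", "y_um"]].iloc[0]
                df.loc[sel, "x_um"] += center[0]
                df.loc[sel, "y_um"] += center[1]
            df["track_id"] = df["track_id"].map(dict(zip(df["track_id"].unique(), ids)))
            return df

        c0 = chain_geometry.swellings[0][0]
        (p0, p1, _) = chain_geometry.fingers[0]
        mid = ((p0[0] + p1[0]) / 2, (p0[1] + p1[1]) / 2)
        tracks = pd.concat([
            diffusing_tracks(c0, d_swell, range(0, 40)),
            diffusing_tracks(mid, d_finger, range(40, 80)),
        ], ignore_index=True)
        assign = assign_tracks(tracks, chain_geometry)
        d_est = {}
        for region in ("swelling", "finger"):
            ids = assign.loc[assign["region"] == region, "track_id"]
            sub = tracks[tracks["track_id"].isin(ids)]
            msd = sv.compute_msd(sub, 1.0, min_track_length=5)
            d_est[region] = sv.estimate_d(msd).d_coef
        assert d_est["finger"] > d_est["swelling"]
        assert d_est["finger"] / d_est["swelling"] == pytest.approx(
            d_finger / d_swell, rel=0.5)


class TestDirectionProportions:
    def test_all_tracks_along_normal_are_outward(self):
        tracks = df_from_tracks({i: [(i, 0.0), (i, 2.0)] for i in range(5)})
        out = direction_proportions(tracks, cleft_normal=(0.0, 1.0))
        assert out.outward_pct == 100.0
        assert out.n_classified == 5

    def test_isotropic_displacements_match_cone_measure(self):
        # 45° cones: outward and inward each cover 25% of angle, lateral 50%
        rng = np.random.default_rng(2)
        n = 4000
        theta = rng.uniform(0, 2 * np.pi, n)
        tracks = df_from_tracks({
            i: [(0.0, 0.0), (np.cos(th), np.sin(th))] for i, th in enumerate(theta)})
        out = direction_proportions(tracks, (0.0, 1.0), cone_halfangle=45.0)
        se = 100 * 3 * np.sqrt(0.25 * 0.75 / n)
        assert out.outward_pct == pytest.approx(25.0, abs=se)
        assert out.inward_pct == pytest.approx(25.0, abs=se)
        assert out.lateral_pct == pytest.approx(50.0, abs=2 * se)

    def test_stationary_tracks_are_excluded(self):
        tracks = df_from_tracks({0: [(1.0, 1.0)] * 4, 1: [(2.0, 2.0)] * 4})
        out = direction_proportions(tracks, (0.0, 1.0))
        assert out.n_classified == 0
        assert out.n_excluded == 2

    def test_zero_normal_rejected(self):
        tracks = df_from_tracks({0: [(0.0, 0.0), (1.0, 1.0)]})
        with pytest.raises(ValueError):
            direction_proportions(tracks, (0.0, 0.0))


class TestPearsonColocalization:
    def test_identical_channels_give_one(self, rng):
        img = rng.poisson(50, (40, 40)).astype(float)
        assert pearson_colocalization(img, img) == pytest.approx(1.0)

    def test_inverted_channel_gives_minus_one(self, rng):
        img = rng.poisson(50, (40, 40)).astype(float)
        assert pearson_colocalization(img, img.max() - img) == pytest.approx(-1.0)

    def test_symmetric_and_affine_invariant(self, rng):
        a = rng.normal(10, 2, (30, 30))
        b = rng.normal(10, 2, (30, 30))
        p = pearson_colocalization(a, b)
        assert pearson_colocalization(b, a) == pytest.approx(p, rel=1e-12)
        assert pearson_colocalization(3.0 * a + 7.0, b) == pytest.approx(p, rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_colocalization(np.ones((5, 5)), np.random.default_rng(0).normal(size=(5, 5)))

    def test_shared_positions_raise_colocalization(self, single_swelling_geometry):
        """Independent spot sets barely colocalize; sharing positions
        raises P — the newly-endocytosed-pool mixing readout."""
        g = single_swelling_geometry
        optics = sv.OpticsConfig(photons_per_spot=3000, background=10.0)
        m = MotionModel(d_free=0.0, d_tethered=0.0, v_run=0.0, active_fraction=0.0,
                        switch_rates=(), p_init_passive=(1.0, 0.0, 0.0))

        def render(seed):
            truth = sv.simulate_tracks(g, m, 25, 1, 1.0, seed=seed)
            return truth, sv.render_movie(truth, g, optics, seed=seed + 100).frames[0]

        t1, ch_a = render(seed=1)
        _, ch_indep = render(seed=2)
        ch_shared = sv.render_movie(t1, g, optics, seed=300).frames[0]
        mask = g.mask()
        p_indep = pearson_colocalization(ch_a, ch_indep, mask)
        p_shared = pearson_colocalization(ch_a, ch_shared, mask)
        assert p_indep < 0.4
        assert p_shared > 0.8
        assert p_shared > p_indep


class TestAzRecruitment:
    def test_identical_track_sets_fold_one(self):
        g = sv.build_terminal_geometry(2, seed=3, n_az=2)
        m = MotionModel()
        truth = sv.simulate_tracks(g, m, 40, 10, 1.0, seed=4)
        out = az_recruitment(truth.to_dataframe(), truth.to_dataframe(), g)
        assert out["fold_change"] == pytest.approx(1.0)

    def test_az_attraction_increases_inside_fraction_monotonically(self):
        g = sv.build_terminal_geometry(2, seed=5, n_az=2)
        m = MotionModel(active_fraction=0.0)
        fracs = []
        for bias in (0.0, 0.05, 0.15):
            truth = sv.simulate_tracks(g, m, 120, 30, 1.0, seed=6,
                                       az_attraction=bias)
            assign = assign_tracks(truth.to_dataframe(), g)
            fracs.append((assign["az_label"] == "az_in").mean())
        assert fracs[0] < fracs[1] < fracs[2]

    def test_empty_az_rejected(self, chain_geometry):
        tracks = df_from_tracks({0: [(1.0, 1.0), (1.1, 1.0)]})
        with pytest.raises(ValueError):
            az_recruitment(tracks, tracks, chain_geometry)
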