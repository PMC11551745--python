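import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smmtracks import (CellGeometry, TrackSet, classify_dwelling,
                       classify_tracks, density_map,
                       distance_probability_histogram, foci_from_dwelling,
                       nearest_focus_distances, preset, simulate_tracks,
                       standardize)
from smmtracks.track_io import FOCI_COLUMNS, TRACK_COLUMNS


def _trackset(per_track_xy, cell_ids=None, channel="green", delta_t=0.03):
    rows = []
    for tid, xy in enumerate(per_track_xy):
        cid = 0 if cell_ids is None else cell_ids[tid]
        for k, (x, y) in enumerate(xy):
            rows.append((cid, tid, channel, k, x, y))
    return TrackSet(pd.DataFrame(rows, columns=TRACK_COLUMNS), delta_t)


class TestStandardize:
    def test_center_and_poles(self):
        g = CellGeometry(2.5, 0.5, center=(1.0, 2.0), orientation=0.0)
        pts = np.array([[1.0, 2.0], [1.0 + 1.25, 2.0], [1.0 - 1.25, 2.0]])
        norm, dropped = standardize(pts, g)
        assert dropped == 0
        np.testing.assert_allclose(norm, [[0, 0], [0.5, 0], [-0.5, 0]],
                                   atol=1e-12)

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(0)
        g0 = CellGeometry(2.5, 0.5)
        pts = g0.sample_uniform(rng, 200)
        norm0, _ = standardize(pts, g0)
        theta, shift = 1.1, np.array([3.0, -2.0])
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        g1 = CellGeometry(2.5, 0.5, center=tuple(shift), orientation=theta)
        norm1, _ = standardize(pts @ R.T + shift, g1)
        np.testing.assert_allclose(norm1, norm0, atol=1e-9)

    def test_far_outside_points_dropped(self):
        g = CellGeometry(2.5, 0.5)
        pts = np.array([[0.0, 0.0], [5.0, 5.0]])
        norm, dropped = standardize(pts, g)
        assert dropped == 1 and len(norm) == 1


class TestDensityMap:
    def test_total_mass_one_and_central_peak(self):
        ts = _trackset([[(0.0, 0.0)] * 20])
        geoms = {0: CellGeometry(2.5, 0.5)}
        cmap = density_map(ts, geoms, grid_shape=(21, 11),
                           smooth_sigma_bins=0)
        assert cmap.density.sum() == pytest.approx(1.0)
        assert cmap.density[10, 5] == pytest.approx(1.0)

    def test_uniform_scanning_fills_interior(self):
        cfg = preset("wildtype", seed=3, n_cells=30, anchor_fraction=0.0)
        tracks, _ = simulate_tracks(cfg)
        geoms = {c: cfg.geometry for c in range(cfg.n_cells)}
        cmap = density_map(tracks, geoms, grid_shape=(20, 10))
        # central band should hold mass roughly proportional to its area
        mid = cmap.density[5:15, :].sum()
        assert 0.3 < mid < 0.75

    def test_polar_anchoring_shifts_mass_poleward(self):
        kw = dict(n_cells=40, n_frames=150, seed=6)
        anchored = preset("target_plasmid", polar_bias=1.0,
                          anchor_fraction=1.0, **kw)
        uniform = preset("nontarget_plasmid", **kw)
        geoms = {c: anchored.geometry for c in range(40)}

        def polar_mass(cfg):
            tracks, _ = simulate_tracks(cfg)
            cmap = density_map(tracks, geoms, grid_shape=(20, 10))
            return cmap.density[:5, :].sum() + cmap.density[15:, :].sum()

        assert polar_mass(anchored) > polar_mass(uniform)


class TestDwelling:
    def test_stationary_track_static(self):
        xy = np.zeros((10, 2))
        assert classify_dwelling(xy, 0.09, 0.8) == "static"

    def test_fast_directed_track_mobile(self):
        xy = np.column_stack([np.linspace(0, 0.9 * 10, 10), np.zeros(10)])
        assert classify_dwelling(xy, 0.09, 0.8) == "mobile"

    def test_simulated_populations_classified_correctly(self):
        # bound (tethered) slow molecules vs freely diffusing mobile ones
        cfg = preset("dnax_nontarget", seed=9, n_cells=40,
                     anchor_fraction=1.0)
        tracks, truth = simulate_tracks(cfg)
        labels = classify_tracks(tracks)
        merged = labels.merge(truth.molecules, on=["cell_id", "track_id"])
        # slow population (index 0) -> static, mobile population -> mobile
        expect = np.where(merged["population"] == 0, "static", "mobile")
        agree = np.mean(merged["label"].to_numpy() == expect)
        assert agree >= 0.90


class TestFociFromDwelling:
    def test_single_static_track_centroid(self):
        xy = [(0.50, 0.20)] * 8
        ts = _trackset([xy])
        foci = foci_from_dwelling(ts)
        assert len(foci) == 1
        assert foci.loc[0, "x_um"] == pytest.approx(0.50)
        assert foci.loc[0, "y_um"] == pytest.approx(0.20)

    def test_distant_tracks_stay_separate(self):
        ts = _trackset([[(0.0, 0.0)] * 8, [(1.0, 0.0)] * 8])
        foci = foci_from_dwelling(ts, merge_radius=0.15)
        assert len(foci) == 2

    def test_close_tracks_merge(self):
        ts = _trackset([[(0.0, 0.0)] * 8, [(0.05, 0.0)] * 8])
        foci = foci_from_dwelling(ts, merge_radius=0.15)
        assert len(foci) == 1
        assert foci.loc[0, "x_um"] == pytest.approx(0.025)

    def test_recovers_simulated_focus_positions(self):
        cfg = preset("dnax_target", seed=15, n_cells=12, n_foci=1,
                     anchor_fraction=1.0, anchor_radius=0.08)
        tracks, truth = simulate_tracks(cfg)
        anchored_ids = truth.molecules.loc[
            truth.molecules["anchor_focus_id"] >= 0, ["cell_id", "track_id"]]
        sub = tracks.df.merge(anchored_ids, on=["cell_id", "track_id"])
        foci = foci_from_dwelling(TrackSet(sub, cfg.delta_t),
                                  confinement_radius=0.12)
        hits = 0
        total = 0
        for cid, fgroup in truth.foci.groupby("cell_id"):
            est = foci[foci["cell_id"] == cid]
            if est.empty:
                continue
            for _, f in fgroup.iterrows():
                d = np.hypot(est["x_um"] - f["x_um"], est["y_um"] - f["y_um"])
                total += 1
                if d.min() < 0.1:
                    hits += 1
        assert total > 0 and hits / total >= 0.8


class TestNearestFocusDistances:
    def test_345_triangle(self):
        ts = _trackset([[(3.0, 4.0)] * 6])
        foci = pd.DataFrame([(0, 0, 0.0, 0.0)], columns=FOCI_COLUMNS)
        out = nearest_focus_distances(ts, foci)
        np.testing.assert_allclose(out["distance_um"], 5.0)
        assert len(out) == 5  # five points per track

    def test_coincident_point(self):
        ts = _trackset([[(0.2, 0.3)] * 6])
        foci = pd.DataFrame([(0, 0, 0.2, 0.3)], columns=FOCI_COLUMNS)
        out = nearest_focus_distances(ts, foci)
        np.testing.assert_allclose(out["distance_um"], 0.0, atol=1e-12)

    def test_cell_without_foci_skipped(self):
        ts = _trackset([[(0.0, 0.0)] * 6, [(1.0, 1.0)] * 6], cell_ids=[0, 1])
        foci = pd.DataFrame([(0, 0, 0.0, 0.0)], columns=FOCI_COLUMNS)
        out = nearest_focus_distances(ts, foci)
        assert set(out["cell_id"]) == {0}

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_tracks = rng.integers(1, 5)
        n_foci = rng.integers(1, 21)
        trajs = [rng.uniform(-2, 2, (rng.integers(5, 12), 2))
                 for _ in range(n_tracks)]
        ts = _trackset([list(map(tuple, t)) for t in trajs])
        foci = pd.DataFrame(
            [(0, i, *rng.uniform(-2, 2, 2)) for i in range(n_foci)],
            columns=FOCI_COLUMNS)
        out = nearest_focus_distances(ts, foci, points_per_track=5)
        fxy = foci[["x_um", "y_um"]].to_numpy()
        expected = []
        for t in trajs:
            for p in t[:5]:
                expected.append(np.min(np.hypot(fxy[:, 0] - p[0],
                                                fxy[:, 1] - p[1])))
        np.testing.assert_allclose(np.sort(out["distance_um"]),
                                   np.sort(expected), atol=1e-12)

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(-1, 1, (6, 2))
        f = rng.uniform(-1, 1, (3, 2))
        ts = _trackset([list(map(tuple, pts))])
        foci = pd.DataFrame([(0, i, *f[i]) for i in range(3)],
                            columns=FOCI_COLUMNS)
        d0 = nearest_focus_distances(ts, foci)["distance_um"].to_numpy()
        th = 0.8
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        shift = np.array([2.0, -1.0])
        ts2 = _trackset([list(map(tuple, pts @ R.T + shift))])
        foci2 = pd.DataFrame([(0, i, *(f[i] @ R.T + shift))
                              for i in range(3)], columns=FOCI_COLUMNS)
        d1 = nearest_focus_distances(ts2, foci2)["distance_um"].to_numpy()
        np.testing.assert_allclose(d1, d0, atol=1e-9)


class TestDistanceHistogram:
    def test_identical_distances_single_bin(self):
        h = distance_probability_histogram(np.full(50, 0.25), bin_width=0.1)
        assert h.probability.sum() == pytest.approx(1.0)
        assert h.probability.max() == pytest.approx(1.0)

    def test_probability_normalized(self):
        rng = np.random.default_rng(1)
        h = distance_probability_histogram(rng.uniform(0, 2, 1000))
        assert h.probability.sum() == pytest.approx(1.0)

    def test_target_condition_concentrates_near_foci(self):
        # anchored (target) tracks should sit closer to foci than free ones
        kw = dict(n_cells=40, seed=19)
        tgt_cfg = preset("target_plasmid", anchor_fraction=0.9, **kw)
        nt_cfg = preset("nontarget_plasmid", **kw)

        def near_mass(cfg):
            tracks, truth = simulate_tracks(cfg)
            d = nearest_focus_distances(tracks, truth.foci)
            h = distance_probability_histogram(d["distance_um"].to_numpy(),
                                               bin_width=0.1)
            return h.probability[:2].sum()  # mass within 0.2 μm

        assert near_mass(tgt_cfg) > near_mass(nt_cfg)
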