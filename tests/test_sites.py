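"""Site assembly, residence kinetics, binding modes, selectivity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cholmap.density import DensityGrid, Hotspot
from cholmap.sites import (InteractionSite, classify_topology,
                           count_binding_modes, estimate_mean_dwell,
                           match_outliers_to_hotspots, merge_event_lists,
                           min_distance_timeseries, reference_bound_pose,
                           residence_events, rmsd_series, site_selectivity,
                           summarize_site)


class TestResidenceEvents:
    def test_hand_traced_series(self):
        """[3,5,8,9,12,4,11] at cutoffs 6/10.8: bound frames {0..3} and {5}."""
        evs = residence_events(np.array([3, 5, 8, 9, 12, 4, 11.0]), dt=1.0)
        assert [e.duration for e in evs] == [4.0, 1.0]
        assert [e.start_frame for e in evs] == [0, 5]
        assert not any(e.censored for e in evs)

    def test_always_unbound(self):
        assert residence_events(np.full(20, 12.0), dt=1.0) == []

    def test_always_bound_single_censored_event(self):
        evs = residence_events(np.full(15, 3.0), dt=2.0)
        assert len(evs) == 1
        assert evs[0].duration == 30.0 and evs[0].censored

    def test_band_entry_does_not_start_event(self):
        # values between the cutoffs never trigger binding
        evs = residence_events(np.array([8.0, 9.0, 10.0, 7.0]), dt=1.0)
        assert evs == []

    def test_non_finite_rmsd_raises(self):
        with pytest.raises(ValueError):
            residence_events(np.array([3.0, np.nan]), dt=1.0)

    def test_invalid_cutoffs(self):
        with pytest.raises(ValueError):
            residence_events(np.array([1.0]), dt=1.0, bound_cutoff=6,
                             unbound_cutoff=6)

    @settings(max_examples=200, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_widening_band_never_shortens_events(self, seed):
        """Hysteresis guarantee: every event at (6, 6+eps) lies inside an
        event at (6, 10.8) with at least that duration."""
        rng = np.random.default_rng(seed)
        series = rng.uniform(0, 15, size=30)
        narrow = residence_events(series, dt=1.0, bound_cutoff=6.0,
                                  unbound_cutoff=6.0 + 1e-9)
        wide = residence_events(series, dt=1.0, bound_cutoff=6.0,
                                unbound_cutoff=10.8)
        for ne in narrow:
            host = [w for w in wide if w.start_frame <= ne.start_frame
                    and w.end_frame >= ne.end_frame]
            assert len(host) == 1
            assert host[0].duration >= ne.duration

    def test_split_halves_no_straddling_event(self):
        series = np.array([3, 3, 12, 12, 3, 3, 12.0, 12.0])
        full = residence_events(series, dt=1.0)
        a = residence_events(series[:4], dt=1.0)
        b = residence_events(series[4:], dt=1.0, time_origin=4.0)
        merged = merge_event_lists(a, b)
        assert [e.duration for e in merged] == [e.duration for e in full]

    def test_split_halves_straddling_event_merges(self):
        series = np.array([12, 3, 3, 3, 3, 3, 12.0, 12.0])
        full = residence_events(series, dt=1.0)
        a = residence_events(series[:4], dt=1.0)
        b = residence_events(series[4:], dt=1.0, time_origin=4.0)
        merged = merge_event_lists(a, b)
        assert len(full) == len(merged) == 1
        assert merged[0].duration == full[0].duration
        assert not merged[0].censored

    def test_survival_consistent_with_exponential_dwell(self):
        """Event durations built from an exponential dwell pass a KS test
        against the planted rate."""
        from scipy import stats as sps
        rng = np.random.default_rng(77)
        dt, tau = 1.0, 40.0
        durations = []
        series = []
        # build a long synthetic RMSD trace with known bound spans
        for _ in range(200):
            dwell = max(1, int(round(rng.exponential(tau))))
            series.extend([2.0] * dwell + [12.0] * 3)
            durations.append(dwell)
        evs = residence_events(np.array(series), dt=dt)
        obs = np.array([e.duration for e in evs if not e.censored])
        ks = sps.kstest(obs, "expon", args=(0, obs.mean()))
        assert ks.pvalue > 0.01


class TestReferencePose:
    def _grid_with_peak(self, peak_at):
        counts = np.zeros((20, 20, 20), dtype=np.int64)
        counts[peak_at] = 100
        return DensityGrid(np.zeros(3), 1.0, counts, 1, 0.1)

    def test_parked_lipid_pose_and_zero_rmsd(self):
        grid = self._grid_with_peak((5, 5, 5))
        coords = np.tile(np.array([[[5.5, 5.5, 5.5]]]), (10, 1, 1))
        pose, frame = reference_bound_pose(coords, grid)
        assert frame == 0  # earliest tie wins
        assert np.allclose(rmsd_series(coords, pose), 0.0)

    def test_lipid_never_in_density_returns_none(self):
        grid = self._grid_with_peak((5, 5, 5))
        coords = np.tile(np.array([[[15.5, 15.5, 15.5]]]), (4, 1, 1))
        pose, frame = reference_bound_pose(coords, grid)
        assert pose is None and frame == -1

    def test_two_sites_give_distinct_poses(self):
        counts = np.zeros((20, 20, 20), dtype=np.int64)
        counts[3, 3, 3] = 50
        counts[15, 15, 15] = 50
        grid = DensityGrid(np.zeros(3), 1.0, counts, 1, 0.1)
        coords = np.concatenate([
            np.tile(np.array([[[3.5, 3.5, 3.5]]]), (5, 1, 1)),
            np.tile(np.array([[[15.5, 15.5, 15.5]]]), (5, 1, 1))])
        vox_a = np.array([[3, 3, 3]])
        vox_b = np.array([[15, 15, 15]])
        pose_a, fa = reference_bound_pose(coords, grid, voxels=vox_a)
        pose_b, fb = reference_bound_pose(coords, grid, voxels=vox_b)
        assert not np.allclose(pose_a, pose_b)
        assert fa == 0 and fb == 5


class TestTopologyAndSummary:
    def test_single_segment_window_is_linear(self):
        site = InteractionSite("L", [265, 267, 268, 272], [], [])
        segmap = {r: "TM4" for r in range(260, 280)}
        assert classify_topology(site, segmap) == "linear"

    def test_three_segments_is_non_linear(self):
        site = InteractionSite("K", [10, 110, 210], [], [])
        segmap = {10: "TM2", 110: "TM6", 210: "TM7"}
        assert classify_topology(site, segmap) == "non-linear"

    def test_single_residue_is_linear(self):
        site = InteractionSite("X", [42], [], [])
        assert classify_topology(site, {42: "TM1"}) == "linear"

    def test_wide_span_on_one_segment_is_non_linear(self):
        site = InteractionSite("Y", [5, 40], [], [])
        segmap = {5: "TM1", 40: "TM1"}
        assert classify_topology(site, segmap, window=10) == "non-linear"

    def test_unannotated_residue_raises(self):
        site = InteractionSite("Z", [1, 2], [], [])
        with pytest.raises(KeyError):
            classify_topology(site, {1: "TM1"})

    def _event(self, dur_ns, lipid=1, censored=False):
        from cholmap.sites import ResidenceEvent
        return ResidenceEvent(lipid, "s", 0.0, dur_ns, dur_ns, 0,
                              int(dur_ns), censored)

    def test_summary_counts_and_threshold(self):
        evs = {"d1": [self._event(500.0, 1), self._event(1500.0, 2),
                      self._event(3000.0, 2)]}
        s = summarize_site(evs, threshold_specific_us=1.0)
        assert s.n_events_total == 3
        assert s.n_events_gt_threshold == 2
        assert s.max_residence_us == pytest.approx(3.0)
        assert s.mean_visiting_lipids == 2.0

    def test_summary_single_event(self):
        s = summarize_site({"d": [self._event(2300.0)]})
        assert s.max_residence_us == pytest.approx(2.3)
        assert s.n_events_total == 1 and s.n_events_gt_threshold == 1

    def test_mean_dwell_estimator_recovers_exponential_mean(self):
        rng = np.random.default_rng(5)
        evs = [self._event(d) for d in rng.exponential(1000.0, 400)]
        evs += [self._event(d) for d in rng.exponential(20.0, 2000)]  # grazing
        tau, n = estimate_mean_dwell(evs, floor_ns=200.0)
        assert tau == pytest.approx(1000.0, rel=0.15)
        assert n >= 200


class TestBindingModes:
    def test_identical_poses_one_confident_mode(self):
        poses = np.tile(np.arange(12.0).reshape(1, 4, 3), (50, 1, 1))
        n, low = count_binding_modes(poses)
        assert n == 1 and not low

    def test_two_orientations_two_modes(self):
        base = np.arange(12.0).reshape(4, 3)
        rot = np.array([[0.0, -1, 0], [1.0, 0, 0], [0, 0, 1.0]])
        rotated = base @ rot.T
        poses = np.concatenate([np.tile(base, (30, 1, 1)),
                                np.tile(rotated, (30, 1, 1))])
        n, low = count_binding_modes(poses, cluster_rmsd=4.0)
        assert n == 2 and not low

    def test_noise_poses_flagged_low_confidence(self):
        rng = np.random.default_rng(6)
        poses = rng.uniform(0, 100, size=(200, 4, 3))
        n, low = count_binding_modes(poses, cluster_rmsd=4.0)
        assert low


class TestMinDistanceSeries:
    def test_identical_groups_zero(self):
        from conftest import build_system
        res = np.array([[5.0, 5, 5], [7.0, 5, 5]])
        lip = np.zeros((3, 1, 3)) + 20.0
        topo, traj = build_system(res, lip)
        d = min_distance_timeseries(traj, [0, 1], [0, 1])
        assert np.allclose(d, 0.0)

    def test_symmetric_and_matches_brute_force(self):
        from conftest import random_toy_system
        rng = np.random.default_rng(7)
        topo, traj = random_toy_system(rng, n_frames=6, n_res=4, n_lip=5)
        a = [0, 1]
        b = [5, 6, 7]
        d1 = min_distance_timeseries(traj, a, b)
        d2 = min_distance_timeseries(traj, b, a)
        assert np.allclose(d1, d2)
        from cholmap.core import pairwise_min_image_distances
        for f in range(traj.n_frames):
            brute = pairwise_min_image_distances(
                traj.coords[f][a], traj.coords[f][b], traj.box[f]).min()
            assert d1[f] == pytest.approx(brute)


class TestMatchingAndSelectivity:
    def _hotspot(self, hid, center, peak=100.0):
        vox = np.array([[int(c) for c in center]])
        return Hotspot(hid, vox, peak, np.asarray(center, dtype=float) + 0.5,
                       1.0)

    def _topo_ref(self):
        from cholmap.core import BeadTopology, Lipid, Residue
        residues = [Residue(i + 1, "ALA", "A", (i,), True, i + 1)
                    for i in range(4)]
        lipids = [Lipid(10, "CHOL", (4,))]
        topo = BeadTopology(residues, lipids, 5)
        ref = np.array([[5.0, 5, 5], [30.0, 30, 30], [31.0, 30, 30],
                        [50.0, 50, 50], [0.0, 0, 0]])
        return topo, ref

    def test_hotspot_in_two_of_three_systems_excluded(self):
        topo, ref = self._topo_ref()
        grid = DensityGrid(np.zeros(3), 1.0,
                           np.zeros((60, 60, 60), dtype=np.int64), 1, 0.1)
        hs = {
            "SYS1": [self._hotspot(1, (5, 5, 5)), self._hotspot(2, (30, 30, 30))],
            "SYS2": [self._hotspot(1, (5, 5, 5)), self._hotspot(2, (30, 30, 30))],
            "SYS3": [self._hotspot(1, (5, 5, 5))],
        }
        outliers = pd.DataFrame({"residue": [1, 2], "tmax_ns": [2000.0, 1500.0]})
        sites, cands, nonrep = match_outliers_to_hotspots(
            outliers, hs, grid, topo, ref, site_merge_radius=5.0)
        assert len(sites) == 1
        assert sites[0].residue_ids == [1]
        assert {h.id for _, h in nonrep} == {2}

    def test_outlier_inside_hotspot_matches_any_radius(self):
        topo, ref = self._topo_ref()
        grid = DensityGrid(np.zeros(3), 1.0,
                           np.zeros((60, 60, 60), dtype=np.int64), 1, 0.1)
        hs = {"SYS1": [self._hotspot(1, (5, 5, 5))]}
        outliers = pd.DataFrame({"residue": [1], "tmax_ns": [2000.0]})
        sites, _, _ = match_outliers_to_hotspots(outliers, hs, grid, topo, ref,
                                                 match_radius=1.0)
        assert sites and sites[0].outlier_ids == [1]

    def test_candidate_without_outlier_is_unranked(self):
        topo, ref = self._topo_ref()
        grid = DensityGrid(np.zeros(3), 1.0,
                           np.zeros((60, 60, 60), dtype=np.int64), 1, 0.1)
        hs = {"SYS1": [self._hotspot(1, (30, 30, 30))]}
        outliers = pd.DataFrame({"residue": [], "tmax_ns": []})
        sites, cands, _ = match_outliers_to_hotspots(outliers, hs, grid, topo,
                                                     ref)
        assert sites == [] and len(cands) == 1
        assert not cands[0].ranked and cands[0].name == "U1"

    def _selectivity_inputs(self, pc_density):
        site = InteractionSite("S1", [1, 2], [1], [],
                               member_voxels=np.array([[1, 1, 1], [1, 1, 2]]))
        counts_ch = np.zeros((4, 4, 4), dtype=np.int64)
        counts_ch[1, 1, 1] = counts_ch[1, 1, 2] = 100
        counts_pc = np.zeros((4, 4, 4), dtype=np.int64)
        counts_pc[1, 1, 1] = counts_pc[1, 1, 2] = pc_density
        grids = {
            "CHOL": DensityGrid(np.zeros(3), 1.0, counts_ch, 10, 0.1),
            "PC": DensityGrid(np.zeros(3), 1.0, counts_pc, 10, 0.1),
        }
        prof = pd.DataFrame(
            [(1, "CHOL", 900.0, True), (2, "CHOL", 700.0, True),
             (1, "PC", 30.0, True), (2, "PC", 10.0, True)],
            columns=["residue", "species", "mean_tmax_ns", "contacted"],
        ).set_index(["residue", "species"])
        return site, prof, grids

    def test_zero_phospholipid_density_is_non_annular(self):
        site, prof, grids = self._selectivity_inputs(pc_density=0)
        rep = site_selectivity(site, prof, grids)
        assert rep["non_annular"]
        assert rep["species"]["CHOL"]["mean_tmax_ns"] == pytest.approx(800.0)

    def test_equal_density_is_annular(self):
        site, prof, grids = self._selectivity_inputs(pc_density=100)
        rep = site_selectivity(site, prof, grids)
        assert not rep["non_annular"]
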