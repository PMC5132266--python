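"""Topology/trajectory I/O, periodic distances and superposition."""

import numpy as np
import pytest

from cholmap.core import (fit_frame, min_image_distance, read_topology,
                          read_trajectory, write_gro, fit_trajectory)
from cholmap.errors import (EmptyTrajectoryError, FormatError,
                            IllConditionedFitError, TopologyMismatchError,
                            TriclinicBoxError)
from cholmap.synthetic import generate_system, study_spec, write_fixture


@pytest.fixture(scope="module")
def fixture_dir(tmp_path_factory):
    spec = study_spec(0.20, seed=11, n_frames=5, n_lipids=60)
    topo, traj, gt = generate_system(spec)
    outdir = tmp_path_factory.mktemp("fixture")
    paths = write_fixture(topo, traj, outdir, ground_truth=gt, spec=spec)
    return {"paths": paths, "topo": topo, "traj": traj}


class TestReadTopology:
    def test_round_trip_counts_and_species(self, fixture_dir):
        p = fixture_dir["paths"]
        topo = read_topology(p["topology"], monomers=p["monomers"],
                             membrane_facing=p["membrane_facing"])
        orig = fixture_dir["topo"]
        assert len(topo.residues) == len(orig.residues)
        assert len(topo.lipids) == len(orig.lipids)
        assert topo.n_beads == orig.n_beads
        assert topo.species_counts() == orig.species_counts()
        # POPE resname classifies as PE, DSPC as PC
        assert {l.species for l in topo.lipids} == {"CHOL", "PC", "PE"}

    def test_monomer_partition_and_seq_ids(self, fixture_dir):
        p = fixture_dir["paths"]
        topo = read_topology(p["topology"], monomers=p["monomers"])
        assert topo.monomer_labels == ["A", "B"]
        seqs_a = sorted(r.seq_id for r in topo.monomer_residues("A"))
        seqs_b = sorted(r.seq_id for r in topo.monomer_residues("B"))
        assert seqs_a == seqs_b  # positions are comparable across monomers

    def test_unknown_resname_becomes_other(self, tmp_path, caplog):
        gro = tmp_path / "odd.gro"
        gro.write_text(
            "t\n    2\n"
            "    1ALA    BB    1   1.000   1.000   1.000\n"
            "    2XXXX   R1    2   2.000   2.000   2.000\n"
            "  10.0  10.0  10.0\n")
        topo = read_topology(gro)
        assert topo.lipids[0].species == "OTHER"

    def test_empty_file_is_format_error(self, tmp_path):
        empty = tmp_path / "empty.gro"
        empty.write_text("")
        with pytest.raises(FormatError):
            read_topology(empty)

    def test_unparseable_record_names_line(self, tmp_path):
        gro = tmp_path / "bad.gro"
        gro.write_text("t\n    1\n"
                       "    1ALA    BB    1   xxx   1.000   1.000\n"
                       "  10.0  10.0  10.0\n")
        with pytest.raises(FormatError, match="line 3"):
            read_topology(gro)


class TestReadTrajectory:
    def _write(self, path, n_frames, dt_ns, n_beads=3, box=(10.0, 10.0, 10.0)):
        coords = np.tile(np.arange(n_beads, dtype=float)[:, None], (1, 3))
        frames = np.repeat(coords[None], n_frames, axis=0)
        write_gro(path, [1] * n_beads, ["ALA"] * n_beads, ["BB"] * n_beads,
                  frames, np.asarray(box),
                  times=[i * dt_ns for i in range(n_frames)])

    def test_discard_initial(self, tmp_path):
        path = tmp_path / "t.gro"
        self._write(path, 10, 100.0)
        topo = read_topology(path)
        traj = read_trajectory(path, topo, discard_initial=500.0)
        assert traj.n_frames == 5
        assert traj.times[0] == pytest.approx(500.0)

    def test_discard_zero_keeps_all(self, tmp_path):
        path = tmp_path / "t.gro"
        self._write(path, 10, 100.0)
        topo = read_topology(path)
        assert read_trajectory(path, topo).n_frames == 10

    def test_discard_everything_raises(self, tmp_path):
        path = tmp_path / "t.gro"
        self._write(path, 4, 10.0)
        topo = read_topology(path)
        with pytest.raises(EmptyTrajectoryError):
            read_trajectory(path, topo, discard_initial=1e6)

    def test_bead_count_mismatch(self, tmp_path, fixture_dir):
        path = tmp_path / "t.gro"
        self._write(path, 3, 10.0)
        with pytest.raises(TopologyMismatchError):
            read_trajectory(path, fixture_dir["topo"], dt=10.0)

    def test_triclinic_rejected(self, tmp_path):
        gro = tmp_path / "tri.gro"
        gro.write_text("t\n    1\n"
                       "    1ALA    BB    1   1.000   1.000   1.000\n"
                       "  10.0 10.0 10.0 0.0 0.0 5.0 0.0 0.0 0.0\n")
        with pytest.raises(TriclinicBoxError):
            read_topology(gro)

    def test_round_trip_coordinates(self, fixture_dir):
        p = fixture_dir["paths"]
        topo = read_topology(p["topology"], monomers=p["monomers"])
        traj = read_trajectory(p["trajectory"], topo, discard_initial=0.0)
        orig = fixture_dir["traj"]
        assert traj.n_frames == orig.n_frames
        assert traj.dt == pytest.approx(orig.dt)
        # GRO stores nm with 3 decimals: 0.005 Å round-trip precision
        assert np.abs(traj.coords - orig.coords).max() < 0.006


class TestMinImage:
    def test_identity(self):
        box = np.array([10.0, 10.0, 10.0])
        assert min_image_distance(np.ones(3), np.ones(3), box) == 0.0

    def test_wrap_around(self):
        box = np.array([100.0, 100.0, 100.0])
        d = min_image_distance(np.array([1.0, 0, 0]), np.array([99.0, 0, 0]), box)
        assert d == pytest.approx(2.0)

    def test_against_27_image_enumeration(self):
        rng = np.random.default_rng(0)
        box = np.array([17.0, 23.0, 9.0])
        shifts = np.array([(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                           for k in (-1, 0, 1)], dtype=float) * box
        for _ in range(200):
            a = rng.uniform(-30, 60, 3) % box
            b = rng.uniform(-30, 60, 3) % box
            brute = np.min(np.linalg.norm(b + shifts - a, axis=1))
            assert min_image_distance(a, b, box) == pytest.approx(brute)

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(1)
        box = np.array([12.0, 12.0, 12.0])
        for _ in range(100):
            a, b, c = rng.uniform(0, 12, (3, 3))
            dab = min_image_distance(a, b, box)
            assert dab == pytest.approx(min_image_distance(b, a, box))
            assert dab <= (min_image_distance(a, c, box)
                           + min_image_distance(c, b, box) + 1e-9)


class TestFitFrame:
    def _cloud(self, rng, n=12):
        return rng.normal(0, 5, size=(n, 3))

    def test_identity_fit(self):
        rng = np.random.default_rng(2)
        ref = self._cloud(rng)
        sup, moved = fit_frame(ref, ref, np.arange(len(ref)))
        assert sup.rmsd_after == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-10)

    def test_exact_recovery_of_rotation_translation(self):
        rng = np.random.default_rng(3)
        ref = self._cloud(rng)
        rot = np.array([[0.0, -1.0, 0], [1.0, 0.0, 0], [0, 0, 1.0]])  # 90 deg z
        frame = ref @ rot.T + np.array([3.0, -2.0, 7.0])
        sup, moved = fit_frame(frame, ref, np.arange(len(ref)))
        assert sup.rmsd_after == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(moved, ref, atol=1e-8)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0)

    def test_noisy_fit_matches_independent_solver(self):
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(4)
        ref = self._cloud(rng)
        frame = ref @ Rotation.random(random_state=5).as_matrix().T
        frame += rng.normal(0, 0.4, frame.shape) + np.array([1.0, 2.0, 3.0])
        sup, moved = fit_frame(frame, ref, np.arange(len(ref)))
        assert sup.rmsd_after <= sup.rmsd_before
        # independent oracle: scipy's Kabsch on centered clouds
        rot_o, rssd = Rotation.align_vectors(ref - ref.mean(0),
                                             frame - frame.mean(0))
        oracle_rmsd = rssd / np.sqrt(len(ref))
        assert sup.rmsd_after == pytest.approx(oracle_rmsd, abs=1e-8)

    def test_idempotent(self):
        rng = np.random.default_rng(6)
        ref = self._cloud(rng)
        frame = self._cloud(rng) + 4.0
        _, once = fit_frame(frame, ref, np.arange(len(ref)))
        _, twice = fit_frame(once, ref, np.arange(len(ref)))
        assert np.abs(twice - once).max() < 1e-6

    def test_small_selection_raises(self):
        ref = np.eye(3) * 5
        with pytest.raises(IllConditionedFitError):
            fit_frame(ref, ref, [0, 1])

    def test_collinear_selection_raises(self):
        pts = np.outer(np.arange(5.0), np.array([1.0, 0, 0]))
        with pytest.raises(IllConditionedFitError):
            fit_frame(pts, pts, np.arange(5))

    def test_fit_trajectory_applies_to_all_beads(self):
        rng = np.random.default_rng(7)
        ref = self._cloud(rng, 8)
        from cholmap.core import Trajectory
        coords = np.stack([ref + 2.0, ref - 1.0])
        traj = Trajectory(coords, 1.0, np.array([50.0, 50.0, 50.0]))
        fitted = fit_trajectory(traj, ref, np.arange(5))
        assert np.allclose(fitted[0], ref, atol=1e-8)
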