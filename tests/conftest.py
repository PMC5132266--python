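"""Shared fixtures: hand-built toy systems and a small synthetic study."""

from __future__ import annotations

import numpy as np
import pytest

from cholmap.core import BeadTopology, Lipid, Residue, Trajectory


def build_system(res_positions, lipid_frames, box=(100.0, 100.0, 100.0),
                 dt=1.0, species="CHOL", res_beads_per_residue=1):
    """Hand-build a (topology, trajectory) pair from raw coordinates.

    ``res_positions``: (n_res_beads, 3) static protein bead positions.
    ``lipid_frames``: (n_frames, n_lipid_beads, 3); each lipid bead is its
    own single-bead molecule unless a list of species is given (one per
    lipid bead).
    """
    res_positions = np.asarray(res_positions, dtype=float)
    lipid_frames = np.asarray(lipid_frames, dtype=float)
    n_rb = len(res_positions)
    n_res = n_rb // res_beads_per_residue
    residues = []
    for i in range(n_res):
        beads = tuple(range(i * res_beads_per_residue,
                            (i + 1) * res_beads_per_residue))
        residues.append(Residue(i + 1, "ALA", "A", beads, True, i + 1))
    n_lip = lipid_frames.shape[1]
    if isinstance(species, str):
        species = [species] * n_lip
    lipids = [Lipid(n_res + j + 1, species[j], (n_rb + j,))
              for j in range(n_lip)]
    topo = BeadTopology(residues, lipids, n_rb + n_lip)
    n_frames = lipid_frames.shape[0]
    coords = np.empty((n_frames, n_rb + n_lip, 3))
    coords[:, :n_rb] = res_positions[None]
    coords[:, n_rb:] = lipid_frames
    traj = Trajectory(coords, dt, np.asarray(box, dtype=float))
    return topo, traj


def random_toy_system(rng, n_frames=20, n_res=4, n_lip=6, box=25.0):
    """A small random membrane-free system for oracle comparisons."""
    res = rng.uniform(0, box, size=(n_res, 3))
    lip = rng.uniform(0, box, size=(n_frames, n_lip, 3))
    return build_system(res, lip, box=(box, box, box))


@pytest.fixture(scope="session")
def small_study():
    """A scaled-down full study (3 systems x 2 replicas x 2 monomers) with
    planted dwells of 400/200/100 ns; used by pipeline-level tests."""
    from cholmap.pipeline import RunConfig, run_protocol, synthetic_study
    datasets, truths, specs, segmap = synthetic_study(
        seed=5, n_frames=400, dt=10.0, dwells=(400.0, 200.0, 100.0))
    # contour levels scale with accumulated frames; the fixture has ~10x
    # fewer bead-frame counts than the full-size study
    config = RunConfig(datasets=datasets, discard_initial=100.0,
                       segment_map=segmap, residence_floor_ns=50.0,
                       contour_levels=(15.0, 25.0), site_contour=15.0)
    report = run_protocol(config)
    return {"config": config, "report": report, "truths": truths,
            "specs": specs, "segment_map": segmap}


@pytest.fixture(scope="session")
def planted_truth(small_study):
    """Ground-truth site residues (per monomer A) of the small study."""
    gt = small_study["truths"]["SYS1.1"]
    return {s["name"]: s for s in gt["sites"] if s["monomer"] == "A"}
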