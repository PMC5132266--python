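"""Residue-lipid contact series and maximum occupancy times (t_max).

A residue contacts a lipid molecule in a frame when ANY bead pair between
them lies within the distance cutoff (6 Å by default, the first minimum of
the bead-bead radial distribution function at this resolution), evaluated
under periodic boundaries.  t_max of a residue for a species is the longest
consecutive-frame contact run with a single lipid molecule of that species
times the frame interval; pooling contact frames across different molecules
is deliberately not allowed, because the single-molecule condition is what
separates long-lived specific binding from a busy but anonymous lipid shell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from cholmap.core import BeadTopology, Trajectory, pairwise_min_image_distances

logger = logging.getLogger(__name__)

TMAX_COLUMNS = ["dataset", "residue", "monomer", "species", "tmax_ns", "contacting"]


@dataclass
class OccupancySeries:
    """Per-frame contact indicator between one residue and one lipid."""

    residue_id: int
    seq_id: int
    monomer: str
    lipid_id: int
    species: str
    mask: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


def longest_run(mask: np.ndarray, gap_tolerance: int = 0) -> int:
    """Longest run of True allowing up to ``gap_tolerance`` interior False
    frames in total; gap frames count toward the run length."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 0
    if gap_tolerance == 0:
        # run lengths via cumulative reset
        padded = np.concatenate(([False], mask, [False])).astype(np.int8)
        edges = np.flatnonzero(np.diff(padded))
        return int((edges[1::2] - edges[0::2]).max())
    best = 0
    left = 0
    gaps = 0
    for right in range(len(mask)):
        if not mask[right]:
            gaps += 1
        while gaps > gap_tolerance:
            if not mask[left]:
                gaps -= 1
            left += 1
        # trim window to start/end on contact frames
        lo, hi = left, right
        while lo <= hi and not mask[lo]:
            lo += 1
        while hi >= lo and not mask[hi]:
            hi -= 1
        if hi >= lo:
            best = max(best, hi - lo + 1)
    return best


def _resolve_residues(topo: BeadTopology, residue_mask) -> list:
    if residue_mask is None:
        residues = [r for r in topo.residues if r.membrane_facing]
    elif residue_mask == "all":
        residues = list(topo.residues)
    else:
        wanted = set(residue_mask)
        residues = [r for r in topo.residues if r.seq_id in wanted
                    or r.residue_id in wanted]
    if not residues:
        raise ValueError("empty residue mask")
    return residues


def _contact_matrix_frame(res_xyz, lip_xyz, res_owner, lip_owner, box, cutoff,
                          n_res, n_lip, engine):
    """Boolean (n_res, n_lip) matrix: any bead pair within cutoff."""
    out = np.zeros((n_res, n_lip), dtype=bool)
    if engine == "brute":
        dist = pairwise_min_image_distances(res_xyz, lip_xyz, box)
        ii, jj = np.nonzero(dist <= cutoff)
        out[res_owner[ii], lip_owner[jj]] = True
    else:
        tree_r = cKDTree(np.mod(res_xyz, box), boxsize=box)
        tree_l = cKDTree(np.mod(lip_xyz, box), boxsize=box)
        pairs = tree_r.query_ball_tree(tree_l, r=cutoff)
        for i, hits in enumerate(pairs):
            if hits:
                out[res_owner[i], lip_owner[hits]] = True
    return out


def detect_contacts(traj: Trajectory, topo: BeadTopology, cutoff: float = 6.0,
                    species: str | Iterable[str] | None = "CHOL",
                    residue_mask=None, engine: str = "kdtree") -> list[OccupancySeries]:
    """Contact series for every (residue, lipid molecule) pair that ever
    touches.  Residues default to the membrane-facing mask; pass "all" for
    the full surface.  ``engine`` selects the neighbour search: "kdtree"
    (periodic KD-tree) or "brute" (all-pairs minimum image, the oracle path).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    residues = _resolve_residues(topo, residue_mask)
    lipids = topo.lipids_of_species(species)
    if not lipids:
        return []
    res_beads = np.concatenate([np.asarray(r.bead_indices, dtype=np.intp)
                                for r in residues])
    res_owner = np.concatenate([np.full(len(r.bead_indices), i, dtype=np.intp)
                                for i, r in enumerate(residues)])
    lip_beads = np.concatenate([np.asarray(l.bead_indices, dtype=np.intp)
                                for l in lipids])
    lip_owner = np.concatenate([np.full(len(l.bead_indices), i, dtype=np.intp)
                                for i, l in enumerate(lipids)])
    n_res, n_lip = len(residues), len(lipids)
    masks = np.zeros((traj.n_frames, n_res, n_lip), dtype=bool)
    for f in range(traj.n_frames):
        masks[f] = _contact_matrix_frame(
            traj.coords[f][res_beads], traj.coords[f][lip_beads],
            res_owner, lip_owner, traj.box[f], cutoff, n_res, n_lip, engine)
    series = []
    any_contact = masks.any(axis=0)
    for i, j in zip(*np.nonzero(any_contact)):
        r, l = residues[i], lipids[j]
        series.append(OccupancySeries(r.residue_id, r.seq_id, r.monomer_label,
                                      l.molecule_id, l.species,
                                      masks[:, i, j], traj.dt))
    return series


def compute_tmax(series: Sequence[OccupancySeries], dt: float | None = None,
                 gap_tolerance: int = 0, topo: BeadTopology | None = None,
                 residue_mask=None, dataset: str = "DS") -> pd.DataFrame:
    """Collapse contact series to a per-residue, per-species t_max table.

    When ``topo`` is given, residues of the evaluated mask that never contact
    any lipid are included with t_max 0 and contacting=False (they belong to
    the evaluated universe, and their count is what the "number of contacting
    residues" is measured against).
    """
    if dt is None:
        if not series:
            raise ValueError("empty series and no dt")
        dt = series[0].dt
    best: dict[tuple[int, str, str], float] = {}
    for s in series:
        key = (s.seq_id, s.monomer, s.species)
        run = longest_run(s.mask, gap_tolerance) * dt
        if run > best.get(key, -1.0):
            best[key] = run
    rows = []
    species_seen = sorted({s.species for s in series}) or ["CHOL"]
    if topo is not None:
        residues = _resolve_residues(topo, residue_mask)
        for sp in species_seen:
            for r in residues:
                t = best.get((r.seq_id, r.monomer_label, sp), 0.0)
                rows.append((dataset, r.seq_id, r.monomer_label, sp, t, t > 0))
    else:
        for (seq, mono, sp), t in sorted(best.items()):
            rows.append((dataset, seq, mono, sp, t, t > 0))
    return pd.DataFrame(rows, columns=TMAX_COLUMNS)


def tmax_from_trajectory(traj: Trajectory, topo: BeadTopology,
                         cutoff: float = 6.0,
                         species: str | Iterable[str] | None = "CHOL",
                         residue_mask=None, gap_tolerance: int = 0,
                         dataset: str = "DS",
                         engine: str = "kdtree",
                         monomer: str | None = None) -> pd.DataFrame:
    """Streaming fused contact-detection + t_max path (no stored series).

    Equivalent to ``compute_tmax(detect_contacts(...))`` for
    gap_tolerance=0; larger tolerances fall back to the stored-series path.
    ``monomer`` restricts the evaluated residues to one monomer, which is how
    per-monomer data-sets are produced from a dimer trajectory.
    """
    if gap_tolerance != 0:
        series = detect_contacts(traj, topo, cutoff, species, residue_mask, engine)
        if monomer is not None:
            series = [s for s in series if s.monomer == monomer]
        return compute_tmax(series, traj.dt, gap_tolerance, topo,
                            residue_mask, dataset)
    residues = _resolve_residues(topo, residue_mask)
    if monomer is not None:
        residues = [r for r in residues if r.monomer_label == monomer]
        if not residues:
            raise ValueError(f"no residues for monomer {monomer!r}")
    lipids = topo.lipids_of_species(species)
    res_beads = np.concatenate([np.asarray(r.bead_indices, dtype=np.intp)
                                for r in residues])
    res_owner = np.concatenate([np.full(len(r.bead_indices), i, dtype=np.intp)
                                for i, r in enumerate(residues)])
    lip_beads = np.concatenate([np.asarray(l.bead_indices, dtype=np.intp)
                                for l in lipids]) if lipids else np.empty(0, np.intp)
    lip_owner = np.concatenate([np.full(len(l.bead_indices), i, dtype=np.intp)
                                for i, l in enumerate(lipids)]) if lipids else np.empty(0, np.intp)
    n_res, n_lip = len(residues), len(lipids)
    cur = np.zeros((n_res, n_lip), dtype=np.int32)
    peak = np.zeros((n_res, n_lip), dtype=np.int32)
    for f in range(traj.n_frames):
        if n_lip:
            contact = _contact_matrix_frame(
                traj.coords[f][res_beads], traj.coords[f][lip_beads],
                res_owner, lip_owner, traj.box[f], cutoff, n_res, n_lip, "kdtree"
                if engine == "kdtree" else "brute")
            cur = np.where(contact, cur + 1, 0)
            np.maximum(peak, cur, out=peak)
    rows = []
    species_order = sorted({l.species for l in lipids}) or ["CHOL"]
    for sp in species_order:
        cols = [j for j, l in enumerate(lipids) if l.species == sp]
        per_res = peak[:, cols].max(axis=1) if cols else np.zeros(n_res, np.int32)
        for i, r in enumerate(residues):
            t = float(per_res[i]) * traj.dt
            rows.append((dataset, r.seq_id, r.monomer_label, sp, t, t > 0))
    return pd.DataFrame(rows, columns=TMAX_COLUMNS)


def merge_tmax_tables(tables: Sequence[pd.DataFrame], label: str = "merged") -> pd.DataFrame:
    """Aggregate data-sets into one distribution: per residue (seq position)
    and species, t_max is the maximum over the member data-sets, and a
    residue counts as contacting if it contacts in any member.  This mirrors
    merging monomer trajectories into a macro-sample: the number of
    contacting residues of the merged table is the union, not the sum.
    """
    allt = pd.concat(tables, ignore_index=True)
    agg = (allt.groupby(["residue", "species"], as_index=False)
           .agg(tmax_ns=("tmax_ns", "max")))
    agg["dataset"] = label
    agg["monomer"] = "*"
    agg["contacting"] = agg["tmax_ns"] > 0
    return agg[TMAX_COLUMNS]


def species_tmax_profile(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Per-residue mean t_max per species across data-sets.

    A residue absent from a data-set's table contributes 0 ns to the mean for
    that data-set (it was evaluated and never contacted); a note is logged
    when tables cover different residue universes.  Returns a frame indexed
    by (residue, species) with columns mean_tmax_ns and contacted.
    """
    allt = pd.concat([t for t in tables if len(t)], ignore_index=True)
    universes = [set(t["residue"]) for t in tables if len(t)]
    union = set().union(*universes) if universes else set()
    if any(u != union for u in universes):
        logger.info("data-sets cover different residue universes; missing "
                    "residues treated as t_max 0")
    n = len(tables)
    # mean over data-sets: per dataset take the max over monomers first
    per_ds = (allt.groupby(["dataset", "residue", "species"], as_index=False)
              .agg(tmax_ns=("tmax_ns", "max")))
    prof = (per_ds.groupby(["residue", "species"])
            .agg(total=("tmax_ns", "sum"), contacted=("tmax_ns", lambda v: (v > 0).any()))
            .reset_index())
    prof["mean_tmax_ns"] = prof["total"] / n
    return prof.set_index(["residue", "species"])[["mean_tmax_ns", "contacted"]]
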