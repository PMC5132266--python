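"""Assembly and characterisation of lipid interaction sites.

A site is born where the two independent analyses agree: a residue with an
outlying maximum occupancy time sits inside (or next to) a density hotspot
that is reproducible in every simulated system.  Sites are then classified
as linear (one contiguous sequence stretch on a single segment) or
non-linear (a 3-D pocket built from several helices), and their kinetics are
characterised by residence-time events detected with a dual-RMSD hysteresis
rule: a lipid becomes bound when its RMSD to the reference bound pose drops
below the lower cutoff (6 Å) and only becomes unbound again above the upper
cutoff (10.8 Å); the tolerance band in between absorbs plastic, partially
unbound configurations that would otherwise fragment one long visit into
many short ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from cholmap.core import BeadTopology, Trajectory, pairwise_min_image_distances
from cholmap.density import DensityGrid

logger = logging.getLogger(__name__)


@dataclass
class InteractionSite:
    name: str
    residue_ids: list[int]                 # seq positions
    outlier_ids: list[int]
    hotspot_ids: list[tuple[str, int]]     # (system label, hotspot id)
    member_voxels: np.ndarray | None = None
    peak_density: float = 0.0
    ranked: bool = True
    topology_class: str | None = None
    n_binding_modes: int | None = None

    def __post_init__(self) -> None:
        self.residue_ids = sorted(set(self.residue_ids))
        self.outlier_ids = sorted(set(self.outlier_ids))
        if not set(self.outlier_ids) <= set(self.residue_ids):
            raise ValueError("outliers must be site residues")


@dataclass(frozen=True)
class ResidenceEvent:
    lipid_id: int
    site: str
    start: float          # ns
    end: float            # ns
    duration: float       # ns
    start_frame: int
    end_frame: int        # exclusive
    censored: bool = False


@dataclass(frozen=True)
class SiteSummary:
    site: str
    max_residence_us: float
    n_events_total: int
    n_events_gt_threshold: int
    mean_visiting_lipids: float

    @property
    def visiting_rounded(self) -> int:
        return int(round(self.mean_visiting_lipids))


# ---------------------------------------------------------------------------
# Outlier / hotspot matching
# ---------------------------------------------------------------------------

def _reproducible_groups(hotspots_by_system: dict, radius: float):
    """Group hotspots across systems by centroid proximity; keep only groups
    with a member in EVERY system."""
    systems = list(hotspots_by_system)
    if not systems:
        return [], []
    seeds = hotspots_by_system[systems[0]]
    groups, nonrep = [], []
    used = {s: set() for s in systems}
    for h in seeds:
        members = {systems[0]: h}
        for s in systems[1:]:
            best, bestd = None, radius
            for other in hotspots_by_system[s]:
                if other.id in used[s]:
                    continue
                d = float(np.linalg.norm(other.centroid - h.centroid))
                if d <= bestd:
                    best, bestd = other, d
            if best is not None:
                members[s] = best
        if len(members) == len(systems):
            for s, m in members.items():
                used[s].add(m.id)
            groups.append(members)
        else:
            nonrep.append((systems[0], h))
    for s in systems[1:]:
        for h in hotspots_by_system[s]:
            if h.id not in used[s]:
                nonrep.append((s, h))
    return groups, nonrep


def _cluster_groups(groups: list[dict], radius: float) -> list[list[dict]]:
    """Single-linkage clustering of hotspot groups by member-centroid
    distance: blobs closer than about one lipid length belong to one site
    (multiple binding modes / bead heights of the same pocket split the
    density into adjacent lobes, like sub-sites of one site)."""
    n = len(groups)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    cents = [np.array([m.centroid for m in g.values()]) for g in groups]
    for i in range(n):
        for j in range(i + 1, n):
            d = np.linalg.norm(cents[i][:, None, :] - cents[j][None, :, :],
                               axis=2).min()
            if d <= radius:
                parent[find(i)] = find(j)
    clusters: dict[int, list[dict]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(groups[i])
    return list(clusters.values())


def match_outliers_to_hotspots(outliers: pd.DataFrame,
                               hotspots_by_system: dict,
                               grid: DensityGrid,
                               topo: BeadTopology,
                               reference: np.ndarray,
                               match_radius: float = 6.0,
                               site_merge_radius: float = 12.0,
                               monomer: str | None = None):
    """Assemble interaction sites from outliers and reproducible hotspots.

    Only hotspots reproducible in every provided system seed sites.  Nearby
    reproducible hotspot groups (centroids within ``site_merge_radius``) are
    clustered into one site.  An outlier matches a site when any of its
    beads (in the fitted reference coordinates) lies within ``match_radius``
    of a super-contour voxel center; the site's residues are all residues
    within that distance of the hotspot voxels.  Sites are ranked by
    matched-outlier count, then peak density.  Hotspot clusters without any
    matched outlier are returned as unranked candidates rather than dropped.

    Returns ``(sites, candidates, nonreproducible)``.
    """
    raw_groups, nonrep = _reproducible_groups(hotspots_by_system, match_radius)
    groups = _cluster_groups(raw_groups, site_merge_radius)
    if monomer is None:
        monomer = topo.monomer_labels[0]
    residues = topo.monomer_residues(monomer)
    outlier_set = set(outliers["residue"]) if len(outliers) else set()

    ranked, unranked = [], []
    for cluster in groups:
        vox = np.vstack([m.voxels for g in cluster for m in g.values()])
        vox = np.unique(vox, axis=0)
        centers = grid.voxel_centers(vox)
        member_res, member_out = [], []
        for res in residues:
            beads = reference[np.asarray(res.bead_indices, dtype=np.intp)]
            d2 = ((beads[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            if d2.min() <= match_radius ** 2:
                member_res.append(res.seq_id)
                if res.seq_id in outlier_set:
                    member_out.append(res.seq_id)
        peak = max(m.peak for g in cluster for m in g.values())
        site = InteractionSite(
            name="", residue_ids=member_res, outlier_ids=member_out,
            hotspot_ids=sorted({(s, m.id) for g in cluster for s, m in g.items()}),
            member_voxels=vox, peak_density=peak, ranked=bool(member_out))
        (ranked if member_out else unranked).append(site)
    ranked.sort(key=lambda s: (-len(s.outlier_ids), -s.peak_density))
    unranked.sort(key=lambda s: -s.peak_density)
    for i, s in enumerate(ranked, start=1):
        s.name = f"S{i}"
    for i, s in enumerate(unranked, start=1):
        s.name = f"U{i}"
    return ranked, unranked, nonrep


def classify_topology(site: InteractionSite, segment_map: dict,
                      window: int = 10) -> str:
    """"linear" iff all site residues lie on one segment within a contiguous
    window of at most ``window`` sequence positions, else "non-linear"."""
    missing = [r for r in site.residue_ids if r not in segment_map]
    if missing:
        raise KeyError(f"residues without segment annotation: {missing}")
    segs = {segment_map[r] for r in site.residue_ids}
    span = max(site.residue_ids) - min(site.residue_ids) + 1
    cls = "linear" if len(segs) == 1 and span <= window else "non-linear"
    site.topology_class = cls
    return cls


# ---------------------------------------------------------------------------
# Residence-time events
# ---------------------------------------------------------------------------

def residence_events(rmsd: np.ndarray, dt: float,
                     bound_cutoff: float = 6.0, unbound_cutoff: float = 10.8,
                     lipid_id: int = -1, site: str = "",
                     time_origin: float = 0.0) -> list[ResidenceEvent]:
    """Detect binding events with hysteresis on an RMSD series.

    The state machine enters the bound state when RMSD < ``bound_cutoff``,
    stays bound while RMSD <= ``unbound_cutoff`` and leaves it when RMSD
    exceeds ``unbound_cutoff``.  The duration is the number of bound frames
    times dt; an event still open at the final frame is flagged censored.
    """
    rmsd = np.asarray(rmsd, dtype=float)
    if not np.all(np.isfinite(rmsd)):
        raise ValueError("non-finite RMSD values")
    if unbound_cutoff <= bound_cutoff:
        raise ValueError("unbound_cutoff must exceed bound_cutoff")
    events = []
    start = None
    for i, r in enumerate(rmsd):
        if start is None:
            if r < bound_cutoff:
                start = i
        elif r > unbound_cutoff:
            events.append(_make_event(start, i, dt, lipid_id, site,
                                      time_origin, censored=False))
            start = None
    if start is not None:
        events.append(_make_event(start, len(rmsd), dt, lipid_id, site,
                                  time_origin, censored=True))
    return events


def _make_event(start: int, end: int, dt: float, lipid_id: int, site: str,
                time_origin: float, censored: bool) -> ResidenceEvent:
    return ResidenceEvent(lipid_id, site,
                          start=time_origin + start * dt,
                          end=time_origin + end * dt,
                          duration=(end - start) * dt,
                          start_frame=start, end_frame=end, censored=censored)


def merge_event_lists(first: list[ResidenceEvent],
                      second: list[ResidenceEvent]) -> list[ResidenceEvent]:
    """Join event lists from two consecutive trajectory segments.

    An event censored at the end of the first segment fuses with an event of
    the same lipid starting at the very first frame of the second segment.
    The fusion is exact when the RMSD at the junction is below the bound
    cutoff; a junction inside the hysteresis band (between the two cutoffs)
    cannot be recovered from the segment-local series and stays split.
    """
    if not first or not second:
        return list(first) + list(second)
    out = list(first)
    rest = list(second)
    last = out[-1]
    if last.censored:
        for k, ev in enumerate(rest):
            if ev.lipid_id == last.lipid_id and ev.site == last.site \
                    and ev.start_frame == 0 and np.isclose(ev.start, last.end):
                fused = ResidenceEvent(
                    last.lipid_id, last.site, last.start, ev.end,
                    last.duration + ev.duration, last.start_frame,
                    last.end_frame + ev.end_frame, censored=ev.censored)
                out[-1] = fused
                rest.pop(k)
                break
    return out + rest


def reference_bound_pose(lipid_coords: np.ndarray, grid: DensityGrid,
                         voxels: np.ndarray | None = None):
    """Reference bound pose of a lipid: its (fitted-frame) coordinates at the
    frame maximising the summed hotspot density over its bead positions.

    ``lipid_coords`` has shape (frames, beads, 3) in the fitted frame.  When
    ``voxels`` is given the score only counts density inside that hotspot's
    voxel set.  Ties break to the earliest frame; a lipid that never overlaps
    the density returns None.
    """
    pts = lipid_coords.reshape(-1, 3)
    idx = np.floor((pts - grid.origin) / grid.voxel).astype(np.int64)
    ok = np.all((idx >= 0) & (idx < np.asarray(grid.shape)), axis=1)
    values = np.zeros(len(pts))
    if voxels is not None:
        sel = np.zeros(grid.shape, dtype=bool)
        sel[tuple(np.asarray(voxels).T)] = True
        source = np.where(sel, grid.counts, 0)
    else:
        source = grid.counts
    values[ok] = source[tuple(idx[ok].T)]
    scores = values.reshape(lipid_coords.shape[0], lipid_coords.shape[1]).sum(axis=1)
    if scores.max() <= 0:
        return None, -1
    frame = int(np.argmax(scores))           # argmax takes the first maximum
    return lipid_coords[frame].copy(), frame


def rmsd_series(lipid_coords: np.ndarray, pose: np.ndarray) -> np.ndarray:
    """Frame-wise RMSD of a lipid to its reference pose (no refitting; the
    global superposition of the frames onto the protein is the only fit)."""
    d = lipid_coords - pose[None, :, :]
    return np.sqrt((d ** 2).sum(axis=2).mean(axis=1))


def summarize_site(events_by_dataset: dict, threshold_specific_us: float = 1.0,
                   site: str = "") -> SiteSummary:
    """Table-style kinetic summary of one site across data-sets: longest
    residence, event counts (total and above the specific threshold) and the
    mean number of distinct visiting lipids per data-set."""
    all_events = [e for evs in events_by_dataset.values() for e in evs]
    durations_us = np.array([e.duration for e in all_events]) / 1000.0
    n_total = len(all_events)
    visiting = [len({e.lipid_id for e in evs}) for evs in events_by_dataset.values()]
    return SiteSummary(
        site=site,
        max_residence_us=float(durations_us.max()) if n_total else 0.0,
        n_events_total=n_total,
        n_events_gt_threshold=int((durations_us > threshold_specific_us).sum()),
        mean_visiting_lipids=float(np.mean(visiting)) if visiting else 0.0,
    )


def estimate_mean_dwell(events, floor_ns: float = 200.0) -> tuple[float, int]:
    """Mean specific dwell time from a mixed event population.

    Site event lists mix long, specific visits with a large population of
    brief diffusive grazes.  For an exponentially distributed specific dwell,
    memorylessness makes the excess time over a floor c exponential with the
    same mean, so the censored-data maximum-likelihood estimate

        tau = sum(d_i - c over all events with d_i > c) / n_complete

    recovers the mean dwell: events below the floor (the grazing population)
    drop out entirely, and events cut off by the trajectory ends still
    contribute their observed excess time to the numerator (simply dropping
    them would under-estimate the mean, because long dwells touch the ends
    preferentially).  The floor should sit well above the grazing time scale
    and well below the dwell; the 200 ns default separates nanosecond
    contact noise from the microsecond specific scale.

    Returns ``(mean_dwell_ns, n_complete_events)``; NaN when no completed
    event clears the floor.
    """
    durations = np.array([e.duration for e in events])
    censored = np.array([e.censored for e in events], dtype=bool)
    above = durations > floor_ns
    n_complete = int((above & ~censored).sum())
    if n_complete == 0:
        return float("nan"), 0
    total_excess = float((durations[above] - floor_ns).sum())
    return total_excess / n_complete, n_complete


def count_binding_modes(poses: np.ndarray, cluster_rmsd: float = 4.0,
                        min_fraction: float = 0.05) -> tuple[int, bool]:
    """Number of preferred orientations among bound-frame poses.

    Greedy leader clustering: each pose joins the first existing cluster
    whose leader it matches within ``cluster_rmsd``, else founds a new one.
    Only clusters holding at least ``min_fraction`` of the poses count as
    modes.  The low-confidence flag is raised when the counted modes cover
    less than half of the poses (no real clustering structure).
    """
    poses = np.asarray(poses, dtype=float)
    if poses.ndim != 3 or len(poses) == 0:
        raise ValueError("poses must be (n, beads, 3) with n >= 1")
    leaders: list[np.ndarray] = []
    counts: list[int] = []
    for p in poses:
        for k, lead in enumerate(leaders):
            r = np.sqrt(((p - lead) ** 2).sum(axis=1).mean())
            if r <= cluster_rmsd:
                counts[k] += 1
                break
        else:
            leaders.append(p)
            counts.append(1)
    counts_arr = np.asarray(counts)
    big = counts_arr >= max(1, min_fraction * len(poses))
    n_modes = int(big.sum())
    covered = counts_arr[big].sum() / len(poses) if n_modes else 0.0
    return n_modes, bool(covered < 0.5)


def min_distance_timeseries(traj: Trajectory, beads_a, beads_b) -> np.ndarray:
    """Per-frame minimum over cross-pair minimum-image distances."""
    beads_a = np.asarray(beads_a, dtype=np.intp)
    beads_b = np.asarray(beads_b, dtype=np.intp)
    if beads_a.size == 0 or beads_b.size == 0:
        raise ValueError("empty bead group")
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        d = pairwise_min_image_distances(traj.coords[f][beads_a],
                                         traj.coords[f][beads_b], traj.box[f])
        out[f] = d.min()
    return out


def site_selectivity(site: InteractionSite,
                     profiles: pd.DataFrame,
                     grids_by_species: dict,
                     chol_species: str = "CHOL",
                     density_fraction: float = 0.1) -> dict:
    """Species selectivity of one site.

    Compares, across lipid species, the mean t_max over the site residues
    (from a per-residue species profile) and the mean normalised density g
    over the site voxels.  The site is non-annular when every non-reference
    species shows less than ``density_fraction`` of the reference species'
    mean site density — a pocket other lipids effectively cannot enter.
    """
    report: dict = {"site": site.name, "species": {}}
    for sp, grid in grids_by_species.items():
        if site.member_voxels is not None and len(site.member_voxels):
            gvals = grid.g[tuple(np.asarray(site.member_voxels).T)]
            mean_g = float(gvals.mean())
        else:
            mean_g = float("nan")
        tvals = []
        for r in site.residue_ids:
            try:
                tvals.append(float(profiles.loc[(r, sp), "mean_tmax_ns"]))
            except KeyError:
                tvals.append(0.0)
        report["species"][sp] = {"mean_tmax_ns": float(np.mean(tvals)) if tvals else 0.0,
                                 "mean_g": mean_g}
    ref_g = report["species"].get(chol_species, {}).get("mean_g", 0.0)
    others = [v["mean_g"] for k, v in report["species"].items() if k != chol_species]
    report["non_annular"] = bool(ref_g > 0 and others
                                 and all(o < density_fraction * ref_g for o in others))
    return report
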