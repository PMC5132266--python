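"""End-to-end orchestration of the site-mapping protocol.

The protocol runs in four stages on a collection of data-sets (one per
monomer per replica per system):

1. per-residue maximum occupancy times and their spread descriptors;
2. statistical merging of data-sets into macro-samples (Kruskal-Wallis with
   iterative leave-one-out), cross-system pooling into a single t_max
   population, and Tukey-fence outlier extraction;
3. spatial density grids per system on the merged populations, hotspot
   extraction at the configured contour levels, and a reproducibility
   filter across systems;
4. site assembly (outlier-hotspot matching), topology classification,
   residence-time kinetics with the dual-RMSD hysteresis rule, binding-mode
   counting, species selectivity, and an optional CRAC/CARC motif scan.

Residence kinetics are computed over all merged data-sets of every system
(rather than the most cholesterol-rich system only) to maximise event
statistics at the simulated problem sizes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

import cholmap
from cholmap.core import (BeadTopology, Trajectory, fit_frame, read_topology,
                          read_trajectory)
from cholmap.contacts import merge_tmax_tables, species_tmax_profile, tmax_from_trajectory
from cholmap.density import DensityGrid, extract_hotspots, make_grid, merge_grids, reimage_about
from cholmap.motifs import mask_hits, scan_motifs
from cholmap.sites import (classify_topology, count_binding_modes,
                           estimate_mean_dwell, reference_bound_pose,
                           residence_events, rmsd_series, site_selectivity,
                           summarize_site)
from cholmap.stats import (MacroSample, dagostino_pearson, find_outliers,
                           kruskal_wallis, leave_one_out_merge, summarize)

logger = logging.getLogger(__name__)


@dataclass
class DatasetSpec:
    """One replica trajectory; its monomers become separate data-sets."""

    label: str
    system: str
    topology: BeadTopology | str | Path
    trajectory: Trajectory | str | Path
    monomers: str | Path | dict | None = None
    membrane_facing: str | Path | None = None
    dt: float | None = None


@dataclass
class RunConfig:
    datasets: list[DatasetSpec] = field(default_factory=list)
    contact_cutoff: float = 6.0
    bound_cutoff: float = 6.0
    unbound_cutoff: float = 10.8
    alpha: float = 0.01
    voxel: float = 1.0
    contour_levels: tuple = (40.0, 60.0)
    site_contour: float = 40.0
    min_voxels: int = 5
    discard_initial: float = 500.0
    match_radius: float = 6.0
    site_merge_radius: float = 12.0
    species: tuple = ("CHOL", "PC", "PE")
    site_species: str = "CHOL"
    gap_tolerance: int = 0
    quartile_method: str = "linear"
    linear_window: int = 10
    segment_map: dict | None = None
    sequence: str | None = None
    sequence_offset: int = 1
    cluster_rmsd: float = 4.0
    threshold_specific_us: float = 1.0
    residence_floor_ns: float = 200.0
    density_fraction: float = 0.1
    grid_margin: float = 15.0
    seed: int = 0
    out_dir: str | Path | None = None
    write_grids: bool = False

    def __post_init__(self) -> None:
        for name in ("contact_cutoff", "bound_cutoff", "unbound_cutoff", "voxel"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.unbound_cutoff <= self.bound_cutoff:
            raise ValueError("unbound_cutoff must exceed bound_cutoff")
        labels = [d.label for d in self.datasets]
        if len(labels) != len(set(labels)):
            raise ValueError("dataset labels must be unique")


@dataclass
class ProtocolReport:
    table1: pd.DataFrame = None
    table2: pd.DataFrame = None
    tmax_tables: dict = field(default_factory=dict)
    tests: dict = field(default_factory=dict)
    macro_per_system: dict = field(default_factory=dict)
    population: MacroSample = None
    outliers: pd.DataFrame = None
    grids: dict = field(default_factory=dict)
    hotspots: dict = field(default_factory=dict)
    sites: list = field(default_factory=list)
    candidates: list = field(default_factory=list)
    nonreproducible: list = field(default_factory=list)
    events: pd.DataFrame = None
    site_summaries: pd.DataFrame = None
    binding_modes: dict = field(default_factory=dict)
    selectivity: list = field(default_factory=list)
    motif_hits: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)


class _Dataset:
    """A loaded per-monomer data-set with lazy fitted coordinates."""

    def __init__(self, label, system, topo, traj, monomer):
        self.label = label
        self.system = system
        self.topo = topo
        self.traj = traj
        self.monomer = monomer
        self._fitted = None

    def fit_selection(self):
        return self.topo.protein_bead_indices(self.monomer, membrane_facing_only=True)

    def fitted(self, reference):
        if self._fitted is None:
            sel = self.fit_selection()
            out = np.empty_like(self.traj.coords)
            for f in range(self.traj.n_frames):
                frame = self.traj.coords[f]
                center = frame[sel].mean(axis=0)
                frame = reimage_about(frame, center, self.traj.box[f])
                _, out[f] = fit_frame(frame, reference, sel)
            self._fitted = out
        return self._fitted

    def drop_fitted(self):
        self._fitted = None


def _load_datasets(config: RunConfig) -> list[_Dataset]:
    out = []
    for ds in config.datasets:
        if isinstance(ds.topology, BeadTopology):
            topo = ds.topology
        else:
            topo = read_topology(ds.topology, monomers=ds.monomers,
                                 membrane_facing=ds.membrane_facing)
        if isinstance(ds.trajectory, Trajectory):
            traj = ds.trajectory
            keep = traj.times >= config.discard_initial - 1e-9
            if not keep.all():
                traj = Trajectory(traj.coords[keep], traj.dt, traj.box[keep],
                                  time_origin=float(traj.times[keep][0]))
        else:
            traj = read_trajectory(ds.trajectory, topo,
                                   discard_initial=config.discard_initial,
                                   dt=ds.dt)
        for i, mono in enumerate(topo.monomer_labels):
            suffix = chr(ord("a") + i)
            out.append(_Dataset(f"{ds.label}{suffix}", ds.system, topo, traj, mono))
    return out


def _reference_coords_for(ds: _Dataset, ref_ds: _Dataset,
                          ref_frame: np.ndarray) -> np.ndarray:
    """Reference array for fitting: the reference monomer's coordinates
    written at this data-set's monomer bead indices (matched by sequence
    position), so every monomer of every system maps onto one common frame."""
    ref = np.zeros((ds.topo.n_beads, 3))
    ref_res = {r.seq_id: r for r in ref_ds.topo.monomer_residues(ref_ds.monomer)}
    for res in ds.topo.monomer_residues(ds.monomer):
        src = ref_res.get(res.seq_id)
        if src is None or len(src.bead_indices) != len(res.bead_indices):
            raise ValueError(f"monomer mismatch at seq {res.seq_id}")
        for bsrc, bdst in zip(src.bead_indices, res.bead_indices):
            ref[bdst] = ref_frame[bsrc]
    return ref


def run_protocol(config: RunConfig) -> ProtocolReport:
    """Execute the full protocol; returns a ProtocolReport and optionally
    writes CSV/JSON artifacts to ``config.out_dir``."""
    rpt = ProtocolReport()
    datasets = _load_datasets(config)
    if not datasets:
        raise ValueError("no datasets")
    systems = []
    for ds in datasets:
        if ds.system not in systems:
            systems.append(ds.system)
    ref_ds = datasets[0]
    ref_frame = ref_ds.traj.coords[0]
    ref_sel = ref_ds.fit_selection()

    # ---- stage 1: contacts and t_max -------------------------------------
    logger.info("stage 1: contacts on %d data-sets", len(datasets))
    t1_rows = []
    for ds in datasets:
        table = tmax_from_trajectory(
            ds.traj, ds.topo, cutoff=config.contact_cutoff,
            species=config.species, gap_tolerance=config.gap_tolerance,
            dataset=ds.label, monomer=ds.monomer)
        rpt.tmax_tables[ds.label] = table
        vals = _contacting(table, config.site_species)
        s = summarize(vals, ds.label, config.quartile_method)
        norm = dagostino_pearson(vals, config.alpha)
        rpt.tests[f"normality:{ds.label}"] = norm
        t1_rows.append((ds.system, ds.label, s.n_contacting, s.median, s.q1,
                        s.q3, s.outlier_threshold_T / 1000.0))
    rpt.table1 = pd.DataFrame(t1_rows, columns=[
        "system", "dataset", "n_contacting", "median_ns", "q1_ns", "q3_ns",
        "outlier_threshold_us"])

    # ---- stage 2: merging and outliers ------------------------------------
    logger.info("stage 2: statistical merging")
    system_members: dict[str, list[str]] = {}
    system_agg: dict[str, pd.DataFrame] = {}
    for sysname in systems:
        members = [ds for ds in datasets if ds.system == sysname]
        values = {ds.label: _contacting(rpt.tmax_tables[ds.label],
                                        config.site_species)
                  for ds in members}
        if len(values) == 1:
            macro = MacroSample(list(values), {}, next(iter(values.values())))
        else:
            macro = leave_one_out_merge(values, config.alpha)
        agg = merge_tmax_tables(
            [rpt.tmax_tables[l][rpt.tmax_tables[l]["species"] == config.site_species]
             for l in macro.members], label=sysname)
        macro.residue_tmax = agg.set_index("residue")["tmax_ns"]
        rpt.macro_per_system[sysname] = macro
        system_members[sysname] = macro.members
        system_agg[sysname] = agg

    sys_values = {s: _contacting(system_agg[s], config.site_species)
                  for s in systems}
    kept_systems = list(systems)
    if len(systems) > 1:
        cross = kruskal_wallis(list(sys_values.values()), config.alpha)
        rpt.tests["cross-system"] = cross
        if cross.reject:
            macro_sys = leave_one_out_merge(sys_values, config.alpha)
            kept_systems = macro_sys.members or list(systems)
            logger.warning("cross-system merge excluded: %s", macro_sys.excluded)

    member_labels = [l for s in kept_systems for l in system_members[s]]
    pop_tables = [rpt.tmax_tables[l][rpt.tmax_tables[l]["species"] == config.site_species]
                  for l in member_labels]
    pop_agg = merge_tmax_tables(pop_tables, label="ALL")
    population = MacroSample(
        member_labels,
        {l: "excluded upstream" for s in systems for l in
         [d.label for d in datasets if d.system == s] if l not in member_labels},
        np.concatenate([_contacting(rpt.tmax_tables[l], config.site_species)
                        for l in member_labels]),
        residue_tmax=pop_agg.set_index("residue")["tmax_ns"])
    rpt.population = population

    t2_rows = []
    for sysname in systems:
        agg_vals = _contacting(system_agg[sysname], config.site_species)
        s = summarize(agg_vals, sysname, config.quartile_method)
        total_us = sum(ds.traj.total_time for ds in datasets
                       if ds.label in system_members[sysname]) / 1000.0
        t2_rows.append((sysname, total_us, s.n_contacting, s.median, s.q1,
                        s.q3, s.outlier_threshold_T / 1000.0))
    pop_summary = summarize(_contacting(pop_agg, config.site_species), "ALL",
                            config.quartile_method)
    total_us = sum(ds.traj.total_time for ds in datasets
                   if ds.label in member_labels) / 1000.0
    t2_rows.append(("ALL", total_us, pop_summary.n_contacting,
                    pop_summary.median, pop_summary.q1, pop_summary.q3,
                    pop_summary.outlier_threshold_T / 1000.0))
    rpt.table2 = pd.DataFrame(t2_rows, columns=[
        "sample", "aggregated_time_us", "n_contacting", "median_ns", "q1_ns",
        "q3_ns", "outlier_threshold_us"])
    rpt.outliers = find_outliers(population, pop_summary)

    # ---- stage 3: density -------------------------------------------------
    logger.info("stage 3: spatial density")
    ds_by_label = {ds.label: ds for ds in datasets}
    proto_grid = make_grid(ref_frame, ref_sel, config.voxel, config.grid_margin)
    species_grids_last: dict[str, DensityGrid] = {}
    for sysname in systems:
        member_grids = []
        for label in system_members[sysname]:
            ds = ds_by_label[label]
            fitted = ds.fitted(_reference_coords_for(ds, ref_ds, ref_frame))
            g = DensityGrid(proto_grid.origin.copy(), proto_grid.voxel,
                            np.zeros(proto_grid.shape, dtype=np.int64), 0, 0.0)
            beads = ds.topo.lipid_bead_indices(config.site_species)
            g.reference_density = beads.size / float(np.prod(ds.traj.box[0]))
            g.n_outside += g.bin_points(fitted[:, beads, :].reshape(-1, 3))
            g.n_frames += ds.traj.n_frames
            member_grids.append(g)
        rpt.grids[sysname] = merge_grids(member_grids)
        rpt.hotspots[sysname] = {
            level: extract_hotspots(rpt.grids[sysname], level,
                                    config.min_voxels)
            for level in set(config.contour_levels) | {config.site_contour}}

    # per-species grids of the last (most enriched) system, for selectivity
    sel_system = systems[-1]
    for sp in config.species:
        grids = []
        for label in system_members[sel_system]:
            ds = ds_by_label[label]
            fitted = ds.fitted(_reference_coords_for(ds, ref_ds, ref_frame))
            beads = ds.topo.lipid_bead_indices(sp)
            if beads.size == 0:
                continue
            g = DensityGrid(proto_grid.origin.copy(), proto_grid.voxel,
                            np.zeros(proto_grid.shape, dtype=np.int64), 0,
                            beads.size / float(np.prod(ds.traj.box[0])))
            g.n_outside += g.bin_points(fitted[:, beads, :].reshape(-1, 3))
            g.n_frames += ds.traj.n_frames
            grids.append(g)
        if grids:
            species_grids_last[sp] = merge_grids(grids)

    # ---- stage 4: sites ---------------------------------------------------
    logger.info("stage 4: site assembly and kinetics")
    from cholmap.sites import match_outliers_to_hotspots
    hot_for_seeding = {s: rpt.hotspots[s][config.site_contour]
                       for s in kept_systems}
    any_grid = rpt.grids[systems[0]]
    sites, candidates, nonrep = match_outliers_to_hotspots(
        rpt.outliers, hot_for_seeding, any_grid, ref_ds.topo,
        _reference_coords_for(ref_ds, ref_ds, ref_frame),
        config.match_radius, config.site_merge_radius, monomer=ref_ds.monomer)
    rpt.sites, rpt.candidates, rpt.nonreproducible = sites, candidates, nonrep
    if config.segment_map:
        for site in sites + candidates:
            classify_topology(site, config.segment_map, config.linear_window)

    event_rows = []
    events_by_site: dict[str, dict[str, list]] = {s.name: {} for s in sites}
    poses_by_site: dict[str, list] = {s.name: [] for s in sites}
    residence_labels = [l for s in kept_systems for l in system_members[s]]
    for label in residence_labels:
        ds = ds_by_label[label]
        fitted = ds.fitted(_reference_coords_for(ds, ref_ds, ref_frame))
        grid = rpt.grids[ds.system]
        lipids = ds.topo.lipids_of_species(config.site_species)
        for site in sites:
            site_events = []
            for lip in lipids:
                beads = np.asarray(lip.bead_indices, dtype=np.intp)
                lip_coords = fitted[:, beads, :]
                pose, _ = reference_bound_pose(lip_coords, grid,
                                               voxels=site.member_voxels)
                if pose is None:
                    continue
                series = rmsd_series(lip_coords, pose)
                evs = residence_events(series, ds.traj.dt,
                                       config.bound_cutoff,
                                       config.unbound_cutoff,
                                       lipid_id=lip.molecule_id,
                                       site=site.name)
                site_events.extend(evs)
                for e in evs:
                    event_rows.append((label, site.name, lip.molecule_id,
                                       e.start, e.end, e.duration, e.censored))
                bound = series < config.bound_cutoff
                if bound.any():
                    poses_by_site[site.name].append(lip_coords[bound][::10])
            events_by_site[site.name][label] = site_events
        ds.drop_fitted()

    rpt.events = pd.DataFrame(event_rows, columns=[
        "dataset", "site", "lipid_id", "start_ns", "end_ns", "duration_ns",
        "censored"])

    summary_rows = []
    for site in sites:
        summ = summarize_site(events_by_site[site.name],
                              config.threshold_specific_us, site.name)
        all_events = [e for evs in events_by_site[site.name].values()
                      for e in evs]
        tau_ns, n_tau = estimate_mean_dwell(all_events,
                                            config.residence_floor_ns)
        if poses_by_site[site.name]:
            poses = np.concatenate(poses_by_site[site.name])[:2000]
            n_modes, lowconf = count_binding_modes(poses, config.cluster_rmsd)
            site.n_binding_modes = n_modes
            rpt.binding_modes[site.name] = {"n_modes": n_modes,
                                            "low_confidence": lowconf}
        summary_rows.append((site.name, site.topology_class,
                             site.n_binding_modes,
                             ",".join(map(str, site.residue_ids)),
                             ",".join(map(str, site.outlier_ids)),
                             summ.max_residence_us, summ.n_events_total,
                             summ.n_events_gt_threshold,
                             summ.mean_visiting_lipids,
                             tau_ns / 1000.0, n_tau))
    rpt.site_summaries = pd.DataFrame(summary_rows, columns=[
        "site", "topology", "n_binding_modes", "residues", "outliers",
        "max_residence_us", "n_events_total", "n_events_gt_1us",
        "mean_visiting_lipids", "mean_dwell_us", "n_dwell_events"])

    # selectivity
    if species_grids_last:
        profile_tables = [rpt.tmax_tables[l] for l in system_members[sel_system]]
        profiles = species_tmax_profile(profile_tables)
        for site in sites:
            rpt.selectivity.append(site_selectivity(
                site, profiles, species_grids_last, config.site_species,
                config.density_fraction))

    # motifs
    if config.sequence:
        hits = scan_motifs(config.sequence, offset=config.sequence_offset)
        facing = {r.seq_id for r in ref_ds.topo.monomer_residues(ref_ds.monomer)
                  if r.membrane_facing}
        rpt.motif_hits = mask_hits(hits, facing) if facing else hits

    rpt.manifest = _manifest(config)
    if config.out_dir is not None:
        _write_outputs(rpt, config)
    return rpt


def _contacting(table: pd.DataFrame, species: str) -> np.ndarray:
    sub = table[(table["species"] == species) & table["contacting"]]
    return sub["tmax_ns"].to_numpy()


def _manifest(config: RunConfig) -> dict:
    cfg = asdict(config)
    cfg["datasets"] = [
        {"label": d.label, "system": d.system,
         "topology": str(d.topology) if not isinstance(d.topology, BeadTopology)
         else "<in-memory>",
         "trajectory": str(d.trajectory) if not isinstance(d.trajectory, Trajectory)
         else "<in-memory>"}
        for d in config.datasets]
    cfg["out_dir"] = str(config.out_dir) if config.out_dir else None
    return {
        "package": "cholmap",
        "version": cholmap.__version__,
        "config": cfg,
        "conventions": {
            "quartiles": config.quartile_method,
            "hotspot_connectivity": 26,
            "contour_lattice": "raw voxel hit counts",
            "pose_tie_break": "earliest frame",
            "merged_tmax": "per-residue max over member data-sets",
        },
    }


def _write_outputs(rpt: ProtocolReport, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = "%.6g"
    rpt.table1.to_csv(out / "table1.csv", index=False, float_format=fmt)
    rpt.table2.to_csv(out / "table2.csv", index=False, float_format=fmt)
    rpt.outliers.to_csv(out / "outliers.csv", index=False, float_format=fmt)
    rpt.events.to_csv(out / "events.csv", index=False, float_format=fmt)
    rpt.site_summaries.to_csv(out / "site_summary.csv", index=False,
                              float_format=fmt)
    tests = {k: asdict(v) for k, v in rpt.tests.items()}
    with open(out / "tests.json", "w") as fh:
        json.dump(tests, fh, indent=1, sort_keys=True)
    sites_payload = []
    for site in rpt.sites + rpt.candidates:
        sites_payload.append({
            "name": site.name, "ranked": site.ranked,
            "residues": site.residue_ids, "outliers": site.outlier_ids,
            "topology": site.topology_class,
            "n_binding_modes": site.n_binding_modes,
            "peak_density": site.peak_density,
            "hotspots": [list(h) for h in site.hotspot_ids]})
    with open(out / "sites.json", "w") as fh:
        json.dump({"sites": sites_payload,
                   "selectivity": rpt.selectivity,
                   "motifs": [str(h) for h in rpt.motif_hits]}, fh, indent=1)
    with open(out / "manifest.json", "w") as fh:
        json.dump(rpt.manifest, fh, indent=1, sort_keys=True)
    if config.write_grids:
        for sysname, grid in rpt.grids.items():
            grid.write_dx(out / f"sdf_{sysname}.dx")


# ---------------------------------------------------------------------------
# Synthetic study helper
# ---------------------------------------------------------------------------

def synthetic_study(seed: int = 0, n_frames: int = 3000, dt: float = 10.0,
                    n_replicas: int = 2,
                    chol_fractions: tuple = (0.15, 0.20, 0.25),
                    dwells: tuple = (2000.0, 1000.0, 500.0),
                    n_lipids: int = 360, planted: bool = True):
    """Generate the full study design in memory: one system per cholesterol
    mole fraction, ``n_replicas`` independent replicas each, two monomers
    per box.  Returns (config datasets, ground truths, specs, segment_map)
    where segment_map assigns each sequence position its helix index."""
    from cholmap.synthetic import generate_system, study_spec
    datasets, truths, specs = [], {}, {}
    rng = np.random.default_rng(seed)
    segment_map: dict[int, int] = {}
    for i, frac in enumerate(chol_fractions, start=1):
        sysname = f"SYS{i}"
        for rep in range(1, n_replicas + 1):
            sub_seed = int(rng.integers(0, 2 ** 31 - 1))
            spec = study_spec(frac, seed=sub_seed, n_frames=n_frames, dt=dt,
                              n_lipids=n_lipids, dwells=dwells, planted=planted)
            topo, traj, gt = generate_system(spec)
            label = f"{sysname}.{rep}"
            datasets.append(DatasetSpec(label=label, system=sysname,
                                        topology=topo, trajectory=traj))
            truths[label] = gt
            specs[label] = spec
            if not segment_map:
                segment_map = {
                    seq: (seq - 1) // spec.beads_per_helix
                    for seq in range(1, spec.n_helices * spec.beads_per_helix + 1)}
    return datasets, truths, specs, segment_map
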