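"""Synthetic coarse-grained membrane trajectories with planted lipid sites.

The generator emulates the structure of the simulated data the analysis
protocol was designed for: a static transmembrane helix bundle (two monomers
per box), a two-leaflet membrane of 2-D-diffusing lipids of 2-3 species at a
chosen cholesterol mole fraction, and "planted" surface sites where lipids of
one species dwell for exponentially distributed times, on top of short-lived
background contacts that arise from diffusion alone.  There are no forces or
energetics: bound lipids are pinned near their site anchor, free lipids
perform lateral Brownian motion and are reflected off the protein footprint.

All randomness is drawn from a single numpy Generator seeded once, so a
given spec is bit-reproducible.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from cholmap.core import BeadTopology, Lipid, Residue, Trajectory, write_gro
from cholmap.errors import PackingError

logger = logging.getLogger(__name__)

#: z offsets (Å) of lipid beads from the membrane mid-plane, per species;
#: sign selects the leaflet.
_BEAD_Z = {
    "CHOL": (14.0, 8.0),
    "PC": (16.0, 10.0, 4.0),
    "PE": (16.0, 10.0, 4.0),
    "OTHER": (10.0,),
}

_RESNAME_OF_SPECIES = {"CHOL": "CHOL", "PC": "DSPC", "PE": "POPE", "OTHER": "LIPX"}

_PROTEIN_NAMES = ("ALA", "LEU", "VAL", "GLY", "SER", "ILE", "PHE", "THR")

#: minimum area per lipid used for the packing check (Å²)
_MIN_AREA_PER_LIPID = 45.0


@dataclass
class PlantedSite:
    """A surface site where one lipid of ``species`` at a time can dwell.

    ``helix`` indexes the monomer helix carrying the site; its upper-leaflet
    beads become the site residues.  A lipid entering ``capture_radius`` of
    the site anchor (laterally) binds with ``binding_prob`` per frame and then
    stays pinned within the contact cutoff of the site residues for an
    exponential dwell with mean ``mean_dwell`` (ns).
    """

    name: str
    helix: int
    mean_dwell: float
    capture_radius: float = 10.0
    binding_prob: float = 0.3
    species: str = "CHOL"
    leaflet: str = "upper"

    def __post_init__(self) -> None:
        if self.mean_dwell <= 0:
            raise ValueError("mean_dwell must be > 0")
        if not (0 < self.binding_prob <= 1):
            raise ValueError("binding_prob must be in (0, 1]")


@dataclass
class SyntheticSpec:
    """Full description of one synthetic system (one replica)."""

    box: tuple[float, float, float] = (130.0, 130.0, 100.0)
    n_frames: int = 3000
    dt: float = 10.0
    n_helices: int = 10
    beads_per_helix: int = 6
    helix_radius: float = 18.0
    n_monomers: int = 2
    monomer_spacing: float = 64.0
    lipid_counts: dict = field(default_factory=lambda: {"CHOL": 54, "PC": 153, "PE": 153})
    diffusion_coeff: dict = field(default_factory=lambda: {"CHOL": 3.0, "PC": 2.0, "PE": 2.0})
    planted_sites: list = field(default_factory=list)
    protein_jitter: float = 0.3
    bound_jitter: float = 1.0
    helix_z_span: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.lipid_counts.values())
        if total <= 0:
            raise ValueError("need at least one lipid")
        for sp, n in self.lipid_counts.items():
            if n < 0:
                raise ValueError(f"negative count for {sp}")
        for site in self.planted_sites:
            if site.capture_radius > 6.0:
                logger.info("site %s: capture radius %.1f Å exceeds the 6 Å "
                            "contact cutoff (allowed)", site.name, site.capture_radius)
        area = self.box[0] * self.box[1]
        footprint = self.n_monomers * math.pi * (self.helix_radius + 2.0) ** 2
        per_leaflet = math.ceil(total / 2)
        if per_leaflet * _MIN_AREA_PER_LIPID > area - footprint:
            raise PackingError(
                f"{per_leaflet} lipids per leaflet exceed available area "
                f"{area - footprint:.0f} Å²")

    @property
    def chol_fraction(self) -> float:
        total = sum(self.lipid_counts.values())
        return self.lipid_counts.get("CHOL", 0) / total


def study_spec(chol_fraction: float = 0.25, seed: int = 0, n_frames: int = 3000,
               dt: float = 10.0, n_lipids: int = 360,
               planted: bool = True,
               dwells: tuple[float, ...] = (2000.0, 1000.0, 500.0),
               diffusion_scaling: float = 1.5) -> SyntheticSpec:
    """Build the default study conditions for one replica.

    Cholesterol mole fraction is 0.15/0.20/0.25 across the three systems of
    the study design; the remaining lipids split evenly into PC and PE.
    Lateral diffusion slows modestly with cholesterol enrichment
    (factor 1 - diffusion_scaling*(x_chol - 0.15)), mirroring the observed
    trend in cholesterol-enriched membranes.  Three sites per monomer carry
    mean dwells of 2 µs, 1 µs and 0.5 µs against a ~10 ns diffusive
    background.
    """
    n_chol = round(chol_fraction * n_lipids)
    n_rest = n_lipids - n_chol
    counts = {"CHOL": n_chol, "PC": n_rest // 2, "PE": n_rest - n_rest // 2}
    factor = max(0.2, 1.0 - diffusion_scaling * (chol_fraction - 0.15))
    diff = {"CHOL": 3.0 * factor, "PC": 2.0 * factor, "PE": 2.0 * factor}
    sites = []
    if planted:
        helices = (0, 3, 6)
        for i, (h, dwell) in enumerate(zip(helices, dwells), start=1):
            sites.append(PlantedSite(name=f"P{i}", helix=h, mean_dwell=dwell))
    return SyntheticSpec(lipid_counts=counts, diffusion_coeff=diff,
                         planted_sites=sites, n_frames=n_frames, dt=dt,
                         seed=seed)


# ---------------------------------------------------------------------------


def _protein_layout(spec: SyntheticSpec):
    """Static bead positions, residue bookkeeping and per-site geometry."""
    cx, cy, cz = spec.box[0] / 2, spec.box[1] / 2, spec.box[2] / 2
    if spec.n_monomers == 1:
        centers = [(cx, cy)]
    else:
        half = spec.monomer_spacing / 2
        centers = [(cx - half + i * spec.monomer_spacing, cy)
                   for i in range(spec.n_monomers)]
    z0 = cz - spec.helix_z_span / 2
    zs = (np.linspace(0.0, spec.helix_z_span, spec.beads_per_helix) + z0
          if spec.beads_per_helix > 1 else np.array([cz]))
    coords = []
    residues = []
    bead = 0
    resid = 0
    monomer_labels = [chr(ord("A") + i) for i in range(spec.n_monomers)]
    for m, (mx, my) in enumerate(centers):
        seq = 0
        for h in range(spec.n_helices):
            theta = 2 * math.pi * h / spec.n_helices
            hx = mx + spec.helix_radius * math.cos(theta)
            hy = my + spec.helix_radius * math.sin(theta)
            for z in zs:
                resid += 1
                seq += 1
                coords.append((hx, hy, z))
                residues.append(Residue(resid, _PROTEIN_NAMES[seq % len(_PROTEIN_NAMES)],
                                        monomer_labels[m], (bead,), True, seq))
                bead += 1
    return np.asarray(coords), residues, centers, zs


def _site_geometry(spec: SyntheticSpec, centers, zs, contact_cutoff: float = 6.0):
    """Anchor point, outward direction and residue seq_ids for every planted
    site, replicated on every monomer.

    The site residues listed in the ground truth are the helix beads that a
    lipid pinned at the anchor can actually reach within the contact cutoff
    (anchor sits 4 Å outside the helix; bead heights are species specific).
    """
    cz = spec.box[2] / 2
    geo = []
    for m, (mx, my) in enumerate(centers):
        label = chr(ord("A") + m)
        for site in spec.planted_sites:
            theta = 2 * math.pi * site.helix / spec.n_helices
            direction = np.array([math.cos(theta), math.sin(theta)])
            helix_lat = np.array([mx, my]) + spec.helix_radius * direction
            anchor = helix_lat + 4.0 * direction
            sign = 1.0 if site.leaflet == "upper" else -1.0
            lip_z = cz + sign * np.asarray(_BEAD_Z[site.species])
            seq_ids = []
            for i, z in enumerate(zs):
                if sign * (z - cz) <= 0:
                    continue  # wrong leaflet
                dz = np.abs(lip_z - z).min()
                if math.hypot(4.0, dz) <= contact_cutoff:
                    seq_ids.append(site.helix * spec.beads_per_helix + i + 1)
            geo.append({
                "site": site, "monomer": label, "anchor": anchor,
                "direction": direction, "seq_ids": seq_ids,
            })
    return geo


def _reflect_off_disc(lat: np.ndarray, center: np.ndarray, radius: float,
                      mask: np.ndarray | None) -> np.ndarray:
    """Specular reflection of lateral positions off a hard disc.

    Positions inside the disc are mirrored across its boundary
    (r -> 2*radius - r), which keeps the lipid density smooth at the wall
    instead of piling everything onto a delta shell.
    """
    d = lat - center
    r = np.sqrt((d ** 2).sum(axis=1))
    degenerate = r < 1e-9
    d[degenerate] = (radius + 0.5, 0.0)
    r[degenerate] = radius + 0.5
    inside = r < radius
    if mask is not None:
        inside &= mask
    lat = lat.copy()
    lat[inside] = center + d[inside] * ((2.0 * radius - r[inside]) / r[inside])[:, None]
    return lat


def generate_system(spec: SyntheticSpec):
    """Generate one synthetic replica.

    Returns ``(topology, trajectory, ground_truth)`` where ground_truth is a
    dict with the planted site definitions and every realised binding
    interval (start/end frames, end exclusive; intervals still open at the
    final frame are flagged censored).
    """
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.box, dtype=float)
    prot_xyz, residues, centers, zs = _protein_layout(spec)
    n_prot = len(prot_xyz)
    geo = _site_geometry(spec, centers, zs)

    # ---- lipid bookkeeping ------------------------------------------------
    species_list = []
    for sp in sorted(spec.lipid_counts):
        species_list.extend([sp] * spec.lipid_counts[sp])
    n_lip = len(species_list)
    # alternate leaflets within each species for an even split
    leaflet = np.zeros(n_lip, dtype=int)  # +- indicator: 0 upper, 1 lower
    counter: dict[str, int] = {}
    for i, sp in enumerate(species_list):
        k = counter.get(sp, 0)
        leaflet[i] = k % 2
        counter[sp] = k + 1

    lipids = []
    bead = n_prot
    resid = residues[-1].residue_id if residues else 0
    bead_species = []
    lip_bead_slices = []
    for i, sp in enumerate(species_list):
        resid += 1
        nb = len(_BEAD_Z[sp])
        lipids.append(Lipid(resid, sp, tuple(range(bead, bead + nb))))
        lip_bead_slices.append((bead, bead + nb))
        bead_species.extend([sp] * nb)
        bead += nb
    n_beads = bead
    topo = BeadTopology(residues, lipids, n_beads)

    # per-lipid z coordinates of its beads
    cz = box[2] / 2
    lip_bead_z = []
    for i, sp in enumerate(species_list):
        sign = 1.0 if leaflet[i] == 0 else -1.0
        lip_bead_z.append(cz + sign * np.asarray(_BEAD_Z[sp]))

    # ---- initial lateral positions ---------------------------------------
    lat = rng.uniform(0.0, 1.0, size=(n_lip, 2)) * box[:2]
    footprint = spec.helix_radius + 2.0
    for c in centers:
        lat = _reflect_off_disc(lat, np.asarray(c), footprint, None)

    sigma = np.array([math.sqrt(2.0 * spec.diffusion_coeff.get(sp, 1.0) * spec.dt)
                      for sp in species_list])

    # ---- site state -------------------------------------------------------
    n_sites = len(geo)
    occupant = np.full(n_sites, -1, dtype=int)
    release_frame = np.zeros(n_sites, dtype=int)
    start_frame = np.zeros(n_sites, dtype=int)
    bound_to = np.full(n_lip, -1, dtype=int)
    upper_mask = leaflet == 0
    events: list[dict] = []

    coords = np.empty((spec.n_frames, n_beads, 3))
    unwrapped = lat.copy()
    unwrapped_log = np.empty((spec.n_frames, n_lip, 2))

    for f in range(spec.n_frames):
        # protein with thermal jitter
        coords[f, :n_prot] = prot_xyz + rng.normal(0.0, spec.protein_jitter,
                                                   size=(n_prot, 3))
        # free lipid diffusion
        steps = rng.normal(0.0, 1.0, size=(n_lip, 2)) * sigma[:, None]
        free = bound_to < 0
        lat[free] += steps[free]
        unwrapped[free] += steps[free]
        lat[:, 0] %= box[0]
        lat[:, 1] %= box[1]
        # reflect free lipids off each monomer footprint
        for c in centers:
            lat = _reflect_off_disc(lat, np.asarray(c), footprint, free)

        # releases due this frame
        for s in range(n_sites):
            if occupant[s] >= 0 and f >= release_frame[s]:
                lip = occupant[s]
                g = geo[s]
                lat[lip] = ((g["anchor"] + g["direction"]
                             * (g["site"].capture_radius + 4.0)) % box[:2])
                events.append({
                    "site": g["site"].name, "monomer": g["monomer"],
                    "lipid_id": lipids[lip].molecule_id,
                    "start_frame": int(start_frame[s]), "end_frame": int(f),
                    "duration_ns": (f - start_frame[s]) * spec.dt,
                    "censored": False,
                })
                occupant[s] = -1
                bound_to[lip] = -1

        # captures
        site_jitter = rng.normal(0.0, spec.bound_jitter, size=(n_sites, 2))
        for s in range(n_sites):
            g = geo[s]
            site = g["site"]
            if occupant[s] < 0:
                want_upper = site.leaflet == "upper"
                d = lat - g["anchor"]
                d -= box[:2] * np.round(d / box[:2])
                r2 = (d ** 2).sum(axis=1)
                cand = np.nonzero(
                    (bound_to < 0)
                    & (upper_mask == want_upper)
                    & np.array([sp == site.species for sp in species_list])
                    & (r2 <= site.capture_radius ** 2))[0]
                for lip in cand:
                    if rng.random() < site.binding_prob:
                        occupant[s] = lip
                        bound_to[lip] = s
                        start_frame[s] = f
                        dwell = rng.exponential(site.mean_dwell)
                        release_frame[s] = f + max(1, int(round(dwell / spec.dt)))
                        break
            if occupant[s] >= 0:
                lat[occupant[s]] = (g["anchor"] + site_jitter[s]) % box[:2]

        # write lipid beads
        for i, (b0, b1) in enumerate(lip_bead_slices):
            coords[f, b0:b1, 0] = lat[i, 0]
            coords[f, b0:b1, 1] = lat[i, 1]
            coords[f, b0:b1, 2] = lip_bead_z[i]
        unwrapped_log[f] = unwrapped

    # close events still open at the last frame
    for s in range(n_sites):
        if occupant[s] >= 0:
            g = geo[s]
            events.append({
                "site": g["site"].name, "monomer": g["monomer"],
                "lipid_id": lipids[occupant[s]].molecule_id,
                "start_frame": int(start_frame[s]), "end_frame": int(spec.n_frames),
                "duration_ns": (spec.n_frames - start_frame[s]) * spec.dt,
                "censored": True,
            })

    traj = Trajectory(coords, spec.dt, box)
    ground_truth = {
        "sites": [{
            "name": g["site"].name, "monomer": g["monomer"],
            "residue_seq_ids": g["seq_ids"],
            "anchor": [float(x) for x in g["anchor"]],
            "mean_dwell_ns": g["site"].mean_dwell,
            "species": g["site"].species,
            "capture_radius": g["site"].capture_radius,
            "binding_prob": g["site"].binding_prob,
        } for g in geo],
        "events": sorted(events, key=lambda e: (e["site"], e["monomer"],
                                                e["start_frame"])),
        "species": species_list,
        "leaflet": ["upper" if l == 0 else "lower" for l in leaflet],
        "unwrapped_lateral": unwrapped_log,
        "seed": spec.seed,
    }
    return topo, traj, ground_truth


# ---------------------------------------------------------------------------
# Fixture writing
# ---------------------------------------------------------------------------

def _gro_arrays(topo: BeadTopology):
    resids = np.empty(topo.n_beads, dtype=int)
    resnames = [""] * topo.n_beads
    atomnames = [""] * topo.n_beads
    for res in topo.residues:
        for b in res.bead_indices:
            resids[b] = res.residue_id
            resnames[b] = res.name
            atomnames[b] = "BB"
    for lip in topo.lipids:
        for k, b in enumerate(lip.bead_indices):
            resids[b] = lip.molecule_id
            resnames[b] = _RESNAME_OF_SPECIES.get(lip.species, lip.species[:5])
            atomnames[b] = f"R{k + 1}"
    return resids, resnames, atomnames


def write_fixture(topo: BeadTopology, traj: Trajectory, outdir: str | Path,
                  ground_truth: dict | None = None,
                  spec: SyntheticSpec | None = None) -> dict:
    """Write a generated system as plain-text files readable by the package.

    Emits ``system.gro`` (first frame, doubles as the topology),
    ``traj.gro`` (all frames, concatenated GRO), ``monomers.json`` and
    ``membrane_facing.txt`` sidecars, plus ``ground_truth.json`` and a
    ``spec.json`` echo when provided.  Returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    resids, resnames, atomnames = _gro_arrays(topo)
    paths = {
        "topology": outdir / "system.gro",
        "trajectory": outdir / "traj.gro",
        "monomers": outdir / "monomers.json",
        "membrane_facing": outdir / "membrane_facing.txt",
    }
    write_gro(paths["topology"], resids, resnames, atomnames,
              traj.coords[0], traj.box[0])
    write_gro(paths["trajectory"], resids, resnames, atomnames,
              traj.coords, traj.box, times=traj.times)
    monomer_map: dict[str, list[int]] = {}
    for res in topo.residues:
        monomer_map.setdefault(res.monomer_label, []).append(res.residue_id)
    with open(paths["monomers"], "w") as fh:
        json.dump({"monomers": monomer_map}, fh, indent=1)
    facing = sorted({r.seq_id for r in topo.residues if r.membrane_facing})
    paths["membrane_facing"].write_text(" ".join(str(s) for s in facing) + "\n")
    if ground_truth is not None:
        gt = {k: v for k, v in ground_truth.items() if k != "unwrapped_lateral"}
        paths["ground_truth"] = outdir / "ground_truth.json"
        with open(paths["ground_truth"], "w") as fh:
            json.dump(gt, fh, indent=1)
    if spec is not None:
        paths["spec"] = outdir / "spec.json"
        serial = asdict(spec)
        serial["planted_sites"] = [asdict(s) for s in spec.planted_sites]
        with open(paths["spec"], "w") as fh:
            json.dump(serial, fh, indent=1)
    return paths
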