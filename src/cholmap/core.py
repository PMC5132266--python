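"""Domain types, topology/trajectory I/O, periodic distances and superposition.

Internal units are angstrom (Å) for lengths and nanoseconds (ns) for times
throughout the package; GRO files (nm) are converted on read and write.
Only orthorhombic boxes are supported, which keeps minimum-image distances
exact and cheap.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from cholmap.errors import (
    EmptyTrajectoryError,
    FormatError,
    IllConditionedFitError,
    TopologyMismatchError,
    TriclinicBoxError,
)

logger = logging.getLogger(__name__)

NM_TO_ANGSTROM = 10.0

#: residue names treated as protein residues
AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: default residue-name -> lipid-species mapping
DEFAULT_SPECIES_MAP = {
    "CHOL": "CHOL",
    "CHL1": "CHOL",
    "DSPC": "PC",
    "DPPC": "PC",
    "POPC": "PC",
    "DOPC": "PC",
    "POPE": "PE",
    "DOPE": "PE",
    "DPPE": "PE",
}

KNOWN_SPECIES = ("CHOL", "PC", "PE", "OTHER")


@dataclass(frozen=True)
class Residue:
    """One protein residue of the bead topology.

    ``residue_id`` is globally unique; ``seq_id`` is the position within the
    monomer (1-based) and is shared between monomers of an oligomer, so that
    per-monomer data-sets can be compared residue by residue.
    """

    residue_id: int
    name: str
    monomer_label: str
    bead_indices: tuple[int, ...]
    membrane_facing: bool = True
    seq_id: int = 0


@dataclass(frozen=True)
class Lipid:
    molecule_id: int
    species: str
    bead_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bead_indices) < 1:
            raise ValueError(f"lipid {self.molecule_id} has no beads")


@dataclass
class BeadTopology:
    """Residue and lipid bead assignments for one simulated system."""

    residues: list[Residue]
    lipids: list[Lipid]
    n_beads: int

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for group in self.residues + self.lipids:  # type: ignore[operator]
            idx = set(group.bead_indices)
            if idx & seen:
                raise ValueError("bead index sets overlap between groups")
            seen |= idx
        if seen and max(seen) >= self.n_beads:
            raise ValueError("bead index exceeds n_beads")

    # -- convenience views -------------------------------------------------

    @property
    def monomer_labels(self) -> list[str]:
        labels: list[str] = []
        for res in self.residues:
            if res.monomer_label not in labels:
                labels.append(res.monomer_label)
        return labels

    def monomer_residues(self, label: str) -> list[Residue]:
        return [r for r in self.residues if r.monomer_label == label]

    def protein_bead_indices(self, monomer: str | None = None,
                             membrane_facing_only: bool = False) -> np.ndarray:
        out: list[int] = []
        for res in self.residues:
            if monomer is not None and res.monomer_label != monomer:
                continue
            if membrane_facing_only and not res.membrane_facing:
                continue
            out.extend(res.bead_indices)
        return np.asarray(sorted(out), dtype=np.intp)

    def lipid_bead_indices(self, species: str | Iterable[str] | None = None) -> np.ndarray:
        if species is None:
            wanted = None
        elif isinstance(species, str):
            wanted = {species}
        else:
            wanted = set(species)
        out: list[int] = []
        for lip in self.lipids:
            if wanted is None or lip.species in wanted:
                out.extend(lip.bead_indices)
        return np.asarray(sorted(out), dtype=np.intp)

    def lipids_of_species(self, species: str | Iterable[str] | None = None) -> list[Lipid]:
        if species is None:
            return list(self.lipids)
        wanted = {species} if isinstance(species, str) else set(species)
        return [l for l in self.lipids if l.species in wanted]

    def species_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for lip in self.lipids:
            counts[lip.species] = counts.get(lip.species, 0) + 1
        return counts


@dataclass
class Trajectory:
    """Bead coordinates over time.

    coords has shape (n_frames, n_beads, 3) in Å; box is the per-frame
    orthorhombic box edge lengths, shape (n_frames, 3) in Å.
    """

    coords: np.ndarray
    dt: float
    box: np.ndarray
    time_origin: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, beads, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        self.box = np.asarray(self.box, dtype=float)
        if self.box.shape == (3,):
            self.box = np.tile(self.box, (self.coords.shape[0], 1))
        if self.box.shape != (self.coords.shape[0], 3):
            raise ValueError("box must have shape (frames, 3)")
        if not np.all(self.box > 0):
            raise ValueError("box lengths must be > 0")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_beads(self) -> int:
        return self.coords.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.time_origin + self.dt * np.arange(self.n_frames)

    @property
    def total_time(self) -> float:
        """Total analysed time span in ns (frame count × dt)."""
        return self.n_frames * self.dt


@dataclass(frozen=True)
class Superposition:
    """Rigid-body transform from a least-squares fit."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd_before: float
    rmsd_after: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# GRO parsing / writing (fixed-column format; concatenated frames form a
# trajectory, following the GROMACS trjconv convention)
# ---------------------------------------------------------------------------

def _parse_gro_frames(path: Path) -> list[dict]:
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not any(line.strip() for line in lines):
        raise FormatError(f"{path}: empty file")
    i = 0
    while i < len(lines):
        if not lines[i].strip() and i == len(lines) - 1:
            break
        title = lines[i]
        try:
            natoms = int(lines[i + 1].strip())
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{path}: line {i + 2}: expected atom count") from exc
        atom_lines = lines[i + 2: i + 2 + natoms]
        if len(atom_lines) < natoms:
            raise FormatError(f"{path}: truncated frame starting at line {i + 1}")
        resids = np.empty(natoms, dtype=int)
        resnames: list[str] = []
        atomnames: list[str] = []
        xyz = np.empty((natoms, 3))
        for j, line in enumerate(atom_lines):
            lineno = i + 3 + j
            try:
                resids[j] = int(line[0:5])
                resnames.append(line[5:10].strip())
                atomnames.append(line[10:15].strip())
                xyz[j, 0] = float(line[20:28])
                xyz[j, 1] = float(line[28:36])
                xyz[j, 2] = float(line[36:44])
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}: line {lineno}: unparseable atom record") from exc
        try:
            box_fields = [float(x) for x in lines[i + 2 + natoms].split()]
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{path}: missing box line after line {i + 2 + natoms}") from exc
        if len(box_fields) not in (3, 9):
            raise FormatError(f"{path}: box line must have 3 or 9 fields")
        if len(box_fields) == 9 and any(abs(v) > 1e-9 for v in box_fields[3:]):
            raise TriclinicBoxError(f"{path}: triclinic box not supported")
        time = None
        if "t=" in title:
            try:
                time = float(title.split("t=")[1].split()[0])
            except (IndexError, ValueError):
                time = None
        frames.append({
            "title": title,
            "resids": resids,
            "resnames": resnames,
            "atomnames": atomnames,
            "xyz": xyz * NM_TO_ANGSTROM,
            "box": np.array(box_fields[:3]) * NM_TO_ANGSTROM,
            "time": time,
        })
        i += 3 + natoms
        while i < len(lines) and not lines[i].strip():
            i += 1
    return frames


def write_gro(path: str | Path, resids: Sequence[int], resnames: Sequence[str],
              atomnames: Sequence[str], coords: np.ndarray, box: np.ndarray,
              times: Sequence[float] | None = None, append: bool = False,
              title: str = "cholmap system") -> None:
    """Write one or more frames in GRO format (coords in Å, stored as nm).

    ``coords`` may be (n_beads, 3) for a single frame or (n_frames, n_beads, 3);
    ``times`` (ns, written as ps in the title line) must match the frame count
    when given.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    box = np.asarray(box, dtype=float)
    if box.ndim == 1:
        box = np.tile(box, (coords.shape[0], 1))
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        for f in range(coords.shape[0]):
            head = title
            if times is not None:
                head = f"{title} t= {times[f] * 1000.0:.3f}"
            fh.write(head + "\n")
            fh.write(f"{coords.shape[1]:5d}\n")
            frame_nm = coords[f] / NM_TO_ANGSTROM
            for j in range(coords.shape[1]):
                fh.write(
                    f"{resids[j] % 100000:5d}{resnames[j]:<5.5s}{atomnames[j]:>5.5s}"
                    f"{(j + 1) % 100000:5d}"
                    f"{frame_nm[j, 0]:8.3f}{frame_nm[j, 1]:8.3f}{frame_nm[j, 2]:8.3f}\n"
                )
            b = box[f] / NM_TO_ANGSTROM
            fh.write(f"{b[0]:10.5f}{b[1]:10.5f}{b[2]:10.5f}\n")


# ---------------------------------------------------------------------------
# Topology reading
# ---------------------------------------------------------------------------

def _load_monomer_map(monomers) -> dict[str, list[int]] | None:
    if monomers is None:
        return None
    if isinstance(monomers, (str, Path)):
        with open(monomers) as fh:
            data = json.load(fh)
        monomers = data.get("monomers", data)
    # accept {label: [resids]} directly
    return {str(k): [int(x) for x in v] for k, v in monomers.items()}


def _load_facing(membrane_facing) -> set[int] | None:
    if membrane_facing is None:
        return None
    if isinstance(membrane_facing, (str, Path)):
        with open(membrane_facing) as fh:
            return {int(tok) for tok in fh.read().split()}
    return {int(x) for x in membrane_facing}


def read_topology(path: str | Path, dialect: str | None = None,
                  species_map: Mapping[str, str] | None = None,
                  monomers=None, membrane_facing=None) -> BeadTopology:
    """Read a bead topology from a GRO or PDB file.

    Residues whose name is a standard amino-acid code become protein residues;
    all others are lipid molecules classified by ``species_map`` (unknown
    names fall back to species OTHER with a warning).

    Parameters
    ----------
    monomers : mapping, path or None
        ``{label: [global residue ids]}`` partitioning the protein residues
        into monomers (a JSON sidecar path is accepted).  When omitted all
        protein residues form one monomer "A".  Sequence positions (seq_id)
        are assigned 1..n within each monomer in residue-id order.
    membrane_facing : iterable of int, path or None
        seq_ids of membrane-facing residues (applied in every monomer); a
        whitespace-separated text sidecar is accepted.  Default: all facing.
    """
    path = Path(path)
    if dialect is None:
        dialect = path.suffix.lstrip(".").lower() or "gro"
    species_map = dict(DEFAULT_SPECIES_MAP if species_map is None else species_map)
    if dialect == "gro":
        frame = _parse_gro_frames(path)[0]
        resids, resnames = frame["resids"], frame["resnames"]
    elif dialect == "pdb":
        import MDAnalysis as mda
        try:
            u = mda.Universe(str(path))
        except Exception as exc:  # pragma: no cover - mda error zoo
            raise FormatError(f"{path}: could not parse PDB: {exc}") from exc
        resids = u.atoms.resids
        resnames = [str(r) for r in u.atoms.resnames]
    else:
        raise FormatError(f"unknown topology dialect {dialect!r}")

    n_beads = len(resids)
    # group consecutive beads by (resid, resname)
    groups: list[tuple[int, str, list[int]]] = []
    for j in range(n_beads):
        if groups and groups[-1][0] == resids[j] and groups[-1][1] == resnames[j]:
            groups[-1][2].append(j)
        else:
            groups.append((int(resids[j]), resnames[j], [j]))

    monomer_map = _load_monomer_map(monomers)
    facing = _load_facing(membrane_facing)

    residues: list[Residue] = []
    lipids: list[Lipid] = []
    warned: set[str] = set()
    for resid, resname, beads in groups:
        if resname.upper() in AMINO_ACIDS:
            residues.append(Residue(resid, resname.upper(), "A",
                                    tuple(beads), True, 0))
        else:
            species = species_map.get(resname.upper())
            if species is None:
                if resname not in warned:
                    logger.warning("residue name %r not in species map; "
                                   "classified as OTHER", resname)
                    warned.add(resname)
                species = "OTHER"
            lipids.append(Lipid(resid, species, tuple(beads)))

    # assign monomer labels and per-monomer sequence ids
    if monomer_map is None:
        monomer_map = {"A": [r.residue_id for r in residues]}
    label_of = {rid: lab for lab, rids in monomer_map.items() for rid in rids}
    seq_of: dict[int, int] = {}
    for lab, rids in monomer_map.items():
        for seq, rid in enumerate(sorted(rids), start=1):
            seq_of[rid] = seq
    final: list[Residue] = []
    for res in residues:
        lab = label_of.get(res.residue_id)
        if lab is None:
            raise FormatError(f"protein residue {res.residue_id} missing from monomer map")
        seq = seq_of[res.residue_id]
        face = True if facing is None else seq in facing
        final.append(Residue(res.residue_id, res.name, lab, res.bead_indices,
                             face, seq))
    return BeadTopology(final, lipids, n_beads)


# ---------------------------------------------------------------------------
# Trajectory reading
# ---------------------------------------------------------------------------

def read_trajectory(path: str | Path, topology: BeadTopology,
                    discard_initial: float = 0.0, dt: float | None = None,
                    dialect: str | None = None,
                    mda_topology: str | Path | None = None) -> Trajectory:
    """Read a multi-frame trajectory and drop the initial equilibration span.

    Frames with time < ``discard_initial`` (ns) are removed, mirroring the
    discard of the first 500 ns of each production run.  Times are taken from
    the file when present ("t=" in GRO titles, in ps); otherwise frames are
    assumed uniformly spaced by ``dt`` (ns), which is then required.
    """
    path = Path(path)
    if discard_initial < 0:
        raise ValueError("discard_initial must be >= 0")
    if dialect is None:
        dialect = path.suffix.lstrip(".").lower()
    if dialect == "gro":
        frames = _parse_gro_frames(path)
        coords = np.stack([f["xyz"] for f in frames])
        box = np.stack([f["box"] for f in frames])
        times_ps = [f["time"] for f in frames]
        times = None
        if all(t is not None for t in times_ps) and len(times_ps) > 1:
            times = np.asarray(times_ps, dtype=float) / 1000.0  # ps -> ns
    elif dialect in ("pdb", "xtc", "dcd"):
        import MDAnalysis as mda
        if dialect == "pdb":
            u = mda.Universe(str(path))
        else:
            if mda_topology is None:
                raise FormatError(f"{dialect} trajectories need mda_topology")
            u = mda.Universe(str(mda_topology), str(path))
        coords_l, box_l, times_l = [], [], []
        for ts in u.trajectory:
            dims = ts.dimensions
            if dims is None:
                raise FormatError(f"{path}: missing box information")
            if not np.allclose(dims[3:], 90.0, atol=1e-3):
                raise TriclinicBoxError(f"{path}: triclinic box not supported")
            coords_l.append(u.atoms.positions.astype(float).copy())
            box_l.append(np.asarray(dims[:3], dtype=float))
            times_l.append(float(ts.time) / 1000.0)
        coords = np.stack(coords_l)
        box = np.stack(box_l)
        times = np.asarray(times_l)
        if np.allclose(times, 0.0) or len(set(np.round(times, 9))) < len(times):
            times = None
    else:
        raise FormatError(f"unknown trajectory dialect {dialect!r}")

    if coords.shape[1] != topology.n_beads:
        raise TopologyMismatchError(
            f"trajectory has {coords.shape[1]} beads, topology {topology.n_beads}")

    if times is not None and len(times) > 1:
        spacings = np.diff(times)
        if spacings.min() <= 0 or (np.ptp(spacings) > 1e-6 * max(spacings.max(), 1.0)):
            if dt is None:
                raise FormatError(f"{path}: non-uniform frame spacing and no dt given")
        elif dt is None:
            dt = float(spacings[0])
    if dt is None:
        if coords.shape[0] == 1:
            dt = 1.0
        else:
            raise FormatError(f"{path}: frame interval dt not inferable; pass dt=")

    t0 = times[0] if times is not None else 0.0
    frame_times = (np.asarray(times) if times is not None
                   else t0 + dt * np.arange(coords.shape[0]))
    keep = frame_times >= discard_initial - 1e-9
    if not keep.any():
        raise EmptyTrajectoryError(
            f"discard_initial={discard_initial} ns removes all "
            f"{coords.shape[0]} frames")
    return Trajectory(coords[keep], dt, box[keep],
                      time_origin=float(frame_times[keep][0]))


# ---------------------------------------------------------------------------
# Periodic-boundary distances
# ---------------------------------------------------------------------------

def min_image_displacement(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement b-a for orthorhombic box (broadcasts)."""
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    box = np.asarray(box, dtype=float)
    return d - box * np.round(d / box)


def min_image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image Euclidean distance between points under PBC."""
    d = min_image_displacement(a, b, box)
    return np.sqrt(np.sum(d * d, axis=-1))


def pairwise_min_image_distances(xa: np.ndarray, xb: np.ndarray,
                                 box: np.ndarray) -> np.ndarray:
    """All cross distances (len(xa), len(xb)) under minimum image."""
    d = xb[None, :, :] - xa[:, None, :]
    d -= box * np.round(d / box)
    return np.sqrt(np.sum(d * d, axis=-1))


# ---------------------------------------------------------------------------
# Least-squares superposition (Kabsch)
# ---------------------------------------------------------------------------

def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def fit_frame(frame: np.ndarray, reference: np.ndarray,
              selection: Sequence[int] | np.ndarray) -> tuple[Superposition, np.ndarray]:
    """Least-squares fit of ``frame`` onto ``reference`` over ``selection``.

    The proper rotation and translation minimising the RMSD over the selected
    beads (Kabsch algorithm, SVD with reflection guard) are applied to ALL
    beads of the frame.
    """
    sel = np.asarray(selection, dtype=np.intp)
    if sel.size < 3:
        raise IllConditionedFitError("selection must contain at least 3 beads")
    frame = np.asarray(frame, dtype=float)
    reference = np.asarray(reference, dtype=float)
    x = frame[sel]
    y = reference[sel]
    cx = x.mean(axis=0)
    cy = y.mean(axis=0)
    x0 = x - cx
    y0 = y - cy
    h = x0.T @ y0
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-10 * max(s[0], 1.0):
        raise IllConditionedFitError("degenerate (collinear) fit selection")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = cy - rot @ cx
    rmsd_before = _rmsd(x, y)
    transformed = frame @ rot.T + trans
    rmsd_after = _rmsd(transformed[sel], y)
    return Superposition(rot, trans, rmsd_before, rmsd_after), transformed


def fit_trajectory(traj: Trajectory, reference: np.ndarray,
                   selection: Sequence[int] | np.ndarray) -> np.ndarray:
    """Superpose every frame onto ``reference``; returns fitted coords."""
    out = np.empty_like(traj.coords)
    for f in range(traj.n_frames):
        _, out[f] = fit_frame(traj.coords[f], reference, selection)
    return out
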