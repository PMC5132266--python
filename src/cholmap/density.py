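"""Spatial density function (SDF) of lipid beads around the fitted protein.

Every frame is superposed onto a reference structure over a fixed bead
selection, lipid beads of the chosen species are re-imaged about the protein
and binned into cubic voxels (1 Å³ by default).  The normalised density is

    g(x, y, z) = N(x, y, z) / (rho * dV * n_frames)

with N the per-voxel hit count, dV the voxel volume and rho the bulk number
density of the species' beads (bead count / box volume of the reference
frame), so that g averages to 1 in bulk.  Hotspots are connected components
of voxels above a contour level applied to the RAW hit counts (hits/Å³), the
convention the display contours use; both lattices are kept so either can
be contoured.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from cholmap.core import BeadTopology, Trajectory, fit_frame
from cholmap.errors import GeometryMismatchError

logger = logging.getLogger(__name__)


@dataclass
class DensityGrid:
    origin: np.ndarray
    voxel: float
    counts: np.ndarray
    n_frames: int
    reference_density: float
    n_outside: int = 0

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.counts = np.asarray(self.counts)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts.shape

    @property
    def g(self) -> np.ndarray:
        dv = self.voxel ** 3
        return self.counts / (self.reference_density * dv * self.n_frames)

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        """Cartesian centers (Å) of voxels given integer index triples."""
        return self.origin + (np.asarray(indices, dtype=float) + 0.5) * self.voxel

    def bin_points(self, points: np.ndarray) -> int:
        """Accumulate points into counts; returns how many fell outside."""
        idx = np.floor((points - self.origin) / self.voxel).astype(np.int64)
        ok = np.all((idx >= 0) & (idx < np.asarray(self.shape)), axis=1)
        np.add.at(self.counts, tuple(idx[ok].T), 1)
        return int((~ok).sum())

    def write_dx(self, path, field: str = "g") -> None:
        """Export the grid as an OpenDX scalar field."""
        from gridData import Grid
        values = self.g if field == "g" else self.counts.astype(float)
        Grid(values, origin=self.origin + self.voxel / 2,
             delta=[self.voxel] * 3).export(str(path), "dx")


@dataclass
class Hotspot:
    id: int
    voxels: np.ndarray            # (n, 3) integer indices
    peak: float
    centroid: np.ndarray          # Å
    volume: float                 # Å³


def make_grid(reference: np.ndarray, protein_beads: np.ndarray, voxel: float = 1.0,
              margin: float = 15.0, n_species_beads: int = 0,
              box_volume: float = 1.0) -> DensityGrid:
    """Empty grid covering the reference protein bounding box plus margin,
    axis aligned, with the voxel lattice anchored on integer multiples of
    the voxel edge so that independently constructed grids coincide."""
    prot = reference[protein_beads]
    lo = np.floor((prot.min(axis=0) - margin) / voxel) * voxel
    hi = np.ceil((prot.max(axis=0) + margin) / voxel) * voxel
    shape = np.round((hi - lo) / voxel).astype(int)
    rho = n_species_beads / box_volume
    return DensityGrid(lo, voxel, np.zeros(shape, dtype=np.int64), 0, rho)


def reimage_about(coords: np.ndarray, center: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Shift each point by whole box vectors to its minimum image about
    ``center`` (orthorhombic)."""
    return coords - box * np.round((coords - center) / box)


def compute_sdf(traj: Trajectory, topo: BeadTopology,
                species: str = "CHOL",
                fit_selection: np.ndarray | None = None,
                voxel: float = 1.0, reference: np.ndarray | None = None,
                margin: float = 15.0, fit: bool = True,
                grid: DensityGrid | None = None) -> DensityGrid:
    """Accumulate the SDF of ``species`` beads over a trajectory.

    Frames are superposed onto ``reference`` (default: the first frame) over
    ``fit_selection`` (default: all membrane-facing protein beads); species
    beads are re-imaged about the protein centroid before fitting, so lipids
    wrapped across the periodic boundary land on the correct side.  Beads
    falling outside the grid are tallied in ``n_outside`` rather than
    silently dropped.  Pass an explicit ``grid`` to accumulate several
    data-sets on identical geometry.
    """
    if fit_selection is None:
        fit_selection = topo.protein_bead_indices(membrane_facing_only=True)
    fit_selection = np.asarray(fit_selection, dtype=np.intp)
    lip_beads = topo.lipid_bead_indices(species)
    if lip_beads.size == 0:
        raise ValueError(f"no beads of species {species!r}")
    if reference is None:
        reference = traj.coords[0]
    box0 = traj.box[0]
    volume = float(np.prod(box0))
    if grid is None:
        grid = make_grid(reference, fit_selection, voxel, margin,
                         n_species_beads=lip_beads.size, box_volume=volume)
    elif grid.reference_density == 0:
        grid.reference_density = lip_beads.size / volume

    points = np.empty((traj.n_frames, lip_beads.size, 3))
    for f in range(traj.n_frames):
        frame = traj.coords[f]
        if fit:
            center = frame[fit_selection].mean(axis=0)
            frame = reimage_about(frame, center, traj.box[f])
            _, frame = fit_frame(frame, reference, fit_selection)
        points[f] = frame[lip_beads]
    grid.n_outside += grid.bin_points(points.reshape(-1, 3))
    grid.n_frames += traj.n_frames
    return grid


def merge_grids(grids) -> DensityGrid:
    """Sum counts and frames of grids with identical geometry; g follows."""
    grids = list(grids)
    if len(grids) < 1:
        raise ValueError("nothing to merge")
    first = grids[0]
    counts = first.counts.copy()
    n_frames = first.n_frames
    n_outside = first.n_outside
    for g in grids[1:]:
        if (g.voxel != first.voxel or g.counts.shape != first.counts.shape
                or not np.allclose(g.origin, first.origin)
                or not np.isclose(g.reference_density, first.reference_density,
                                  rtol=0.05)):
            raise GeometryMismatchError("grids have incompatible geometry")
        counts += g.counts
        n_frames += g.n_frames
        n_outside += g.n_outside
    return DensityGrid(first.origin.copy(), first.voxel, counts, n_frames,
                       first.reference_density, n_outside)


_STRUCTURES = {26: np.ones((3, 3, 3), dtype=bool),
               6: ndimage.generate_binary_structure(3, 1)}


def extract_hotspots(grid: DensityGrid, contour: float, min_voxels: int = 5,
                     connectivity: int = 26, on: str = "counts") -> list[Hotspot]:
    """Connected components of voxels at or above the contour level.

    ``on`` selects the contoured lattice: raw "counts" (hits/Å³, the
    convention of display contour levels) or normalised "g".  Components
    with fewer than ``min_voxels`` voxels are suppressed as single-voxel
    noise.  Hotspots come back sorted by decreasing peak value.
    """
    if contour <= 0:
        raise ValueError("contour must be > 0")
    values = grid.counts if on == "counts" else grid.g
    mask = values >= contour
    labels, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    spots = []
    for lab in range(1, n + 1):
        vox = np.argwhere(labels == lab)
        if len(vox) < min_voxels:
            continue
        vals = values[tuple(vox.T)]
        weights = vals / vals.sum()
        centroid = (grid.voxel_centers(vox) * weights[:, None]).sum(axis=0)
        spots.append(Hotspot(0, vox, float(vals.max()), centroid,
                             float(len(vox) * grid.voxel ** 3)))
    spots.sort(key=lambda h: -h.peak)
    for i, h in enumerate(spots, start=1):
        h.id = i
    return spots
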