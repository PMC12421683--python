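"""Voxel-grid accumulation of water occupancy, energies and hydrogen-bond
densities, grid finalisation, OpenDX export and density-derived surfaces.

Each frame, every water oxygen inside the grid deposits its per-molecule
energies and hydrogen-bond counts into the voxel containing it (half-open
voxel intervals, boundary points assigned upward).  After accumulation the
grid is finalised into densities:

* ``rho_vox`` — number density, n_wat / (n_frames * voxel volume);
* ``g`` — rho_vox / rho0;
* ``e_dens`` — g times the per-water mean referenced energy (the printed
  voxel energy-density formula);
* ``e_per_frame`` — sum of referenced energies / n_frames, the additive
  quantity whose sum over any voxel set is the subvolume total.

Waters outside the grid are ignored (counted in ``n_outside``); the grid is
not periodically wrapped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .core import Trajectory
from .energetics import EnergyEvaluator, InteractionModel
from .hbonds import HBondCriteria, HBondEngine

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GridSpec:
    """Regular cubic-voxel grid: corner ``origin``, ``spacing`` Å, ``shape``
    voxel counts per axis."""

    origin: tuple
    spacing: float
    shape: tuple

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        object.__setattr__(self, "origin", tuple(float(x) for x in self.origin))
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        if len(self.origin) != 3 or len(self.shape) != 3 or min(self.shape) < 1:
            raise ValueError("origin and shape must be 3-vectors, shape >= 1")

    @property
    def voxel_volume(self) -> float:
        return self.spacing ** 3

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def centers(self) -> np.ndarray:
        """Voxel centers as an (n_voxels, 3) array in C (x-slowest) order."""
        ax = [self.origin[d] + (np.arange(self.shape[d]) + 0.5) * self.spacing for d in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def flat_index(self, ijk: np.ndarray) -> np.ndarray:
        return np.ravel_multi_index(tuple(np.asarray(ijk, dtype=np.int64).T), self.shape)


def assign_voxel(position, spec: GridSpec):
    """Voxel index triplet for one position, or ``None`` if outside the grid.

    Half-open convention: voxel i spans [origin + i*h, origin + (i+1)*h).
    """
    ijk, inside = assign_voxels(np.asarray(position, float)[None, :], spec)
    return tuple(int(x) for x in ijk[0]) if inside[0] else None


def assign_voxels(positions: np.ndarray, spec: GridSpec):
    """Vectorised voxel assignment: (indices (n,3), inside mask (n,))."""
    rel = (np.asarray(positions, float) - np.array(spec.origin)) / spec.spacing
    ijk = np.floor(rel).astype(np.int64)
    inside = np.all((ijk >= 0) & (ijk < np.array(spec.shape)), axis=1)
    return ijk, inside


_FIELDS = ("n_wat", "g", "rho_vox", "e_dens", "e_per_frame", "e_sw", "e_ww", "hb_sw", "hb_ww")


@dataclass
class GistGrid:
    """Accumulators and derived per-voxel fields (flat arrays, C order)."""

    spec: GridSpec
    n_frames: int = 0
    n_wat: np.ndarray = None
    sum_e_sw: np.ndarray = None
    sum_e_ww: np.ndarray = None
    sum_e_ref: np.ndarray = None
    n_hb_sw: np.ndarray = None
    n_hb_ww: np.ndarray = None
    n_outside: int = 0
    # derived (filled by finalize)
    rho_vox: np.ndarray = None
    g: np.ndarray = None
    e_dens: np.ndarray = None
    e_per_frame: np.ndarray = None
    e_sw: np.ndarray = None
    e_ww: np.ndarray = None
    hb_sw: np.ndarray = None
    hb_ww: np.ndarray = None
    finalized: bool = False

    def __post_init__(self):
        n = self.spec.n_voxels
        for name in ("n_wat", "sum_e_sw", "sum_e_ww", "sum_e_ref", "n_hb_sw", "n_hb_ww"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(n))

    def field(self, name: str) -> np.ndarray:
        """Finalized per-voxel field by name (for export)."""
        if name not in _FIELDS:
            raise KeyError(f"unknown field {name!r}; available: {', '.join(_FIELDS)}")
        v = getattr(self, name)
        if v is None:
            raise ValueError("grid not finalized")
        return v

    @property
    def field_names(self):
        return _FIELDS


def accumulate(
    trajectory: Trajectory,
    model: InteractionModel,
    spec: GridSpec,
    hbond_criteria: HBondCriteria | None = None,
) -> GistGrid:
    """Accumulate per-voxel occupancy, energy and H-bond sums over all frames."""
    if trajectory.n_frames == 0:
        raise ValueError("empty trajectory")
    if trajectory.topology.n_solvent == 0:
        raise ValueError("topology has no solvent molecules")
    ev = EnergyEvaluator(trajectory.topology, model)
    engine = (
        HBondEngine(trajectory.topology, hbond_criteria, trajectory.frames[0])
        if hbond_criteria is not None
        else None
    )
    grid = GistGrid(spec=spec, n_frames=trajectory.n_frames)
    oxy = trajectory.topology.solvent_oxygen_indices
    for frame in trajectory.frames:
        we = ev.frame_energies(frame)
        ijk, inside = assign_voxels(frame.coordinates[oxy], spec)
        grid.n_outside += int(np.sum(~inside))
        if not np.any(inside):
            continue
        flat = spec.flat_index(ijk[inside])
        np.add.at(grid.n_wat, flat, 1.0)
        np.add.at(grid.sum_e_sw, flat, we.e_sw[inside])
        np.add.at(grid.sum_e_ww, flat, we.e_ww[inside])
        np.add.at(grid.sum_e_ref, flat, we.e_tot_ref[inside])
        if engine is not None:
            hb_sw, hb_ww, _, _ = engine.per_water_counts(frame)
            np.add.at(grid.n_hb_sw, flat, hb_sw[inside])
            np.add.at(grid.n_hb_ww, flat, hb_ww[inside])
    if grid.n_outside:
        logger.info("%d water observations fell outside the grid", grid.n_outside)
    return grid


def finalize(grid: GistGrid, model: InteractionModel) -> GistGrid:
    """Fill the derived per-voxel densities; never-visited voxels stay 0."""
    v = grid.spec.voxel_volume
    occ = grid.n_wat
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_ref = np.where(occ > 0, grid.sum_e_ref / np.maximum(occ, 1), 0.0)
    grid.rho_vox = occ / (grid.n_frames * v)
    grid.g = grid.rho_vox / model.rho0
    grid.e_dens = grid.g * mean_ref
    grid.e_per_frame = grid.sum_e_ref / grid.n_frames
    grid.e_sw = grid.sum_e_sw / grid.n_frames
    grid.e_ww = grid.sum_e_ww / grid.n_frames
    grid.hb_sw = grid.n_hb_sw / grid.n_frames
    grid.hb_ww = grid.n_hb_ww / grid.n_frames
    grid.finalized = True
    return grid


# ---------------------------------------------------------------------------
# OpenDX export
# ---------------------------------------------------------------------------

def write_dx(grid: GistGrid, field_name: str, path) -> None:
    """Write one per-voxel field as an OpenDX scalar file (regular positions,
    regular connections; last index varies fastest)."""
    data = grid.field(field_name)
    spec = grid.spec
    nx, ny, nz = spec.shape
    h = spec.spacing
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.10g} {:.10g} {:.10g}\n".format(*spec.origin))
        fh.write(f"delta {h:.10g} 0 0\n")
        fh.write(f"delta 0 {h:.10g} 0\n")
        fh.write(f"delta 0 0 {h:.10g}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {spec.n_voxels} data follows\n"
        )
        flat = np.asarray(data, float).ravel()
        for i in range(0, len(flat), 3):
            fh.write(" ".join(f"{x:.17g}" for x in flat[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')


def read_dx(path):
    """Read an OpenDX scalar file written by :func:`write_dx`.

    Returns (GridSpec, flat data array in C order).
    """
    origin = None
    deltas = []
    counts = None
    data = []
    n_items = None
    with open(path) as fh:
        for line in fh:
            t = line.split()
            if not t:
                continue
            if t[0] == "object" and "gridpositions" in line:
                counts = tuple(int(x) for x in t[-3:])
            elif t[0] == "origin":
                origin = tuple(float(x) for x in t[1:4])
            elif t[0] == "delta":
                deltas.append([float(x) for x in t[1:4]])
            elif t[0] == "object" and "data follows" in line:
                n_items = int(t[t.index("items") + 1])
            elif n_items is not None and len(data) < n_items:
                try:
                    data.extend(float(x) for x in t)
                except ValueError:
                    pass
    spacing = deltas[0][0]
    spec = GridSpec(origin=origin, spacing=spacing, shape=counts)
    return spec, np.array(data[: n_items])


# ---------------------------------------------------------------------------
# Density-derived solvent-accessible surface
# ---------------------------------------------------------------------------

class SasaResult(NamedTuple):
    area: float
    face_area: float


def sasa_from_density(
    grid: GistGrid,
    g_threshold: float = 0.5,
    smoothing_sigma: float = 1.0,
) -> SasaResult:
    """Surface area of the g = ``g_threshold`` isosurface (Å²).

    The normalised density is smoothed with a Gaussian of ``smoothing_sigma``
    voxels and triangulated by marching cubes; ``face_area`` is the coarse
    voxel-face approximation (faces between voxels straddling the threshold
    times spacing²) kept as a cross-check.
    """
    from scipy.ndimage import gaussian_filter
    from skimage.measure import marching_cubes, mesh_surface_area

    if grid.g is None:
        raise ValueError("grid not finalized")
    h = grid.spec.spacing
    vol = np.asarray(grid.g, float).reshape(grid.spec.shape)
    sm = gaussian_filter(vol, sigma=smoothing_sigma)
    lo, hi = sm.min(), sm.max()
    if not (lo < g_threshold < hi):
        warnings.warn("density never crosses the threshold; surface area is 0")
        return SasaResult(0.0, 0.0)
    verts, faces, _, _ = marching_cubes(sm, level=g_threshold, spacing=(h, h, h))
    area = float(mesh_surface_area(verts, faces))
    above = sm >= g_threshold
    nfaces = 0
    for ax in range(3):
        a = np.swapaxes(above, 0, ax)
        nfaces += int(np.sum(a[1:] != a[:-1]))
    return SasaResult(area, nfaces * h * h)
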