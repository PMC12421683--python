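"""Ligand-proximity subvolumes, integrated quantities, block-averaged errors
and rigid-vs-flexible comparison rows.

A subvolume is the set of voxels whose center lies within a given distance
(inclusive) of any heavy atom of the aligned reference ligand.  Integrated
quantities are sums of the additive per-frame voxel quantities over the set;
per-water values divide by the mean water count.  Errors come from block
averaging (default four contiguous blocks).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import ReferenceStructure, Trajectory
from .energetics import EnergyEvaluator, InteractionModel
from .grid import GistGrid, GridSpec, assign_voxels
from .hbonds import HBondCriteria, HBondEngine

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubvolumeSpec:
    """Voxels whose center is within ``distance`` Å of any ligand heavy atom."""

    ligand_heavy_atoms: ReferenceStructure
    distance: float

    def __post_init__(self):
        if self.distance <= 0:
            raise ValueError("distance must be positive")

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Inclusive distance test for arbitrary points (used by site search)."""
        pts = np.atleast_2d(np.asarray(points, float))
        tree = cKDTree(self.ligand_heavy_atoms.coordinates)
        d, _ = tree.query(pts, k=1)
        return d <= self.distance


def select_voxels(grid_or_spec, spec: SubvolumeSpec) -> np.ndarray:
    """Flat indices (C order) of voxels whose center lies in the subvolume."""
    gspec: GridSpec = grid_or_spec.spec if isinstance(grid_or_spec, GistGrid) else grid_or_spec
    centers = gspec.centers()
    tree = cKDTree(spec.ligand_heavy_atoms.coordinates)
    d, _ = tree.query(centers, k=1)
    idx = np.flatnonzero(d <= spec.distance)
    if len(idx) == 0:
        logger.warning("ligand lies entirely outside the grid; empty subvolume")
    return idx


@dataclass
class IntegratedQuantities:
    """Subvolume totals (kcal/mol, counts/frame) and per-water variants."""

    distance: float
    n_water: float
    e_tot: float
    e_sw: float
    e_ww: float
    hb_sw: float
    hb_ww: float

    @property
    def per_water(self) -> dict[str, float]:
        n = self.n_water
        keys = ("e_tot", "e_sw", "e_ww", "hb_sw", "hb_ww")
        return {k: (getattr(self, k) / n if n > 0 else 0.0) for k in keys}


def integrate(grid: GistGrid, voxels: np.ndarray, distance: float = 0.0) -> IntegratedQuantities:
    """Sum the additive per-frame voxel quantities over a voxel set."""
    if not grid.finalized:
        raise ValueError("grid not finalized")
    v = np.asarray(voxels, dtype=np.int64)
    return IntegratedQuantities(
        distance=distance,
        n_water=float(np.sum(grid.n_wat[v])) / grid.n_frames,
        e_tot=float(np.sum(grid.e_per_frame[v])),
        e_sw=float(np.sum(grid.e_sw[v])),
        e_ww=float(np.sum(grid.e_ww[v])),
        hb_sw=float(np.sum(grid.hb_sw[v])),
        hb_ww=float(np.sum(grid.hb_ww[v])),
    )


@dataclass
class BlockStats:
    """Mean and standard error from contiguous block averaging."""

    block_means: np.ndarray
    mean: float
    sem: float


def block_average(series: Sequence[float], n_blocks: int = 4) -> BlockStats:
    """Split a per-frame series into ``n_blocks`` contiguous equal blocks and
    return mean of block means and their standard error (sample SD / sqrt(n)).

    Trailing frames that do not fill a block are dropped (logged).
    """
    x = np.asarray(series, dtype=float)
    if len(x) < n_blocks:
        raise ValueError(f"series of length {len(x)} shorter than {n_blocks} blocks")
    m = len(x) // n_blocks
    if len(x) % n_blocks:
        logger.info("dropping %d trailing frames for block averaging", len(x) % n_blocks)
        x = x[: m * n_blocks]
    means = x.reshape(n_blocks, m).mean(axis=1)
    sem = float(np.std(means, ddof=1) / np.sqrt(n_blocks))
    return BlockStats(block_means=means, mean=float(means.mean()), sem=sem)


# ---------------------------------------------------------------------------
# Per-frame subvolume series (for block averaging)
# ---------------------------------------------------------------------------

def per_frame_subvolume_series(
    trajectory: Trajectory,
    model: InteractionModel,
    spec: GridSpec,
    voxels: np.ndarray,
    hbond_criteria: HBondCriteria | None = None,
) -> pd.DataFrame:
    """Trajectory-direct per-frame totals over a voxel set.

    Each frame, waters whose oxygen falls in one of the selected voxels
    contribute their count, referenced energies and H-bond counts; the frame
    means of these series reproduce the grid-integrated totals exactly.
    """
    ev = EnergyEvaluator(trajectory.topology, model)
    engine = (
        HBondEngine(trajectory.topology, hbond_criteria, trajectory.frames[0])
        if hbond_criteria is not None
        else None
    )
    vox = np.zeros(spec.n_voxels, dtype=bool)
    vox[np.asarray(voxels, dtype=np.int64)] = True
    oxy = trajectory.topology.solvent_oxygen_indices
    rows = []
    for frame in trajectory.frames:
        we = ev.frame_energies(frame)
        ijk, inside = assign_voxels(frame.coordinates[oxy], spec)
        sel = np.zeros(len(oxy), dtype=bool)
        if np.any(inside):
            sel[inside] = vox[spec.flat_index(ijk[inside])]
        row = {
            "frame": frame.frame_index,
            "n_water": int(np.sum(sel)),
            "e_tot": float(np.sum(we.e_tot_ref[sel])),
            "e_sw": float(np.sum(we.e_sw[sel])),
            "e_ww": float(np.sum(we.e_ww[sel])),
        }
        if engine is not None:
            hb_sw, hb_ww, _, _ = engine.per_water_counts(frame)
            row["hb_sw"] = float(np.sum(hb_sw[sel]))
            row["hb_ww"] = float(np.sum(hb_ww[sel]))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Comparison
# ---------------------------------------------------------------------------

_DELTA_KEYS = ("n_water", "e_tot", "e_sw", "e_ww", "hb_sw", "hb_ww")


@dataclass
class ComparisonRow:
    """Rigid-vs-flexible deltas (rigid - flexible) for one subvolume."""

    distance: float
    rigid: IntegratedQuantities
    flexible: IntegratedQuantities
    delta: dict[str, float]
    delta_per_water: dict[str, float]
    rigid_stats: dict[str, BlockStats] | None = None
    flexible_stats: dict[str, BlockStats] | None = None


def compare(
    rigid: IntegratedQuantities,
    flexible: IntegratedQuantities,
    rigid_stats: dict[str, BlockStats] | None = None,
    flexible_stats: dict[str, BlockStats] | None = None,
) -> ComparisonRow:
    """Delta row: rigid minus flexible for every total and per-water value.

    Positive energy deltas mean the flexible system is more favorable.
    """
    if rigid.distance != flexible.distance:
        raise ValueError(
            f"mismatched subvolume distances: {rigid.distance} vs {flexible.distance}"
        )
    delta = {k: getattr(rigid, k) - getattr(flexible, k) for k in _DELTA_KEYS}
    rpw, fpw = rigid.per_water, flexible.per_water
    delta_pw = {k: rpw[k] - fpw[k] for k in rpw}
    return ComparisonRow(
        distance=rigid.distance,
        rigid=rigid,
        flexible=flexible,
        delta=delta,
        delta_per_water=delta_pw,
        rigid_stats=rigid_stats,
        flexible_stats=flexible_stats,
    )


def comparison_table(rows: Sequence[ComparisonRow]) -> pd.DataFrame:
    """Totals table: one row per subvolume distance."""
    recs = []
    for r in rows:
        recs.append(
            {
                "distance": r.distance,
                "e_tot_rigid": r.rigid.e_tot,
                "e_tot_flexible": r.flexible.e_tot,
                "delta_e_tot": r.delta["e_tot"],
                "e_per_water_rigid": r.rigid.per_water["e_tot"],
                "e_per_water_flexible": r.flexible.per_water["e_tot"],
                "delta_e_per_water": r.delta_per_water["e_tot"],
                "n_water_rigid": r.rigid.n_water,
                "n_water_flexible": r.flexible.n_water,
                "delta_hb_sw": r.delta["hb_sw"],
                "delta_hb_ww": r.delta["hb_ww"],
            }
        )
    return pd.DataFrame(recs)


def cross_system_average(rows: Sequence[ComparisonRow]) -> dict[str, float]:
    """Unweighted mean of per-system deltas (totals and per-water)."""
    out = {}
    for k in _DELTA_KEYS:
        out[f"delta_{k}"] = float(np.mean([r.delta[k] for r in rows]))
        out[f"delta_{k}_per_water"] = float(np.mean([r.delta_per_water[k] for r in rows]))
    return out
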