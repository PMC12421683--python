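"""Per-water interaction energies under a truncated point-charge + LJ model.

Each solvent molecule gets a solute-water energy ``e_sw``, a water-water
energy ``e_ww`` (each pair energy shared between its two partners by
``ww_split``, default 1/2 so that grid and subvolume totals are additive),
and a total ``e_tot_ref = e_sw + e_ww - e_neat`` referenced to the mean
potential energy of one molecule in neat solvent.

Conventions:

* electrostatics and LJ are truncated at ``cutoff``; no Ewald or switching;
* solute-water sums gate each (water molecule, solute atom) pair by the
  water-oxygen distance, so a neutral water molecule is never split across
  the truncation sphere (splitting it produces multi-kcal/mol artifacts
  near charged solute sites);
* water-water sums are gated at the molecule level by the oxygen-oxygen
  minimum-image distance, so a molecule pair is included whole or not at all;
* Lorentz-Berthelot combination (arithmetic sigma, geometric epsilon).

The generic :func:`pair_energy` helper applies a plain per-atom-pair cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    Frame,
    Topology,
    Trajectory,
    minimum_image_displacement,
    distance_matrix,
)

#: Coulomb constant in kcal·Å/(mol·e²)
COULOMB_CONSTANT = 332.0636

#: minimum separation (Å) below which interacting atoms are deemed overlapping
OVERLAP_TOL = 1e-6


class OverlapError(ValueError):
    """Two interacting atoms closer than the overlap tolerance."""


@dataclass
class InteractionModel:
    """Nonbonded model constants.

    Parameters
    ----------
    coulomb_constant : kcal·Å/(mol·e²).
    cutoff : Å; interactions beyond it contribute zero.
    e_neat : kcal/mol, mean potential energy of one molecule in neat solvent
        (the reference subtracted from every water's total energy).
    rho0 : molecules/Å³, number density of the neat solvent.
    ww_split : fraction of each water-water pair energy credited to each
        partner; 0.5 makes per-water sums additive without double counting.
    """

    coulomb_constant: float = COULOMB_CONSTANT
    cutoff: float = 10.0
    e_neat: float = -12.259
    rho0: float = 0.0334
    ww_split: float = 0.5

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if not (0 < self.ww_split <= 1):
            raise ValueError("ww_split must be in (0, 1]")
        if self.rho0 <= 0:
            raise ValueError("rho0 must be positive")


@dataclass
class AtomGroup:
    """Coordinates plus per-atom nonbonded parameters for one atom set."""

    coords: np.ndarray
    charge: np.ndarray
    sigma: np.ndarray
    epsilon: np.ndarray

    @classmethod
    def from_topology(
        cls, topology: Topology, indices: Sequence[int], coordinates: np.ndarray
    ) -> "AtomGroup":
        idx = np.asarray(indices, dtype=np.int64)
        return cls(
            coords=np.asarray(coordinates, float)[idx],
            charge=topology.charges[idx],
            sigma=topology.lj_sigma[idx],
            epsilon=topology.lj_epsilon[idx],
        )

    def __len__(self) -> int:
        return len(self.coords)


def _pair_terms(r, qq, sig, eps, coulomb_constant):
    """Energy per atom pair at distances r (no cutoff masking here)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        coul = coulomb_constant * qq / r
        sr6 = (sig / r) ** 6
        lj = 4.0 * eps * (sr6 * sr6 - sr6)
    return coul + lj


def pair_energy(a: AtomGroup, b: AtomGroup, model: InteractionModel, box) -> float:
    """Total nonbonded energy between two disjoint atom groups (kcal/mol).

    Sum over atom pairs of ``k q_i q_j / r + 4 eps_ij ((sig_ij/r)^12 -
    (sig_ij/r)^6)`` with Lorentz-Berthelot combination, minimum-image
    distances and a per-pair cutoff.  Raises :class:`OverlapError` when two
    interacting atoms lie closer than 1e-6 Å.
    """
    r = distance_matrix(a.coords, b.coords, box)
    qq = np.outer(a.charge, b.charge)
    sig = 0.5 * (a.sigma[:, None] + b.sigma[None, :])
    eps = np.sqrt(np.outer(a.epsilon, b.epsilon))
    interacting = (qq != 0) | (eps > 0)
    if np.any((r < OVERLAP_TOL) & interacting):
        raise OverlapError("overlapping atoms (r < 1e-6 Å) with nonzero interaction")
    e = _pair_terms(r, qq, sig, eps, model.coulomb_constant)
    e = np.where((r <= model.cutoff) & interacting, e, 0.0)
    return float(np.sum(e))


@dataclass
class WaterEnergies:
    """Per-solvent-molecule energies for one frame (kcal/mol)."""

    molecule_ids: np.ndarray
    e_sw: np.ndarray
    e_ww: np.ndarray
    e_tot_ref: np.ndarray
    frame_index: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frame_index,
                "molecule_id": self.molecule_ids,
                "e_sw": self.e_sw,
                "e_ww": self.e_ww,
                "e_tot_ref": self.e_tot_ref,
            }
        )


class EnergyEvaluator:
    """Vectorised per-water energy evaluation bound to one topology/model.

    The same object (and hence the identical potential) is used by the grid
    accumulator, the hydration-site thermodynamics and the Monte Carlo
    generator, so sampled and re-evaluated energies agree exactly.
    """

    def __init__(self, topology: Topology, model: InteractionModel):
        self.topology = topology
        self.model = model
        self.water_atoms = topology.water_atom_matrix()  # (n_w, k)
        self.oxygen_indices = topology.solvent_oxygen_indices
        self.solute_indices = topology.solute_indices
        k = self.water_atoms.shape[1]
        w0 = self.water_atoms[0]
        self.q_w = topology.charges[w0]
        self.sig_w = topology.lj_sigma[w0]
        self.eps_w = topology.lj_epsilon[w0]
        # parameter tables are identical across solvent molecules of one model
        for row in self.water_atoms:
            if not (
                np.array_equal(topology.charges[row], self.q_w)
                and np.array_equal(topology.lj_sigma[row], self.sig_w)
            ):
                raise ValueError("solvent molecules have heterogeneous parameters")
        self._qq_ww = np.outer(self.q_w, self.q_w)  # (k, k)
        self._sig_ww = 0.5 * (self.sig_w[:, None] + self.sig_w[None, :])
        self._eps_ww = np.sqrt(np.outer(self.eps_w, self.eps_w))
        self._act_ww = (self._qq_ww != 0) | (self._eps_ww > 0)
        s = self.solute_indices
        self.q_s = topology.charges[s]
        self._qq_sw = np.outer(self.q_w, self.q_s)  # (k, n_s)
        self._sig_sw = 0.5 * (self.sig_w[:, None] + topology.lj_sigma[s][None, :])
        self._eps_sw = np.sqrt(np.outer(self.eps_w, topology.lj_epsilon[s]))
        self._act_sw = (self._qq_sw != 0) | (self._eps_sw > 0)

    # -- water-water --------------------------------------------------------

    def _ww_pair_list(self, coords: np.ndarray, box: np.ndarray):
        """Molecule pairs (i<j) whose O-O minimum-image distance is within cutoff."""
        O = coords[self.oxygen_indices]
        d = distance_matrix(O, O, box)
        iu, ju = np.triu_indices(len(O), k=1)
        keep = d[iu, ju] <= self.model.cutoff
        return iu[keep], ju[keep]

    def _ww_pair_energies(self, coords, box, pi, pj) -> np.ndarray:
        if len(pi) == 0:
            return np.zeros(0)
        W = coords[self.water_atoms]  # (n_w, k, 3)
        disp = W[pi][:, :, None, :] - W[pj][:, None, :, :]
        disp = minimum_image_displacement(disp, box)
        r = np.sqrt(np.einsum("...k,...k->...", disp, disp))
        if np.any((r < OVERLAP_TOL) & self._act_ww):
            raise OverlapError("overlapping solvent atoms")
        e = _pair_terms(r, self._qq_ww, self._sig_ww, self._eps_ww, self.model.coulomb_constant)
        e = np.where(self._act_ww, e, 0.0)
        return e.sum(axis=(1, 2))

    # -- solute-water -------------------------------------------------------

    def solute_water_energies(self, coords: np.ndarray, box: np.ndarray) -> np.ndarray:
        """e_sw for every solvent molecule (oxygen-gated molecular cutoff)."""
        n_w = len(self.water_atoms)
        if len(self.solute_indices) == 0:
            return np.zeros(n_w)
        W = coords[self.water_atoms]  # (n_w, k, 3)
        S = coords[self.solute_indices]  # (n_s, 3)
        disp = W[:, :, None, :] - S[None, None, :, :]
        disp = minimum_image_displacement(disp, box)
        r = np.sqrt(np.einsum("...k,...k->...", disp, disp))
        if np.any((r < OVERLAP_TOL) & self._act_sw):
            raise OverlapError("overlapping solute/solvent atoms")
        r_gate = distance_matrix(coords[self.oxygen_indices], S, box)  # (n_w, n_s)
        e = _pair_terms(r, self._qq_sw, self._sig_sw, self._eps_sw, self.model.coulomb_constant)
        e = np.where((r_gate[:, None, :] <= self.model.cutoff) & self._act_sw, e, 0.0)
        return e.sum(axis=(1, 2))

    # -- public API ---------------------------------------------------------

    def frame_energies(self, frame: Frame) -> WaterEnergies:
        """Per-water e_sw, e_ww and referenced total for one frame."""
        coords, box = frame.coordinates, frame.box
        e_sw = self.solute_water_energies(coords, box)
        pi, pj = self._ww_pair_list(coords, box)
        pe = self._ww_pair_energies(coords, box, pi, pj)
        e_ww = np.zeros(len(self.water_atoms))
        np.add.at(e_ww, pi, pe)
        np.add.at(e_ww, pj, pe)
        e_ww *= self.model.ww_split
        return WaterEnergies(
            molecule_ids=self.topology.solvent_molecule_ids,
            e_sw=e_sw,
            e_ww=e_ww,
            e_tot_ref=e_sw + e_ww - self.model.e_neat,
            frame_index=frame.frame_index,
        )

    def single_water_energy(self, w: int, coords: np.ndarray, box: np.ndarray) -> float:
        """Full (unsplit) interaction energy of solvent molecule ``w`` with
        everything else — the quantity a Metropolis move of that molecule
        changes."""
        e = 0.0
        if len(self.solute_indices) > 0:
            e += float(self.solute_water_energies_single(w, coords, box))
        O = coords[self.oxygen_indices]
        d = np.sqrt(
            np.sum(minimum_image_displacement(O - O[w], box) ** 2, axis=-1)
        )
        others = np.flatnonzero((d <= self.model.cutoff) & (np.arange(len(O)) != w))
        if len(others) > 0:
            pe = self._ww_pair_energies(
                coords, box, np.full(len(others), w), others
            )
            e += float(np.sum(pe))
        return e

    def solute_water_energies_single(self, w: int, coords, box) -> float:
        Wc = coords[self.water_atoms[w]]  # (k, 3)
        S = coords[self.solute_indices]
        disp = minimum_image_displacement(Wc[:, None, :] - S[None, :, :], box)
        r = np.sqrt(np.einsum("...k,...k->...", disp, disp))
        if np.any((r < OVERLAP_TOL) & self._act_sw):
            raise OverlapError("overlapping solute/solvent atoms")
        o = coords[self.oxygen_indices[w]]
        r_gate = np.sqrt(
            np.sum(minimum_image_displacement(o - S, box) ** 2, axis=-1)
        )
        e = _pair_terms(r, self._qq_sw, self._sig_sw, self._eps_sw, self.model.coulomb_constant)
        e = np.where((r_gate[None, :] <= self.model.cutoff) & self._act_sw, e, 0.0)
        return float(e.sum())

    def solute_subset_water_energy(
        self, subset: np.ndarray, positions: np.ndarray, coords, box
    ) -> float:
        """Interaction of a solute-atom subset (at ``positions``) with all
        solvent, under the same oxygen-gated molecular cutoff as ``e_sw``.

        Used by the Monte Carlo gate-flip move so sampled and analysed
        energies share one convention."""
        subset = np.asarray(subset, dtype=np.int64)
        sub_pos = np.asarray(positions, float)
        W = coords[self.water_atoms]  # (n_w, k, 3)
        disp = minimum_image_displacement(
            W[:, :, None, :] - sub_pos[None, None, :, :], box
        )
        r = np.sqrt(np.einsum("...k,...k->...", disp, disp))
        q_s = self.topology.charges[subset]
        qq = np.outer(self.q_w, q_s)
        sig = 0.5 * (self.sig_w[:, None] + self.topology.lj_sigma[subset][None, :])
        eps = np.sqrt(np.outer(self.eps_w, self.topology.lj_epsilon[subset]))
        act = (qq != 0) | (eps > 0)
        if np.any((r < OVERLAP_TOL) & act):
            raise OverlapError("overlapping solute/solvent atoms")
        r_gate = distance_matrix(coords[self.oxygen_indices], sub_pos, box)
        e = _pair_terms(r, qq, sig, eps, self.model.coulomb_constant)
        e = np.where((r_gate[:, None, :] <= self.model.cutoff) & act, e, 0.0)
        return float(e.sum())

    def total_energy(self, frame: Frame) -> float:
        """Total nonbonded energy of a configuration (solute-water plus
        unique-pair water-water), independent of ``ww_split``."""
        coords, box = frame.coordinates, frame.box
        e = float(np.sum(self.solute_water_energies(coords, box)))
        pi, pj = self._ww_pair_list(coords, box)
        e += float(np.sum(self._ww_pair_energies(coords, box, pi, pj)))
        return e


def water_energies(frame: Frame, topology: Topology, model: InteractionModel) -> WaterEnergies:
    """One-shot convenience wrapper around :class:`EnergyEvaluator`."""
    return EnergyEvaluator(topology, model).frame_energies(frame)


def trajectory_energies(trajectory: Trajectory, model: InteractionModel) -> list[WaterEnergies]:
    ev = EnergyEvaluator(trajectory.topology, model)
    return [ev.frame_energies(f) for f in trajectory.frames]


def energies_to_tsv(per_frame: list[WaterEnergies], path) -> None:
    pd.concat([we.to_dataframe() for we in per_frame]).to_csv(path, sep="\t", index=False)
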