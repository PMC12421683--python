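"""Geometric hydrogen-bond detection, neighbor counts, per-group solvation
statistics and side-chain conformer occupancies.

A hydrogen bond is declared when the donor and acceptor heavy atoms are
closer than ``heavy_distance_max`` (strict, "less than") and the angle at the
donor heavy atom between the donor->acceptor and donor->hydrogen directions
is smaller than ``angle_max`` (strict).  An alternative convention measures
the deviation of the donor-hydrogen-acceptor angle from linearity instead;
the two conventions never mix within one criteria object.

"Neighbors" are water oxygens within ``cutoff`` (inclusive, "within") of any
heavy atom of a group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .core import (
    Frame,
    ROLE_SOLUTE,
    ROLE_SOLVENT_OXYGEN,
    Topology,
    Trajectory,
    distance_matrix,
    minimum_image_displacement,
)

logger = logging.getLogger(__name__)

HB_SOLUTE_WATER = "solute-water"
HB_WATER_WATER = "water-water"
HB_SOLUTE_SOLUTE = "solute-solute"

#: maximum covalent O/N/S-H bond length used to attach hydrogens to donors
COVALENT_H_MAX = 1.25


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond definition."""

    heavy_distance_max: float = 3.6
    angle_max: float = 30.0
    angle_convention: str = "acceptor_donor_hydrogen"
    polar_elements: frozenset = frozenset({"N", "O", "S"})

    def __post_init__(self):
        if self.heavy_distance_max <= 0:
            raise ValueError("distance must be positive")
        if not (0 < self.angle_max <= 180):
            raise ValueError("angle must be in (0, 180]")
        if self.angle_convention not in ("acceptor_donor_hydrogen", "donor_hydrogen_acceptor"):
            raise ValueError(f"unknown angle convention {self.angle_convention!r}")


class HBond(NamedTuple):
    donor_heavy: int
    hydrogen: int
    acceptor_heavy: int
    kind: str


@dataclass
class FunctionalGroup:
    """A labelled set of polar heavy atoms (e.g. SER289-OG) with its donor
    hydrogens and donor/acceptor capability."""

    label: str
    atom_ids: Sequence[int]
    donor_hydrogens: Sequence[int] = field(default_factory=tuple)
    capability: str = "both"

    def __post_init__(self):
        if len(self.atom_ids) == 0:
            raise ValueError(f"group {self.label}: empty atom set")
        if self.capability not in ("donor", "acceptor", "both"):
            raise ValueError(f"group {self.label}: bad capability {self.capability!r}")
        if self.capability in ("donor", "both") and len(self.donor_hydrogens) == 0:
            raise ValueError(f"group {self.label}: donor capability without hydrogens")


class HBondEngine:
    """Vectorised hydrogen-bond detector bound to one topology.

    Donor (heavy, hydrogen) pairs and acceptor candidates are resolved once:
    water oxygens donate through their molecule's hydrogens and accept; polar
    solute heavy atoms (N/O/S by default) accept, and donate through
    hydrogens of the same residue within 1.25 Å in the attachment frame.
    """

    def __init__(
        self,
        topology: Topology,
        criteria: HBondCriteria = HBondCriteria(),
        attach_frame: Frame | None = None,
    ):
        self.topology = topology
        self.criteria = criteria
        top = topology
        dh: list[tuple[int, int]] = []
        acc: list[int] = []
        # solvent
        for row in top.water_atom_matrix():
            o = [i for i in row if top.roles[i] == ROLE_SOLVENT_OXYGEN][0]
            acc.append(o)
            for i in row:
                if top.roles[i] == "solvent_hydrogen":
                    dh.append((o, i))
        # solute
        solute = top.solute_indices
        polar = [i for i in solute if top.elements[i] in criteria.polar_elements]
        acc.extend(polar)
        solute_h = [i for i in solute if top.elements[i] == "H"]
        if polar and solute_h:
            if attach_frame is None:
                raise ValueError("solute has polar atoms and hydrogens; attach_frame required")
            c = attach_frame.coordinates
            for h in solute_h:
                d = np.linalg.norm(c[polar] - c[h], axis=1)
                near = [p for p, dd in zip(polar, d)
                        if dd < COVALENT_H_MAX and top.residue_ids[p] == top.residue_ids[h]]
                if near:
                    dh.append((near[int(np.argmin([np.linalg.norm(c[p] - c[h]) for p in near]))], h))
        self.donor_heavy = np.array([p[0] for p in dh], dtype=np.int64)
        self.donor_h = np.array([p[1] for p in dh], dtype=np.int64)
        self.acceptors = np.array(acc, dtype=np.int64)
        self._mol_of_water_o = {
            int(o): j for j, o in enumerate(top.solvent_oxygen_indices)
        }

    # -- detection ----------------------------------------------------------

    def detect(self, frame: Frame) -> list[HBond]:
        return self._detect_arrays(frame)[0]

    def _detect_arrays(self, frame: Frame):
        """Return (bond list, donor-pair index array, acceptor index array)."""
        top, crit = self.topology, self.criteria
        coords, box = frame.coordinates, frame.box
        dheavy, dh, acc = self.donor_heavy, self.donor_h, self.acceptors
        if len(dheavy) == 0 or len(acc) == 0:
            return [], np.zeros(0, int), np.zeros(0, int)
        r = distance_matrix(coords[dheavy], coords[acc], box)  # (D, A)
        mask = (r < crit.heavy_distance_max) & (r > 1e-9)
        # exclusions: same heavy atom; donor and acceptor within one solvent
        # molecule; solute-solute within one residue
        same_atom = dheavy[:, None] == acc[None, :]
        same_mol = top.molecule_ids[dheavy][:, None] == top.molecule_ids[acc][None, :]
        solvent_d = (top.roles[dheavy] != ROLE_SOLUTE)[:, None]
        solvent_a = (top.roles[acc] != ROLE_SOLUTE)[None, :]
        solute_pair = ~solvent_d & ~solvent_a
        same_res = top.residue_ids[dheavy][:, None] == top.residue_ids[acc][None, :]
        mask &= ~same_atom
        mask &= ~(same_mol & (solvent_d | solvent_a))
        mask &= ~(solute_pair & same_res)
        if crit.angle_convention == "acceptor_donor_hydrogen":
            v_da = minimum_image_displacement(coords[acc][None, :, :] - coords[dheavy][:, None, :], box)
            v_dh = minimum_image_displacement(coords[dh] - coords[dheavy], box)
            denom = np.linalg.norm(v_da, axis=-1) * np.linalg.norm(v_dh, axis=-1)[:, None]
            with np.errstate(divide="ignore", invalid="ignore"):
                cosang = np.einsum("dak,dk->da", v_da, v_dh) / denom
            mask &= denom > 0
            mask &= cosang > np.cos(np.radians(crit.angle_max))
        else:  # donor_hydrogen_acceptor: within angle_max of linearity
            v_ha = minimum_image_displacement(coords[acc][None, :, :] - coords[dh][:, None, :], box)
            v_hd = minimum_image_displacement(coords[dheavy] - coords[dh], box)
            denom = np.linalg.norm(v_ha, axis=-1) * np.linalg.norm(v_hd, axis=-1)[:, None]
            with np.errstate(divide="ignore", invalid="ignore"):
                cosang = np.einsum("dak,dk->da", v_ha, v_hd) / denom
            mask &= denom > 0
            mask &= cosang < np.cos(np.radians(180.0 - crit.angle_max))
        di, ai = np.nonzero(mask)
        bonds = []
        for d, a in zip(di, ai):
            d_solvent = top.roles[dheavy[d]] != ROLE_SOLUTE
            a_solvent = top.roles[acc[a]] != ROLE_SOLUTE
            kind = (
                HB_WATER_WATER
                if d_solvent and a_solvent
                else HB_SOLUTE_SOLUTE
                if not d_solvent and not a_solvent
                else HB_SOLUTE_WATER
            )
            bonds.append(HBond(int(dheavy[d]), int(dh[d]), int(acc[a]), kind))
        return bonds, di, ai

    # -- per-water aggregation ---------------------------------------------

    def per_water_counts(self, frame: Frame):
        """(hb_sw, hb_ww, donates_to_solute, accepts_from_solute) per solvent
        molecule.

        Water-water bonds are credited to both partners (each bond counted
        once globally, twice across the per-water vectors); solute-water
        bonds to the participating water.
        """
        n_w = len(self.topology.solvent_oxygen_indices)
        hb_sw = np.zeros(n_w)
        hb_ww = np.zeros(n_w)
        donates = np.zeros(n_w, dtype=bool)
        accepts = np.zeros(n_w, dtype=bool)
        for b in self._detect_arrays(frame)[0]:
            if b.kind == HB_WATER_WATER:
                hb_ww[self._mol_of_water_o[b.donor_heavy]] += 1
                hb_ww[self._mol_of_water_o[b.acceptor_heavy]] += 1
            elif b.kind == HB_SOLUTE_WATER:
                if b.donor_heavy in self._mol_of_water_o:
                    w = self._mol_of_water_o[b.donor_heavy]
                    donates[w] = True
                else:
                    w = self._mol_of_water_o[b.acceptor_heavy]
                    accepts[w] = True
                hb_sw[w] += 1
        return hb_sw, hb_ww, donates, accepts


def detect_hbonds(
    frame: Frame,
    topology: Topology,
    criteria: HBondCriteria = HBondCriteria(),
    attach_frame: Frame | None = None,
) -> list[HBond]:
    """Detect hydrogen bonds in one frame (convenience wrapper)."""
    return HBondEngine(topology, criteria, attach_frame or frame)._detect_arrays(frame)[0]


def count_neighbors(
    frame: Frame, topology: Topology, group: FunctionalGroup, cutoff: float = 3.6
) -> int:
    """Water oxygens within ``cutoff`` (inclusive) of any heavy group atom."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    oxy = topology.solvent_oxygen_indices
    idx = np.asarray(group.atom_ids, dtype=np.int64)
    if len(idx) == 0:
        raise ValueError("empty group")
    r = distance_matrix(frame.coordinates[oxy], frame.coordinates[idx], frame.box)
    return int(np.sum(np.any(r <= cutoff, axis=1)))


@dataclass
class GroupSolvationStats:
    """Per-group means over frames plus their totals (table layout)."""

    labels: list[str]
    mean_water_neighbors: np.ndarray
    mean_water_hbonds: np.ndarray

    @property
    def total_neighbors(self) -> float:
        return float(np.sum(self.mean_water_neighbors))

    @property
    def total_hbonds(self) -> float:
        return float(np.sum(self.mean_water_hbonds))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "group": self.labels + ["total"],
                "mean_water_neighbors": np.append(self.mean_water_neighbors, self.total_neighbors),
                "mean_water_hbonds": np.append(self.mean_water_hbonds, self.total_hbonds),
            }
        )
        return df


def group_stats(
    trajectory: Trajectory,
    groups: Sequence[FunctionalGroup],
    criteria: HBondCriteria = HBondCriteria(),
    neighbor_cutoff: float = 3.6,
) -> GroupSolvationStats:
    """Average water-neighbor and group-water hydrogen-bond counts per frame."""
    top = trajectory.topology
    engine = HBondEngine(top, criteria, trajectory.frames[0])
    group_sets = [set(int(i) for i in g.atom_ids) for g in groups]
    water_o = set(int(i) for i in top.solvent_oxygen_indices)
    nb = np.zeros(len(groups))
    hb = np.zeros(len(groups))
    for frame in trajectory.frames:
        bonds = engine._detect_arrays(frame)[0]
        for gi, g in enumerate(groups):
            nb[gi] += count_neighbors(frame, top, g, neighbor_cutoff)
            for b in bonds:
                if b.kind != HB_SOLUTE_WATER:
                    continue
                solute_end = b.donor_heavy if b.acceptor_heavy in water_o else b.acceptor_heavy
                if solute_end in group_sets[gi]:
                    hb[gi] += 1
    n = trajectory.n_frames
    return GroupSolvationStats(
        labels=[g.label for g in groups],
        mean_water_neighbors=nb / n,
        mean_water_hbonds=hb / n,
    )


def conformer_occupancy(
    trajectory: Trajectory,
    probe_atom: int,
    reference_positions: dict[str, np.ndarray],
    assign_rule: str = "nearest",
) -> dict[str, float]:
    """Fraction of frames in which the probe atom is nearest each labelled
    reference position (minimum-image).  Exact ties go to the first label in
    input order and are logged."""
    if assign_rule != "nearest":
        raise ValueError("only 'nearest' assignment is supported")
    labels = list(reference_positions)
    if len(labels) < 2:
        raise ValueError("need at least 2 labelled reference positions")
    refs = np.array([reference_positions[k] for k in labels], dtype=float)
    counts = dict.fromkeys(labels, 0)
    for frame in trajectory.frames:
        p = frame.coordinates[probe_atom]
        d = np.sqrt(
            np.sum(minimum_image_displacement(refs - p, frame.box) ** 2, axis=1)
        )
        best = int(np.argmin(d))
        if np.sum(d == d[best]) > 1:
            logger.info("frame %d: tie between references, assigned to %s",
                        frame.frame_index, labels[best])
        counts[labels[best]] += 1
    n = trajectory.n_frames
    return {k: counts[k] / n for k in labels}


def read_groups_tsv(path, topology: Topology, attach_frame: Frame) -> list[FunctionalGroup]:
    """Read functional-group definitions (label, residue_id, atom_names,
    capability); donor hydrogens are attached by covalent distance."""
    df = pd.read_csv(path, sep="\t", comment="#")
    groups = []
    c = attach_frame.coordinates
    for _, row in df.iterrows():
        names = [s.strip() for s in str(row["atom_names"]).split(",")]
        ids = np.flatnonzero(
            (topology.residue_ids == int(row["residue_id"]))
            & np.isin(topology.names, names)
        )
        if len(ids) == 0:
            raise ValueError(f"group {row['label']}: no matching atoms")
        hyd = []
        for h in np.flatnonzero(
            (topology.residue_ids == int(row["residue_id"])) & (topology.elements == "H")
        ):
            if np.min(np.linalg.norm(c[ids] - c[h], axis=1)) < COVALENT_H_MAX:
                hyd.append(int(h))
        groups.append(
            FunctionalGroup(
                label=str(row["label"]),
                atom_ids=[int(i) for i in ids],
                donor_hydrogens=hyd,
                capability=str(row["capability"]),
            )
        )
    return groups
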