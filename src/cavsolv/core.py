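"""Topology and trajectory data model, file I/O, periodic geometry, superposition.

The solvation-mapping pipeline works on a fixed topology (atoms with partial
charges, Lennard-Jones parameters and solute/solvent roles) plus an ordered
sequence of frames (coordinates and an orthorhombic periodic box).  Topologies
are read from PDB files with a sidecar parameter table; frames come either
from multi-model PDB files or from a simple XYZ-with-box text dialect.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio
from scipy.spatial.transform import Rotation

logger = logging.getLogger(__name__)

#: atom roles
ROLE_SOLUTE = "solute"
ROLE_SOLVENT_OXYGEN = "solvent_oxygen"
ROLE_SOLVENT_HYDROGEN = "solvent_hydrogen"
ROLE_SOLVENT_VIRTUAL = "solvent_virtual"
ROLES = (ROLE_SOLUTE, ROLE_SOLVENT_OXYGEN, ROLE_SOLVENT_HYDROGEN, ROLE_SOLVENT_VIRTUAL)

#: residue names auto-detected as water
DEFAULT_WATER_RESIDUES = frozenset({"WAT", "HOH", "SOL", "TIP", "OPC"})


class TopologyError(ValueError):
    """Raised for malformed topology input or missing parameters."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, partial charge (e), LJ parameters (Å, kcal/mol), role."""

    index: int
    name: str
    residue_name: str
    residue_id: int
    element: str
    charge: float
    lj_sigma: float
    lj_epsilon: float
    molecule_id: int
    role: str


class Topology:
    """Immutable collection of :class:`AtomRecord` with array views.

    Validates on construction that every solvent molecule has exactly one
    solvent oxygen, that each solvent molecule is net neutral to 1e-6 e, and
    that LJ parameters are non-negative.
    """

    def __init__(self, atoms: Sequence[AtomRecord]):
        self.atoms = tuple(atoms)
        n = len(self.atoms)
        if n == 0:
            raise TopologyError("topology has no atoms")
        self.names = np.array([a.name for a in self.atoms])
        self.residue_names = np.array([a.residue_name for a in self.atoms])
        self.residue_ids = np.array([a.residue_id for a in self.atoms], dtype=np.int64)
        self.elements = np.array([a.element for a in self.atoms])
        self.charges = np.array([a.charge for a in self.atoms], dtype=np.float64)
        self.lj_sigma = np.array([a.lj_sigma for a in self.atoms], dtype=np.float64)
        self.lj_epsilon = np.array([a.lj_epsilon for a in self.atoms], dtype=np.float64)
        self.molecule_ids = np.array([a.molecule_id for a in self.atoms], dtype=np.int64)
        self.roles = np.array([a.role for a in self.atoms])
        self._validate()

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        bad = set(self.roles) - set(ROLES)
        if bad:
            raise TopologyError(f"unknown roles: {sorted(bad)}")
        if np.any(self.lj_sigma < 0) or np.any(self.lj_epsilon < 0):
            raise TopologyError("negative Lennard-Jones parameters")
        for mol in self.solvent_molecule_ids:
            sel = self.molecule_ids == mol
            n_ox = int(np.sum(self.roles[sel] == ROLE_SOLVENT_OXYGEN))
            if n_ox != 1:
                raise TopologyError(
                    f"solvent molecule {mol} has {n_ox} solvent_oxygen atoms (need 1)"
                )
            q = float(np.sum(self.charges[sel]))
            if abs(q) > 1e-6:
                raise TopologyError(
                    f"solvent molecule {mol} has net charge {q:+.2e} e (must be 0)"
                )

    # -- derived views ------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def solute_indices(self) -> np.ndarray:
        return np.flatnonzero(self.roles == ROLE_SOLUTE)

    @property
    def solvent_mask(self) -> np.ndarray:
        return self.roles != ROLE_SOLUTE

    @property
    def solvent_oxygen_indices(self) -> np.ndarray:
        return np.flatnonzero(self.roles == ROLE_SOLVENT_OXYGEN)

    @property
    def solvent_molecule_ids(self) -> np.ndarray:
        """Sorted unique molecule ids of solvent molecules."""
        return np.unique(self.molecule_ids[self.solvent_mask])

    @property
    def n_solvent(self) -> int:
        return len(self.solvent_molecule_ids)

    def water_atom_matrix(self) -> np.ndarray:
        """Atom indices of each solvent molecule as an (n_solvent, k) array.

        Requires every solvent molecule to have the same atom count (true for
        any single rigid water model); raises :class:`TopologyError` otherwise.
        """
        mols = self.solvent_molecule_ids
        groups = [np.flatnonzero((self.molecule_ids == m) & self.solvent_mask) for m in mols]
        sizes = {len(g) for g in groups}
        if len(sizes) > 1:
            raise TopologyError(f"solvent molecules have mixed atom counts: {sorted(sizes)}")
        return np.array(groups, dtype=np.int64)

    def __len__(self) -> int:
        return self.n_atoms

    def __repr__(self) -> str:
        return f"Topology({self.n_atoms} atoms, {self.n_solvent} solvent molecules)"


@dataclass
class Frame:
    """Coordinates (Å) for every topology atom plus an orthorhombic box (Å)."""

    coordinates: np.ndarray
    box: np.ndarray
    frame_index: int = 0

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be (n_atoms, 3)")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive lengths")


@dataclass
class Trajectory:
    """Ordered frames sharing one topology; ``frame_interval`` in ps."""

    topology: Topology
    frames: list[Frame] = field(default_factory=list)
    frame_interval: float = 1.0

    def __post_init__(self):
        idx = [f.frame_index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("frame_index must be strictly increasing")
        for f in self.frames:
            if f.coordinates.shape[0] != self.topology.n_atoms:
                raise ValueError(
                    f"frame {f.frame_index}: {f.coordinates.shape[0]} coordinates "
                    f"for {self.topology.n_atoms} atoms"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class ReferenceStructure:
    """Named coordinate subset (e.g. ligand heavy atoms) used for subvolumes
    and superposition."""

    coordinates: np.ndarray
    atom_names: Sequence[str]

    def __post_init__(self):
        self.coordinates = np.atleast_2d(np.asarray(self.coordinates, dtype=np.float64))
        if self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be (n, 3)")
        if len(self.atom_names) != len(self.coordinates):
            raise ValueError("atom_names length mismatch")


# ---------------------------------------------------------------------------
# Periodic geometry
# ---------------------------------------------------------------------------

def minimum_image_displacement(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the minimum image of an orthorhombic box."""
    box = np.asarray(box, dtype=np.float64)
    if np.any(box <= 0):
        raise ValueError("box lengths must be positive")
    return delta - box * np.round(delta / box)


def minimum_image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image Euclidean distance between points (broadcasts over leading axes)."""
    d = minimum_image_displacement(np.asarray(a, float) - np.asarray(b, float), box)
    return np.sqrt(np.sum(d * d, axis=-1))


def distance_matrix(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """All-pairs minimum-image distances, shape (len(a), len(b))."""
    d = minimum_image_displacement(a[:, None, :] - b[None, :, :], box)
    return np.sqrt(np.einsum("ijk,ijk->ij", d, d))


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def superpose(
    frame: Frame,
    reference: ReferenceStructure,
    atom_selection: Sequence[int],
) -> Frame:
    """Rigidly transform ``frame`` so the selected atoms best fit the reference.

    Least-squares (Kabsch) rotation plus translation on the selection; the
    whole frame is transformed identically.  The selection must contain at
    least three non-collinear atoms.
    """
    sel = np.asarray(atom_selection, dtype=np.int64)
    if len(sel) < 3:
        raise ValueError("superposition needs at least 3 atoms")
    mobile = frame.coordinates[sel]
    ref = reference.coordinates
    if len(ref) != len(sel):
        raise ValueError("selection and reference sizes differ")
    mob_c = mobile - mobile.mean(axis=0)
    s = np.linalg.svd(mob_c, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) selection")
    rot, _ = Rotation.align_vectors(ref - ref.mean(axis=0), mob_c)
    new_coords = rot.apply(frame.coordinates - mobile.mean(axis=0)) + ref.mean(axis=0)
    return replace(frame, coordinates=new_coords)


def selection_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (non-periodic) RMSD between matched coordinate sets."""
    d = np.asarray(a, float) - np.asarray(b, float)
    return float(np.sqrt(np.mean(np.sum(d * d, axis=-1))))


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

PARAM_COLUMNS = ["residue_name", "atom_name", "charge", "sigma", "epsilon", "role"]


def read_parameter_table(params_path: str | Path) -> pd.DataFrame:
    """Read the sidecar TSV mapping (residue_name, atom_name) to parameters."""
    df = pd.read_csv(params_path, sep="\t", comment="#")
    missing = set(PARAM_COLUMNS) - set(df.columns)
    if missing:
        raise TopologyError(f"parameter table missing columns: {sorted(missing)}")
    return df.set_index(["residue_name", "atom_name"])


def _validate_pdb_lines(text: str) -> None:
    for i, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            if len(line) < 54:
                raise TopologyError(f"malformed PDB line {i}: record too short")
            try:
                float(line[30:38]), float(line[38:46]), float(line[46:54])
            except ValueError as exc:
                raise TopologyError(f"malformed PDB line {i}: bad coordinates") from exc


def read_topology(
    pdb_path: str | Path,
    params_path: str | Path,
    water_residues: Iterable[str] = DEFAULT_WATER_RESIDUES,
) -> Topology:
    """Build a :class:`Topology` from a PDB file and a parameter table.

    Water residues (by residue name) become solvent molecules, one molecule
    per residue; all other atoms are solute (molecule 0).  Roles come from the
    parameter table.
    """
    text = Path(pdb_path).read_text()
    _validate_pdb_lines(text)
    pdb = pdbio.PDBFile.read(io.StringIO(text))
    arr = pdb.get_structure(model=1)
    params = read_parameter_table(params_path)
    water_residues = set(water_residues)

    atoms: list[AtomRecord] = []
    mol_counter = 0
    water_mol_of_res: dict[tuple[str, int], int] = {}
    for i in range(arr.array_length()):
        res_name = str(arr.res_name[i])
        name = str(arr.atom_name[i])
        key = (res_name, name)
        try:
            row = params.loc[key]
        except KeyError:
            raise TopologyError(
                f"no parameters for atom {name} in residue {res_name}"
            ) from None
        if res_name in water_residues:
            rkey = (str(arr.chain_id[i]), int(arr.res_id[i]))
            if rkey not in water_mol_of_res:
                mol_counter += 1
                water_mol_of_res[rkey] = mol_counter
            mol_id = water_mol_of_res[rkey]
        else:
            mol_id = 0
        atoms.append(
            AtomRecord(
                index=i,
                name=name,
                residue_name=res_name,
                residue_id=int(arr.res_id[i]),
                element=str(arr.element[i]) or name[0],
                charge=float(row["charge"]),
                lj_sigma=float(row["sigma"]),
                lj_epsilon=float(row["epsilon"]),
                molecule_id=mol_id,
                role=str(row["role"]),
            )
        )
    return Topology(atoms)


def _to_atom_array(topology: Topology, coordinates: np.ndarray, box: np.ndarray) -> struc.AtomArray:
    n = topology.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coordinates, dtype=np.float32)
    arr.chain_id[:] = "A"
    arr.res_id = topology.residue_ids.astype(int)
    arr.res_name = topology.residue_names
    arr.atom_name = topology.names
    arr.element = topology.elements
    arr.hetero[:] = topology.solvent_mask
    arr.box = np.diag(np.asarray(box, dtype=np.float32))
    return arr


def write_topology(
    topology: Topology,
    frame: Frame,
    pdb_path: str | Path,
    params_path: str | Path,
) -> None:
    """Write a single-model PDB plus the matching parameter TSV."""
    pdb = pdbio.PDBFile()
    pdb.set_structure(_to_atom_array(topology, frame.coordinates, frame.box))
    pdb.write(str(pdb_path))
    rows = {}
    for a in topology.atoms:
        rows[(a.residue_name, a.name)] = (a.charge, a.lj_sigma, a.lj_epsilon, a.role)
    df = pd.DataFrame(
        [(rn, an, *vals) for (rn, an), vals in rows.items()],
        columns=PARAM_COLUMNS,
    )
    df.to_csv(params_path, sep="\t", index=False)


def write_frames_pdb(trajectory: Trajectory, pdb_path: str | Path) -> None:
    """Write trajectory frames as a multi-model PDB (CRYST1 from frame 0)."""
    stack = struc.stack(
        [_to_atom_array(trajectory.topology, f.coordinates, f.box) for f in trajectory.frames]
    )
    stack.box = np.array([np.diag(f.box) for f in trajectory.frames], dtype=np.float32)
    pdb = pdbio.PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(pdb_path))


def read_frames_pdb(pdb_path: str | Path, topology: Topology) -> Trajectory:
    """Read a multi-model PDB as trajectory frames for an existing topology."""
    pdb = pdbio.PDBFile.read(str(pdb_path))
    stack = pdb.get_structure()
    if stack.array_length() != topology.n_atoms:
        raise TopologyError(
            f"{pdb_path}: {stack.array_length()} atoms, topology has {topology.n_atoms}"
        )
    boxes = stack.box
    frames = []
    for m in range(stack.stack_depth()):
        box = np.diag(boxes[m] if boxes is not None else np.eye(3)).astype(float)
        frames.append(Frame(coordinates=stack.coord[m].astype(float), box=box, frame_index=m))
    return Trajectory(topology=topology, frames=frames)


def write_frames_xyz(trajectory: Trajectory, path: str | Path) -> None:
    """Write frames in the XYZ-with-box dialect (box on the comment line)."""
    top = trajectory.topology
    with open(path, "w") as fh:
        for f in trajectory.frames:
            fh.write(f"{top.n_atoms}\n")
            fh.write(
                f"box {f.box[0]:.10g} {f.box[1]:.10g} {f.box[2]:.10g} frame {f.frame_index}\n"
            )
            for name, xyz in zip(top.names, f.coordinates):
                fh.write(f"{name} {xyz[0]:.10f} {xyz[1]:.10f} {xyz[2]:.10f}\n")


def read_frames_xyz(path: str | Path, topology: Topology) -> Trajectory:
    """Read the XYZ-with-box dialect written by :func:`write_frames_xyz`."""
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i])
        parts = lines[i + 1].split()
        if parts[0] != "box":
            raise ValueError(f"{path}: expected 'box' comment line, got {lines[i + 1]!r}")
        box = np.array(parts[1:4], dtype=float)
        frame_index = int(parts[5]) if len(parts) >= 6 else len(frames)
        coords = np.array(
            [lines[i + 2 + j].split()[1:4] for j in range(n)], dtype=float
        )
        frames.append(Frame(coordinates=coords, box=box, frame_index=frame_index))
        i += 2 + n
    return Trajectory(topology=topology, frames=frames)


def read_reference_pdb(
    pdb_path: str | Path, heavy_only: bool = True
) -> ReferenceStructure:
    """Read a reference coordinate set (e.g. an aligned cocrystal ligand)."""
    pdb = pdbio.PDBFile.read(str(pdb_path))
    arr = pdb.get_structure(model=1)
    if heavy_only:
        arr = arr[arr.element != "H"]
    return ReferenceStructure(
        coordinates=arr.coord.astype(float), atom_names=[str(s) for s in arr.atom_name]
    )
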