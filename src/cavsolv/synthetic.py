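"""Synthetic topologies and trajectories with known statistical structure.

Three generators cover the analysis pipeline's needs:

* ``gen_ideal_gas`` — non-interacting uniform placements, the null model for
  density and energy checks (g -> 1, energies 0 with a zero-parameter model);
* ``gen_lattice`` — a deterministic static cubic lattice;
* ``gen_mc_water`` — rigid-water Metropolis Monte Carlo around a fixed toy
  solute, producing equilibrium configurations under exactly the truncated
  point-charge + LJ potential the analysis modules evaluate.

Two toy solutes are provided: a rigid cage of LJ spheres forming a binding
pocket that presents two acceptor oxygens at a configurable separation (a
carboxylate mimic), and a compact capsule with a cryptic polar site whose
acceptor pair is either buried (cognate) or surface-exposed (alternate).
The capsule's two-state "gate" yields matched rigid/flexible trajectory
pairs: the rigid run holds the buried ligand-bound arrangement, the
flexible run lets the pair hop between states under the same Metropolis
rule, emulating side-chain restructuring around an unligated binding site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from . import constants as C
from .core import (
    AtomRecord,
    Frame,
    ROLE_SOLUTE,
    ROLE_SOLVENT_HYDROGEN,
    ROLE_SOLVENT_OXYGEN,
    Topology,
    Trajectory,
    minimum_image_displacement,
)
from .energetics import EnergyEvaluator, InteractionModel

logger = logging.getLogger(__name__)


def default_model(**overrides) -> InteractionModel:
    """The synthetic water model's interaction constants."""
    kw = dict(
        cutoff=C.SYNTHETIC_CUTOFF,
        e_neat=C.SYNTHETIC_E_NEAT,
        rho0=C.SYNTHETIC_RHO0,
    )
    kw.update(overrides)
    return InteractionModel(**kw)


def water_template() -> np.ndarray:
    """Rigid 3-site water coordinates (O, H1, H2) with O at the origin."""
    ang = np.radians(C.WATER_HOH_DEG)
    return np.array(
        [
            [0.0, 0.0, 0.0],
            [C.WATER_OH, 0.0, 0.0],
            [C.WATER_OH * np.cos(ang), C.WATER_OH * np.sin(ang), 0.0],
        ]
    )


@dataclass
class ToySolute:
    """A rigid toy solute: names/elements/parameters plus fixed positions.

    ``groups`` maps functional-group labels to atom indices (within the
    solute); ``alternate_positions`` optionally stores a second position for
    a subset of atoms (the two-state gate)."""

    names: list[str]
    elements: list[str]
    charges: np.ndarray
    sigmas: np.ndarray
    epsilons: np.ndarray
    positions: np.ndarray
    groups: dict[str, list[int]] = field(default_factory=dict)
    enclosure: str = "open"
    acceptor_pair_separation: float = 0.0
    alternate_positions: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def n_atoms(self) -> int:
        return len(self.names)


@dataclass
class GeneratorConfig:
    """Shared generator settings; all randomness flows from ``seed``."""

    n_waters: int = 64
    box: tuple = (12.4, 12.4, 12.4)
    n_frames: int = 100
    temperature: float = C.SYNTHETIC_TEMPERATURE
    seed: int = 0
    mode: str = "ideal_gas"
    sweeps_per_frame: int = 5
    n_equil_sweeps: int = 200
    max_translation: float = 0.15
    max_rotation_deg: float = 20.0
    jump_probability: float = 0.1
    gate_flip_interval: int = 3

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        self.box = tuple(float(b) for b in self.box)


# ---------------------------------------------------------------------------
# Topology construction
# ---------------------------------------------------------------------------

def build_topology(
    n_waters: int, solute: ToySolute | None = None, zero_parameters: bool = False
) -> Topology:
    """Topology with the solute atoms first, then ``n_waters`` rigid waters.

    With ``zero_parameters`` all charges and LJ well depths are zero (an
    ideal-gas "water" that keeps the molecular geometry and roles).
    """
    atoms: list[AtomRecord] = []
    i = 0
    if solute is not None:
        for j in range(solute.n_atoms):
            atoms.append(
                AtomRecord(
                    index=i,
                    name=solute.names[j],
                    residue_name="POC",
                    residue_id=1,
                    element=solute.elements[j],
                    charge=float(solute.charges[j]),
                    lj_sigma=float(solute.sigmas[j]),
                    lj_epsilon=float(solute.epsilons[j]),
                    molecule_id=0,
                    role=ROLE_SOLUTE,
                )
            )
            i += 1
    if zero_parameters:
        spec = [
            ("O", "O", 0.0, 0.0, 0.0, ROLE_SOLVENT_OXYGEN),
            ("H1", "H", 0.0, 0.0, 0.0, ROLE_SOLVENT_HYDROGEN),
            ("H2", "H", 0.0, 0.0, 0.0, ROLE_SOLVENT_HYDROGEN),
        ]
    else:
        spec = [
            ("O", "O", C.WATER_Q_O, C.WATER_SIGMA_O, C.WATER_EPSILON_O, ROLE_SOLVENT_OXYGEN),
            ("H1", "H", C.WATER_Q_H, 0.0, 0.0, ROLE_SOLVENT_HYDROGEN),
            ("H2", "H", C.WATER_Q_H, 0.0, 0.0, ROLE_SOLVENT_HYDROGEN),
        ]
    for w in range(n_waters):
        for name, elem, q, sig, eps, role in spec:
            atoms.append(
                AtomRecord(
                    index=i,
                    name=name,
                    residue_name="WAT",
                    residue_id=2 + w,
                    element=elem,
                    charge=q,
                    lj_sigma=sig,
                    lj_epsilon=eps,
                    molecule_id=1 + w,
                    role=role,
                )
            )
            i += 1
    return Topology(atoms)


def _water_coords(o_positions: np.ndarray, rotations: Rotation) -> np.ndarray:
    """Assemble per-molecule atom coordinates from O positions and rotations."""
    tpl = water_template()
    # rotate the template per molecule, then translate to the O position
    out = np.empty((len(o_positions), 3, 3))
    mats = rotations.as_matrix()
    for k in range(len(o_positions)):
        out[k] = tpl @ mats[k].T + o_positions[k]
    return out.reshape(-1, 3)


def _assemble_frame(
    solute: ToySolute | None, water_xyz: np.ndarray, box, frame_index: int,
    solute_positions: np.ndarray | None = None,
) -> Frame:
    parts = []
    if solute is not None:
        parts.append(solute_positions if solute_positions is not None else solute.positions)
    parts.append(water_xyz)
    return Frame(coordinates=np.vstack(parts), box=np.asarray(box, float), frame_index=frame_index)


# ---------------------------------------------------------------------------
# Ideal gas and lattice
# ---------------------------------------------------------------------------

def gen_ideal_gas(
    config: GeneratorConfig,
    solute: ToySolute | None = None,
    zero_parameters: bool = False,
) -> Trajectory:
    """Uniform random placements with random orientations, no interactions
    implied (pair with ``zero_parameters`` for a true ideal gas)."""
    if config.mode != "ideal_gas":
        raise ValueError("config.mode must be 'ideal_gas'")
    rng = np.random.default_rng(config.seed)
    top = build_topology(config.n_waters, solute, zero_parameters=zero_parameters)
    box = np.array(config.box)
    frames = []
    for f in range(config.n_frames):
        o = rng.uniform(0.0, 1.0, size=(config.n_waters, 3)) * box
        rot = Rotation.random(config.n_waters, rng=rng)
        frames.append(_assemble_frame(solute, _water_coords(o, rot), box, f))
    return Trajectory(topology=top, frames=frames)


def gen_lattice(config: GeneratorConfig, spacing: float, jitter: float = 0.0) -> Trajectory:
    """Cubic lattice of waters.

    With the default ``jitter = 0`` every frame is identical and all waters
    share one fixed orientation (a fully deterministic fixture).  A positive
    ``jitter`` displaces each water uniformly within ``±jitter`` per axis and
    randomises orientations independently every frame: cheap overlap-free
    random configurations for conservation checks at scale.
    """
    if spacing < 2.4:
        raise ValueError("lattice spacing too small for a water molecule")
    box = np.array(config.box)
    per_axis = np.floor(box / spacing).astype(int)
    if np.prod(per_axis) < config.n_waters:
        raise ValueError(
            f"lattice fits {int(np.prod(per_axis))} waters, {config.n_waters} requested"
        )
    idx = np.stack(
        np.meshgrid(*[np.arange(n) for n in per_axis], indexing="ij"), axis=-1
    ).reshape(-1, 3)[: config.n_waters]
    o = (idx + 0.5) * spacing
    top = build_topology(config.n_waters)
    if jitter == 0.0:
        xyz = _water_coords(o, Rotation.identity(config.n_waters))
        frames = [
            Frame(coordinates=xyz.copy(), box=box.copy(), frame_index=f)
            for f in range(config.n_frames)
        ]
    else:
        rng = np.random.default_rng(config.seed)
        frames = []
        for f in range(config.n_frames):
            disp = rng.uniform(-jitter, jitter, size=o.shape)
            rot = Rotation.random(config.n_waters, rng=rng)
            frames.append(
                Frame(coordinates=_water_coords(o + disp, rot), box=box.copy(), frame_index=f)
            )
    return Trajectory(topology=top, frames=frames)


# ---------------------------------------------------------------------------
# Metropolis Monte Carlo
# ---------------------------------------------------------------------------

@dataclass
class MCResult:
    trajectory: Trajectory
    acceptance_rate: float
    state_trace: list[str] | None = None
    frame_energies: list[float] | None = None
    solute_offset: np.ndarray | None = None


def _initial_waters(rng, n, box, solute: ToySolute | None, seed_points=()):
    """Random insertion with overlap rejection; optional guaranteed seeds."""
    placed = [np.asarray(p, float) for p in seed_points]
    attempts = 0
    while len(placed) < n:
        p = rng.uniform(0.0, 1.0, 3) * box
        ok = all(
            np.linalg.norm(minimum_image_displacement(p - q, box)) > 2.5 for q in placed
        )
        if ok and solute is not None:
            d = np.linalg.norm(
                minimum_image_displacement(p - solute.positions, box), axis=1
            )
            ok = np.min(d) > 2.6
        if ok:
            placed.append(p)
        attempts += 1
        if attempts > 200000:
            raise RuntimeError("could not place waters without overlap; box too small")
    return np.array(placed[:n])


def gen_mc_water(
    config: GeneratorConfig,
    solute: ToySolute | None = None,
    model: InteractionModel | None = None,
    flexible_group: Sequence[int] | None = None,
    alternate_positions: dict[int, np.ndarray] | None = None,
    seed_points: Sequence = (),
    center_solute: bool = True,
    initial_state: str = "cognate",
    return_details: bool = False,
):
    """Rigid-water Metropolis Monte Carlo at ``config.temperature``.

    Each sweep proposes one translation+rotation per water; when a two-state
    ``flexible_group`` is given, one gate flip between the cognate and
    alternate positions is proposed per sweep as well.  Frames are saved
    every ``sweeps_per_frame`` sweeps after ``n_equil_sweeps`` of burn-in.
    The sampler evaluates moves with the same :class:`EnergyEvaluator` the
    analysis modules use, so saved-frame energies re-evaluate identically.

    The solute (built around the origin) is shifted to the box center and
    water molecules are wrapped into the primary box by their oxygen, so
    saved coordinates can be binned on a grid without periodic wrapping;
    ``seed_points`` are given in solute coordinates and shifted identically.

    ``initial_state`` selects the gate arrangement the chain starts from
    ("cognate" or "alternate"); the chain is free to leave it.  Starting a
    flexible run from the alternate state plays the role of beginning an
    unligated simulation from a relaxed, solvent-adapted structure: flips
    into a fully formed hydration shell carry a large steric penalty, so a
    cognate start can take many sweeps to find its first transition.
    """
    if config.mode != "metropolis":
        raise ValueError("config.mode must be 'metropolis'")
    model = model if model is not None else default_model()
    rng = np.random.default_rng(config.seed)
    top = build_topology(config.n_waters, solute)
    box = np.array(config.box)
    ev = EnergyEvaluator(top, model)
    kT = C.BOLTZMANN_KCAL * config.temperature

    offset = box / 2.0 if (center_solute and solute is not None) else np.zeros(3)
    solute_positions = solute.positions + offset if solute is not None else None
    shifted = (
        replace(solute, positions=solute_positions) if solute is not None else None
    )
    o_pos = _initial_waters(
        rng, config.n_waters, box, shifted, [np.asarray(p) + offset for p in seed_points]
    )
    rot = Rotation.random(config.n_waters, rng=rng)
    quats = rot.as_quat()
    n_solute = solute.n_atoms if solute is not None else 0
    coords = np.empty((top.n_atoms, 3))
    if solute is not None:
        coords[:n_solute] = solute_positions
    coords[n_solute:] = _water_coords(o_pos, Rotation.from_quat(quats))

    gate = list(flexible_group) if flexible_group else []
    alt = dict(alternate_positions or (solute.alternate_positions if solute else {}))
    alt = {g: np.asarray(p) + offset for g, p in alt.items()}
    if gate:
        for g in gate:
            if g not in alt:
                raise ValueError(f"no alternate position for gate atom {g}")
            d = np.linalg.norm(
                minimum_image_displacement(
                    np.asarray(alt[g]) - np.delete(solute_positions, gate, axis=0), box
                ),
                axis=1,
            )
            if np.min(d) < 0.5:
                raise ValueError("alternate gate position overlaps cage atoms")
    if initial_state not in ("cognate", "alternate"):
        raise ValueError("initial_state must be 'cognate' or 'alternate'")
    state = initial_state if gate else "cognate"
    if gate and state == "alternate":
        coords[np.asarray(gate, dtype=np.int64)] = np.array([alt[int(g)] for g in gate])

    def water_atoms_of(w):
        return slice(n_solute + 3 * w, n_solute + 3 * w + 3)

    n_acc = n_try = 0
    frames, state_trace, frame_e = [], [], []
    max_rot = np.radians(config.max_rotation_deg)
    total_sweeps = config.n_equil_sweeps + config.n_frames * config.sweeps_per_frame
    zero_acc_guard = 0
    for sweep in range(total_sweeps):
        for w in rng.permutation(config.n_waters):
            e_old = ev.single_water_energy(w, coords, box)
            old = coords[water_atoms_of(w)].copy()
            if rng.random() < config.jump_probability:
                # reinsertion move: uniform position, uniform orientation
                # (symmetric proposal, preserves detailed balance; lets
                # waters enter and leave enclosed regions)
                o_new = rng.uniform(0.0, 1.0, 3) * box
                new = Rotation.random(rng=rng).apply(water_template()) + o_new
            else:
                shift = rng.uniform(-config.max_translation, config.max_translation, 3)
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                ang = rng.uniform(-max_rot, max_rot)
                r = Rotation.from_rotvec(axis * ang)
                o = old[0]
                new = r.apply(old - o) + o + shift
                new -= np.floor(new[0] / box) * box  # wrap molecule by its oxygen
            coords[water_atoms_of(w)] = new
            try:
                e_new = ev.single_water_energy(w, coords, box)
            except Exception:
                e_new = np.inf
            n_try += 1
            if e_new <= e_old or rng.random() < np.exp(-(e_new - e_old) / kT):
                n_acc += 1
            else:
                coords[water_atoms_of(w)] = old
        if (
            gate
            and sweep >= config.n_equil_sweeps
            and sweep % config.gate_flip_interval == 0
        ):
            # the gate is held fixed during burn-in so the solvent first
            # adapts to the starting structure (staged equilibration)
            state = _try_gate_flip(
                rng, coords, box, ev, top, shifted, gate, alt, state, kT
            )
        if n_try >= config.n_waters * 50 and n_acc == 0:
            raise RuntimeError(
                "no accepted moves over the sweep budget; adjust step sizes"
            )
        if sweep >= config.n_equil_sweeps and (
            (sweep - config.n_equil_sweeps) % config.sweeps_per_frame == 0
        ):
            frames.append(
                Frame(coordinates=coords.copy(), box=box.copy(), frame_index=len(frames))
            )
            state_trace.append(state)
            if return_details:
                frame_e.append(ev.total_energy(frames[-1]))
        if len(frames) >= config.n_frames:
            break
    traj = Trajectory(topology=top, frames=frames)
    rate = n_acc / max(n_try, 1)
    logger.info("MC acceptance rate %.3f over %d trials", rate, n_try)
    if return_details:
        return MCResult(traj, rate, state_trace if gate else None, frame_e, offset)
    return traj


def _try_gate_flip(rng, coords, box, ev, top, solute, gate, alt, state, kT):
    """Metropolis flip of the gate group between cognate and alternate.

    The flip is scored on the gate's interaction with the solvent only: the
    rigid solute's internal energy is taken as equal in both states (a
    symmetric two-state rotamer), so with no waters nearby the states are
    isoenergetic and equally occupied.
    """
    gate_idx = np.asarray(gate, dtype=np.int64)
    e_old = ev.solute_subset_water_energy(gate_idx, coords[gate_idx], coords, box)
    new_pos = (
        np.array([alt[int(i)] for i in gate_idx])
        if state == "cognate"
        else solute.positions[gate_idx]
    )
    try:
        e_new = ev.solute_subset_water_energy(gate_idx, new_pos, coords, box)
    except Exception:
        return state
    if e_new <= e_old or rng.random() < np.exp(-(e_new - e_old) / kT):
        coords[gate_idx] = new_pos
        return "alternate" if state == "cognate" else "cognate"
    return state


# ---------------------------------------------------------------------------
# Toy pockets
# ---------------------------------------------------------------------------

def _fibonacci_shell(n: int) -> np.ndarray:
    """n roughly equidistant unit vectors (deterministic)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def build_bidentate_pocket(
    separation: float = 2.3,
    enclosure: str = "enclosed",
    radius: float = 3.6,
    shell_points: int = 80,
) -> ToySolute:
    """A rigid cage of LJ spheres with a mouth along +z, presenting two
    acceptor oxygens near the bottom at the given separation.

    The enclosed variant (mouth half-angle 45°) admits at most one water
    oxygen in the throat; the open variant (80°) is a shallow bowl.
    """
    if separation <= 0:
        raise ValueError("separation must be positive")
    if enclosure not in ("open", "enclosed"):
        raise ValueError("enclosure must be 'open' or 'enclosed'")
    mouth = np.radians(45.0 if enclosure == "enclosed" else 80.0)
    radius = max(radius, separation / 2 + 1.4)
    dirs = _fibonacci_shell(shell_points)
    keep = np.arccos(np.clip(dirs[:, 2], -1, 1)) > mouth  # exclude the mouth cap
    shell = dirs[keep] * radius
    z_a = -(radius - 1.8)
    acc = np.array([[-separation / 2, 0.0, z_a], [separation / 2, 0.0, z_a]])
    comp = acc + np.array([0.0, 0.0, -1.2])
    names, elements, q, sig, eps, pos = [], [], [], [], [], []
    for k, p in enumerate(shell):
        names.append(f"C{k+1}")
        elements.append("C")
        q.append(0.0)
        sig.append(3.4)
        eps.append(0.1)
        pos.append(p)
    for k, p in enumerate(acc):
        names.append(f"OA{k+1}")
        elements.append("O")
        q.append(-0.6)
        sig.append(3.0)
        eps.append(0.17)
        pos.append(p)
    for k, p in enumerate(comp):
        names.append(f"CP{k+1}")
        elements.append("C")
        q.append(0.6)
        sig.append(3.4)
        eps.append(0.1)
        pos.append(p)
    n_shell = len(shell)
    solute = ToySolute(
        names=names,
        elements=elements,
        charges=np.array(q),
        sigmas=np.array(sig),
        epsilons=np.array(eps),
        positions=np.array(pos),
        groups={"ACC1": [n_shell], "ACC2": [n_shell + 1]},
        enclosure=enclosure,
        acceptor_pair_separation=separation,
    )
    return solute


def pocket_throat_points(
    solute: ToySolute,
    clearance: float = 2.6,
    hbond_reach: float = 3.6,
    resolution: float = 0.25,
) -> np.ndarray:
    """Geometric scan: positions where a water oxygen fits (clearance to all
    solute atoms) while within hydrogen-bond reach of an acceptor oxygen."""
    acc_idx = [i for lbl, ids in solute.groups.items() if lbl.startswith("ACC") for i in ids]
    acc = solute.positions[acc_idx]
    lo = acc.min(axis=0) - hbond_reach
    hi = acc.max(axis=0) + hbond_reach
    ax = [np.arange(lo[d], hi[d] + resolution, resolution) for d in range(3)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    d_acc = np.min(
        np.linalg.norm(pts[:, None, :] - acc[None, :, :], axis=-1), axis=1
    )
    pts = pts[d_acc < hbond_reach]
    d_sol = np.min(
        np.linalg.norm(pts[:, None, :] - solute.positions[None, :, :], axis=-1), axis=1
    )
    return pts[d_sol >= clearance]


def pocket_admits_two_waters(solute: ToySolute, min_oo: float = 2.4, **scan_kw) -> bool:
    """Whether two water oxygens at least ``min_oo`` apart both fit in the
    pocket throat (both within hydrogen-bond reach of an acceptor)."""
    pts = pocket_throat_points(solute, **scan_kw)
    if len(pts) < 2:
        return False
    from scipy.spatial.distance import pdist

    return bool(np.max(pdist(pts)) >= min_oo)


def build_two_state_site(separation: float = 2.3, radius: float = 2.6,
                         shell_points: int = 42) -> ToySolute:
    """A compact solute with a cryptic polar site: a closed carbon capsule
    whose acceptor pair is either buried inside (cognate, the ligand-bound
    arrangement used by the rigid system) or exposed on the surface
    (alternate, water-accessible).

    The capsule shell is dense enough that no water fits inside or slips
    between shell atoms, so the buried pair is beyond hydrogen-bond reach;
    the exposed pair pokes slightly out of the surface and hydrogen-bonds
    freely with bulk water.  ``groups['GATE']`` lists the four gate atoms
    (acceptors plus compensating charges) and ``alternate_positions`` holds
    the exposed coordinates; the flexible Monte Carlo run hops between the
    two states, the rigid run holds the cognate state.
    """
    if separation <= 0:
        raise ValueError("separation must be positive")
    x = separation / 2.0
    shell = _fibonacci_shell(shell_points) * radius
    z_e = np.sqrt((radius + 0.45) ** 2 - x ** 2)
    names, elements, q, sig, eps, pos = [], [], [], [], [], []
    for k, p in enumerate(shell):
        names.append(f"C{k+1}")
        elements.append("C")
        q.append(0.0)
        sig.append(3.4)
        eps.append(0.1)
        pos.append(p)
    buried = {
        "OA1": np.array([-x, 0.0, 0.2]),
        "OA2": np.array([x, 0.0, 0.2]),
        "CP1": np.array([-x, 0.0, -1.0]),
        "CP2": np.array([x, 0.0, -1.0]),
    }
    exposed = {
        "OA1": np.array([-x, 0.0, z_e]),
        "OA2": np.array([x, 0.0, z_e]),
        "CP1": np.array([-x, 0.0, z_e - 1.2]),
        "CP2": np.array([x, 0.0, z_e - 1.2]),
    }
    gate_ids = []
    for name in ("OA1", "OA2", "CP1", "CP2"):
        gate_ids.append(len(names))
        names.append(name)
        elements.append("O" if name.startswith("OA") else "C")
        q.append(-0.6 if name.startswith("OA") else 0.6)
        sig.append(3.0 if name.startswith("OA") else 3.4)
        eps.append(0.17 if name.startswith("OA") else 0.1)
        pos.append(buried[name])
    return ToySolute(
        names=names,
        elements=elements,
        charges=np.array(q),
        sigmas=np.array(sig),
        epsilons=np.array(eps),
        positions=np.array(pos),
        groups={"ACC1": [gate_ids[0]], "ACC2": [gate_ids[1]], "GATE": gate_ids},
        enclosure="enclosed",
        acceptor_pair_separation=separation,
        alternate_positions={g: exposed[names[g]] for g in gate_ids},
    )


def make_rigid_flexible_pair(
    solute: ToySolute,
    config: GeneratorConfig,
    model: InteractionModel | None = None,
    flexible_group: Sequence[int] | None = None,
    alternate_positions: dict[int, np.ndarray] | None = None,
    return_details: bool = False,
):
    """Matched rigid and flexible MC trajectories of a gated pocket.

    The rigid trajectory holds the gate at its cognate (closed) position; the
    flexible trajectory lets it hop between cognate and alternate under the
    Metropolis rule, so state occupancies reflect the water-mediated energy
    difference.  Both runs use the same seed stream structure and model.
    """
    gate = list(flexible_group) if flexible_group is not None else solute.groups.get("GATE")
    if not gate:
        raise ValueError("solute has no gate group; use build_two_state_site() or pass flexible_group")
    model = model if model is not None else default_model()
    throat = pocket_throat_points(solute)
    seeds = [throat.mean(axis=0)] if len(throat) else []
    rigid = gen_mc_water(
        replace(config, mode="metropolis"),
        solute=solute,
        model=model,
        seed_points=seeds,
        return_details=return_details,
    )
    flexible = gen_mc_water(
        replace(config, mode="metropolis", seed=config.seed + 1),
        solute=solute,
        model=model,
        flexible_group=gate,
        alternate_positions=alternate_positions,
        seed_points=seeds,
        initial_state="alternate",
        return_details=return_details,
    )
    return rigid, flexible
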