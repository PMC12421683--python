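"""Geometric hydrogen bonds, neighbors, group statistics, conformers."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cavsolv.core import Frame, Trajectory
from cavsolv.hbonds import (
    FunctionalGroup,
    HBondCriteria,
    HBondEngine,
    conformer_occupancy,
    count_neighbors,
    detect_hbonds,
    group_stats,
)
from cavsolv.synthetic import (
    GeneratorConfig,
    build_bidentate_pocket,
    build_topology,
    gen_ideal_gas,
)

from helpers import oracle_hbonds, oracle_neighbors

BOX = np.array([50.0, 50.0, 50.0])


def _two_waters(acceptor_o):
    """Water at origin with H1 along +x; a second water O at the given point
    with hydrogens pointing away along +y/+z."""
    top = build_topology(2)
    coords = np.zeros((6, 3))
    coords[1] = [0.9572, 0, 0]
    coords[2] = [-0.24, 0.927, 0]
    coords[3] = acceptor_o
    coords[4] = np.asarray(acceptor_o) + [0, 0.9572, 0]
    coords[5] = np.asarray(acceptor_o) + [0, 0, 0.9572]
    return top, Frame(coordinates=coords, box=BOX)


class TestDetect:
    def test_collinear_donation_detected(self):
        top, frame = _two_waters([2.8, 0, 0])
        bonds = detect_hbonds(frame, top)
        donated = [b for b in bonds if b.donor_heavy == 0 and b.acceptor_heavy == 3]
        assert len(donated) == 1
        assert donated[0].hydrogen == 1
        assert donated[0].kind == "water-water"

    def test_right_angle_rejected(self):
        top, frame = _two_waters([0, 0, 2.8])  # 90 deg from the O-H1 direction
        bonds = detect_hbonds(frame, top)
        assert not any(b.donor_heavy == 0 and b.hydrogen == 1 and b.acceptor_heavy == 3 for b in bonds)

    def test_distance_boundary_strict(self):
        top, frame = _two_waters([3.6, 0, 0])
        bonds = detect_hbonds(frame, top)
        assert not any(b.donor_heavy == 0 and b.acceptor_heavy == 3 for b in bonds)

    @pytest.mark.parametrize("convention", ["acceptor_donor_hydrogen", "donor_hydrogen_acceptor"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_oracle(self, convention, seed):
        cfg = GeneratorConfig(n_waters=50, box=(12, 12, 12), n_frames=1, seed=seed)
        traj = gen_ideal_gas(cfg)
        crit = HBondCriteria(angle_convention=convention)
        got = {
            (b.donor_heavy, b.hydrogen, b.acceptor_heavy)
            for b in detect_hbonds(traj.frames[0], traj.topology, crit)
        }
        assert got == oracle_hbonds(traj.frames[0], traj.topology, crit)

    def test_solute_water_classes_with_pocket(self):
        solute = build_bidentate_pocket(2.3, "open")
        cfg = GeneratorConfig(n_waters=30, box=(14, 14, 14), n_frames=1, seed=5)
        traj = gen_ideal_gas(cfg, solute)
        crit = HBondCriteria()
        frame = traj.frames[0]
        got = {
            (b.donor_heavy, b.hydrogen, b.acceptor_heavy)
            for b in detect_hbonds(frame, traj.topology, crit)
        }
        assert got == oracle_hbonds(frame, traj.topology, crit)

    def test_invariant_under_rigid_rotation(self):
        cfg = GeneratorConfig(n_waters=25, box=(60, 60, 60), n_frames=1, seed=3)
        traj = gen_ideal_gas(cfg)
        # shrink into the box middle to avoid wrap effects, then rotate rigidly
        frame = traj.frames[0]
        coords = frame.coordinates * 0.25 + 15.0
        f0 = Frame(coordinates=coords, box=frame.box)
        rot = Rotation.from_euler("xyz", [20, -40, 75], degrees=True)
        center = np.array([30.0, 30.0, 30.0])
        f1 = Frame(coordinates=rot.apply(coords - center) + center, box=frame.box)
        n0 = len(detect_hbonds(f0, traj.topology))
        n1 = len(detect_hbonds(f1, traj.topology))
        assert n0 == n1


class TestNeighbors:
    def test_single_atom_group(self):
        top = build_topology(2)
        coords = np.zeros((6, 3))
        coords[0] = [2.0, 0, 0]
        coords[1] = [2.96, 0, 0]
        coords[2] = [1.76, 0.93, 0]
        coords[3] = [4.0, 0, 0]
        coords[4] = [4.96, 0, 0]
        coords[5] = [3.76, 0.93, 0]
        frame = Frame(coordinates=coords, box=BOX)
        solute = build_bidentate_pocket(2.3, "open")
        top_s = build_topology(2, solute)
        coords_s = np.vstack([solute.positions + 25.0, coords + [[0, 10, 0]] * 6])
        frame_s = Frame(coordinates=coords_s, box=BOX)
        group = FunctionalGroup("probe", [solute.n_atoms], capability="acceptor")
        # place one water at 2 and one at 4 Angstroms from solute atom 0
        coords_s[solute.n_atoms + 0] = solute.positions[0] + 25.0 + [2.0, 0, 0]
        coords_s[solute.n_atoms + 1] = coords_s[solute.n_atoms + 0] + [0.96, 0, 0]
        coords_s[solute.n_atoms + 2] = coords_s[solute.n_atoms + 0] + [0, 0.96, 0]
        coords_s[solute.n_atoms + 3] = solute.positions[0] + 25.0 + [0, 4.0, 0]
        coords_s[solute.n_atoms + 4] = coords_s[solute.n_atoms + 3] + [0.96, 0, 0]
        coords_s[solute.n_atoms + 5] = coords_s[solute.n_atoms + 3] + [0, 0.96, 0]
        group0 = FunctionalGroup("g0", [0], capability="acceptor")
        assert count_neighbors(Frame(coordinates=coords_s, box=BOX), top_s, group0, 3.6) == 1

    def test_no_waters(self):
        solute = build_bidentate_pocket(2.3, "open")
        top = build_topology(0, solute)
        frame = Frame(coordinates=solute.positions + 25.0, box=BOX)
        g = FunctionalGroup("g", [0], capability="acceptor")
        assert count_neighbors(frame, top, g, 3.6) == 0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            FunctionalGroup("bad", [], capability="acceptor")

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_double_loop_oracle(self, seed):
        solute = build_bidentate_pocket(2.3, "open")
        cfg = GeneratorConfig(n_waters=100, box=(16, 16, 16), n_frames=1, seed=seed)
        traj = gen_ideal_gas(cfg, solute)
        group_atoms = [0, 5, 11]
        g = FunctionalGroup("g", group_atoms, capability="acceptor")
        for cutoff in (3.5, 3.6):
            got = count_neighbors(traj.frames[0], traj.topology, g, cutoff)
            assert got == oracle_neighbors(traj.frames[0], traj.topology, group_atoms, cutoff)


class TestGroupStats:
    def _pinned_traj(self):
        """One water permanently donating to acceptor OA1 of the pocket."""
        solute = build_bidentate_pocket(6.0, "open")
        top = build_topology(1, solute)
        acc = solute.positions[solute.groups["ACC1"][0]]
        o = acc + np.array([0.0, 0.0, 2.8])
        coords = np.vstack(
            [solute.positions, [o, o + [0.23, 0, -0.93], o + [0.0, 0.93, 0.23]]]
        ) + 25.0
        frames = [
            Frame(coordinates=coords.copy(), box=BOX, frame_index=i) for i in range(10)
        ]
        return solute, Trajectory(topology=top, frames=frames)

    def test_permanent_bond_gives_mean_one(self):
        solute, traj = self._pinned_traj()
        n = solute.n_atoms
        g1 = FunctionalGroup("ACC1", [solute.groups["ACC1"][0]], capability="acceptor")
        g2 = FunctionalGroup("ACC2", [solute.groups["ACC2"][0]], capability="acceptor")
        stats = group_stats(traj, [g1, g2], HBondCriteria(), neighbor_cutoff=3.6)
        assert stats.mean_water_hbonds[0] == pytest.approx(1.0)
        assert stats.mean_water_hbonds[1] == pytest.approx(0.0)
        assert stats.total_hbonds == pytest.approx(np.sum(stats.mean_water_hbonds))

    def test_means_equal_per_frame_oracle(self):
        solute = build_bidentate_pocket(2.3, "open")
        cfg = GeneratorConfig(n_waters=40, box=(15, 15, 15), n_frames=20, seed=17)
        traj = gen_ideal_gas(cfg, solute)
        acc1, acc2 = solute.groups["ACC1"][0], solute.groups["ACC2"][0]
        groups = [
            FunctionalGroup("a1", [acc1], capability="acceptor"),
            FunctionalGroup("a2", [acc2], capability="acceptor"),
        ]
        stats = group_stats(traj, groups, HBondCriteria(), neighbor_cutoff=3.6)
        water_o = set(int(i) for i in traj.topology.solvent_oxygen_indices)
        for gi, atom in enumerate([acc1, acc2]):
            nb = hb = 0
            for f in traj.frames:
                nb += oracle_neighbors(f, traj.topology, [atom], 3.6)
                for d, h, a in oracle_hbonds(f, traj.topology, HBondCriteria()):
                    solute_end = d if a in water_o else (a if d in water_o else None)
                    if solute_end == atom and (d in water_o or a in water_o):
                        hb += 1
            assert stats.mean_water_neighbors[gi] == pytest.approx(nb / 20)
            assert stats.mean_water_hbonds[gi] == pytest.approx(hb / 20)

    def test_hbonds_bounded_by_neighbors(self):
        solute = build_bidentate_pocket(2.3, "open")
        cfg = GeneratorConfig(n_waters=60, box=(14, 14, 14), n_frames=10, seed=23)
        traj = gen_ideal_gas(cfg, solute)
        groups = [
            FunctionalGroup("a1", solute.groups["ACC1"], capability="acceptor"),
        ]
        stats = group_stats(traj, groups, HBondCriteria(), neighbor_cutoff=3.6)
        assert stats.mean_water_hbonds[0] <= stats.mean_water_neighbors[0] + 1e-12


class TestConformers:
    def _traj_with_probe(self, positions):
        top = build_topology(1)
        frames = []
        for i, p in enumerate(positions):
            coords = np.array([p, np.add(p, [0.96, 0, 0]), np.add(p, [0, 0.96, 0])])
            frames.append(Frame(coordinates=coords, box=BOX, frame_index=i))
        return Trajectory(topology=top, frames=frames)

    def test_fixed_probe(self):
        traj = self._traj_with_probe([[1.0, 1.0, 1.0]] * 5)
        occ = conformer_occupancy(traj, 0, {"A": np.array([1.0, 1, 1]), "B": np.array([9.0, 9, 9])})
        assert occ == {"A": 1.0, "B": 0.0}

    def test_three_of_four_frames(self):
        traj = self._traj_with_probe([[1, 1, 1], [1, 1, 1], [1, 1, 1], [9, 9, 9]])
        occ = conformer_occupancy(traj, 0, {"A": np.array([1.0, 1, 1]), "B": np.array([9.0, 9, 9])})
        assert occ["A"] == pytest.approx(0.75)
        assert occ["B"] == pytest.approx(0.25)
        assert sum(occ.values()) == pytest.approx(1.0, abs=1e-12)

    def test_translation_invariance(self):
        pos = [[1, 1, 1], [8, 2, 3], [1, 1, 2], [7.5, 2, 3]]
        refs = {"A": np.array([1.0, 1, 1]), "B": np.array([8.0, 2, 3])}
        traj = self._traj_with_probe(pos)
        occ0 = conformer_occupancy(traj, 0, refs)
        shift = np.array([3.3, -2.2, 7.7])
        traj2 = self._traj_with_probe([np.add(p, shift) for p in pos])
        occ1 = conformer_occupancy(traj2, 0, {k: v + shift for k, v in refs.items()})
        assert occ0 == occ1

    def test_requires_two_references(self):
        traj = self._traj_with_probe([[1, 1, 1]])
        with pytest.raises(ValueError):
            conformer_occupancy(traj, 0, {"A": np.array([1.0, 1, 1])})


class TestPerWaterCounts:
    def test_ww_bond_credited_to_both_partners(self):
        top, frame = _two_waters([2.8, 0, 0])
        engine = HBondEngine(top, HBondCriteria(), frame)
        hb_sw, hb_ww, donates, accepts = engine.per_water_counts(frame)
        assert hb_ww[0] == hb_ww[1] == 1.0
        assert np.all(hb_sw == 0)
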