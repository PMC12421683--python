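"""Generators: determinism, statistical structure, Monte Carlo sanity, toy
pocket geometry and the two-state fixture."""

import numpy as np
import pytest
from scipy import stats

from cavsolv.energetics import EnergyEvaluator, InteractionModel
from cavsolv.synthetic import (
    GeneratorConfig,
    build_bidentate_pocket,
    build_two_state_site,
    default_model,
    gen_ideal_gas,
    gen_lattice,
    gen_mc_water,
    make_rigid_flexible_pair,
    pocket_admits_two_waters,
    pocket_throat_points,
)


def _coords_equal(t1, t2):
    return all(
        np.array_equal(f1.coordinates, f2.coordinates) for f1, f2 in zip(t1.frames, t2.frames)
    )


class TestDeterminism:
    def test_ideal_gas_seeded(self):
        cfg = GeneratorConfig(n_waters=10, box=(10, 10, 10), n_frames=4, seed=77)
        assert _coords_equal(gen_ideal_gas(cfg), gen_ideal_gas(cfg))

    def test_lattice_seeded(self):
        cfg = GeneratorConfig(n_waters=8, box=(10, 10, 10), n_frames=3, seed=1)
        assert _coords_equal(gen_lattice(cfg, 3.1), gen_lattice(cfg, 3.1))

    def test_mc_seeded(self):
        cfg = GeneratorConfig(
            n_waters=10, box=(9, 9, 9), n_frames=5, seed=5, mode="metropolis",
            sweeps_per_frame=2, n_equil_sweeps=10,
        )
        t1 = gen_mc_water(cfg, model=default_model())
        t2 = gen_mc_water(cfg, model=default_model())
        assert _coords_equal(t1, t2)


class TestIdealGas:
    def test_sphere_occupancy_binomial(self):
        cfg = GeneratorConfig(n_waters=40, box=(12, 12, 12), n_frames=500, seed=19)
        traj = gen_ideal_gas(cfg, zero_parameters=True)
        oxy = traj.topology.solvent_oxygen_indices
        center = np.array([6.0, 6.0, 6.0])
        hits = sum(
            int(np.sum(np.linalg.norm(f.coordinates[oxy] - center, axis=1) <= 1.0))
            for f in traj.frames
        )
        p = (4 / 3 * np.pi) / 12.0 ** 3
        expect = 40 * 500 * p
        se = np.sqrt(40 * 500 * p * (1 - p))
        assert abs(hits - expect) < 3 * se

    def test_density_uniform_chi_square(self):
        cfg = GeneratorConfig(n_waters=50, box=(12, 12, 12), n_frames=200, seed=29)
        traj = gen_ideal_gas(cfg, zero_parameters=True)
        oxy = traj.topology.solvent_oxygen_indices
        counts = np.zeros(27)
        for f in traj.frames:
            cells = np.floor(f.coordinates[oxy] / 4.0).astype(int)
            cells = np.clip(cells, 0, 2)
            idx = cells[:, 0] * 9 + cells[:, 1] * 3 + cells[:, 2]
            np.add.at(counts, idx, 1)
        chi2 = float(np.sum((counts - counts.mean()) ** 2 / counts.mean()))
        assert chi2 < stats.chi2.ppf(0.999, df=26)


class TestLattice:
    def test_voxels_only_at_lattice_points(self):
        from cavsolv.grid import GridSpec, accumulate, finalize

        cfg = GeneratorConfig(n_waters=27, box=(9.3, 9.3, 9.3), n_frames=5, seed=0)
        traj = gen_lattice(cfg, 3.1)
        model = InteractionModel(cutoff=6.0, e_neat=0.0, rho0=27 / 9.3 ** 3)
        spec = GridSpec(origin=(0, 0, 0), spacing=0.31, shape=(30, 30, 30))
        grid = finalize(accumulate(traj, model, spec), model)
        assert int(np.sum(grid.g > 0)) == 27
        assert grid.n_wat.sum() == 27 * 5

    def test_interior_sites_symmetric_eww(self):
        """A fully periodic lattice makes every site equivalent: identical
        per-water water-water energies."""
        cfg = GeneratorConfig(n_waters=27, box=(9.3, 9.3, 9.3), n_frames=1, seed=0)
        traj = gen_lattice(cfg, 3.1)
        model = InteractionModel(cutoff=4.0, e_neat=0.0)
        ev = EnergyEvaluator(traj.topology, model)
        we = ev.frame_energies(traj.frames[0])
        assert np.allclose(we.e_ww, we.e_ww[0], atol=1e-9)

    def test_zero_frame_to_frame_variance(self):
        cfg = GeneratorConfig(n_waters=8, box=(10, 10, 10), n_frames=6, seed=0)
        traj = gen_lattice(cfg, 3.2)
        ref = traj.frames[0].coordinates
        assert all(np.array_equal(f.coordinates, ref) for f in traj.frames)

    def test_too_small_spacing_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            gen_lattice(GeneratorConfig(n_waters=8, box=(10, 10, 10), n_frames=1), 2.0)


class TestMonteCarlo:
    def test_saved_energies_match_reevaluation(self):
        cfg = GeneratorConfig(
            n_waters=16, box=(10, 10, 10), n_frames=10, seed=13, mode="metropolis",
            sweeps_per_frame=2, n_equil_sweeps=40,
        )
        res = gen_mc_water(cfg, model=default_model(), return_details=True)
        ev = EnergyEvaluator(res.trajectory.topology, default_model())
        for frame, e in zip(res.trajectory.frames, res.frame_energies):
            assert ev.total_energy(frame) == pytest.approx(e, abs=1e-9)

    def test_energy_stable_after_burn_in(self):
        """After discarding the burn-in, the sampled energy shows no drift
        between halves beyond what block-resolved noise allows."""
        from cavsolv.subvolume import block_average

        cfg = GeneratorConfig(
            n_waters=32, box=(9.9, 9.9, 9.9), n_frames=120, seed=101, mode="metropolis",
            sweeps_per_frame=10, n_equil_sweeps=2500,
        )
        res = gen_mc_water(cfg, model=default_model(), return_details=True)
        e = np.array(res.frame_energies)
        half = len(e) // 2
        a, b = block_average(e[:half], 4), block_average(e[half:], 4)
        se = np.sqrt(a.sem ** 2 + b.sem ** 2)
        assert abs(a.mean - b.mean) < 3 * se

    def test_infinite_temperature_flattens_structure(self):
        """At very high temperature the oxygen-oxygen radial histogram
        approaches the ideal-gas (uniform) profile."""
        def oo_histogram(traj):
            oxy = traj.topology.solvent_oxygen_indices
            from cavsolv.core import distance_matrix

            counts = np.zeros(8)
            for f in traj.frames:
                d = distance_matrix(f.coordinates[oxy], f.coordinates[oxy], f.box)
                iu = np.triu_indices(len(oxy), k=1)
                h, _ = np.histogram(d[iu], bins=np.arange(1.0, 5.5, 0.5))
                counts += h
            return counts / counts.sum()

        cfg = dict(n_waters=24, box=(10, 10, 10), n_frames=40, mode="metropolis",
                   sweeps_per_frame=3, n_equil_sweeps=200)
        cold = gen_mc_water(GeneratorConfig(seed=7, temperature=300.0, **cfg), model=default_model())
        hot = gen_mc_water(
            GeneratorConfig(seed=7, temperature=1e7, **cfg),
            model=default_model(),
        )
        ideal = gen_ideal_gas(GeneratorConfig(seed=7, **{**cfg, "mode": "ideal_gas"}), zero_parameters=True)
        h_cold, h_hot, h_ideal = oo_histogram(cold), oo_histogram(hot), oo_histogram(ideal)
        assert np.abs(h_hot - h_ideal).sum() < np.abs(h_cold - h_ideal).sum()

    def test_wrong_mode_rejected(self):
        with pytest.raises(ValueError, match="metropolis"):
            gen_mc_water(GeneratorConfig(mode="ideal_gas"))


class TestBidentatePocket:
    def test_enclosed_throat_admits_one_water(self):
        pocket = build_bidentate_pocket(2.3, "enclosed")
        pts = pocket_throat_points(pocket)
        assert len(pts) > 0  # one water fits
        assert not pocket_admits_two_waters(pocket)

    def test_open_wide_pocket_admits_two(self):
        pocket = build_bidentate_pocket(6.0, "open")
        assert pocket_admits_two_waters(pocket)

    def test_rigid_solute_fixed_in_every_frame(self):
        pocket = build_bidentate_pocket(2.3, "enclosed")
        cfg = GeneratorConfig(
            n_waters=12, box=(14, 14, 14), n_frames=6, seed=3, mode="metropolis",
            sweeps_per_frame=1, n_equil_sweeps=10,
        )
        traj = gen_mc_water(cfg, solute=pocket, model=default_model())
        n_s = pocket.n_atoms
        ref = traj.frames[0].coordinates[:n_s]
        assert all(np.array_equal(f.coordinates[:n_s], ref) for f in traj.frames)

    def test_separated_acceptors_host_two_sites(self):
        """With the acceptors 6 Å apart in an open bowl, hydration-site
        analysis resolves one site per acceptor."""
        from cavsolv.sites import find_sites
        from cavsolv.subvolume import SubvolumeSpec
        from cavsolv.core import ReferenceStructure

        pocket = build_bidentate_pocket(6.0, "open")
        cfg = GeneratorConfig(
            n_waters=60, box=(14.0, 14.0, 14.0), n_frames=150, seed=23,
            mode="metropolis", sweeps_per_frame=3, n_equil_sweeps=500,
        )
        # start one water in each acceptor niche; the chain keeps it there
        # only if the site is genuinely favorable
        throat = pocket_throat_points(pocket)
        seeds = []
        for aid in (pocket.groups["ACC1"][0], pocket.groups["ACC2"][0]):
            d = np.linalg.norm(throat - pocket.positions[aid], axis=1)
            cand = throat[d < 3.3]
            seeds.append(cand[np.argmin(np.abs(np.linalg.norm(cand - pocket.positions[aid], axis=1) - 2.9))])
        res = gen_mc_water(
            cfg, solute=pocket, model=default_model(), seed_points=seeds, return_details=True
        )
        acc_ids = [pocket.groups["ACC1"][0], pocket.groups["ACC2"][0]]
        acc = pocket.positions[acc_ids] + res.solute_offset
        region = SubvolumeSpec(
            ReferenceStructure(acc, ["O1", "O2"]), distance=3.5
        )
        sites = find_sites(
            res.trajectory, region, min_occupancy_ratio=2.0, rho0=default_model().rho0
        )
        near = [
            s for s in sites
            if min(np.linalg.norm(s.center - a) for a in acc) < 3.5
        ]
        assert len(near) >= 2

    def test_zero_separation_rejected(self):
        with pytest.raises(ValueError):
            build_bidentate_pocket(0.0)


class TestTwoState:
    def test_rigid_run_stays_cognate(self):
        solute = build_two_state_site()
        cfg = GeneratorConfig(
            n_waters=12, box=(12, 12, 12), n_frames=5, seed=3, mode="metropolis",
            sweeps_per_frame=1, n_equil_sweeps=20,
        )
        rigid, flexible = make_rigid_flexible_pair(solute, cfg, return_details=True)
        gate = solute.groups["GATE"]
        n_off = rigid.solute_offset
        for f in rigid.trajectory.frames:
            assert np.allclose(
                f.coordinates[gate], solute.positions[gate] + n_off, atol=1e-12
            )

    def test_isoenergetic_states_equally_occupied(self):
        """When the alternate position coincides with the cognate one the
        flip is always energy-neutral, so the chain spends about half its
        time in each labelled state."""
        solute = build_two_state_site()
        alt = {g: solute.positions[g].copy() for g in solute.groups["GATE"]}
        cfg = GeneratorConfig(
            n_waters=6, box=(12, 12, 12), n_frames=300, seed=31, mode="metropolis",
            sweeps_per_frame=1, n_equil_sweeps=20, gate_flip_interval=1,
        )
        res = gen_mc_water(
            cfg, solute=solute, model=default_model(),
            flexible_group=solute.groups["GATE"], alternate_positions=alt,
            return_details=True,
        )
        frac = np.mean([s == "alternate" for s in res.state_trace])
        # flips accepted every attempt: state alternates, fraction ~ 0.5
        assert abs(frac - 0.5) < 3 * 0.5 / np.sqrt(len(res.state_trace) / 2)

    def test_overlapping_alternate_rejected(self):
        solute = build_two_state_site()
        gate = solute.groups["GATE"]
        bad = {g: solute.positions[0].copy() for g in gate}  # on top of a cage atom
        cfg = GeneratorConfig(
            n_waters=4, box=(12, 12, 12), n_frames=2, seed=1, mode="metropolis",
            sweeps_per_frame=1, n_equil_sweeps=2,
        )
        with pytest.raises(ValueError, match="overlap"):
            gen_mc_water(
                cfg, solute=solute, model=default_model(),
                flexible_group=gate, alternate_positions=bad,
            )

    def test_buried_pair_beyond_hbond_reach(self):
        """Geometric scan: no water-oxygen position with normal clearance
        comes within hydrogen-bond distance of the buried acceptors."""
        from scipy.spatial import cKDTree

        s = build_two_state_site()
        gate = s.groups["GATE"]
        static_idx = [i for i in range(s.n_atoms) if i not in gate]
        pts = np.mgrid[-7.01:7:0.2, -7.01:7:0.2, -7.01:7:0.2].reshape(3, -1).T
        ts = cKDTree(s.positions[static_idx])
        ok = (ts.query(pts)[0] >= 2.5) & (cKDTree(s.positions[gate]).query(pts)[0] >= 2.5)
        d = cKDTree(s.positions[gate[:2]]).query(pts[ok])[0]
        assert d.min() > 3.6
        # while the exposed acceptors are reachable
        alt = np.array([s.alternate_positions[g] for g in gate])
        ok2 = (ts.query(pts)[0] >= 2.5) & (cKDTree(alt).query(pts)[0] >= 2.5)
        d2 = cKDTree(alt[:2]).query(pts[ok2])[0]
        assert d2.min() < 3.0
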