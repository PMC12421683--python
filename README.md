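# cavsolv

Grid-based solvation mapping of protein binding cavities, for researchers
who study how water structures itself in and around binding sites — and how
much solvation energy a protein forfeits by holding its ligand-bound
("rigid") conformation instead of relaxing ("flexible") side chains around
the water.

`cavsolv` post-processes trajectory frames of a solute in explicit rigid
water and computes:

- **voxel solvation maps** — per-voxel water density g = ρ_vox/ρ°, energy
  density g·⟨E_sw + E_ww − E_neat⟩, additive per-frame energies and
  hydrogen-bond densities, exported as OpenDX grids;
- **ligand-proximity subvolumes** — integrated totals and per-water values
  over the voxels whose centers lie within a chosen distance of any heavy
  atom of an aligned reference ligand, with four-block standard errors;
- **geometric hydrogen bonds and neighbors** — heavy-atom distance < 3.6 Å
  and acceptor–donor–hydrogen angle < 30°; water-oxygen neighbors within an
  inclusive cutoff; per-functional-group solvation tables and side-chain
  conformer occupancies;
- **hydration sites** — greedy 1 Å-radius high-density spheres with
  per-site E_sw, E_ww, E_tot and a 60 %-of-occupants donor/acceptor
  classification;
- **rigid-vs-flexible comparison reports** — rigid − flexible deltas of all
  totals and per-water quantities.

Here E_sw is a water's interaction energy with the solute, E_ww its share
of water–water pair energies (split evenly between partners so regional
sums are additive), and E_tot = E_sw + E_ww − E_neat references everything
to the mean energy of a neat-water molecule, so positive totals flag water
that is worse off than bulk.

Because trajectories of real proteins are large, the package ships a
first-class synthetic-data module: seeded ideal-gas and lattice ensembles
with known statistics, and a rigid-water Metropolis Monte Carlo sampler
with toy solutes — a bidentate binding pocket whose enclosed throat admits
exactly one water, and a "cryptic polar site" capsule whose acceptor pair
is buried (cognate) or surface-exposed (alternate), giving matched
rigid/flexible trajectory pairs under an exactly known potential.

## Worked example

Generate a matched rigid/flexible pair of the cryptic-site capsule, map
both on a 0.5 Å grid and integrate the subvolume within 4.5 Å of the
exposed acceptor positions:

```python
import numpy as np
from cavsolv import (
    GeneratorConfig, HBondCriteria, GridSpec, ReferenceStructure,
    SubvolumeSpec, accumulate, build_two_state_site, compare, default_model,
    finalize, integrate, make_rigid_flexible_pair, select_voxels,
)

solute = build_two_state_site()
cfg = GeneratorConfig(n_waters=55, box=(12.8,) * 3, n_frames=150, seed=7,
                      mode="metropolis", sweeps_per_frame=4, n_equil_sweeps=600)
model = default_model()          # E_neat = -10.97, rho0 = 0.0334, cutoff 6 A
rigid, flex = make_rigid_flexible_pair(solute, cfg, model=model, return_details=True)

spec = GridSpec(origin=(0, 0, 0), spacing=0.5, shape=(26, 26, 26))
gate = solute.groups["GATE"]
exposed = np.array([solute.alternate_positions[g] for g in gate[:2]]) + rigid.solute_offset
ligand = ReferenceStructure(exposed, ["OA1", "OA2"])
vox = select_voxels(spec, SubvolumeSpec(ligand, 4.5))

iqs = {}
for label, res in (("rigid", rigid), ("flexible", flex)):
    grid = finalize(accumulate(res.trajectory, model, spec, HBondCriteria()), model)
    iqs[label] = integrate(grid, vox, 4.5)
    print(f"{label:9s} E_tot {iqs[label].e_tot:7.2f}  E_sw {iqs[label].e_sw:7.2f}  "
          f"hb_sw {iqs[label].hb_sw:5.2f}  n_water {iqs[label].n_water:5.2f}")
row = compare(iqs["rigid"], iqs["flexible"])
print(f"delta E_tot (rigid - flexible): {row.delta['e_tot']:.2f} kcal/mol")
```

prints

```
rigid     E_tot    5.02  E_sw  -13.28  hb_sw  0.00  n_water  9.07
flexible  E_tot   -4.83  E_sw  -21.91  hb_sw  2.99  n_water  8.78
delta E_tot (rigid - flexible): 9.84 kcal/mol
```

Read: with the polar pair buried (rigid), the subvolume's water is worse
off than bulk (+5.02 kcal/mol total, no solute–water hydrogen bonds); with
the pair exposed (flexible), waters hydrogen-bond it (~3 bonds/frame), the
solute–water term improves by 8.6 kcal/mol and the region's total solvation
energy turns favorable — the rigid conformation pays a ~10 kcal/mol
solvation penalty for staying ligand-ready.

A thin CLI exposes the stages (`cavsolv simulate`, `cavsolv gist`,
`cavsolv hsa`, `cavsolv groups`, `cavsolv conformers`, `cavsolv run
config.toml`); `cavsolv run` drives the whole pipeline from a TOML file and
writes DX grids, TSV tables, site PDBs and a JSON run log.

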