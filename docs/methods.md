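# Methods

`cavsolv` maps the structure and energetics of water in and around binding
cavities from simulation frames, and compares matched *rigid* (all heavy
atoms held in the ligand-bound arrangement) and *flexible* (side-chain-like
groups free to restructure) systems. This note records the models, the
conventions, the synthetic study conditions and the known limitations.

## Voxel solvation mapping

Frames are discretised on a regular cubic grid (default spacing 0.5 Å,
voxel volume 0.125 Å³). Each frame, every water **oxygen** inside the grid
deposits that water's per-molecule quantities into the voxel containing it;
hydrogens and massless virtual sites never enter voxel assignment or
neighbor counting. Voxel intervals are half-open with boundary points
assigned upward, so assignment is deterministic. Waters outside the grid are
counted and ignored; the grid is not wrapped periodically.

Per-voxel finalisation produces:

- `rho_vox = n_wat / (n_frames · V_vox)` and `g = rho_vox / ρ°`,
- `e_dens = g · ⟨E_sw + E_ww − E_neat⟩_occ` — the conventional voxel
  energy-density estimate (normalised density times the per-water mean
  referenced energy),
- `e_per_frame = Σ_occ (E_sw + E_ww − E_neat) / n_frames` — the additive
  quantity whose sum over any voxel set equals the region's per-frame total.

Both forms are stored and exported; **subvolume integration uses the
additive form**, because only it sums to the trajectory-direct region total
(verified to 1e-9 kcal/mol in the test suite). Empty voxels report zero for
every derived field.

## Interaction model

Water energies use a rigid point-charge plus Lennard-Jones model with plain
truncation (no Ewald, switching or long-range corrections): Coulomb constant
332.0636 kcal·Å/(mol·e²), Lorentz–Berthelot combination. Truncation
conventions, chosen so that no neutral molecule is ever split across the
cutoff sphere:

- water–water: a molecule pair is included whole iff the oxygen–oxygen
  minimum-image distance is within the cutoff;
- solute–water: each (water molecule, solute atom) pair is gated by the
  oxygen–atom distance. Splitting the water instead (a bare per-atom-pair
  cutoff) leaves unbalanced ±0.4 e charges at the cutoff boundary and
  produces multi-kcal/mol discontinuities near charged solute sites, which
  corrupts Monte Carlo sampling; the generic `pair_energy` helper retains
  the per-atom-pair rule for arbitrary atom groups.

Each water's total `E_tot = E_sw + E_ww − E_neat` is referenced to the mean
potential energy of one molecule in the neat liquid. Water–water pair
energies are split evenly between the two partners (`ww_split = 0.5`), so
per-water energies add up to the configuration total without double
counting and region totals satisfy `E_tot = E_sw + E_ww − N·E_neat`
identically. A `ww_split = 1.0` convention ("full pair energy to each
water") is available where the per-water, rather than additive, reading is
wanted.

Boxes are orthorhombic; the minimum-image convention requires the cutoff
not to exceed half the shortest box length.

## Hydrogen bonds and neighbors

A hydrogen bond is declared when the donor–acceptor heavy-atom
minimum-image distance is **strictly less than** 3.6 Å and the angle at the
donor heavy atom between the donor→acceptor and donor→hydrogen directions
is **strictly less than** 30°. This acceptor–donor–hydrogen convention is
the default; the common donor–hydrogen–acceptor convention (deviation from
linearity below the same bound) is available and the two never mix within
one criteria object. Polar N/O/S atoms accept; donors are polar heavy atoms
with a covalently attached hydrogen (attachment by <1.25 Å in the
attachment frame, same residue). Water–water bonds are credited to both
participating waters in per-water vectors while counted once globally.

Neighbors are water oxygens within a cutoff (**inclusive**) of any heavy
atom of a functional group. The default neighbor cutoff is 3.6 Å; a 3.5 Å
variant is exposed because both values appear in the literature for this
quantity, and which produced a given printed table is not always stated.

## Subvolumes, integration and errors

A subvolume is the set of voxels whose center lies within a distance
(inclusive) of any heavy atom of an aligned reference ligand; selections
are nested in distance by construction. Integrated quantities are sums of
additive voxel quantities; per-water values divide by the mean water count
(oxygen-based). Errors come from block averaging: the frame series is cut
into four contiguous equal blocks (trailing remainder dropped and logged)
and the SEM is the sample standard deviation of block means over √4.
Comparison rows report rigid − flexible deltas for every total and
per-water quantity; positive energy deltas mean the flexible system is more
favorable.

## Hydration sites

Candidate centers are the observed in-region water-oxygen positions
themselves (data-driven, no grid bias). Greedy selection repeatedly accepts
the candidate whose 1 Å sphere holds the most remaining observations
(ties to the earliest observation), removes those observations, keeps
accepted centers ≥ 2 Å apart, and stops when the best sphere's occupancy
per frame falls below `min_occupancy_ratio × ρ°·(4/3)π r³`. The default
ratio of 2.0 ("at least twice bulk density") is a conventional choice for
hydration-site detection and is configurable. A site is a donor (acceptor)
when ≥ 60 % of its occupant waters donate (accept) at least one hydrogen
bond to the solute; "both" when both fractions reach 60 % (the threshold is
applied inclusively on both sides for consistency). Analyses accept a frame
range so a trailing window of a run can be analysed on its own.

## Synthetic solvent and study conditions

The synthetic solvent is a rigid 3-site water with TIP3P geometry and
charges (O −0.834 e, H +0.417 e, O σ 3.15061 Å, ε 0.1521 kcal/mol),
truncated at 6.0 Å — the cutoff keeps minimum-image validity in desk-scale
boxes. Its neat reference values are measured once and frozen in
`cavsolv.constants`:

- `E_neat = −10.97 kcal/mol`, from `scripts/calibrate_neat.py`: 64 waters
  at 0.0334 molecules/Å³, 300 K, 6000 equilibration sweeps, then 600 frames
  saved every 10 sweeps (seed 2027). Quarter-means fluctuate about ±0.15
  kcal/mol around this value after burn-in and independent seeds agree to
  roughly ±0.3; every downstream use is a contrast or sign check that is
  insensitive to this precision. The value is specific to this model and
  truncation and is not comparable to untruncated water-model energies.
- `ρ° = 0.0334 molecules/Å³` (imposed at constant volume).

Three generators supply test ensembles:

- **ideal gas** — uniform positions, uniform orientations; with
  zero-parameter waters it is the exact null model (g → 1, all energies 0);
- **lattice** — deterministic cubic lattice, identical frames; an optional
  per-frame jitter produces overlap-free random configurations for
  conservation checks at scale;
- **Metropolis Monte Carlo** — rigid-water translation/rotation moves
  (0.15 Å, 20°; ≈ 25–40 % acceptance) plus a 10 % fraction of uniform
  reinsertion moves for ergodicity, at 300 K. The sampler scores moves with
  the same energy evaluator the analysis modules use, so saved-frame
  energies re-evaluate identically. The solute is centered in the box and
  waters are wrapped by their oxygen so frames bin directly on a grid.

Toy solutes: a rigid cage of carbon-like LJ spheres forming a bowl-shaped
pocket presenting two acceptor oxygens (q −0.6 e with +0.6 e compensating
charges behind them — a carboxylate-strength bidentate mimic) at a
configurable separation; the enclosed variant's throat geometrically admits
one water oxygen but never two 2.4 Å apart (verified by a clearance scan).
And a closed capsule with a *cryptic* polar site: the acceptor pair is
either buried inside the shell (cognate, beyond hydrogen-bond reach of any
water that fits outside) or exposed flush with the surface (alternate,
freely hydrogen-bonding).

**Rigid/flexible pairs.** The rigid trajectory pins the capsule's pair at
the cognate position; the flexible trajectory lets it hop between cognate
and alternate with Metropolis acceptance computed from the gate–solvent
interaction alone (the rigid solute's internal energy is taken as equal in
both states, so with no waters nearby the states are exactly isoenergetic
and equally occupied — a property the suite asserts). Flips are attempted
every third sweep after burn-in; during burn-in the gate is held fixed so
the solvent first adapts to the starting structure (staged equilibration).
The flexible chain starts from the alternate state: raising charges into a
fully formed hydration shell carries a large steric proposal penalty, so a
cognate start can take arbitrarily long to find its first transition, while
an alternate start is the analogue of beginning an unligated simulation
from a relaxed, solvent-adapted structure. The chain remains free to bury
the pair; that it does not is the water-stabilisation signal the
rigid/flexible comparison measures.

Default two-state study conditions (used by the acceptance checks): 55
waters in a 12.8 Å box (bulk density around the 46-atom capsule), 600
equilibration sweeps, 150 frames saved every 4 sweeps, subvolume = voxels
within 4.5 Å of the two exposed acceptor positions.

What the generators do **not** emulate: conformational diversity beyond a
two-state group, polarisation, long-range electrostatics, realistic
protein chemistry, or MD kinetics. Passing tests therefore demonstrate the
correctness of the mapping/analysis machinery and the qualitative
rigid-vs-flexible energetic structure under an exactly known potential —
not quantitative agreement with any protein system.

## Density-derived surface area

The solvent-accessible surface is realised as the marching-cubes
isosurface of the Gaussian-smoothed (σ = 1 voxel) normalised density at
g = 0.5; threshold and smoothing are configurable, and a voxel-face area
approximation is returned alongside for cross-checking. On an analytic
hard-sphere density at 0.5 Å spacing the estimate lands within 15 % of
4πR² and converges toward it as the grid is refined.

## Numerical choices and degenerate inputs

- Overlapping interacting atoms (r < 1e-6 Å) raise an error rather than
  returning infinities.
- Superposition (least-squares rotation + translation) rejects collinear
  selections (second singular value < 1e-8 of the first); it is optional
  and off by default since generated frames share one frame of reference.
- Never-visited voxels report zeros; empty subvolumes integrate to zeros;
  per-water values with zero waters are zero rather than NaN.
- Exact ties in conformer assignment go to the first label in input order
  and are logged.
- All generators are seed-deterministic end to end; re-running a pipeline
  config reproduces every output byte-identically.

## Known limitations

- Truncated electrostatics make absolute energies model-specific; only
  referenced contrasts are meaningful.
- Single-particle Monte Carlo equilibrates dense liquid slowly; neat-liquid
  averages carry ~0.2–0.3 kcal/mol systematic uncertainty at the packaged
  run lengths, and enclosed pockets exchange water essentially only through
  reinsertion moves.
- At desk scale the water–water "frustration" signal of a single bound
  water is diluted by the surrounding bulk-like subvolume waters; the
  rigid/flexible water–water opposition is therefore resolved only at the
  sign level within block-averaged noise, while the total-energy,
  solute–water and hydrogen-bond contrasts are strong (several SEM).
- Boxes are orthorhombic only; triclinic cells are out of scope.
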