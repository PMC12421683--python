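"""Physical constants and the packaged synthetic water model.

The synthetic solvent is a rigid 3-site water (TIP3P geometry and charges)
with electrostatics and LJ truncated at 6 Å.  Its neat-liquid reference
energy ``SYNTHETIC_E_NEAT`` and bulk number density ``SYNTHETIC_RHO0`` were
measured once from a long neat Metropolis run of 64 molecules at 300 K and
0.0334 molecules/Å³ (see docs/methods.md) and are frozen here, the same way
a neat-water reference energy is fixed once per water model in production
grid-solvation analyses.
"""

#: Boltzmann constant, kcal/(mol K)
BOLTZMANN_KCAL = 0.0019872041

#: synthetic water geometry (Å, degrees) — TIP3P rigid geometry
WATER_OH = 0.9572
WATER_HOH_DEG = 104.52

#: synthetic water charges (e) and LJ parameters (Å, kcal/mol)
WATER_Q_O = -0.834
WATER_Q_H = 0.417
WATER_SIGMA_O = 3.15061
WATER_EPSILON_O = 0.1521

#: truncation radius of the synthetic model (Å)
SYNTHETIC_CUTOFF = 6.0

#: reference temperature (K)
SYNTHETIC_TEMPERATURE = 300.0

#: neat-liquid reference energy of one synthetic water (kcal/mol), measured
#: from the packaged neat calibration run (scripts/calibrate_neat.py,
#: seed 2027; frozen — see docs/methods.md)
SYNTHETIC_E_NEAT = -10.97

#: bulk number density of the synthetic model (molecules/Å³)
SYNTHETIC_RHO0 = 0.0334
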