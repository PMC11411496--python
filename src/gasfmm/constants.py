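"""Physical constants and element tables in MD units.

Units used throughout the package: lengths in nm, charges in elementary
charges e, masses in Da, energies in kJ/mol, forces in kJ mol^-1 nm^-1,
times in ps (MD configs accept fs for the step size).
"""

#: Coulomb factor 1/(4 pi eps0) in kJ mol^-1 nm e^-2 (MD-units convention).
COULOMB_K = 138.935458

#: Boltzmann constant in kJ mol^-1 K^-1.
BOLTZMANN_KB = 0.00831446261815324

#: All-atom number density of folded proteins, particles per nm^3.
PROTEIN_DENSITY = 100.0

#: Average atomic mass of protein matter including hydrogens, Da per atom.
#: Any protein-composition average in 7-8 Da/atom is defensible; this one is
#: consistent with ~135 atoms per kDa.
ATOMS_PER_KDA = 135.0

#: Hard-sphere (vdW-like) radii in nm, per element, used for SASA and CCS.
ELEMENT_RADII = {"H": 0.110, "C": 0.170, "N": 0.155, "O": 0.152, "S": 0.180}

#: Atomic masses in Da.
ELEMENT_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}

#: Composition of the synthetic all-atom systems (fractions sum to 1); gives
#: a mean mass of ~7.3 Da/atom, matching the protein average above.
SYNTHETIC_COMPOSITION = (("H", 0.50), ("C", 0.30), ("N", 0.10), ("O", 0.10))

#: Generic 12-6 Lennard-Jones parameters (sigma nm, epsilon kJ/mol) for the
#: toy gas-phase force field of the dynamics module.
LJ_PARAMS = {
    "H": (0.245, 0.066),
    "C": (0.340, 0.360),
    "N": (0.325, 0.711),
    "O": (0.296, 0.879),
    "S": (0.356, 1.046),
}
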