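"""Physical constants and unit conversions.

Internal units throughout the package: length in Angstrom, energy in
kcal/mol, charge in electrons, time in fs, mass in amu, temperature in K.
"""

# Coulomb constant in kcal mol^-1 A e^-2
KCAL_COULOMB = 332.0638

# 1 eV per particle expressed in kcal/mol (EEM electronegativity/hardness
# parameters are tabulated in eV)
EV_TO_KCAL = 23.060549

# Boltzmann constant in kcal mol^-1 K^-1
KB_KCAL = 0.0019872041

# 1 kcal/mol expressed in amu A^2 fs^-2 (i.e. force kcal/mol/A -> amu A fs^-2)
KCAL_TO_AMU_A2_FS2 = 1.0 / 2390.0573

# Atomic masses (amu); the force field's own mass column takes precedence.
ATOMIC_MASSES = {
    "H": 1.008,
    "O": 15.999,
    "S": 32.06,
    "Fe": 55.845,
}

# Rough single-bond covalent radii (A) used only for bonded-fragment
# guessing in scan generation and water identification.
COVALENT_RADII = {
    "H": 0.31,
    "O": 0.66,
    "S": 1.05,
    "Fe": 1.32,
}
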