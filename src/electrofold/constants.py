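"""Physical constants and unit conventions.

All coordinates are Cartesian angstroms; energies are J/mol inside the
ensemble machinery and kJ/mol at module surfaces that mirror calorimetric
observables (pair energies, free-energy profiles, heat capacities).
"""

#: Gas constant, J mol^-1 K^-1.
R_J = 8.314

#: Gas constant, kJ mol^-1 K^-1 (calorimetric surfaces).
R_KJ = R_J / 1000.0

#: Coulomb prefactor e^2/(4 pi eps0) expressed in kJ A mol^-1 e^-2, so that
#: E[kJ/mol] = COULOMB_KJ * q1*q2 / (eps * r[A]).
COULOMB_KJ = 1389.35

#: Default solvent dielectric used for the Debye screening length.
SOLVENT_DIELECTRIC = 78.5

#: Uniform effective dielectric scaling charge-charge interaction energies
#: (intramolecular and protein-DNA alike).
UNIFORM_DIELECTRIC = 29.0

#: Mean residue mass used to convert residue counts to molar mass, g/mol.
MEAN_RESIDUE_MASS = 110.0
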