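"""Physical constants in the toolkit's unit system (nm, kJ/mol, radian, e).

COULOMB_CONSTANT is 1/(4 pi eps0) expressed in kJ mol^-1 nm e^-2, the value used
by common molecular-mechanics engines.  GAS_CONSTANT converts a temperature in
Kelvin to the reduced temperature used by the Boltzmann training loss
(T_red = R * T, in kJ/mol).
"""

#: 1/(4 pi eps0) in kJ mol^-1 nm e^-2
COULOMB_CONSTANT = 138.935456

#: ideal gas constant in kJ mol^-1 K^-1
GAS_CONSTANT = 8.314e-3

#: Angstrom -> nm conversion applied at every PDB boundary
ANGSTROM_TO_NM = 0.1
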