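"""Physical constants and unit conventions.

The package works in molar MD units throughout: lengths in nm, time in ps,
masses in amu (g/mol), energies in kJ/mol, temperatures in K.  With these
units momenta are amu·nm/ps and the gas constant R has the value below; the
thermal energy is RT (kJ/mol).
"""

#: Ideal gas constant in kJ/(mol K).
GAS_CONSTANT: float = 8.314e-3

#: Conversion factor, femtoseconds -> picoseconds (time steps are usually
#: quoted in fs but all internal arithmetic is in ps).
FS_TO_PS: float = 1e-3
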