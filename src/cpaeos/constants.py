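"""Physical constants in the unit system used throughout the package.

All internal quantities are expressed in K, bar, L and mol, matching the
units of the pure-fluid parameter registry (a0 in L^2.bar/mol^2, b in L/mol,
association energy in bar.L/mol).
"""

#: Universal gas constant, bar.L/(mol.K).
R = 0.083145
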