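"""Physical constants (CODATA 2018 exact values)."""

BOLTZMANN = 1.380649e-23  # J/K
AVOGADRO = 6.02214076e23  # 1/mol

#: Default solvent (water) viscosity, Pa*s, at room temperature.
WATER_VISCOSITY = 0.89e-3

#: Default absolute temperature, K ("room temperature").
ROOM_TEMPERATURE = 298.15
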