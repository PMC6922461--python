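"""Physical constants and shared defaults."""

#: Avogadro's constant (2019 SI exact value), per mole.
AVOGADRO = 6.02214076e23

#: Default CHO cell surface area in square micrometres (15 um diameter sphere,
#: rounded to the nearest hundred).
DEFAULT_CELL_SURFACE_AREA_UM2 = 700.0

#: Default cell diameter in micrometres used for the spherical-cell assumption.
DEFAULT_CELL_DIAMETER_UM = 15.0
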