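"""Unit conversions and physical constants shared across the package.

Internally every tumor size is a (continuous) cell count and every time is a
day.  Volumes reported by CT volumetry convert via the standard rule
``10^-3 ml = 1 mm^3 = 10^6 cells``.
"""

#: Avogadro constant [molecules / mol]
AVOGADRO = 6.02214076e23

#: cells per milliliter of tumor volume
CELLS_PER_ML = 1e9

#: cells per cubic millimeter of tumor volume
CELLS_PER_MM3 = 1e6

#: default tumor carrying capacity [cells]
DEFAULT_K = 1e12

#: default fractal dimension of the dissemination rate (spheroid surface)
DEFAULT_ALPHA = 2.0 / 3.0
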