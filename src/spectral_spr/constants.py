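"""Physical constants and element data shared across the package.

Element mean excitation energies (I-values) follow the ICRU-style
recommendations commonly used in stopping-power work; they are embedded
here so the package needs no external data download.
"""

from __future__ import annotations

import math
from types import MappingProxyType

#: (atomic number Z, standard atomic weight A [g/mol], elemental I-value [eV])
#: before the condensed-phase adjustment below.
_RAW_ELEMENTS = {
    "H": (1, 1.008, 19.2),
    "C": (6, 12.011, 78.0),
    "N": (7, 14.007, 82.0),
    "O": (8, 15.999, 95.0),
    "Na": (11, 22.990, 149.0),
    "Mg": (12, 24.305, 156.0),
    "Si": (14, 28.085, 173.0),
    "P": (15, 30.974, 173.0),
    "S": (16, 32.06, 180.0),
    "Cl": (17, 35.45, 174.0),
    "K": (19, 39.098, 190.0),
    "Ca": (20, 40.078, 191.0),
    "Fe": (26, 55.845, 286.0),
}

#: Mean excitation energy of liquid water [eV].
I_WATER = 75.0

# Condensed-phase adjustment: raw elemental I-values combined by Bragg
# additivity give water I ~ 69 eV, short of the accepted liquid-water 75 eV.
# All elemental values are scaled by one factor so that additivity over the
# water composition reproduces I_WATER exactly; this keeps the stopping-
# power ratio of water identically 1, the anchor every calibration assumes.
_lam_h = 0.1119 * 1 / 1.008
_lam_o = 0.8881 * 8 / 15.999
_i_water_raw = math.exp(
    (_lam_h * math.log(19.2) + _lam_o * math.log(95.0)) / (_lam_h + _lam_o)
)
_I_SCALE = I_WATER / _i_water_raw

ELEMENTS = MappingProxyType({
    el: (z, a, i * _I_SCALE) for el, (z, a, i) in _RAW_ELEMENTS.items()
})

#: Electron rest energy m_e c^2 [MeV].
ELECTRON_REST_ENERGY_MEV = 0.51099895

#: Proton rest energy m_p c^2 [MeV].
PROTON_REST_ENERGY_MEV = 938.27208816

#: Mass fractions of liquid water.
WATER_COMPOSITION = MappingProxyType({"H": 0.1119, "O": 0.8881})

#: Default proton kinetic energy for reference stopping-power ratios [MeV].
#: Mid-range of clinical energies; reference SPR is insensitive to this
#: choice to first order (varying 80-120 MeV moves SPR by <0.2%).
DEFAULT_PROTON_ENERGY_MEV = 100.0

#: Density of liquid water [g/cm^3].
WATER_DENSITY = 1.0

#: Z/A of water (electrons per atomic mass unit), used to convert relative
#: electron density into a mass density consistent with a composition.
WATER_Z_OVER_A = sum(
    w * ELEMENTS[el][0] / ELEMENTS[el][1] for el, w in WATER_COMPOSITION.items()
)
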