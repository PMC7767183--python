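"""Named physical constants and unit conversion factors.

All unit conversions used across the package are explicit module-level
constants so that no magic factor appears inline in a formula.
"""

import math

# unit conversions
MM3_PER_DM3 = 1.0e6
MM3_PER_CM3 = 1.0e3
G_PER_MG = 1.0e-3
DM3_PER_CM3 = 1.0e-3

# water at 20 degC (pycnometer reference) and the air-buoyancy correction
WATER_DENSITY_20C_G_PER_CM3 = 0.997
AIR_BUOYANCY_CORRECTION = 0.0012

# AMPD (2-amino-2-methyl-1,3-propanediol)
AMPD_MOLAR_MASS = 105.14  # g/mol
AMPD_PKA_25C = 8.76  # conjugate acid, 25 degC
#: pKb derived from the 25 degC pKa via pKw = 14: 14 - 8.76
AMPD_PKB_FROM_PKA = 5.24
#: base dissociation constant used in the hydrolysis treatment
AMPD_KB_HYDROLYSIS = 6.309e-6
AMPD_PKB_HYDROLYSIS = -math.log10(AMPD_KB_HYDROLYSIS)  # ~= 5.2000

# stearic acid (the reactive free fatty acid of the model sebum)
STEARIC_MOLAR_MASS = 284.48  # g/mol
STEARIC_KA = 1.778e-5
STEARIC_PKA = -math.log10(STEARIC_KA)  # ~= 4.7500

# water ionic product at 25 degC
PKW_25C = 14.0
KW_25C = 1.0e-14
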