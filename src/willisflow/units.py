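"""Unit conventions and conversion constants.

Interfaces use clinical units: lengths/diameters in mm, pressures in mmHg,
flows in mL/min (reports) or mL/s (solver-facing helpers), resistances in
mmHg.s.mL^-1 and compliances in mL.mmHg^-1.  All internal solver arithmetic
is in SI (m, Pa, m^3/s, Pa.s.m^-3).
"""

MMHG_PA = 133.322          # 1 mmHg in Pa
ML_M3 = 1.0e-6             # 1 mL in m^3
MLMIN_M3S = ML_M3 / 60.0   # 1 mL/min in m^3/s

# resistance: mmHg.s/mL -> Pa.s/m^3
RES_SI = MMHG_PA / ML_M3
# compliance: mL/mmHg -> m^3/Pa
CAP_SI = ML_M3 / MMHG_PA
# inertance: mmHg.s^2/mL -> Pa.s^2/m^3
IND_SI = MMHG_PA / ML_M3

MM_M = 1.0e-3

BLOOD_DENSITY = 1060.0     # kg/m^3
BLOOD_VISCOSITY = 0.0047   # Pa.s


def mmhg_to_pa(p):
    return p * MMHG_PA


def pa_to_mmhg(p):
    return p / MMHG_PA


def mlmin_to_m3s(q):
    return q * MLMIN_M3S


def m3s_to_mlmin(q):
    return q / MLMIN_M3S
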