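"""Unit conversions between SI internals and clinical I/O units.

All computation inside the package uses SI (m, s, Pa, m^3/s) except the
lumped Windkessel circuits, which use the field's customary units
(mmHg, s, mL) so that resistances are mmHg.s/mL and compliances mL/mmHg.
Conversion happens only at these boundaries.
"""

from __future__ import annotations

L_PER_MIN_TO_M3_S: float = 1.0 / 60000.0
M3_S_TO_L_PER_MIN: float = 60000.0
MMHG_TO_PA: float = 133.322
PA_TO_MMHG: float = 1.0 / 133.322
M3_S_TO_ML_S: float = 1.0e6
L_PER_MIN_TO_ML_S: float = 1000.0 / 60.0
ML_S_TO_L_PER_MIN: float = 60.0 / 1000.0
M2_TO_CM2: float = 1.0e4


def l_per_min_to_m3_s(q: float) -> float:
    return q * L_PER_MIN_TO_M3_S


def m3_s_to_l_per_min(q: float) -> float:
    return q * M3_S_TO_L_PER_MIN


def mmhg_to_pa(p: float) -> float:
    return p * MMHG_TO_PA


def pa_to_mmhg(p: float) -> float:
    return p * PA_TO_MMHG
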