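"""Unit conversions between clinical and internal (g–mm–s) units.

Internal unit system:

==============  ====================  ========================
quantity        internal unit         clinical unit
==============  ====================  ========================
pressure        g/(mm·s²)  (= Pa)     mmHg
flow            mm³/s                 L/min
volume          mm³                   mL
resistance      g/(mm⁴·s)             mmHg·min/L (Wood-ish)
compliance      mm⁴·s²/g              mL/mmHg
inertance       g/mm⁴                 —
elastance       g/(mm⁴·s²)            mmHg/mL
==============  ====================  ========================

1 mmHg = 133.322 g/(mm·s²); 1 mL = 1000 mm³.
"""

MMHG = 133.322          # g/(mm·s²) per mmHg
ML = 1000.0             # mm³ per mL
L_PER_MIN = 1.0e6 / 60.0  # mm³/s per L/min
MMHG_PER_ML = MMHG / ML   # elastance: g/(mm⁴·s²) per (mmHg/mL)
ML_PER_MMHG = ML / MMHG   # compliance: mm⁴·s²/g per (mL/mmHg)


def mmhg_to_internal(p_mmhg: float) -> float:
    return p_mmhg * MMHG


def internal_to_mmhg(p_internal: float) -> float:
    return p_internal / MMHG


def lmin_to_mm3s(q_lmin: float) -> float:
    return q_lmin * L_PER_MIN


def mm3s_to_lmin(q_mm3s: float) -> float:
    return q_mm3s / L_PER_MIN
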