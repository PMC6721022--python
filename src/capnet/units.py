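"""Unit conversions used at package interfaces.

All internal computation is in SI (m, Pa, s).  Micrometres, mmHg and
ml/min appear only at interfaces, where clinical and morphometric values
are conventionally quoted.
"""

#: metres per micrometre
UM = 1e-6

#: pascal per millimetre of mercury
MMHG = 133.322

#: cubic metres per second in one millilitre per minute
ML_PER_MIN = 1e-6 / 60.0


def um_to_m(x: float) -> float:
    return x * UM


def m_to_um(x: float) -> float:
    return x / UM


def mmhg_to_pa(p: float) -> float:
    return p * MMHG


def pa_to_mmhg(p: float) -> float:
    return p / MMHG


def ml_min_to_m3s(q: float) -> float:
    return q * ML_PER_MIN


def m3s_to_ml_min(q: float) -> float:
    return q / ML_PER_MIN
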