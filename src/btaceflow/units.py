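"""Unit conversion constants and helpers.

Everything internal is SI (Pa, m, m**3/s). Clinical and bench reporting uses
mmHg and mL/min, so the conversions live in one place.
"""

PA_PER_MMHG = 133.322
M3S_PER_MLMIN = 1.0 / 6.0e7


def pa_to_mmhg(p: float) -> float:
    return p / PA_PER_MMHG


def mmhg_to_pa(p: float) -> float:
    return p * PA_PER_MMHG


def m3s_to_mlmin(q: float) -> float:
    return q * 6.0e7


def mlmin_to_m3s(q: float) -> float:
    return q * M3S_PER_MLMIN
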