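"""Unit conventions and conversions.

All lengths are millimetres, forces Newtons, stresses and pressures
N/mm^2 (identical to MPa).  Clinical blood pressures are quoted in mmHg;
convert explicitly at the boundary of the package.
"""

#: 1 mmHg in N/mm^2 (133.322 Pa).
MMHG_TO_MPA = 133.322e-6


def mmhg_to_mpa(p_mmhg: float) -> float:
    """Convert a pressure from mmHg to N/mm^2 (MPa)."""
    return p_mmhg * MMHG_TO_MPA


def mpa_to_mmhg(p_mpa: float) -> float:
    """Convert a pressure from N/mm^2 (MPa) to mmHg."""
    return p_mpa / MMHG_TO_MPA
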