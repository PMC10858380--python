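"""Unit conversion constants.

All geometry is carried internally in millimeters (the physical space of the
scanner affine); distances are reported in centimeters, volumes in cm³ and the
standardized distance in m⁻¹. Every conversion in the package goes through
this table so the convention lives in one place.
"""

MM_PER_CM = 10.0
MM_PER_M = 1000.0
MM3_PER_CM3 = 1000.0


def mm_to_cm(x_mm: float) -> float:
    return x_mm / MM_PER_CM


def cm_to_mm(x_cm: float) -> float:
    return x_cm * MM_PER_CM


def mm3_to_cm3(v_mm3: float) -> float:
    return v_mm3 / MM3_PER_CM3


def cm_to_m(x_cm: float) -> float:
    return x_cm * MM_PER_CM / MM_PER_M
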