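"""Single conversion path between mmHg, Pa, N/mm^2 (MPa) and N/cm^2.

All stress arithmetic inside the FEA is done in N and mm (stress in N/mm^2);
reported wall stress and strength use N/cm^2 as in the AAA biomechanics
literature.  Every unit conversion in the package goes through this module.
"""

MMHG_TO_PA = 133.322365          # exact conversion constant used throughout
PA_TO_N_PER_CM2 = 1.0e-4         # 1 Pa = 1 N/m^2 = 1e-4 N/cm^2
N_PER_MM2_TO_N_PER_CM2 = 100.0   # 1 N/mm^2 = 100 N/cm^2


def mmhg_to_pa(p: float) -> float:
    return p * MMHG_TO_PA


def pa_to_mmhg(p: float) -> float:
    return p / MMHG_TO_PA


def mmhg_to_n_per_mm2(p: float) -> float:
    """Intraluminal pressure (mmHg) to N/mm^2, the FEA's internal stress unit."""
    return p * MMHG_TO_PA * 1.0e-6  # Pa -> N/mm^2

def n_per_mm2_to_mmhg(s: float) -> float:
    return s * 1.0e6 / MMHG_TO_PA


def n_per_mm2_to_n_per_cm2(s: float) -> float:
    return s * N_PER_MM2_TO_N_PER_CM2


def n_per_cm2_to_n_per_mm2(s: float) -> float:
    return s / N_PER_MM2_TO_N_PER_CM2


def mmhg_to_n_per_cm2(p: float) -> float:
    return n_per_mm2_to_n_per_cm2(mmhg_to_n_per_mm2(p))
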