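"""Standard validation scenarios, in dimensionless units.

All three presets use the cortical penetrating-arteriole parameters
P_ves = 80 mmHg, R_ves = 6 μm and (where applicable) R_t = 200 μm with the
default scales r* = 141 μm, M* = 10⁻³ mmHg·μm⁻², so that M̂ = 1 for the
nominal consumption and the tissue-cylinder radius maps to R̂_t ≈ √2.
"""

from __future__ import annotations

from .core import VesselSpec
from .forward_models import ConsumptionField, Domain, TissueScenario
from .scaling import DEFAULT_SCALES

_P_VES_HAT = 80.0 / DEFAULT_SCALES.pressure_scale      # ≈ 4.02
_R_VES_HAT = 6.0 / DEFAULT_SCALES.r_star               # ≈ 0.0426
_R_T_HAT = 200.0 / DEFAULT_SCALES.r_star               # ≈ 1.418


def single_vessel_scenario(M_hat: float = 1.0) -> TissueScenario:
    """One central arteriole, uniform consumption: the Krogh–Erlang setting."""
    vessel = VesselSpec((0.0, 0.0), _R_VES_HAT, _P_VES_HAT)
    return TissueScenario((vessel,), ConsumptionField.constant(M_hat),
                          Domain("disc", _R_T_HAT), R_t=_R_T_HAT)


def two_level_scenario(M_inner: float = 2.0, M_outer: float = 0.5,
                       breakpoint: float = 0.7, domain_radius: float = 1.45) -> TissueScenario:
    """Central arteriole with a capillary-free region of elevated consumption.

    M̂ = ``M_inner`` for r̂ below the breakpoint and ``M_outer`` beyond it —
    the drop mimics a distant capillary bed acting as an unmodelled oxygen
    source.  Solved numerically on a disc large enough to cover the usual
    ±1 measurement window.
    """
    vessel = VesselSpec((0.0, 0.0), _R_VES_HAT, _P_VES_HAT)
    consumption = ConsumptionField.radial((M_inner, M_outer), (breakpoint,))
    return TissueScenario((vessel,), consumption, Domain("disc", domain_radius),
                          R_t=domain_radius)


def three_vessel_scenario() -> TissueScenario:
    """Three arterioles (wall pressures 80, 70, 50 mmHg) in a square window.

    Vessel placement follows the left / lower-right / upper-right layout of
    the multi-vessel validation example; consumption is uniform M̂ = 1.
    """
    scale = DEFAULT_SCALES.pressure_scale
    vessels = (
        VesselSpec((-0.5, 0.0), _R_VES_HAT, 80.0 / scale),
        VesselSpec((0.5, -0.45), _R_VES_HAT, 70.0 / scale),
        VesselSpec((0.45, 0.5), _R_VES_HAT, 50.0 / scale),
    )
    return TissueScenario(vessels, ConsumptionField.constant(1.0), Domain("square", 1.0))
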