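"""Conversions between physical and dimensionless unit systems.

The Poisson relation ∇²P = M is made dimensionless with a characteristic
length r* and consumption M*:  r̂ = r/r*,  P̂ = P/(M*·r*²),  M̂ = M/M*.
The relation keeps its form under this rescaling, so the whole estimation
pipeline can run on dimensionless maps and convert at the boundaries.

The consumption variable M (units mmHg·μm⁻²) relates to the net oxygen
consumption rate s through s = M·D·α, with D the oxygen diffusion
coefficient and α the oxygen solubility in tissue.
"""

from __future__ import annotations

import numpy as np

from .core import (DIMENSIONLESS, MMHG, ConfigurationError, PhysicalScales,
                   PressureMap, UnitMismatchError)

#: Default scales: r* = 141 μm (so that the 200 μm tissue-cylinder radius maps
#: to R̂t ≈ √2) and M* = 0.001 mmHg·μm⁻² (the nominal cortical consumption).
DEFAULT_SCALES = PhysicalScales(r_star=141.0, M_star=1e-3)


def to_dimensionless(pmap: PressureMap, scales: PhysicalScales) -> PressureMap:
    """Rescale a physical map (mmHg, μm) into the dimensionless system."""
    if pmap.units != MMHG:
        raise UnitMismatchError("map is already dimensionless")
    factor = 1.0 / scales.pressure_scale
    grid = pmap.grid.scaled(1.0 / scales.r_star)
    vessels = None
    if pmap.vessels is not None:
        vessels = tuple(v.scaled(1.0 / scales.r_star, factor) for v in pmap.vessels)
    return PressureMap(grid, pmap.values * factor, DIMENSIONLESS, vessels)


def from_dimensionless(pmap: PressureMap, scales: PhysicalScales) -> PressureMap:
    """Exact inverse of :func:`to_dimensionless` (up to floating round-off)."""
    if pmap.units != DIMENSIONLESS:
        raise UnitMismatchError("map is already in physical units")
    factor = scales.pressure_scale
    grid = pmap.grid.scaled(scales.r_star)
    vessels = None
    if pmap.vessels is not None:
        vessels = tuple(v.scaled(scales.r_star, factor) for v in pmap.vessels)
    return PressureMap(grid, pmap.values * factor, MMHG, vessels)


def pressure_to_dimensionless(value, scales: PhysicalScales):
    """Scalar/array form of the pressure rescaling (also applies to σ_P)."""
    return np.asarray(value, dtype=float) / scales.pressure_scale


def pressure_from_dimensionless(value, scales: PhysicalScales):
    return np.asarray(value, dtype=float) * scales.pressure_scale


def consumption_rate_from_M(M, scales: PhysicalScales):
    """Net oxygen consumption rate s = M·D·α (elementwise).

    Requires the optional scales D and alpha; without them only the
    consumption variable M itself is defined.
    """
    if scales.D is None or scales.alpha is None:
        raise ConfigurationError(
            "converting M to a consumption rate s needs both D and alpha")
    return np.asarray(M, dtype=float) * scales.D * scales.alpha
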