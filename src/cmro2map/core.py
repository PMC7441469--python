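"""Core containers shared by every stage of the CMRO2-estimation pipeline.

The package works on uniform Cartesian grids of oxygen partial pressure
(pO2).  A map is either in physical units (mmHg on a grid in micrometres)
or in the dimensionless system obtained by rescaling with a characteristic
length ``r*`` and a characteristic consumption ``M*``; every container
carries an explicit unit flag so that mixed-unit arithmetic fails loudly
instead of silently producing garbage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

DIMENSIONLESS = "dimensionless"
MMHG = "mmHg"

_VALID_UNITS = (DIMENSIONLESS, MMHG)


class UnitMismatchError(ValueError):
    """Operands carry incompatible unit systems."""


class ConfigurationError(ValueError):
    """A required configuration value is missing or inconsistent."""


class DomainError(ValueError):
    """A point or grid lies outside the region where a model is defined."""


class ScenarioError(ValueError):
    """A tissue scenario violates its geometric invariants."""


class NumericalError(RuntimeError):
    """A solver failed to reach its residual tolerance."""


class MapFormatError(ValueError):
    """A map file on disk is malformed."""


def _check_units(units: str) -> str:
    if units not in _VALID_UNITS:
        raise ConfigurationError(f"unknown unit system {units!r}; expected one of {_VALID_UNITS}")
    return units


def _check_uniform(coords: np.ndarray, spacing: float, name: str) -> None:
    if coords.ndim != 1 or coords.size < 2:
        raise ConfigurationError(f"{name} coordinates must be 1-D with at least two nodes")
    steps = np.diff(coords)
    if np.any(steps <= 0):
        raise ConfigurationError(f"{name} coordinates must be strictly increasing")
    if np.max(np.abs(steps - spacing)) > 1e-12 * max(abs(spacing), 1.0) + 1e-300:
        raise ConfigurationError(f"{name} coordinates are not uniform with spacing {spacing}")


@dataclass(frozen=True)
class GridSpec:
    """Uniform node-centred Cartesian grid, ``x[i] = x0 + i*spacing``."""

    x: np.ndarray
    y: np.ndarray
    spacing: float

    def __post_init__(self):
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.spacing <= 0:
            raise ConfigurationError("grid spacing must be positive")
        _check_uniform(self.x, self.spacing, "x")
        _check_uniform(self.y, self.spacing, "y")

    @classmethod
    def centered(cls, half_width: float, spacing: float) -> "GridSpec":
        """Symmetric square window around the origin, node count odd.

        The window covers ``[-half_width, half_width]`` as closely as the
        spacing allows; coordinates are exact integer multiples of it.
        """
        n_half = int(np.floor(half_width / spacing + 1e-9))
        idx = np.arange(-n_half, n_half + 1, dtype=float)
        coords = idx * spacing
        return cls(coords, coords.copy(), spacing)

    @classmethod
    def from_origin(cls, origin: Tuple[float, float], spacing: float,
                    n_x: int, n_y: int) -> "GridSpec":
        x = origin[0] + np.arange(n_x) * spacing
        y = origin[1] + np.arange(n_y) * spacing
        return cls(x, y, spacing)

    @property
    def n_x(self) -> int:
        return self.x.size

    @property
    def n_y(self) -> int:
        return self.y.size

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.n_x, self.n_y)

    def points(self) -> Tuple[np.ndarray, np.ndarray]:
        """Node coordinates as 2-D arrays with ``ij`` indexing."""
        return np.meshgrid(self.x, self.y, indexing="ij")

    def radii(self, center: Tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
        X, Y = self.points()
        return np.hypot(X - center[0], Y - center[1])

    def refined(self, spacing: float) -> "GridSpec":
        """Finer grid with the same lower-left origin and extent."""
        if spacing > self.spacing * (1 + 1e-12):
            # coarser evaluation grids are allowed, just built the same way
            pass
        nx = int(np.floor((self.x[-1] - self.x[0]) / spacing + 1e-9)) + 1
        ny = int(np.floor((self.y[-1] - self.y[0]) / spacing + 1e-9)) + 1
        return GridSpec(self.x[0] + np.arange(nx) * spacing,
                        self.y[0] + np.arange(ny) * spacing, spacing)

    def scaled(self, factor: float) -> "GridSpec":
        return GridSpec(self.x * factor, self.y * factor, self.spacing * factor)


@dataclass(frozen=True)
class VesselSpec:
    """Penetrating arteriole: a disc of fixed pressure.

    center : (x, y) position of the vessel axis in map coordinates
    R_ves  : vessel radius (same length unit as the map coordinates)
    P_ves  : pO2 imposed at (and inside) the vessel wall
    """

    center: Tuple[float, float]
    R_ves: float
    P_ves: float

    def __post_init__(self):
        if self.R_ves <= 0:
            raise ScenarioError("vessel radius must be positive")
        if self.P_ves <= 0:
            raise ScenarioError("vessel wall pressure must be positive")
        object.__setattr__(self, "center", (float(self.center[0]), float(self.center[1])))

    def scaled(self, length_factor: float, pressure_factor: float) -> "VesselSpec":
        return VesselSpec((self.center[0] * length_factor, self.center[1] * length_factor),
                          self.R_ves * length_factor, self.P_ves * pressure_factor)


@dataclass
class PressureMap:
    """pO2 field on a uniform grid; ``values[i, j]`` lives at ``(x[i], y[j])``."""

    grid: GridSpec
    values: np.ndarray
    units: str = DIMENSIONLESS
    vessels: Optional[Tuple[VesselSpec, ...]] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        _check_units(self.units)
        if self.values.shape != self.grid.shape:
            raise ConfigurationError(
                f"values shape {self.values.shape} does not match grid shape {self.grid.shape}")
        if self.vessels is not None:
            self.vessels = tuple(self.vessels)

    def with_values(self, values: np.ndarray) -> "PressureMap":
        return PressureMap(self.grid, values, self.units, self.vessels)

    def copy(self) -> "PressureMap":
        return PressureMap(self.grid, self.values.copy(), self.units, self.vessels)


@dataclass(frozen=True)
class PhysicalScales:
    """Characteristic scales of the dimensionless system.

    r_star : characteristic length (μm)
    M_star : characteristic consumption (mmHg·μm⁻²)
    D      : oxygen diffusion coefficient in tissue (optional; only needed to
             convert the consumption variable M into a net consumption rate s)
    alpha  : oxygen solubility (optional, same purpose)
    """

    r_star: float
    M_star: float
    D: Optional[float] = None
    alpha: Optional[float] = None

    def __post_init__(self):
        if self.r_star <= 0 or self.M_star <= 0:
            raise ConfigurationError("r_star and M_star must be positive")
        for name in ("D", "alpha"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ConfigurationError(f"{name}, when given, must be positive")

    @property
    def pressure_scale(self) -> float:
        """M*·r*², the factor between physical pressure and P̂."""
        return self.M_star * self.r_star ** 2
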