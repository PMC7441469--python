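"""The diffusion-operator inverse step: M̂_est = ∇²P̂_smooth.

The consumption variable is estimated by applying the 5-point discrete
Laplacian to a (smoothed) pressure map.  Because the second derivative
amplifies high-frequency noise, the estimator is normally preceded by the
penalized-spline smoothing of :mod:`cmro2map.smoothing`; with ``q = 0`` it
reduces to the Laplacian of the interpolated data.

A validity mask accompanies every estimate: the outermost node ring (where
the stencil has no neighbours and values are copied from the nearest
interior node) and, when vessel metadata is available, nodes within one
smoothing length of a vessel wall are flagged invalid.  The flags are
advisory — values are reported, not removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .core import (ConfigurationError, GridSpec, PressureMap, ScenarioError,
                   VesselSpec)
from .smoothing import SmoothedMap, SmoothingConfig, smooth_map


@dataclass
class EstimateMap:
    """Spatially resolved consumption estimate with validity flags."""

    grid: GridSpec
    values: np.ndarray
    validity: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.validity = np.asarray(self.validity, dtype=bool)
        if self.values.shape != self.grid.shape or self.validity.shape != self.grid.shape:
            raise ConfigurationError("estimate fields must match the grid shape")


@dataclass(frozen=True)
class AveragedEstimate:
    """Disc-cut spatial average of an estimate map.

    value    : mean of M̂_est over the retained nodes
    d_cut    : radius of the disc excluded around each vessel centre
    n_points : number of nodes that entered the average
    """

    value: float
    d_cut: float
    n_points: int


def discrete_laplacian(field: Union[PressureMap, SmoothedMap]) -> EstimateMap:
    """5-point finite-difference Laplacian on a uniform grid.

    Interior nodes get ``(P[i+1,j] + P[i-1,j] + P[i,j+1] + P[i,j-1]
    - 4 P[i,j]) / d²`` (the full Laplacian — the common ``del2`` helper
    returns a quarter of this).  The boundary ring is filled by copying the
    nearest interior value and flagged invalid.
    """
    grid = field.grid
    values = field.values
    if grid.n_x < 3 or grid.n_y < 3:
        raise ConfigurationError("the Laplacian stencil needs at least 3 nodes per axis")
    d2 = grid.spacing ** 2
    lap = np.empty_like(values)
    lap[1:-1, 1:-1] = (values[2:, 1:-1] + values[:-2, 1:-1]
                       + values[1:-1, 2:] + values[1:-1, :-2]
                       - 4.0 * values[1:-1, 1:-1]) / d2
    # flag-and-copy boundary ring
    lap[0, 1:-1] = lap[1, 1:-1]
    lap[-1, 1:-1] = lap[-2, 1:-1]
    lap[:, 0] = lap[:, 1]
    lap[:, -1] = lap[:, -2]
    validity = np.zeros(values.shape, dtype=bool)
    validity[1:-1, 1:-1] = True
    return EstimateMap(grid, lap, validity)


def estimate_M(data: PressureMap, config: SmoothingConfig,
               vessels: Optional[Sequence[VesselSpec]] = None) -> EstimateMap:
    """Full diffusion-operator estimate: smooth, refine, differentiate.

    The map is fitted with the penalized spline of ``config``, evaluated on
    the ``d_est`` grid, and differentiated with the 5-point stencil.  When
    vessel metadata is present (either passed explicitly or carried by the
    map) nodes within one smoothing length ``d_q`` of a vessel wall are
    additionally flagged invalid.
    """
    smoothed = smooth_map(data, config)
    est = discrete_laplacian(smoothed)
    if vessels is None:
        vessels = data.vessels
    if vessels:
        d_q = config.resolve_dq(data.grid.spacing)
        X, Y = est.grid.points()
        for v in vessels:
            near = np.hypot(X - v.center[0], Y - v.center[1]) < v.R_ves + d_q
            est.validity &= ~near
    return est


def average_M(est: EstimateMap, vessels: Sequence[VesselSpec],
              d_cut: float) -> AveragedEstimate:
    """Mean estimate outside exclusion discs of radius ``d_cut``.

    Averages the valid nodes whose distance to every vessel centre is at
    least ``d_cut``; pooling trades spatial resolution for precision and
    sidesteps the smoothing-induced bias lobes around the vessels.  The
    exclusion size must reach past the bias lobes (which extend roughly
    two to three smoothing lengths from the vessel) for the average to be
    unbiased — see the methods note for the calibration of this choice.
    """
    if d_cut < 0:
        raise ConfigurationError("d_cut must be non-negative")
    mask = est.validity.copy()
    X, Y = est.grid.points()
    for v in vessels:
        mask &= np.hypot(X - v.center[0], Y - v.center[1]) >= d_cut
    n = int(mask.sum())
    if n == 0:
        raise ScenarioError("no valid node survives the d_cut exclusion")
    return AveragedEstimate(float(est.values[mask].mean()), float(d_cut), n)
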