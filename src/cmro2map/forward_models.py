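"""Ground-truth pO2 maps from known consumption fields.

Two forward models solve ∇²P = M with Dirichlet vessels (P = P_ves on each
vessel disc) and a zero-normal-gradient outer boundary:

* the closed-form Krogh–Erlang solution for a single vessel with constant
  consumption inside a tissue cylinder of radius R_t, and
* finite-difference Poisson solvers for general configurations — a
  Cartesian 5-point scheme on square domains (mirror-ghost Neumann edges)
  and a conservative polar scheme on disc domains with a centred vessel.

Solutions are sampled onto uniform measurement grids, with nodes inside a
vessel overwritten by that vessel's wall pressure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import sparse
from scipy.interpolate import CubicSpline, RectBivariateSpline
from scipy.linalg import solve_banded
from scipy.sparse.linalg import spsolve

from .core import (DomainError, GridSpec, NumericalError, PressureMap,
                   ScenarioError, VesselSpec)

_RESIDUAL_TOL = 1e-10


# ---------------------------------------------------------------------------
# scenario description
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConsumptionField:
    """Net consumption M as a function of position.

    kind
        ``constant`` (one level everywhere), ``radial_piecewise`` (levels
        separated by strictly increasing radial breakpoints, measured from a
        reference vessel centre), or ``gridded`` (one value per node of a
        given grid).
    """

    kind: str
    values: Tuple[float, ...] = (0.0,)
    breakpoints: Tuple[float, ...] = ()
    grid_values: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.kind not in ("constant", "radial_piecewise", "gridded"):
            raise ScenarioError(f"unknown consumption kind {self.kind!r}")
        object.__setattr__(self, "values", tuple(float(v) for v in np.atleast_1d(self.values)))
        object.__setattr__(self, "breakpoints", tuple(float(b) for b in self.breakpoints))
        if self.kind == "constant" and len(self.values) != 1:
            raise ScenarioError("constant consumption takes exactly one level")
        if self.kind == "radial_piecewise":
            if len(self.values) != len(self.breakpoints) + 1:
                raise ScenarioError("radial_piecewise needs len(values) == len(breakpoints)+1")
            if np.any(np.diff(self.breakpoints) <= 0):
                raise ScenarioError("breakpoints must be strictly increasing")
        if self.kind == "gridded" and self.grid_values is None:
            raise ScenarioError("gridded consumption needs grid_values")

    @classmethod
    def constant(cls, M: float) -> "ConsumptionField":
        return cls("constant", (M,))

    @classmethod
    def radial(cls, levels: Sequence[float], breakpoints: Sequence[float]) -> "ConsumptionField":
        return cls("radial_piecewise", tuple(levels), tuple(breakpoints))

    @property
    def is_radial(self) -> bool:
        return self.kind in ("constant", "radial_piecewise")

    def at_radius(self, r) -> np.ndarray:
        """Level at radial distance r from the reference vessel centre."""
        if not self.is_radial:
            raise ScenarioError("radial evaluation of a non-radial consumption field")
        r = np.asarray(r, dtype=float)
        idx = np.searchsorted(np.asarray(self.breakpoints), r, side="right")
        return np.asarray(self.values)[idx]

    def on_grid(self, grid: GridSpec, center: Tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
        if self.kind == "gridded":
            gv = np.asarray(self.grid_values, dtype=float)
            if gv.shape != grid.shape:
                raise ScenarioError("gridded consumption does not match the grid shape")
            return gv
        return self.at_radius(grid.radii(center))


@dataclass(frozen=True)
class Domain:
    """Outer boundary: ``square`` (half-width) or ``disc`` (radius)."""

    kind: str
    size: float

    def __post_init__(self):
        if self.kind not in ("square", "disc"):
            raise ScenarioError(f"unknown domain kind {self.kind!r}")
        if self.size <= 0:
            raise ScenarioError("domain size must be positive")

    def contains(self, x, y, tol: float = 1e-9) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.kind == "square":
            return (np.abs(x) <= self.size + tol) & (np.abs(y) <= self.size + tol)
        return np.hypot(x, y) <= self.size + tol


@dataclass(frozen=True)
class TissueScenario:
    """Vessels + consumption field + domain: the ground truth of a run."""

    vessels: Tuple[VesselSpec, ...]
    consumption: ConsumptionField
    domain: Domain
    R_t: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "vessels", tuple(self.vessels))
        if not self.vessels:
            raise ScenarioError("a scenario needs at least one vessel")
        for v in self.vessels:
            if not np.all(self.domain.contains(*v.center)):
                raise ScenarioError(f"vessel at {v.center} lies outside the domain")
        for i, a in enumerate(self.vessels):
            for b in self.vessels[i + 1:]:
                d = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
                if d <= a.R_ves + b.R_ves:
                    raise ScenarioError("vessel discs must be disjoint")
        if self.R_t is not None and self.R_t <= max(v.R_ves for v in self.vessels):
            raise ScenarioError("R_t must exceed every vessel radius")

    @property
    def single_vessel(self) -> VesselSpec:
        if len(self.vessels) != 1:
            raise ScenarioError("operation requires a single-vessel scenario")
        return self.vessels[0]


# ---------------------------------------------------------------------------
# Krogh–Erlang closed form
# ---------------------------------------------------------------------------

def krogh_erlang_pressure(r, vessel: VesselSpec, M: float, R_t: float):
    """Radial pO2 profile around a single vessel with uniform consumption.

    P(r) = P_ves + M(r² − R_ves²)/4 − M·R_t²·ln(r/R_ves)/2 for
    R_ves ≤ r ≤ R_t, P(r) = P_ves inside the vessel.  The same expression
    serves physical and dimensionless arguments.
    """
    if M < 0:
        raise ScenarioError("consumption M must be non-negative")
    if vessel.R_ves >= R_t:
        raise ScenarioError("R_ves must be smaller than R_t")
    r = np.asarray(r, dtype=float)
    if np.any(r > R_t * (1 + 1e-9)):
        raise DomainError("radius beyond the tissue-cylinder radius R_t")
    if np.any(r < 0):
        raise DomainError("negative radius")
    safe_r = np.maximum(r, vessel.R_ves)
    out = (vessel.P_ves + 0.25 * M * (safe_r ** 2 - vessel.R_ves ** 2)
           - 0.5 * M * R_t ** 2 * np.log(safe_r / vessel.R_ves))
    return out if out.shape else float(out)


def sample_krogh_erlang_map(scenario: TissueScenario, grid: GridSpec,
                            units: str = "dimensionless") -> PressureMap:
    """Evaluate the Krogh–Erlang profile on a measurement grid."""
    vessel = scenario.single_vessel
    if scenario.consumption.kind != "constant":
        raise ScenarioError("the Krogh–Erlang model assumes constant consumption")
    if scenario.R_t is None:
        raise ScenarioError("the Krogh–Erlang model needs the tissue-cylinder radius R_t")
    r = grid.radii(vessel.center)
    if np.any(r > scenario.R_t * (1 + 1e-9)):
        raise DomainError(
            "grid nodes beyond R_t: shrink the window or use the numerical Poisson solver")
    values = krogh_erlang_pressure(r, vessel, scenario.consumption.values[0], scenario.R_t)
    return PressureMap(grid, values, units, scenario.vessels)


def radial_reference_solution(vessel: VesselSpec, consumption: ConsumptionField,
                              R_t: float, n_points: int = 10_000):
    """Dense 1-D finite-difference solve of the radially symmetric problem.

    Finite-volume solve of (1/r) d/dr (r dP/dr) = M(r) with P(R_ves) = P_ves
    and dP/dr(R_t) = 0: unknowns sit at cell centres, the Dirichlet value at
    the inner face and the zero-flux condition at the outer face, so both
    boundary conditions are imposed at their exact radii (second order).
    Returns ``(r, P)`` arrays (the inner face prepended); serves as the
    independent oracle for the 2-D solvers on symmetric scenarios.
    """
    if not consumption.is_radial:
        raise ScenarioError("radial reference needs a radially symmetric consumption field")
    if R_t <= vessel.R_ves:
        raise ScenarioError("R_t must exceed R_ves")
    n = n_points
    dr = (R_t - vessel.R_ves) / n
    faces = vessel.R_ves + dr * np.arange(n + 1)
    centers = 0.5 * (faces[:-1] + faces[1:])
    M = consumption.at_radius(centers)

    # row i: r_f[i+1]*(P[i+1]-P[i])/dr - r_f[i]*(P[i]-P[i-1])/dr = M_i c_i dr
    lower = np.empty(n)
    diag = np.empty(n)
    upper = np.empty(n)
    rhs = M * centers * dr ** 2
    inner_f = faces[1:-1]
    lower[1:] = inner_f
    upper[:-1] = inner_f
    diag[1:-1] = -(inner_f[:-1] + inner_f[1:])
    # inner cell: Dirichlet face at R_ves, half-distance flux 2*(P_1 - P_ves)/dr
    diag[0] = -(2.0 * faces[0] + faces[1])
    rhs[0] -= 2.0 * faces[0] * vessel.P_ves
    # outer cell: zero flux through the face at exactly R_t
    diag[-1] = -faces[-2]
    upper[-1] = 0.0
    ab = np.zeros((3, n))
    ab[0, 1:] = upper[:-1]
    ab[1, :] = diag
    ab[2, :-1] = lower[1:]
    P = solve_banded((1, 1), ab, rhs)
    return (np.concatenate([[vessel.R_ves], centers]),
            np.concatenate([[vessel.P_ves], P]))


# ---------------------------------------------------------------------------
# numerical Poisson solvers
# ---------------------------------------------------------------------------

class PoissonSolution:
    """Evaluable solution of a forward Poisson solve."""

    def __init__(self, scenario: TissueScenario, residual: float):
        self.scenario = scenario
        self.residual = residual

    def evaluate(self, x, y):  # pragma: no cover - abstract
        raise NotImplementedError


class _CartesianSolution(PoissonSolution):
    def __init__(self, scenario, grid: GridSpec, values: np.ndarray, residual: float):
        super().__init__(scenario, residual)
        self.grid = grid
        self.values = values
        self._spline = None

    def evaluate(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if not np.all(self.scenario.domain.contains(x, y)):
            raise DomainError("evaluation point outside the solved domain")
        # exact read-off when the query points sit on solver nodes
        ix = (x - self.grid.x[0]) / self.grid.spacing
        iy = (y - self.grid.y[0]) / self.grid.spacing
        on_nodes = (np.allclose(ix, np.round(ix), atol=1e-8)
                    and np.allclose(iy, np.round(iy), atol=1e-8))
        if on_nodes:
            return self.values[np.round(ix).astype(int), np.round(iy).astype(int)]
        if self._spline is None:
            self._spline = RectBivariateSpline(self.grid.x, self.grid.y, self.values,
                                               kx=3, ky=3, s=0)
        return self._spline(x, y, grid=False)


class _PolarSolution(PoissonSolution):
    def __init__(self, scenario, r_nodes: np.ndarray, theta_nodes: np.ndarray,
                 values: np.ndarray, residual: float):
        super().__init__(scenario, residual)
        self.r_nodes = r_nodes
        self.theta_nodes = theta_nodes
        self.values = values            # (n_r, n_theta), includes r = R_ves row
        # periodic padding in theta for smooth interpolation across the seam
        pad = 4
        th = np.concatenate([theta_nodes[-pad:] - 2 * np.pi, theta_nodes,
                             theta_nodes[:pad] + 2 * np.pi])
        vals = np.concatenate([values[:, -pad:], values, values[:, :pad]], axis=1)
        self._spline = RectBivariateSpline(r_nodes, th, vals, kx=3, ky=3, s=0)
        self._radial = CubicSpline(r_nodes, values.mean(axis=1))

    def evaluate(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if not np.all(self.scenario.domain.contains(x, y)):
            raise DomainError("evaluation point outside the solved domain")
        r = np.hypot(x, y)
        theta = np.mod(np.arctan2(y, x), 2 * np.pi)
        vessel = self.scenario.single_vessel
        r_cl = np.clip(r, self.r_nodes[0], self.r_nodes[-1])
        out = self._spline(r_cl, theta, grid=False)
        return np.where(r < vessel.R_ves, vessel.P_ves, out)

    def radial_profile(self):
        return self.r_nodes, self.values.mean(axis=1)

    def vessel_wall_flux(self) -> float:
        """Total oxygen flux entering the tissue through the vessel wall.

        Uses the same half-distance wall gradient as the discrete scheme, so
        flux balance against the consumed total holds to quadrature accuracy.
        """
        R_ves = self.r_nodes[0]
        dr = self.r_nodes[2] - self.r_nodes[1]
        dtheta = self.theta_nodes[1] - self.theta_nodes[0]
        grad = 2.0 * (self.values[1] - self.values[0]) / dr
        return -float(np.sum(R_ves * grad) * dtheta)


def _solve_cartesian(scenario: TissueScenario, spacing: float) -> _CartesianSolution:
    L = scenario.domain.size
    grid = GridSpec.centered(L, spacing)
    nx, ny = grid.shape
    X, Y = grid.points()

    # 1-D second-difference operator with mirror-ghost Neumann ends
    def neumann_1d(n):
        main = np.full(n, -2.0)
        off = np.ones(n - 1)
        T = sparse.diags([off, main, off], [-1, 0, 1], format="lil")
        T[0, 1] = 2.0
        T[n - 1, n - 2] = 2.0
        return T.tocsr()

    A = (sparse.kron(neumann_1d(nx), sparse.identity(ny))
         + sparse.kron(sparse.identity(nx), neumann_1d(ny))) / spacing ** 2
    A = A.tolil()

    center0 = scenario.vessels[0].center if scenario.consumption.is_radial else (0.0, 0.0)
    M = scenario.consumption.on_grid(grid, center0)
    rhs = M.ravel().astype(float)

    vessel_mask = np.zeros(grid.shape, dtype=bool)
    for v in scenario.vessels:
        vessel_mask |= np.hypot(X - v.center[0], Y - v.center[1]) < v.R_ves
    if not vessel_mask.any():
        raise ScenarioError("no grid node falls inside a vessel; refine the solver mesh")
    flat = np.flatnonzero(vessel_mask.ravel())
    pves_flat = np.zeros(grid.shape)
    for v in scenario.vessels:
        pves_flat[np.hypot(X - v.center[0], Y - v.center[1]) < v.R_ves] = v.P_ves
    for idx in flat:
        A.rows[idx] = [idx]
        A.data[idx] = [1.0]
    rhs[flat] = pves_flat.ravel()[flat]

    A = A.tocsc()
    sol = spsolve(A, rhs)
    residual = float(np.max(np.abs(A @ sol - rhs)))
    scale = max(1.0, float(np.max(np.abs(rhs))))
    if residual > _RESIDUAL_TOL * scale * 1e3:
        raise NumericalError(f"Poisson solve residual {residual:.3g} above tolerance")
    return _CartesianSolution(scenario, grid, sol.reshape(grid.shape), residual)


def _solve_polar(scenario: TissueScenario, n_r: int, n_theta: int) -> _PolarSolution:
    vessel = scenario.single_vessel
    if np.hypot(*vessel.center) > 1e-9 * scenario.domain.size:
        raise ScenarioError("the disc-domain solver needs the vessel at the disc centre")
    # finite-volume cells: faces at R_ves + i*dr, unknowns at cell centres,
    # so the Dirichlet wall and the zero-flux outer rim sit at exact radii
    R_out = scenario.domain.size
    dr = (R_out - vessel.R_ves) / n_r
    faces = vessel.R_ves + dr * np.arange(n_r + 1)
    centers = 0.5 * (faces[:-1] + faces[1:])
    dtheta = 2 * np.pi / n_theta
    theta = dtheta * np.arange(n_theta)

    if not scenario.consumption.is_radial:
        raise ScenarioError("disc-domain solver supports radial consumption fields only")
    M_r = scenario.consumption.at_radius(centers)

    n = n_r * n_theta

    def index(i, j):
        return i * n_theta + (j % n_theta)

    rows, cols, data = [], [], []
    rhs = np.repeat(M_r * centers * dr ** 2, n_theta)
    for i in range(n_r):
        rm = faces[i]                     # inner face radius
        rp = faces[i + 1]                 # outer face radius
        ang = dr ** 2 / (centers[i] * dtheta ** 2)
        for j in range(n_theta):
            k = index(i, j)
            if i == 0:
                # Dirichlet at the wall, half-distance flux 2*rm*(P - P_ves)/dr
                diag = -(2.0 * rm + rp) - 2.0 * ang
                rhs[k] -= 2.0 * rm * vessel.P_ves
            elif i == n_r - 1:
                diag = -rm - 2.0 * ang    # zero flux through the outer face
            else:
                diag = -(rm + rp) - 2.0 * ang
            rows.append(k); cols.append(k); data.append(diag)
            if i > 0:
                rows.append(k); cols.append(index(i - 1, j)); data.append(rm)
            if i < n_r - 1:
                rows.append(k); cols.append(index(i + 1, j)); data.append(rp)
            rows.append(k); cols.append(index(i, j - 1)); data.append(ang)
            rows.append(k); cols.append(index(i, j + 1)); data.append(ang)
    A = sparse.csc_matrix((data, (rows, cols)), shape=(n, n))
    sol = spsolve(A, rhs)
    residual = float(np.max(np.abs(A @ sol - rhs)))
    r_nodes = np.concatenate([[vessel.R_ves], centers])
    values = np.vstack([np.full(n_theta, vessel.P_ves), sol.reshape(n_r, n_theta)])
    return _PolarSolution(scenario, r_nodes, theta, values, residual)


def solve_poisson(scenario: TissueScenario, resolution: Optional[float] = None,
                  n_r: int = 2000, n_theta: int = 48) -> PoissonSolution:
    """Numerical forward solve of ∇²P = M for a tissue scenario.

    Square domains use the Cartesian 5-point scheme at grid step
    ``resolution`` (default: R_ves/6, capped for tractability); disc domains
    use the conservative polar scheme with ``n_r`` radial and ``n_theta``
    angular nodes.  Returns an object evaluable at interior points.
    """
    if scenario.domain.kind == "square":
        if resolution is None:
            resolution = max(min(v.R_ves for v in scenario.vessels) / 6.0,
                             scenario.domain.size / 400.0)
        return _solve_cartesian(scenario, resolution)
    return _solve_polar(scenario, n_r, n_theta)


def sample_to_grid(solution: PoissonSolution, grid: GridSpec,
                   vessels: Optional[Sequence[VesselSpec]] = None,
                   units: str = "dimensionless") -> PressureMap:
    """Sample a forward solution onto a measurement grid.

    Nodes closer than R_ves to a vessel centre are overwritten with that
    vessel's wall pressure, mirroring how measured maps report the
    intravascular pO2.
    """
    if vessels is None:
        vessels = solution.scenario.vessels
    X, Y = grid.points()
    values = np.asarray(solution.evaluate(X.ravel(), Y.ravel())).reshape(grid.shape)
    for v in vessels:
        inside = np.hypot(X - v.center[0], Y - v.center[1]) < v.R_ves
        values[inside] = v.P_ves
    return PressureMap(grid, values, units, tuple(vessels))


def simulate_pressure_map(scenario: TissueScenario, grid: GridSpec,
                          **solver_kwargs) -> PressureMap:
    """Ground-truth map for a scenario: closed form when available, else FD.

    Single-vessel constant-consumption scenarios with a known R_t use the
    Krogh–Erlang formula directly; everything else goes through
    :func:`solve_poisson` + :func:`sample_to_grid`.
    """
    if (len(scenario.vessels) == 1 and scenario.consumption.kind == "constant"
            and scenario.R_t is not None):
        return sample_krogh_erlang_map(scenario, grid)
    solution = solve_poisson(scenario, **solver_kwargs)
    return sample_to_grid(solution, grid)
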