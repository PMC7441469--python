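"""Forward models: closed-form and numerical ground-truth pO2 maps."""

import numpy as np
import pytest

from cmro2map import (ConsumptionField, Domain, DomainError, GridSpec,
                      ScenarioError, TissueScenario, VesselSpec,
                      discrete_laplacian, krogh_erlang_pressure,
                      radial_reference_solution, sample_krogh_erlang_map,
                      sample_to_grid, solve_poisson)
from cmro2map.presets import single_vessel_scenario, three_vessel_scenario, two_level_scenario

VESSEL = VesselSpec((0.0, 0.0), 6.0, 80.0)


# ---------------------------------------------------------------------------
# Krogh–Erlang closed form
# ---------------------------------------------------------------------------

def test_pressure_at_wall_and_inside_is_pves():
    assert krogh_erlang_pressure(6.0, VESSEL, 0.001, 200.0) == pytest.approx(80.0)
    assert krogh_erlang_pressure(2.0, VESSEL, 0.001, 200.0) == pytest.approx(80.0)


def test_zero_consumption_gives_flat_profile():
    r = np.linspace(0, 200, 50)
    np.testing.assert_allclose(krogh_erlang_pressure(r, VESSEL, 0.0, 200.0), 80.0)


def test_profile_value_at_100_micron():
    # frozen from direct evaluation of the closed form at full precision
    assert krogh_erlang_pressure(100.0, VESSEL, 0.001, 200.0) == pytest.approx(
        26.222785664799275, rel=1e-12)


def test_domain_and_scenario_errors():
    with pytest.raises(DomainError):
        krogh_erlang_pressure(201.0, VESSEL, 0.001, 200.0)
    with pytest.raises(ScenarioError):
        krogh_erlang_pressure(5.0, VESSEL, 0.001, 5.0)


def test_radial_laplacian_of_closed_form_equals_M():
    """(1/r) d/dr (r dP/dr) = M for R_ves < r < R_t, via symbolic
    differentiation of an independently written profile expression."""
    import sympy as sp

    r, M, Rt, Rv, Pv = sp.symbols("r M R_t R_v P_v", positive=True)
    profile = Pv + M * (r ** 2 - Rv ** 2) / 4 - M * Rt ** 2 * sp.log(r / Rv) / 2
    lap = sp.simplify(sp.diff(r * sp.diff(profile, r), r) / r)
    assert sp.simplify(lap - M) == 0
    # and the package's implementation matches the symbolic profile
    fn = sp.lambdify(r, profile.subs({M: 0.001, Rt: 200, Rv: 6, Pv: 80}), "numpy")
    radii = np.linspace(10, 199, 25)
    np.testing.assert_allclose(krogh_erlang_pressure(radii, VESSEL, 0.001, 200.0),
                               fn(radii), rtol=1e-12)


def test_neumann_condition_at_tissue_radius():
    M, Rt = 0.001, 200.0
    h = 1e-3 * Rt
    P = lambda r: krogh_erlang_pressure(r, VESSEL, M, Rt)
    # second-order one-sided difference at the outer rim
    dP = (3 * P(Rt) - 4 * P(Rt - h) + P(Rt - 2 * h)) / (2 * h)
    assert abs(dP) < 1e-6 * M * Rt


def test_sampled_map_all_inside_vessel_is_constant():
    scenario = single_vessel_scenario()
    grid = GridSpec.centered(0.02, 0.01)   # 5x5 window inside R_ves ≈ 0.0426
    pmap = sample_krogh_erlang_map(scenario, grid)
    np.testing.assert_allclose(pmap.values, scenario.vessels[0].P_ves)


def test_sampled_map_rotation_symmetry(krogh_map_fine):
    np.testing.assert_allclose(krogh_map_fine.values,
                               np.rot90(krogh_map_fine.values), rtol=1e-12)


def test_window_beyond_Rt_is_rejected():
    scenario = single_vessel_scenario()
    with pytest.raises(DomainError, match="solver"):
        sample_krogh_erlang_map(scenario, GridSpec.centered(1.5, 0.1))


# ---------------------------------------------------------------------------
# radial reference (1-D oracle)
# ---------------------------------------------------------------------------

def test_radial_reference_matches_closed_form():
    scenario = single_vessel_scenario()
    r, P = radial_reference_solution(scenario.single_vessel,
                                     scenario.consumption, scenario.R_t)
    exact = krogh_erlang_pressure(r, scenario.single_vessel, 1.0, scenario.R_t)
    assert np.max(np.abs(P - exact) / np.abs(exact)) < 1e-4


def test_radial_reference_flat_for_zero_consumption():
    v = VesselSpec((0, 0), 0.04, 4.0)
    r, P = radial_reference_solution(v, ConsumptionField.constant(0.0), 1.0, n_points=500)
    np.testing.assert_allclose(P, 4.0, rtol=1e-10)


def test_two_level_profile_flat_beyond_break():
    """Nearly no pO2 decay outside the capillary-free region (tissue edge
    at r̂ = 1, matching the ±1 measurement window)."""
    sc = two_level_scenario(domain_radius=1.0)
    r, P = radial_reference_solution(sc.single_vessel, sc.consumption, sc.R_t)
    inner = (r > 0.3) & (r < 0.65)
    outer = (r > 0.8) & (r < 0.95)
    drop_inner = P[inner].max() - P[inner].min()
    drop_outer = P[outer].max() - P[outer].min()
    assert drop_outer < 0.1 * drop_inner


# ---------------------------------------------------------------------------
# 2-D Poisson solvers
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def polar_solution():
    return solve_poisson(single_vessel_scenario(), n_r=1200, n_theta=32)


def test_polar_solver_agrees_with_closed_form(polar_solution):
    sc = polar_solution.scenario
    r = np.linspace(sc.single_vessel.R_ves, sc.R_t * 0.999, 300)
    exact = krogh_erlang_pressure(r, sc.single_vessel, 1.0, sc.R_t)
    num = polar_solution.evaluate(r, np.zeros_like(r))
    assert np.max(np.abs(num - exact) / np.abs(exact)) < 5e-3


def test_polar_flux_conservation(polar_solution):
    """Total flux through the vessel wall balances the consumed oxygen."""
    sc = polar_solution.scenario
    influx = polar_solution.vessel_wall_flux()
    consumed = 1.0 * np.pi * (sc.R_t ** 2 - sc.single_vessel.R_ves ** 2)
    assert influx == pytest.approx(consumed, rel=1e-3)


def test_polar_mesh_refinement_converges():
    sc = single_vessel_scenario()
    r_ref, P_ref = radial_reference_solution(sc.single_vessel, sc.consumption, sc.R_t)
    errs = []
    for n_r in (200, 400):
        sol = solve_poisson(sc, n_r=n_r, n_theta=16)
        num = sol.evaluate(r_ref[1:-1], np.zeros_like(r_ref[1:-1]))
        errs.append(np.max(np.abs(num - P_ref[1:-1])))
    assert errs[1] < errs[0]


def test_cartesian_laplace_with_single_vessel_is_constant():
    sc = TissueScenario((VesselSpec((0, 0), 0.05, 3.0),),
                        ConsumptionField.constant(0.0), Domain("square", 0.5))
    sol = solve_poisson(sc, resolution=0.02)
    np.testing.assert_allclose(sol.values, 3.0, atol=1e-9)


def test_cartesian_pressure_max_at_vessel_wall():
    sc = TissueScenario((VesselSpec((0, 0), 0.05, 4.0),),
                        ConsumptionField.constant(1.0), Domain("square", 0.5))
    sol = solve_poisson(sc, resolution=0.01)
    assert sol.values.max() == pytest.approx(4.0)


def test_cartesian_discrete_flux_balance():
    """Divergence theorem at the discrete level: the consumed total (free
    cells, with half/quarter volumes on the mirrored edges and corners)
    equals the interface flux drawn from the vessel nodes."""
    sc = TissueScenario((VesselSpec((0, 0), 0.06, 4.0),),
                        ConsumptionField.constant(1.0), Domain("square", 0.5))
    h = 0.01
    sol = solve_poisson(sc, resolution=h)
    grid, P = sol.grid, sol.values
    X, Y = grid.points()
    inside = np.hypot(X, Y) < 0.06
    flux = 0.0
    for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        shifted = np.roll(inside, (dx, dy), axis=(0, 1))
        pairs = (~inside) & shifted
        flux += np.sum(4.0 - P[pairs])       # P_v - P_f summed over interfaces
    weights = np.ones(grid.shape)
    weights[0, :] *= 0.5
    weights[-1, :] *= 0.5
    weights[:, 0] *= 0.5
    weights[:, -1] *= 0.5
    consumed = np.sum(weights[~inside]) * h ** 2
    assert flux == pytest.approx(consumed, rel=1e-8)


def test_three_vessel_map_structure_and_recovery():
    """Multi-vessel field: wall pressures imposed, local maxima at the
    oxygen-delivering vessels, circular symmetry broken, and the Laplacian
    still reads off M̂ = 1 away from the vessels.  (The 50 mmHg arteriole
    sits near the ambient tissue pO2 and delivers almost no oxygen, so it
    is not required to be a strict maximum.)"""
    sc = three_vessel_scenario()
    sol = solve_poisson(sc, resolution=0.008)
    grid = GridSpec.centered(0.95, 0.05)
    pmap = sample_to_grid(sol, grid)
    X, Y = grid.points()
    for v in sc.vessels:
        d = np.hypot(X - v.center[0], Y - v.center[1])
        assert pmap.values[d < v.R_ves].max() == pytest.approx(v.P_ves)
    for v in sc.vessels[:2]:             # the two clearly supplying vessels
        d = np.hypot(X - v.center[0], Y - v.center[1])
        assert pmap.values[d < 0.08].max() > pmap.values[(d > 0.15) & (d < 0.25)].max()
    # symmetry around the strongest vessel is broken by the neighbours
    v0 = sc.vessels[0]
    d0 = np.hypot(X - v0.center[0], Y - v0.center[1])
    ring = pmap.values[(d0 > 0.55) & (d0 < 0.65)]
    assert ring.max() - ring.min() > 0.1
    # the estimator does not rely on symmetry: Laplacian recovers M̂ = 1
    lap = discrete_laplacian(pmap)
    far = lap.validity.copy()
    for v in sc.vessels:
        far &= np.hypot(X - v.center[0], Y - v.center[1]) > 0.2
    assert np.median(lap.values[far]) == pytest.approx(1.0, rel=0.05)


def test_sample_to_grid_cross_checks_closed_form(polar_solution, krogh_map_coarse):
    resampled = sample_to_grid(polar_solution, krogh_map_coarse.grid)
    err = np.abs(resampled.values - krogh_map_coarse.values)
    assert err.max() < 5e-3 * np.abs(krogh_map_coarse.values).max()


def test_sample_to_grid_overwrites_vessel_interior(polar_solution):
    grid = GridSpec.centered(0.03, 0.01)    # entirely inside the vessel
    pmap = sample_to_grid(polar_solution, grid)
    np.testing.assert_allclose(pmap.values, polar_solution.scenario.single_vessel.P_ves)


def test_scenario_validation():
    with pytest.raises(ScenarioError):
        TissueScenario((), ConsumptionField.constant(1.0), Domain("square", 1.0))
    with pytest.raises(ScenarioError):   # overlapping vessels
        TissueScenario((VesselSpec((0, 0), 0.1, 1.0), VesselSpec((0.05, 0), 0.1, 1.0)),
                       ConsumptionField.constant(1.0), Domain("square", 1.0))
    with pytest.raises(ScenarioError):   # vessel outside domain
        TissueScenario((VesselSpec((2.0, 0), 0.1, 1.0),),
                       ConsumptionField.constant(1.0), Domain("square", 1.0))
    with pytest.raises(ScenarioError):   # R_t below vessel radius
        TissueScenario((VesselSpec((0, 0), 0.1, 1.0),),
                       ConsumptionField.constant(1.0), Domain("disc", 1.0), R_t=0.05)
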