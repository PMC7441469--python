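"""Monte-Carlo performance harness: bias, SD, RMSE of the estimator.

Against a known ground truth M̂, a run generates the clean map once, draws
``n_replicates`` independent noisy copies, pushes each through the
diffusion-operator estimator and accumulates, per node (or per disc-cut
average),

    bias = mean_j(M̂_est,j) - M̂
    SD   = population standard deviation of M̂_est,j   (divisor N)
    RMSE = sqrt(mean_j (M̂_est,j - M̂)²) = sqrt(bias² + SD²)

All three are reported as percent of the local true value.  Noise is the
only stochastic element, and every replicate has its own child seed, so a
run is fully reproducible from (seed, N).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import ConfigurationError, GridSpec, PressureMap
from .estimator import average_M, estimate_M
from .forward_models import TissueScenario, simulate_pressure_map
from .noise import NoiseModel, add_noise
from .smoothing import SmoothingConfig


# ---------------------------------------------------------------------------
# the three measures (replicates stacked along axis 0)
# ---------------------------------------------------------------------------

def _stack(estimates) -> np.ndarray:
    arr = np.asarray(estimates, dtype=float)
    if arr.ndim == 0 or arr.shape[0] < 1:
        raise ConfigurationError("at least one replicate is required")
    return arr

def bias_of(estimates, truth) -> np.ndarray:
    """Mean error per node; a single noise-free replicate suffices."""
    arr = _stack(estimates)
    truth = np.asarray(truth, dtype=float)
    if truth.shape != arr.shape[1:]:
        raise ConfigurationError("truth shape does not match the estimates")
    return arr.mean(axis=0) - truth


def sd_of(estimates) -> np.ndarray:
    """Population SD (divisor N) of the replicate estimates per node."""
    arr = _stack(estimates)
    if arr.shape[0] < 2:
        raise ConfigurationError("SD needs at least two replicates")
    return arr.std(axis=0, ddof=0)


def rmse_of(estimates, truth) -> np.ndarray:
    """Root-mean-square error per node; equals sqrt(bias² + SD²)."""
    arr = _stack(estimates)
    truth = np.asarray(truth, dtype=float)
    if truth.shape != arr.shape[1:]:
        raise ConfigurationError("truth shape does not match the estimates")
    return np.sqrt(np.mean((arr - truth) ** 2, axis=0))


# ---------------------------------------------------------------------------
# Monte-Carlo driver
# ---------------------------------------------------------------------------

@dataclass
class PerformanceMaps:
    """Per-node performance fields, in percent of the local true M̂."""

    grid: GridSpec
    bias: np.ndarray
    sd: np.ndarray
    rmse: np.ndarray
    validity: np.ndarray
    truth: np.ndarray
    n_replicates: int
    config: SmoothingConfig
    scenario: Optional[TissueScenario] = None

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be at least 1")


def true_consumption_on(grid: GridSpec, scenario: TissueScenario) -> np.ndarray:
    """Ground-truth M̂ evaluated at the nodes of a grid."""
    center = scenario.vessels[0].center if scenario.consumption.is_radial else (0.0, 0.0)
    return scenario.consumption.on_grid(grid, center)


def run_monte_carlo(scenario: TissueScenario, grid: GridSpec, noise: NoiseModel,
                    config: SmoothingConfig, n_replicates: int,
                    mode: str = "resolved",
                    d_cut_values: Optional[Sequence[float]] = None,
                    clean_map: Optional[PressureMap] = None,
                    **solver_kwargs):
    """Seeded Monte-Carlo evaluation of the estimator on a scenario.

    mode="resolved" returns :class:`PerformanceMaps` on the d_est grid;
    mode="averaged" returns a table with one row per d_cut diameter
    (columns d_q, d_cut, bias_pct, sd_pct, rmse_pct, n_points).
    The clean map may be passed in to share a forward solve across runs.
    """
    if mode not in ("resolved", "averaged"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    if n_replicates < 2 and noise.sigma_P > 0:
        raise ConfigurationError("SD estimation needs at least two replicates")
    if mode == "averaged" and not d_cut_values:
        raise ConfigurationError("averaged mode needs a list of d_cut diameters")

    if clean_map is None:
        clean_map = simulate_pressure_map(scenario, grid, **solver_kwargs)

    n_rep = max(int(n_replicates), 1)
    if mode == "resolved":
        first = estimate_M(add_noise(clean_map, noise, 0), config)
        truth = true_consumption_on(first.grid, scenario)
        s1 = np.zeros(first.grid.shape)
        s2 = np.zeros(first.grid.shape)
        validity = first.validity
        for j in range(n_rep):
            est = first if j == 0 else estimate_M(add_noise(clean_map, noise, j), config)
            s1 += est.values
            s2 += est.values ** 2
        mean = s1 / n_rep
        var = np.maximum(s2 / n_rep - mean ** 2, 0.0)
        bias = mean - truth
        sd = np.sqrt(var)
        rmse = np.hypot(bias, sd)
        denom = np.where(truth == 0, np.nan, np.abs(truth))
        pct = 100.0 / denom
        return PerformanceMaps(first.grid, bias * pct, sd * pct, rmse * pct,
                               validity, truth, n_rep, config, scenario)

    d_cuts = [float(d) for d in d_cut_values]
    values = np.empty((n_rep, len(d_cuts)))
    counts = None
    for j in range(n_rep):
        est = estimate_M(add_noise(clean_map, noise, j), config)
        averages = [average_M(est, scenario.vessels, d) for d in d_cuts]
        values[j] = [a.value for a in averages]
        if counts is None:
            counts = [a.n_points for a in averages]
    if scenario.consumption.kind != "constant":
        raise ConfigurationError("averaged mode assumes a scenario-level true M̂")
    truth = scenario.consumption.values[0]
    bias = values.mean(axis=0) - truth
    sd = values.std(axis=0, ddof=0)
    rmse = np.hypot(bias, sd)
    pct = 100.0 / abs(truth)
    d_q = config.resolve_dq(grid.spacing)
    return pd.DataFrame({
        "d_q": d_q, "d_cut": d_cuts,
        "bias_pct": bias * pct, "sd_pct": sd * pct, "rmse_pct": rmse * pct,
        "n_points": counts,
    })
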