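"""Additive Gaussian measurement noise with reproducible streams.

Every node of a map — vessel-interior nodes included — is independently
replaced by a draw from a normal distribution centred on the clean value
with standard deviation ``sigma_P`` (same units as the map).  Replicate
``j`` of a Monte-Carlo run draws from the child stream ``(seed, j)``, so
runs are reproducible and replicates are independent and order-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import ConfigurationError, PressureMap, UnitMismatchError


@dataclass(frozen=True)
class NoiseModel:
    sigma_P: float
    seed: int = 0
    units: str = "dimensionless"

    def __post_init__(self):
        if self.sigma_P < 0:
            raise ConfigurationError("sigma_P must be non-negative")

    def rng(self, replicate: Optional[int] = None) -> np.random.Generator:
        if replicate is None:
            return np.random.default_rng(np.random.SeedSequence([int(self.seed)]))
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), int(replicate)]))


def add_noise(pmap: PressureMap, noise: NoiseModel,
              replicate: Optional[int] = None) -> PressureMap:
    """Noisy copy of a map; identical seeds give bit-identical output."""
    if noise.units != pmap.units:
        raise UnitMismatchError(
            f"noise SD is in {noise.units!r} but the map is in {pmap.units!r}")
    if noise.sigma_P == 0:
        return pmap.with_values(pmap.values.copy())
    draws = noise.rng(replicate).standard_normal(pmap.values.shape)
    return pmap.with_values(pmap.values + noise.sigma_P * draws)
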