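"""Delimited-text I/O for pressure/estimate maps and run configs.

Map files are plain whitespace-delimited matrices preceded by ``#`` header
lines::

    # cmro2map
    # units: dimensionless
    # spacing: 0.007
    # origin: -0.994 -0.994
    # shape: 285 285

Rows follow the x index, columns the y index (``values[i, j]`` at
``(x[i], y[j])``).  Full decimal precision is preserved, so write/read
round-trips are value-identical.  Headerless legacy matrices are accepted
when the grid spacing is supplied explicitly.
"""

from __future__ import annotations

import os
from typing import Optional, Tuple

import numpy as np
import yaml

from .core import (DIMENSIONLESS, ConfigurationError, GridSpec, MapFormatError,
                   PressureMap)


def write_map(pmap: PressureMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("# cmro2map\n")
        fh.write(f"# units: {pmap.units}\n")
        fh.write(f"# spacing: {float(pmap.grid.spacing)!r}\n")
        fh.write(f"# origin: {float(pmap.grid.x[0])!r} {float(pmap.grid.y[0])!r}\n")
        fh.write(f"# shape: {pmap.grid.n_x} {pmap.grid.n_y}\n")
        np.savetxt(fh, pmap.values, fmt="%.17g")


def _parse_header(path) -> Tuple[dict, int]:
    header = {}
    n_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_lines += 1
            body = line[1:].strip()
            if ":" in body:
                key, _, val = body.partition(":")
                header[key.strip()] = val.strip()
    return header, n_lines


def read_map(path, spacing: Optional[float] = None,
             units: Optional[str] = None) -> PressureMap:
    """Read a map file; header values may be overridden by the arguments."""
    header, n_header = _parse_header(path)
    try:
        values = np.loadtxt(path, comments="#", ndmin=2)
    except ValueError as exc:
        raise MapFormatError(f"{path}: malformed matrix body ({exc})") from exc
    if values.size == 0:
        raise MapFormatError(f"{path}: empty matrix body")

    if spacing is None:
        if "spacing" not in header:
            raise MapFormatError(
                f"{path}: no spacing in the header; pass spacing= explicitly")
        try:
            spacing = float(header["spacing"])
        except ValueError as exc:
            raise MapFormatError(f"{path}: bad spacing value {header['spacing']!r}") from exc
    if "shape" in header:
        try:
            declared = tuple(int(t) for t in header["shape"].split())
        except ValueError as exc:
            raise MapFormatError(f"{path}: bad shape header {header['shape']!r}") from exc
        if declared != values.shape:
            raise MapFormatError(
                f"{path}: header shape {declared} does not match body {values.shape} "
                f"(body starts at line {n_header + 1})")
    origin = (0.0, 0.0)
    if "origin" in header:
        parts = header["origin"].split()
        if len(parts) != 2:
            raise MapFormatError(f"{path}: bad origin header {header['origin']!r}")
        origin = (float(parts[0]), float(parts[1]))
    grid = GridSpec.from_origin(origin, spacing, values.shape[0], values.shape[1])
    return PressureMap(grid, values, units or header.get("units", DIMENSIONLESS))


def write_matrix(values: np.ndarray, path, spacing: float, comment: str = "") -> None:
    """Headered matrix for derived fields (estimates, masks, performance)."""
    with open(path, "w") as fh:
        fh.write("# cmro2map\n")
        if comment:
            fh.write(f"# {comment}\n")
        fh.write(f"# spacing: {float(spacing)!r}\n")
        fh.write(f"# shape: {values.shape[0]} {values.shape[1]}\n")
        np.savetxt(fh, np.asarray(values, dtype=float), fmt="%.17g")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path}: config must be a key-value mapping")
    return cfg


def dump_config(cfg: dict, path) -> None:
    """Resolved-config snapshot written next to every run's outputs."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
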