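"""Grid free-energy (GFE) FragMaps: data model, Boltzmann transform, and OpenDX I/O.

A FragMap is a 3D scalar field of functional-group binding free energies
(kcal/mol) on an axis-aligned Cartesian grid. Maps are derived from
normalized occupancy probabilities of small solute probes via the Boltzmann
transformation; voxels never visited by a probe carry a finite unfavorable
cap rather than +inf so that ligand scores stay finite.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

#: Boltzmann constant in kcal/mol/K.
KB_KCAL = 0.0019872

#: Default GFE assigned to unvisited voxels and out-of-bounds lookups,
#: kcal/mol (~5 kT at 300 K).
DEFAULT_GFE_CAP = 3.0

#: Default FragMap type labels: apolar, H-bond donor, H-bond acceptor,
#: positively charged nitrogen, negatively charged (acetate-like) oxygen.
DEFAULT_MAP_TYPES = ("GENN", "GEND", "GENA", "MAMN", "ACEO")


class GridParseError(ValueError):
    """Raised when an OpenDX file cannot be parsed; names the offending line."""


@dataclass
class FragMapGrid:
    """A single GFE FragMap on an axis-aligned orthogonal grid.

    Parameters
    ----------
    map_type
        FragMap type label (e.g. ``"GENN"``).
    origin
        Cartesian coordinates of voxel (0,0,0) center, Å.
    spacing
        Grid spacing per axis, Å; strictly positive.
    values
        ``(nx, ny, nz)`` array of grid free energies, kcal/mol. Values are
        clipped to ``gfe_cap`` on construction.
    gfe_cap
        Finite unfavorable energy for unvisited voxels and points outside
        the grid, kcal/mol.
    """

    map_type: str
    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray
    gfe_cap: float = DEFAULT_GFE_CAP

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3-D, got shape {self.values.shape}")
        if not np.all(self.spacing > 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.origin)):
            raise ValueError("origin must be finite")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must be finite")
        np.minimum(self.values, self.gfe_cap, out=self.values)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def voxel_center(self, idx) -> np.ndarray:
        """Cartesian center of voxel ``idx = (i, j, k)``, Å."""
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def congruent_with(self, other: "FragMapGrid", atol: float = 1e-9) -> bool:
        """True if the two grids share origin, spacing and dims."""
        return (
            self.dims == other.dims
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.spacing, other.spacing, atol=atol)
        )


def boltzmann_transform(
    prob: np.ndarray,
    temperature: float = 300.0,
    gfe_cap: float = DEFAULT_GFE_CAP,
) -> np.ndarray:
    """Convert normalized occupancy probabilities to grid free energies.

    GFE = -kB*T*ln(p) where p > 0; voxels with p = 0, or whose GFE would
    exceed ``gfe_cap``, are set to ``gfe_cap``.

    Parameters
    ----------
    prob
        Non-negative array of normalized probabilities (p = 1 means bulk
        occupancy, p > 1 enhanced binding).
    temperature
        Simulation temperature, K.
    gfe_cap
        Cap applied to unfavorable / unvisited voxels, kcal/mol.
    """
    prob = np.asarray(prob, dtype=float)
    if not np.all(np.isfinite(prob)):
        raise ValueError("probabilities must be finite")
    if np.any(prob < 0):
        raise ValueError("probabilities must be non-negative")
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    with np.errstate(divide="ignore"):
        gfe = np.where(prob > 0, -KB_KCAL * temperature * np.log(np.maximum(prob, 1e-300)), gfe_cap)
    return np.minimum(gfe, gfe_cap)


def gfe_at(grid: FragMapGrid, xyz) -> float:
    """GFE at a Cartesian point, nearest-voxel convention.

    Index = floor((x - origin)/spacing + 0.5) per axis (half-way points
    round up). Points outside the grid return ``grid.gfe_cap``.
    """
    xyz = np.asarray(xyz, dtype=float).reshape(3)
    if not np.all(np.isfinite(xyz)):
        raise ValueError("coordinates must be finite")
    idx = np.floor((xyz - grid.origin) / grid.spacing + 0.5).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.array(grid.dims)):
        return grid.gfe_cap
    return float(grid.values[idx[0], idx[1], idx[2]])


def gfe_at_many(grid: FragMapGrid, xyz: np.ndarray) -> np.ndarray:
    """Vectorized :func:`gfe_at` over an ``(n, 3)`` coordinate array."""
    xyz = np.asarray(xyz, dtype=float).reshape(-1, 3)
    if not np.all(np.isfinite(xyz)):
        raise ValueError("coordinates must be finite")
    idx = np.floor((xyz - grid.origin) / grid.spacing + 0.5).astype(int)
    dims = np.array(grid.dims)
    inside = np.all((idx >= 0) & (idx < dims), axis=1)
    out = np.full(len(xyz), grid.gfe_cap)
    if inside.any():
        ii = idx[inside]
        out[inside] = grid.values[ii[:, 0], ii[:, 1], ii[:, 2]]
    return out


class FragMapSet(Mapping):
    """A geometrically congruent collection of FragMaps, keyed by map type."""

    def __init__(self, grids: Mapping[str, FragMapGrid]):
        if not grids:
            raise ValueError("FragMapSet must contain at least one grid")
        grids = dict(grids)
        ref = next(iter(grids.values()))
        for name, g in grids.items():
            if not g.congruent_with(ref):
                raise ValueError(
                    f"grid {name!r} is not geometrically congruent with the set "
                    f"(dims {g.dims} vs {ref.dims})"
                )
        self._grids = grids

    def __getitem__(self, key: str) -> FragMapGrid:
        return self._grids[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._grids)

    def __len__(self) -> int:
        return len(self._grids)

    @property
    def map_types(self) -> list[str]:
        return list(self._grids)

    @property
    def reference(self) -> FragMapGrid:
        return next(iter(self._grids.values()))


# ---------------------------------------------------------------------------
# OpenDX scalar-field I/O.
#
# Dialect: "object 1 class gridpositions counts nx ny nz" header, one
# origin line, three delta lines (axis-aligned), "object 2 class
# gridconnections", "object 3 class array ... items N data follows",
# whitespace-separated values in row-major z-fastest order.
# ---------------------------------------------------------------------------

_FLOAT = r"[-+]?\d*\.?\d+(?:[eEdD][-+]?\d+)?"


def write_gfe_map(grid: FragMapGrid, path) -> None:
    """Write a FragMap as an OpenDX scalar field (z-fastest ordering)."""
    nx, ny, nz = grid.dims
    lines = [
        f"# OpenDX GFE map, type {grid.map_type}, kcal/mol",
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        "origin {:.6f} {:.6f} {:.6f}".format(*grid.origin),
        f"delta {grid.spacing[0]:.6f} 0.000000 0.000000",
        f"delta 0.000000 {grid.spacing[1]:.6f} 0.000000",
        f"delta 0.000000 0.000000 {grid.spacing[2]:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {nx * ny * nz} data follows",
    ]
    flat = grid.values.reshape(-1)  # C order == z fastest
    for start in range(0, len(flat), 3):
        lines.append(" ".join(repr(float(v)) for v in flat[start : start + 3]))
    lines.append(f'attribute "dep" string "positions"')
    lines.append("")
    Path(path).write_text("\n".join(lines))


def read_gfe_map(path, map_type: str | None = None, gfe_cap: float = DEFAULT_GFE_CAP) -> FragMapGrid:
    """Read an OpenDX scalar field into a :class:`FragMapGrid`.

    ``map_type`` defaults to the filename convention ``<prefix>.<maptype>.dx``.
    """
    path = Path(path)
    if map_type is None:
        parts = path.name.split(".")
        map_type = parts[-2] if len(parts) >= 3 else path.stem
    counts: tuple[int, int, int] | None = None
    origin: np.ndarray | None = None
    deltas: list[np.ndarray] = []
    n_items: int | None = None
    values: list[float] = []
    in_data = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if in_data:
                if line.startswith(("attribute", "object", "component")):
                    in_data = False
                    continue
                try:
                    values.extend(float(tok) for tok in line.split())
                except ValueError:
                    raise GridParseError(f"{path}:{lineno}: non-numeric data line: {line!r}")
                continue
            if line.startswith("object 1"):
                m = re.search(r"counts\s+(\d+)\s+(\d+)\s+(\d+)", line)
                if m is None:
                    raise GridParseError(f"{path}:{lineno}: malformed gridpositions header: {line!r}")
                counts = (int(m.group(1)), int(m.group(2)), int(m.group(3)))
            elif line.startswith("origin"):
                nums = re.findall(_FLOAT, line)
                if len(nums) != 3:
                    raise GridParseError(f"{path}:{lineno}: malformed origin line: {line!r}")
                origin = np.array([float(v) for v in nums])
            elif line.startswith("delta"):
                nums = re.findall(_FLOAT, line)
                if len(nums) != 3:
                    raise GridParseError(f"{path}:{lineno}: malformed delta line: {line!r}")
                deltas.append(np.array([float(v) for v in nums]))
            elif line.startswith("object 3"):
                m = re.search(r"items\s+(\d+)", line)
                if m is None:
                    raise GridParseError(f"{path}:{lineno}: malformed array header: {line!r}")
                n_items = int(m.group(1))
                in_data = True
    if counts is None:
        raise GridParseError(f"{path}: missing 'object 1 class gridpositions' header")
    if origin is None:
        raise GridParseError(f"{path}: missing origin line")
    if len(deltas) != 3:
        raise GridParseError(f"{path}: expected 3 delta lines, found {len(deltas)}")
    delta = np.vstack(deltas)
    if not np.allclose(delta, np.diag(np.diag(delta))):
        raise GridParseError(f"{path}: non-axis-aligned delta vectors are not supported")
    spacing = np.diag(delta)
    n_expected = counts[0] * counts[1] * counts[2]
    if n_items is not None and n_items != n_expected:
        raise GridParseError(
            f"{path}: array header declares {n_items} items but grid counts give {n_expected}"
        )
    if len(values) != n_expected:
        raise GridParseError(
            f"{path}: {len(values)} data values for {n_expected} voxels declared in header"
        )
    arr = np.array(values).reshape(counts)
    if np.any(arr > gfe_cap + 1e-12):
        warnings.warn(f"{path}: values above gfe_cap={gfe_cap} were clipped")
    return FragMapGrid(map_type=map_type, origin=origin, spacing=spacing, values=arr, gfe_cap=gfe_cap)


def read_fragmap_set(directory, pattern: str = "*.dx", gfe_cap: float = DEFAULT_GFE_CAP) -> FragMapSet:
    """Read every ``<prefix>.<maptype>.dx`` file in a directory into a set."""
    directory = Path(directory)
    grids = {}
    for path in sorted(directory.glob(pattern)):
        g = read_gfe_map(path, gfe_cap=gfe_cap)
        grids[g.map_type] = g
    if not grids:
        raise FileNotFoundError(f"no {pattern} maps found in {directory}")
    return FragMapSet(grids)


def write_fragmap_set(maps: FragMapSet, directory, prefix: str = "maps") -> list[Path]:
    """Write each member grid as ``<prefix>.<maptype>.dx``; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, grid in maps.items():
        p = directory / f"{prefix}.{name}.dx"
        write_gfe_map(grid, p)
        paths.append(p)
    return paths
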