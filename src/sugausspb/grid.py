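"""Uniform cubic lattice around a solute, with world<->index transforms.

Fields live on grid nodes; the 7-point flux stencil additionally needs the
dielectric at the six cell midpoints around each node, which callers
evaluate analytically at the midpoint coordinates (see dielectric module).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .structio import Solute

__all__ = ["Grid", "ScalarField", "VectorField", "build_grid", "write_dx"]


@dataclass(frozen=True)
class Grid:
    """Node-centered uniform lattice.

    origin : world coordinate (A) of node (0, 0, 0)
    h : spacing, A (= 1/scale)
    dims : node counts (Nx, Ny, Nz)
    """

    origin: tuple[float, float, float]
    h: float
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if not self.h > 0:
            raise ValueError("grid spacing must be positive")
        if min(self.dims) < 5:
            raise ValueError(f"grid needs at least 5 nodes per axis, got {self.dims}")

    @property
    def n_nodes(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    @property
    def upper(self) -> np.ndarray:
        """World coordinate of the last node on each axis."""
        return np.asarray(self.origin) + self.h * (np.asarray(self.dims) - 1)

    def world_to_index(self, point) -> np.ndarray:
        """Fractional node index of a world point: (point - origin)/h."""
        return (np.asarray(point, dtype=float) - np.asarray(self.origin)) / self.h

    def index_to_world(self, idx) -> np.ndarray:
        return np.asarray(self.origin) + self.h * np.asarray(idx, dtype=float)

    def node_coords(self) -> np.ndarray:
        """(Nx, Ny, Nz, 3) array of node world coordinates."""
        ox, oy, oz = self.origin
        nx, ny, nz = self.dims
        xs = ox + self.h * np.arange(nx)
        ys = oy + self.h * np.arange(ny)
        zs = oz + self.h * np.arange(nz)
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        return np.stack([X, Y, Z], axis=-1)

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        ox, oy, oz = self.origin
        nx, ny, nz = self.dims
        return (
            ox + self.h * np.arange(nx),
            oy + self.h * np.arange(ny),
            oz + self.h * np.arange(nz),
        )


@dataclass
class ScalarField:
    """One real value per grid node, shape = grid.dims."""

    grid: Grid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.dims:
            raise ValueError(f"field shape {self.values.shape} != grid dims {self.grid.dims}")


@dataclass
class VectorField:
    """One real 3-vector per grid node, shape = grid.dims + (3,)."""

    grid: Grid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.dims + (3,):
            raise ValueError(f"field shape {self.values.shape} != grid dims {self.grid.dims}+(3,)")


def build_grid(solute: Solute, scale: float, padding_A: float) -> Grid:
    """Cuboidal box: the bounding box of atom centers expanded by
    ``padding_A`` on each side, snapped outward to whole cells of
    h = 1/scale.  Every atom center ends up at least ``padding_A`` from
    every box face."""
    if not scale > 0:
        raise ValueError("scale must be > 0")
    if padding_A < 0:
        raise ValueError("padding must be >= 0")
    h = 1.0 / scale
    pos = solute.positions
    lo = pos.min(axis=0) - padding_A
    hi = pos.max(axis=0) + padding_A
    n_cells = np.ceil((hi - lo) / h - 1e-12).astype(int)
    n_cells = np.maximum(n_cells, 4)
    dims = tuple(int(n) + 1 for n in n_cells)
    return Grid(origin=tuple(float(x) for x in lo), h=h, dims=dims)


def write_dx(field: ScalarField, path: str | Path, comment: str = "") -> None:
    """Export a scalar field as an OpenDX regular-grid map (text format
    readable by PyMOL/VMD/Chimera)."""
    g = field.grid
    nx, ny, nz = g.dims
    vals = field.values.reshape(-1)  # x fastest-varying last in DX: use C order (z fastest)
    with Path(path).open("w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.6f} {:.6f} {:.6f}\n".format(*g.origin))
        fh.write(f"delta {g.h:.6f} 0.0 0.0\n")
        fh.write(f"delta 0.0 {g.h:.6f} 0.0\n")
        fh.write(f"delta 0.0 0.0 {g.h:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items {vals.size} data follows\n")
        for i in range(0, vals.size, 3):
            fh.write(" ".join(f"{v:.6e}" for v in vals[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "regular positions regular connections" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')
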