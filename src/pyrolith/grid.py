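"""Occupation-surface grids and the plain-text area-file format.

The occupation surface of a site is discretised into square cells of
50 cm side.  Each cell is interior (usable floor), wall, or exterior.
Grids are defined either programmatically (rectangles) or by "area
files": one character per cell, one grid row per line, using ``I`` for
interior, ``W`` for wall and ``O`` for exterior, LF line endings and no
header.  Two fixed cave-like layouts with 80 and 160 interior cells ship
with the package as the case-study layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from importlib import resources

import numpy as np

#: Side length of one grid cell, in centimetres.  Documentation constant:
#: the simulator itself is unit-free, but hearth and scatter footprints
#: are calibrated to 50-cm cells.
CELL_SIDE_CM = 50.0

_SYMBOLS = {"I", "W", "O"}


class CellState(str, Enum):
    """State of one grid cell: interior floor, cave wall, or exterior."""

    INTERIOR = "I"
    WALL = "W"
    EXTERIOR = "O"


class CaveLayer(str, Enum):
    """The two fixed case-study cave layouts (80 and 160 interior cells)."""

    LAYER1 = "LAYER1"
    LAYER2 = "LAYER2"


class AreaFileError(ValueError):
    """Raised for malformed area-file text."""


@dataclass(frozen=True)
class SiteGrid:
    """Rectangular lattice of cells tagged interior / wall / exterior.

    Parameters
    ----------
    cells
        2-D array of single characters ``'I'``, ``'W'``, ``'O'``.
        Must contain at least one interior cell.
    """

    cells: np.ndarray
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells, dtype="U1")
        if cells.ndim != 2:
            raise AreaFileError("grid must be a 2-D array of cells")
        bad = set(np.unique(cells)) - _SYMBOLS
        if bad:
            raise AreaFileError(f"unknown cell symbols: {sorted(bad)}")
        if not (cells == "I").any():
            raise AreaFileError("grid has no interior cells")
        object.__setattr__(self, "cells", cells)

    @property
    def n_rows(self) -> int:
        return self.cells.shape[0]

    @property
    def n_cols(self) -> int:
        return self.cells.shape[1]

    @property
    def n_interior(self) -> int:
        """Number of interior (usable floor) cells."""
        return int((self.cells == "I").sum())

    def is_interior(self, row: int, col: int) -> bool:
        """True if (row, col) is inside the grid and an interior cell."""
        if 0 <= row < self.n_rows and 0 <= col < self.n_cols:
            return self.cells[row, col] == "I"
        return False

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SiteGrid):
            return NotImplemented
        return self.cells.shape == other.cells.shape and bool(
            (self.cells == other.cells).all()
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.cells.shape, self.cells.tobytes()))


def parse_area_file(text: str) -> SiteGrid:
    """Parse area-file text into a :class:`SiteGrid`.

    Trailing blank lines are ignored.  Rows must all have the same
    length and contain only the symbols ``I``, ``W``, ``O``.

    Raises
    ------
    AreaFileError
        Naming the offending line for ragged rows, or the symbol and its
        1-based (row, col) position for unknown symbols; also raised if
        the grid contains no interior cell.
    """
    lines = text.split("\n")
    while lines and lines[-1].strip() == "":
        lines.pop()
    if not lines:
        raise AreaFileError("empty area file")
    width = len(lines[0])
    rows = []
    for r, line in enumerate(lines):
        if len(line) != width:
            raise AreaFileError(
                f"ragged row: line {r + 1} has length {len(line)}, expected {width}"
            )
        for c, ch in enumerate(line):
            if ch not in _SYMBOLS:
                raise AreaFileError(
                    f"unknown symbol {ch!r} at row {r + 1}, col {c + 1}"
                )
        rows.append(list(line))
    return SiteGrid(np.array(rows, dtype="U1"))


def write_area_file(grid: SiteGrid) -> str:
    """Serialise a grid to area-file text (inverse of :func:`parse_area_file`)."""
    return "\n".join("".join(row) for row in grid.cells) + "\n"


def make_rectangle(n_rows: int, n_cols: int) -> SiteGrid:
    """All-interior rectangular occupation surface of ``n_rows`` x ``n_cols`` cells."""
    if n_rows < 1 or n_cols < 1:
        raise ValueError(f"grid dimensions must be positive, got {n_rows}x{n_cols}")
    return SiteGrid(
        np.full((n_rows, n_cols), "I", dtype="U1"), name=f"{n_rows}x{n_cols}"
    )


def make_case_study_cave(layer: CaveLayer | str) -> SiteGrid:
    """Load one of the two fixed case-study cave layouts.

    ``LAYER1`` has exactly 80 interior cells (20 m2 of floor),
    ``LAYER2`` exactly 160 (40 m2): the larger layer doubles the floor
    space of the smaller one.  The outlines are fixed convex-ish blobs
    bounded by wall cells; results of random-placement runs depend only
    on the interior-cell count.
    """
    layer = CaveLayer(layer)
    fname = "layer1.area" if layer is CaveLayer.LAYER1 else "layer2.area"
    text = resources.files("pyrolith.data").joinpath(fname).read_text()
    grid = parse_area_file(text)
    return SiteGrid(grid.cells, name=layer.value)


def interior_cells(grid: SiteGrid) -> list[tuple[int, int]]:
    """Coordinates of interior cells in deterministic row-major order."""
    rr, cc = np.nonzero(grid.cells == "I")
    return list(zip(rr.tolist(), cc.tolist()))
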