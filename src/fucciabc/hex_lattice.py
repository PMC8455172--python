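"""Hexagonal lattice geometry for the scratch-assay exclusion process.

Sites live on a 2D hexagonal (equilateral-triangular) lattice with
nearest-neighbour spacing ``delta``, the mean cell diameter (20 μm for
WM983C melanoma cells).  Rows are indexed ``i = 1..n_rows`` and columns
``j = 1..n_cols`` (1-based); even rows are shifted half a site to the
right so that every interior site has exactly six neighbours, all at
Euclidean distance ``delta``:

    x = (j - 1) * delta          (i odd)
    x = (j - 1/2) * delta        (i even)
    y = i * delta * sqrt(3)/2

The domain boundary is closed: sites outside ``[1, n_rows] x [1, n_cols]``
simply do not exist, which realises the zero-net-flux boundary condition
of the scratch-assay imaging window (no agent ever leaves or enters).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterator

import numpy as np

__all__ = [
    "LatticeGeometry",
    "site_to_xy",
    "xy_to_site",
    "neighbours",
    "neighbour_table",
    "site_coordinates",
]

#: vertical spacing between rows, in units of delta
ROW_FACTOR = math.sqrt(3.0) / 2.0


@dataclass(frozen=True)
class LatticeGeometry:
    """Rectangular patch of a hexagonal lattice.

    Parameters
    ----------
    n_rows, n_cols
        Lattice dimensions (1-based indexing of sites).
    delta
        Site diameter / nearest-neighbour distance in μm.
    width, height
        Physical extent of the imaged region in μm.  If omitted they
        default to the bounding box of the site centres.
    """

    n_rows: int
    n_cols: int
    delta: float = 20.0
    width: float = field(default=None)  # type: ignore[assignment]
    height: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("lattice must have at least one row and column")
        if self.width is None:
            object.__setattr__(self, "width", (self.n_cols - 0.5) * self.delta)
        if self.height is None:
            object.__setattr__(self, "height", self.n_rows * self.delta * ROW_FACTOR)

    @classmethod
    def from_extent(
        cls, width: float, height: float, delta: float = 20.0
    ) -> "LatticeGeometry":
        """Largest lattice whose site centres fit inside ``width x height`` μm."""
        n_rows = int(math.floor(height / (delta * ROW_FACTOR)))
        # even rows reach (n_cols - 1/2) * delta, the binding constraint
        n_cols = int(math.floor(width / delta + 0.5))
        return cls(n_rows=n_rows, n_cols=n_cols, delta=delta, width=width, height=height)

    @property
    def n_sites(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def midline_x(self) -> float:
        """Vertical centre of the imaged region (the scratch axis)."""
        return self.width / 2.0

    def in_domain(self, i: int, j: int) -> bool:
        return 1 <= i <= self.n_rows and 1 <= j <= self.n_cols

    def site_index(self, i: int, j: int) -> int:
        """Flat 0-based index of site ``(i, j)``."""
        if not self.in_domain(i, j):
            raise ValueError(f"site ({i}, {j}) outside {self.n_rows}x{self.n_cols} lattice")
        return (i - 1) * self.n_cols + (j - 1)

    def site_ij(self, s: int) -> tuple[int, int]:
        """Inverse of :meth:`site_index`."""
        i, j = divmod(int(s), self.n_cols)
        return i + 1, j + 1

    def iter_sites(self) -> Iterator[tuple[int, int]]:
        for i in range(1, self.n_rows + 1):
            for j in range(1, self.n_cols + 1):
                yield i, j


def site_to_xy(ij: tuple[int, int], geom: LatticeGeometry) -> tuple[float, float]:
    """Cartesian centre (μm) of lattice site ``(i, j)``.

    Even rows are offset half a site in ``x``; rows are ``delta*sqrt(3)/2``
    apart in ``y`` so that all six neighbours of an interior site are at
    distance ``delta``.
    """
    i, j = ij
    if not geom.in_domain(i, j):
        raise ValueError(f"site ({i}, {j}) outside the lattice domain")
    if i % 2 == 0:
        x = (j - 0.5) * geom.delta
    else:
        x = (j - 1.0) * geom.delta
    y = i * geom.delta * ROW_FACTOR
    return x, y


def _round_half_up(v: float) -> int:
    """Nearest integer, ties toward +inf (deterministic snap rule)."""
    return int(math.floor(v + 0.5))


def xy_to_site(p: tuple[float, float], geom: LatticeGeometry) -> tuple[int, int]:
    """Snap a Cartesian point (μm) to its lattice site.

    The row is recovered first (``i = round(2y / (sqrt(3) delta))``), then
    the column using the offset of that row's parity.  Ties round toward
    +inf.  Exact inverse of :func:`site_to_xy` on every site centre.
    """
    x, y = p
    if not (np.isfinite(x) and np.isfinite(y)):
        raise ValueError("coordinates must be finite")
    i = _round_half_up(y / (geom.delta * ROW_FACTOR))
    if i % 2 == 0:
        j = _round_half_up(x / geom.delta + 0.5)
    else:
        j = _round_half_up(x / geom.delta + 1.0)
    if not geom.in_domain(i, j):
        raise ValueError(f"point ({x}, {y}) maps to ({i}, {j}) outside the lattice")
    return i, j


def neighbours(ij: tuple[int, int], geom: LatticeGeometry) -> set[tuple[int, int]]:
    """The in-domain hexagonal neighbours of a site (≤ 6 of them).

    Off-lattice candidates are dropped, which is what closes the boundary
    (movement and division attempts targeting them are aborted upstream).
    """
    i, j = ij
    if not geom.in_domain(i, j):
        raise ValueError(f"site ({i}, {j}) outside the lattice domain")
    if i % 2 == 0:
        cand = [(i, j - 1), (i, j + 1), (i - 1, j), (i - 1, j + 1), (i + 1, j), (i + 1, j + 1)]
    else:
        cand = [(i, j - 1), (i, j + 1), (i - 1, j - 1), (i - 1, j), (i + 1, j - 1), (i + 1, j)]
    return {c for c in cand if geom.in_domain(*c)}


@lru_cache(maxsize=16)
def neighbour_table(geom: LatticeGeometry) -> np.ndarray:
    """Flat-index neighbour lookup, shape ``(n_sites, 6)``, -1 = off-lattice.

    Direction slots are fixed per parity so that a uniformly drawn slot is a
    uniformly drawn movement direction (off-lattice slots abort the event).
    Cached per geometry; treat the returned array as read-only.
    """
    nbr = np.full((geom.n_sites, 6), -1, dtype=np.int32)
    for i in range(1, geom.n_rows + 1):
        if i % 2 == 0:
            offs = ((0, -1), (0, 1), (-1, 0), (-1, 1), (1, 0), (1, 1))
        else:
            offs = ((0, -1), (0, 1), (-1, -1), (-1, 0), (1, -1), (1, 0))
        for j in range(1, geom.n_cols + 1):
            s = (i - 1) * geom.n_cols + (j - 1)
            for d, (di, dj) in enumerate(offs):
                ii, jj = i + di, j + dj
                if 1 <= ii <= geom.n_rows and 1 <= jj <= geom.n_cols:
                    nbr[s, d] = (ii - 1) * geom.n_cols + (jj - 1)
    return nbr


@lru_cache(maxsize=16)
def site_coordinates(geom: LatticeGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised ``(x, y)`` centres for all flat site indices (read-only)."""
    i = np.arange(geom.n_sites, dtype=np.int64) // geom.n_cols + 1
    j = np.arange(geom.n_sites, dtype=np.int64) % geom.n_cols + 1
    x = np.where(i % 2 == 0, (j - 0.5) * geom.delta, (j - 1.0) * geom.delta)
    y = i * geom.delta * ROW_FACTOR
    return x.astype(np.float64), y.astype(np.float64)
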