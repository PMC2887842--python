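"""Graded rectilinear grids for the volume-conductor model.

The conduction domain is discretized on a tensor-product (rectilinear) grid:
uniform, fine spacing where the tissue compartments and electrode live, with
cell widths growing geometrically toward the outer boundaries.  This mirrors
the usual practice in bioelectric field modelling of meshing finely around
the source and coarsely in the surrounding bath, and lets the grounded
bounding box sit far enough away that doubling it barely changes the fields
at the nerves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator


class GridError(ValueError):
    """Raised for inconsistent grid construction requests."""


def _geom_steps(h0: float, gap: float, ratio: float, h_max: float) -> np.ndarray:
    """Step sizes growing geometrically from ``h0`` that sum to ``gap``.

    The last step is stretched/shrunk so the steps tile the gap exactly.
    """
    if gap <= 0:
        return np.empty(0)
    steps = []
    h = h0
    total = 0.0
    while total < gap - 1e-12:
        h = min(h * ratio, h_max)
        if total + h > gap:
            h = gap - total
            # avoid a sliver cell: merge into previous step if tiny
            if steps and h < 0.3 * steps[-1]:
                steps[-1] += h
                total += h
                break
        steps.append(h)
        total += h
    return np.asarray(steps)


def graded_axis(
    fine_lo: float,
    fine_hi: float,
    h: float,
    margin_lo: float = 0.0,
    margin_hi: float = 0.0,
    ratio: float = 1.45,
    h_max: float = 16.0,
    refine: tuple[float, float, float] | None = None,
) -> np.ndarray:
    """Cell-edge coordinates for one axis.

    Uniform spacing ``h`` on [fine_lo, fine_hi]; geometric coarsening over the
    margins.  ``refine`` = (a, b, h_fine) optionally subdivides the fine cells
    whose span intersects [a, b] to spacing ``h_fine`` (used for the
    mesh-refinement convergence check near the electrode).
    """
    if h <= 0 or fine_hi <= fine_lo:
        raise GridError("fine region must have positive extent and spacing")
    n = int(round((fine_hi - fine_lo) / h))
    if abs(n * h - (fine_hi - fine_lo)) > 1e-9 * max(1.0, abs(fine_hi)):
        n = int(np.ceil((fine_hi - fine_lo) / h))
    core = fine_lo + h * np.arange(n + 1)
    edges = [core]
    if margin_lo > 0:
        steps = _geom_steps(h, margin_lo, ratio, h_max)
        edges.insert(0, fine_lo - np.cumsum(steps)[::-1])
    if margin_hi > 0:
        steps = _geom_steps(h, margin_hi, ratio, h_max)
        edges.append(core[-1] + np.cumsum(steps))
    out = np.concatenate(edges)
    if refine is not None:
        a, b, hf = refine
        if hf <= 0 or hf > h:
            raise GridError("refinement spacing must be in (0, h]")
        nsub = max(1, int(round(h / hf)))
        pieces = []
        for x0, x1 in zip(out[:-1], out[1:]):
            if x1 > a and x0 < b and (x1 - x0) <= h * 1.0001:
                pieces.append(np.linspace(x0, x1, nsub + 1)[:-1])
            else:
                pieces.append(np.array([x0]))
        out = np.concatenate(pieces + [out[-1:]])
    if np.any(np.diff(out) <= 0):
        raise GridError("axis edges are not strictly increasing")
    return out


@dataclass(frozen=True)
class RectilinearGrid:
    """Axis-aligned rectilinear grid; coordinates in mm."""

    xe: np.ndarray
    ye: np.ndarray
    ze: np.ndarray

    def __post_init__(self):
        for e in (self.xe, self.ye, self.ze):
            if e.ndim != 1 or e.size < 2 or np.any(np.diff(e) <= 0):
                raise GridError("edges must be 1-D, strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.xe.size - 1, self.ye.size - 1, self.ze.size - 1)

    @property
    def n_cells(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    # cell-center coordinates and widths, per axis
    @property
    def xc(self) -> np.ndarray:
        return 0.5 * (self.xe[:-1] + self.xe[1:])

    @property
    def yc(self) -> np.ndarray:
        return 0.5 * (self.ye[:-1] + self.ye[1:])

    @property
    def zc(self) -> np.ndarray:
        return 0.5 * (self.ze[:-1] + self.ze[1:])

    @property
    def dx(self) -> np.ndarray:
        return np.diff(self.xe)

    @property
    def dy(self) -> np.ndarray:
        return np.diff(self.ye)

    @property
    def dz(self) -> np.ndarray:
        return np.diff(self.ze)

    def centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable 3-D center-coordinate arrays (X, Y, Z)."""
        return np.meshgrid(self.xc, self.yc, self.zc, indexing="ij", sparse=True)

    def cell_volumes(self) -> np.ndarray:
        return (
            self.dx[:, None, None] * self.dy[None, :, None] * self.dz[None, None, :]
        )

    def contains(self, points: np.ndarray) -> np.ndarray:
        """True where points (N×3, mm) fall inside the cell-center hull."""
        p = np.atleast_2d(points)
        ok = np.ones(p.shape[0], dtype=bool)
        for d, c in enumerate((self.xc, self.yc, self.zc)):
            ok &= (p[:, d] >= c[0]) & (p[:, d] <= c[-1])
        return ok

    def interpolator(self, values: np.ndarray) -> RegularGridInterpolator:
        """Trilinear interpolator of a cell-centered scalar field."""
        if values.shape != self.shape:
            raise GridError("field shape does not match grid")
        return RegularGridInterpolator(
            (self.xc, self.yc, self.zc), values, method="linear", bounds_error=True
        )

    def is_mirror_symmetric_y(self, rtol: float = 1e-12) -> bool:
        """Whether the y-axis edges are symmetric about y = 0."""
        return bool(
            self.ye.size % 2 == 1
            and np.allclose(self.ye, -self.ye[::-1], rtol=0, atol=rtol * max(1.0, abs(self.ye[-1])))
        )

    def half_y(self) -> "RectilinearGrid":
        """The y ≥ 0 half of a y-symmetric grid."""
        if not self.is_mirror_symmetric_y():
            raise GridError("grid is not mirror-symmetric about y = 0")
        mid = self.ye.size // 2
        return RectilinearGrid(self.xe, self.ye[mid:], self.ze)
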