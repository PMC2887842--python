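"""Small builders shared by the unit tests."""

import numpy as np

from iesim.grid import RectilinearGrid
from iesim.solver import PotentialField


def uniform_field(values: np.ndarray, h_mm: float = 0.5) -> PotentialField:
    """A PotentialField on a uniform grid holding the given cell values."""
    nx, ny, nz = values.shape
    grid = RectilinearGrid(
        h_mm * np.arange(nx + 1), h_mm * np.arange(ny + 1), h_mm * np.arange(nz + 1)
    )
    return PotentialField(grid=grid, values=values, current_a=1e-3, residual=0.0, iterations=0)
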