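"""Closed-form benchmark fields for validating the solver and the metrics.

Scenarios with analytic potentials in a homogeneous medium:

* ``point-source``: V(r) = I / (4 pi sigma r); inside a grounded sphere of
  radius R (a centred source) the exact potential is
  V(r) = I / (4 pi sigma) (1/r - 1/R).
* ``dipole``: superposition of a +I and a -I monopole.
* ``linear`` / ``quadratic``: polynomial fields for exactness checks of the
  interpolation and the discrete second difference.

``homogeneous_sphere_model`` builds a voxel model emulating the grounded
sphere — a uniform medium surrounded by a near-perfect conductor tied to the
grounded box — so the numerical solution can be compared against the exact
closed form rather than an infinite-medium approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .anatomy import AnatomyParams, VoxelModel
from .conductivity import build_conductivity_table
from .grid import RectilinearGrid, graded_axis


class AnalyticError(ValueError):
    """Evaluation at a source point or invalid scenario."""


@dataclass(frozen=True)
class AnalyticScenario:
    """A named closed-form field with its parameters."""

    name: str  # point-source | dipole | linear | quadratic
    current_a: float = 1e-3
    sigma: float = 0.05
    source: tuple[float, float, float] = (0.0, 0.0, 0.0)
    source2: tuple[float, float, float] | None = None  # dipole sink (-I)
    ground_radius_mm: float | None = None  # grounded sphere, if any
    coeffs: tuple[float, ...] = ()  # linear: (a, b, c, d); quadratic: adds axis coeff


def analytic_potential(scenario: AnalyticScenario, points: np.ndarray) -> np.ndarray:
    """Closed-form potential (V) at (N, 3) mm points."""
    p = np.atleast_2d(np.asarray(points, float))
    name = scenario.name
    if name == "linear":
        a, b, c, d = (tuple(scenario.coeffs) + (0.0,) * 4)[:4]
        return a * p[:, 0] + b * p[:, 1] + c * p[:, 2] + d
    if name == "quadratic":
        a, b, c, d, q = (tuple(scenario.coeffs) + (0.0,) * 5)[:5]
        return a * p[:, 0] + b * p[:, 1] + c * p[:, 2] + d + q * p[:, 0] ** 2
    if name not in ("point-source", "dipole"):
        raise AnalyticError(f"unknown scenario {name!r}")

    def mono(src, current):
        r = np.linalg.norm(p - np.asarray(src), axis=1) * 1e-3  # m
        if np.any(r < 1e-12):
            raise AnalyticError("potential evaluated at a source point")
        v = current / (4 * np.pi * scenario.sigma * r)
        if scenario.ground_radius_mm is not None:
            v -= current / (4 * np.pi * scenario.sigma * scenario.ground_radius_mm * 1e-3)
        return v

    v = mono(scenario.source, scenario.current_a)
    if name == "dipole":
        if scenario.source2 is None:
            raise AnalyticError("dipole needs a second (sink) source")
        v = v + mono(scenario.source2, -scenario.current_a)
    return v


def analytic_af_along_fiber(
    scenario: AnalyticScenario,
    distance_mm: float,
    x_mm: np.ndarray,
) -> np.ndarray:
    """Exact AF (V/m^2) of a cathodic point source along a straight fiber.

    The fiber runs parallel to x at perpendicular distance d; for the
    cathodic source the depolarizing-signed AF is
    -d^2/dx^2 [ -I/(4 pi sigma sqrt(d^2+x^2)) ] evaluated at the node
    positions, i.e. positive at the closest point.
    """
    if scenario.name != "point-source":
        raise AnalyticError("fiber oracle is defined for the point source")
    if distance_mm <= 0:
        raise AnalyticError("fiber distance must be > 0")
    d = distance_mm * 1e-3
    x = np.asarray(x_mm, float) * 1e-3
    amp = scenario.current_a / (4 * np.pi * scenario.sigma)
    # V_e = -amp / sqrt(d^2+x^2); AF = V_e'' = amp (d^2 - 2 x^2)/(d^2+x^2)^(5/2)
    return amp * (d**2 - 2 * x**2) / (d**2 + x**2) ** 2.5


def homogeneous_sphere_model(
    sigma: float = 0.05,
    ground_radius_mm: float = 150.0,
    fine_mm: float = 15.5,
    h_mm: float = 1.0,
    ratio: float = 1.5,
) -> tuple[VoxelModel, AnalyticScenario]:
    """Voxel model of a homogeneous sphere with a grounded boundary.

    A uniform medium of conductivity ``sigma`` fills r < R; outside, a very
    high conductivity shell couples to the grounded bounding box, making the
    sphere surface an equipotential at ~0 V.  A unit source voxel sits at
    the origin.  Returns the model and the matching analytic scenario with
    ``ground_radius_mm = R``.
    """
    extent = ground_radius_mm * 1.15
    e = graded_axis(
        -fine_mm, fine_mm, h_mm, margin_lo=extent - fine_mm,
        margin_hi=extent - fine_mm, ratio=ratio, h_max=40.0,
    )
    grid = RectilinearGrid(e, e.copy(), e.copy())
    X, Y, Z = grid.centers()
    R = np.sqrt(X**2 + Y**2 + Z**2)
    cond = np.where(R < ground_radius_mm, sigma, 1e6)
    labels = np.zeros(grid.shape, dtype=np.int8)
    model = VoxelModel(
        grid=grid,
        labels=labels,
        conductivity=cond,
        table=build_conductivity_table(),
        params=AnatomyParams(),  # placeholder; geometry is bespoke here
        insulated_faces=frozenset(),
    )
    scenario = AnalyticScenario(
        "point-source", sigma=sigma, ground_radius_mm=ground_radius_mm
    )
    return model, scenario


def point_source_vector(
    model: VoxelModel, current_a: float = 1e-3
) -> tuple[np.ndarray, np.ndarray]:
    """Cathodic source array injecting -current into the centre voxel.

    Returns the per-voxel source (A) and the mm position of the source voxel
    centre (for use as the analytic scenario's source location).
    """
    s = np.zeros(model.grid.shape)
    i = np.argmin(np.abs(model.grid.xc))
    j = np.argmin(np.abs(model.grid.yc))
    k = np.argmin(np.abs(model.grid.zc))
    s[i, j, k] = -current_a
    pos = np.array([model.grid.xc[i], model.grid.yc[j], model.grid.zc[k]])
    return s, pos
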