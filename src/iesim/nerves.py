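"""Parameterized pudendal sensory nerve trajectories.

The two sensory branches of the pudendal nerve are represented bilaterally
as single trunks, placed dorsally to the urethral lumen (dorsal = +z, axial
x in mm from the meatus):

* DNP (dorsal nerve of the penis): runs along the penile body a few mm
  dorsal to the urethra, terminating distally near the meatus and climbing
  dorsally toward the pudendal trunk proximal of the penile bulb.
* CSN (cranial sensory nerve): runs along the membranous/prostatic urethra,
  terminating near the prostate; over the penile bulb it shares the DNP's
  dorsal corridor before both branches leave the model toward the pudendal
  trunk.  The shared corridor reflects the common neurovascular course of
  the two branches near the bulb and makes stimulation there (~4 cm)
  activate both nerves at nearly identical strength.

Five lateral DNP branches leave the trunk over ~1.4-2.6 cm and wrap
ventrolaterally around the penile body toward the urethral wall; their axial
positions are jittered by +-1 cm in the Monte-Carlo branch experiment.

The nerves are *not* part of the conduction domain; the solved potential is
sampled along them at 0.1 mm increments (smooth tricubic interpolation by
default, trilinear on request).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anatomy import AnatomyParams
from .solver import PotentialField

SAMPLE_MM = 0.1  # sampling step along the nerve


class NerveError(ValueError):
    """Nerve path leaves the model volume or is otherwise invalid."""


@dataclass(frozen=True)
class NerveParams:
    """Waypoint geometry of the nerve templates (mm)."""

    # All trajectories run in the dorsal periurethral fascial plane (the
    # connective-tissue space outside the tunica of the erectile bodies and
    # outside the membranous sphincter sleeve), as the pudendal branches do;
    # this keeps every path inside one conductivity compartment, so sampled
    # potentials are smooth and activating functions are free of spurious
    # tissue-interface spikes.

    # DNP trunk: dorsal course from near the meatus to the bulb, ending in
    # the shared corridor over the bulb (truncated toward the pudendal trunk)
    dnp_y_mm: float = 1.5
    dnp_terminal_x_mm: float = 2.0
    dnp_z_distal_mm: float = 6.22
    dnp_end_x_mm: float = 46.5
    dnp_z_end_mm: float = 6.90  # dorsal offset at the proximal end of the course
    # CSN: membranous course at the sphincter sleeve surface, climbing into
    # the shared dorsal corridor over the bulb
    csn_terminal_x_mm: float = 78.0
    csn_z_mm: float = 5.87
    csn_y_mm: float = 2.0
    csn_turn_x_mm: float = 54.0  # distal end of the straight membranous run
    csn_descent_mm: tuple[tuple[float, float, float], ...] = (
        (52.0, 1.9, 6.1),
        (50.0, 1.85, 6.35),
        (48.0, 1.7, 6.65),
        (46.5, 1.5, 6.90),
    )
    csn_join_x_mm: float = 46.5  # joins the DNP corridor
    csn_end_x_mm: float = 34.0  # truncated end within the corridor
    # lateral DNP branches: wrap ventrolaterally around the penile body in
    # the fascial plane, diving past the edge of the erectile wedge toward
    # the urethra and terminating ventrolateral of it
    branch_base_x_mm: tuple[float, ...] = (14.0, 17.0, 20.0, 23.0, 26.0)
    branch_jitter_mm: float = 10.0
    branch_terminal_radius_mm: float = 4.8
    branch_angle_deg: float = 110.0  # final angle from dorsal: ventrolateral
    branch_dive_deg: tuple[float, float] = (45.0, 75.0)  # angular dive window
    branch_axial_drift_mm: float = 7.0
    branch_clamp_x_mm: tuple[float, float] = (3.0, 37.0)
    smooth_mm: float = 2.0  # Gaussian smoothing of waypoint corners

    def dnp_z(self, x) -> np.ndarray:
        """Dorsal offset of the DNP trunk at axial position x."""
        t = (np.asarray(x, float) - self.dnp_terminal_x_mm) / (
            self.dnp_end_x_mm - self.dnp_terminal_x_mm
        )
        return self.dnp_z_distal_mm + t * (self.dnp_z_end_mm - self.dnp_z_distal_mm)


@dataclass(frozen=True)
class NervePath:
    """Polyline nerve trajectory; index 0 is the distal fiber terminal.

    For truncated ends (where the trunk leaves the model toward the pudendal
    nerve) ``truncated_end`` is True and no terminal activating function is
    evaluated there.
    """

    name: str
    points: np.ndarray  # (n, 3) mm
    truncated_end: bool = True

    def __post_init__(self):
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(seg) == 0:
            raise NerveError(f"{self.name}: need an (n, 3) polyline")
        if np.any(seg <= 0):
            raise NerveError(f"{self.name}: arclength must strictly increase")
        object.__setattr__(self, "_cum", np.concatenate([[0.0], np.cumsum(seg)]))

    @property
    def arclength_mm(self) -> float:
        return float(self._cum[-1])

    def at_arclength(self, s: np.ndarray) -> np.ndarray:
        """Points at arclengths s (mm) from the distal terminal."""
        s = np.asarray(s, float)
        if np.any(s < -1e-9) or np.any(s > self.arclength_mm + 1e-9):
            raise NerveError(f"{self.name}: arclength out of range")
        return np.column_stack(
            [np.interp(s, self._cum, self.points[:, d]) for d in range(3)]
        )

    def mirrored(self, name: str) -> "NervePath":
        pts = self.points.copy()
        pts[:, 1] = -pts[:, 1]
        return NervePath(name, pts, self.truncated_end)


def _smooth(points: np.ndarray, sigma_mm: float, step_mm: float = 0.25) -> np.ndarray:
    """Resample a waypoint polyline finely and round its corners.

    Gaussian smoothing of each coordinate against arclength; endpoints are
    pinned so terminals stay where the template puts them.
    """
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    s = np.arange(0.0, cum[-1] + step_mm / 2, step_mm)
    dense = np.column_stack([np.interp(s, cum, points[:, d]) for d in range(3)])
    if sigma_mm <= 0:
        return dense
    half = int(np.ceil(3 * sigma_mm / step_mm))
    k = np.exp(-0.5 * (np.arange(-half, half + 1) * step_mm / sigma_mm) ** 2)
    k /= k.sum()
    pad = np.pad(dense, ((half, half), (0, 0)), mode="edge")
    out = np.column_stack(
        [np.convolve(pad[:, d], k, mode="valid") for d in range(3)]
    )
    out[0], out[-1] = dense[0], dense[-1]
    return out


def build_trunk_paths(
    params: AnatomyParams | None = None,
    nerves: NerveParams | None = None,
) -> dict[str, NervePath]:
    """The four bilateral trunk paths: DNP-left/right, CSN-left/right.

    Left is y < 0, right is y > 0; the pairs are exact mirror images.
    """
    params = params or AnatomyParams()
    n = nerves or NerveParams()

    xs = np.linspace(n.dnp_terminal_x_mm, n.dnp_end_x_mm, 45)
    dnp_wp = np.column_stack([xs, np.full_like(xs, n.dnp_y_mm), n.dnp_z(xs)])
    dnp_r = NervePath("DNP-right", _smooth(dnp_wp, n.smooth_mm))

    # CSN: from its terminal near the prostate, along the membranous urethra,
    # then climbing waypoints over the bulb into the dorsal corridor it
    # shares with the DNP.
    xs_m = np.linspace(n.csn_terminal_x_mm, n.csn_turn_x_mm, 25)
    mem = np.column_stack(
        [xs_m, np.full_like(xs_m, n.csn_y_mm), np.full_like(xs_m, n.csn_z_mm)]
    )
    descent = np.asarray(n.csn_descent_mm, float)
    xs_j = np.linspace(n.csn_join_x_mm, n.csn_end_x_mm, 7)
    corridor = np.column_stack(
        [xs_j, np.full_like(xs_j, n.dnp_y_mm), n.dnp_z(xs_j)]
    )
    csn_wp = np.vstack([mem, descent, corridor])
    csn_r = NervePath("CSN-right", _smooth(csn_wp, n.smooth_mm))

    out = {
        "DNP-right": dnp_r,
        "DNP-left": dnp_r.mirrored("DNP-left"),
        "CSN-right": csn_r,
        "CSN-left": csn_r.mirrored("CSN-left"),
    }
    hull = params.build_grid()
    for p in out.values():
        if not hull.contains(p.points).all():
            raise NerveError(f"{p.name} leaves the model volume")
    return out


def _branch_path(x0: float, side: int, n: NerveParams, name: str) -> NervePath:
    """One lateral branch: off the trunk, wrapping ventrolaterally inward.

    The branch rides the fascial surface at the trunk's dorsal offset until
    it clears the erectile wedge, then dives radially toward the urethra
    over the angular window ``branch_dive_deg`` and levels off at the
    terminal radius.
    """
    r0 = float(np.hypot(n.dnp_y_mm, n.dnp_z(x0)))
    phi0 = float(np.degrees(np.arctan2(n.dnp_y_mm, n.dnp_z(x0))))
    d0, d1 = n.branch_dive_deg
    t = np.linspace(0.0, 1.0, 41)
    phi_deg = phi0 + t * (n.branch_angle_deg - phi0)
    dive = np.clip((phi_deg - d0) / (d1 - d0), 0.0, 1.0)
    r = r0 + dive * (n.branch_terminal_radius_mm - r0)
    phi = np.radians(phi_deg)
    pts = np.column_stack(
        [x0 + t * n.branch_axial_drift_mm, side * r * np.sin(phi), r * np.cos(phi)]
    )
    # terminal (closest to the urethra) first
    return NervePath(name, _smooth(pts[::-1], n.smooth_mm / 2), truncated_end=True)


@dataclass(frozen=True)
class BranchSet:
    """One Monte-Carlo realization of the five lateral DNP branches."""

    seed: int
    base_x_mm: tuple[float, ...]
    realized_x_mm: np.ndarray
    paths: tuple[NervePath, ...]
    jitter_mm: float


def build_branch_set(
    seed: int,
    nerves: NerveParams | None = None,
    jitter_mm: float | None = None,
) -> BranchSet:
    """Five lateral branches with axial positions jittered uniformly +-1 cm.

    Branches alternate sides (right, left, right, ...); jittered positions
    falling outside the modeled penile segment are clamped to it.  The same
    seed always reproduces the same placement.
    """
    n = nerves or NerveParams()
    jit = n.branch_jitter_mm if jitter_mm is None else jitter_mm
    rng = np.random.default_rng(seed)
    base = np.asarray(n.branch_base_x_mm)
    x = base + rng.uniform(-jit, jit, size=base.size)
    x = np.clip(x, *n.branch_clamp_x_mm)
    paths = tuple(
        _branch_path(float(xk), 1 if k % 2 == 0 else -1, n, f"DNP-branch-{k + 1}")
        for k, xk in enumerate(x)
    )
    return BranchSet(seed, tuple(base), x, paths, jit)


@dataclass(frozen=True)
class PotentialProfile:
    """Extracellular potential sampled at 0.1 mm steps along one path."""

    name: str
    s_mm: np.ndarray  # arclength from the distal terminal
    v: np.ndarray  # volts
    truncated_end: bool
    spacing_mm: float = SAMPLE_MM


def sample_potential(
    field: PotentialField, path: NervePath, method: str = "cubic"
) -> PotentialProfile:
    """Sample V along the path at uniform 0.1 mm arclength increments.

    Interpolation is tricubic by default (smooth enough for the second
    differences the activating function takes); pass ``method="linear"``
    for plain trilinear sampling.
    """
    n_samples = int(np.floor(path.arclength_mm / SAMPLE_MM + 1e-9)) + 1
    s = SAMPLE_MM * np.arange(n_samples)
    pts = path.at_arclength(s)
    if not field.grid.contains(pts).all():
        raise NerveError(f"{path.name}: path point outside the field grid")
    return PotentialProfile(path.name, s, field.at(pts, method=method), path.truncated_end)
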