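"""Steady-state conduction solve  div(sigma grad V) = -s  on the voxel model.

Finite-volume discretization on the rectilinear grid: the flux through the
face between two cells uses the series (harmonic-mean) conductance of the two
half-cells, so current continuity holds exactly across tissue boundaries and
faces into the near-insulating catheter carry essentially no current.
Grounded exterior faces impose V = 0 through a half-cell conductance to
ground; insulated faces (the distal wall adjacent to the prepuce, and the
midsagittal plane when solving on a symmetric half-domain) contribute no
flux.  The resulting system is symmetric positive definite and is solved
with Jacobi-preconditioned conjugate gradients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import LinearOperator, cg

from .anatomy import VoxelModel, source_density
from .electrodes import ElectrodeConfig
from .grid import RectilinearGrid

#: faces of the bounding box
FACES = ("x_min", "x_max", "y_min", "y_max", "z_min", "z_max")


class SolverError(RuntimeError):
    """Singular system or non-convergence."""


def _face_conductance(sig0, sig1, d0, d1, area):
    """Series conductance (S) of two half-cells meeting at a face.

    areas in mm^2, widths in mm -> converted to SI internally.
    """
    # G = A / (d0/(2 s0) + d1/(2 s1)); harmonic mean of the half-cells
    return (area * 1e-3) / (d0 / (2 * sig0) + d1 / (2 * sig1))


def assemble_system(
    model: VoxelModel, insulated_faces: frozenset[str] | None = None
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Sparse SPD operator A (7-point stencil) and its diagonal.

    Row/column ordering is C-order flattening of the (nx, ny, nz) cell array.
    """
    grid = model.grid
    sig = model.conductivity
    nx, ny, nz = grid.shape
    dx, dy, dz = grid.dx, grid.dy, grid.dz
    faces = model.insulated_faces if insulated_faces is None else insulated_faces

    if faces >= set(FACES) and not any(
        m.polarity == "anode" for m in model.contacts
    ):
        raise SolverError(
            "all boundaries insulated with a monopolar source: singular system"
        )

    diag = np.zeros((nx, ny, nz))

    # interior face conductances along each axis
    ax = dy[None, :, None] * dz[None, None, :]
    gx = _face_conductance(
        sig[:-1], sig[1:], dx[:-1, None, None], dx[1:, None, None], ax
    )
    ay = dx[:, None, None] * dz[None, None, :]
    gy = _face_conductance(
        sig[:, :-1], sig[:, 1:], dy[None, :-1, None], dy[None, 1:, None], ay
    )
    az = dx[:, None, None] * dy[None, :, None]
    gz = _face_conductance(
        sig[:, :, :-1], sig[:, :, 1:], dz[None, None, :-1], dz[None, None, 1:], az
    )

    for g, axis in ((gx, 0), (gy, 1), (gz, 2)):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        diag[tuple(lo)] += g
        diag[tuple(hi)] += g

    # grounded boundary faces: half-cell conductance to V = 0
    def ground(face, axis, side):
        if face in faces:
            return
        sl = [slice(None)] * 3
        sl[axis] = 0 if side == 0 else -1
        d = (dx, dy, dz)[axis][0 if side == 0 else -1]
        if axis == 0:
            area = dy[:, None] * dz[None, :]
        elif axis == 1:
            area = dx[:, None] * dz[None, :]
        else:
            area = dx[:, None] * dy[None, :]
        diag[tuple(sl)] += (area * 1e-3) / (d / (2 * sig[tuple(sl)]))

    ground("x_min", 0, 0)
    ground("x_max", 0, 1)
    ground("y_min", 1, 0)
    ground("y_max", 1, 1)
    ground("z_min", 2, 0)
    ground("z_max", 2, 1)

    n = nx * ny * nz
    # off-diagonals at C-order strides; pad interior-face arrays with zeros
    def offdiag(g, axis):
        full = np.zeros((nx, ny, nz))
        sl = [slice(None)] * 3
        sl[axis] = slice(None, -1)
        full[tuple(sl)] = g
        return full.ravel()

    stride = {0: ny * nz, 1: nz, 2: 1}
    bands: dict[int, np.ndarray] = {0: diag.ravel()}
    for g, axis in ((gx, 0), (gy, 1), (gz, 2)):
        if (nx, ny, nz)[axis] < 2:
            continue
        od = offdiag(g, axis)[: n - stride[axis]]
        for off in (stride[axis], -stride[axis]):
            if off in bands:  # degenerate axes can share a stride
                bands[off] = bands[off] - od
            else:
                bands[off] = -od
    offsets = sorted(bands)
    A = sp.diags_array([bands[o] for o in offsets], offsets=offsets, shape=(n, n), format="csr")
    return A, diag.ravel()


@dataclass
class PotentialField:
    """Extracellular potential on the voxel grid (volts)."""

    grid: RectilinearGrid
    values: np.ndarray
    current_a: float
    residual: float
    iterations: int
    model: VoxelModel | None = None

    _interp: object | None = None
    _core: object | None = None

    def interpolator(self):
        if self._interp is None:
            self._interp = self.grid.interpolator(self.values)
        return self._interp

    def _uniform_core(self):
        """Maximal uniformly spaced sub-box of the grid (the fine core).

        Returns (slices, origins, spacings) or None if a trivial core.
        Cached; used for smooth (tricubic) sampling along nerve paths.
        """
        if self._core is None:
            slices, orig, hs = [], [], []
            for c in (self.grid.xc, self.grid.yc, self.grid.zc):
                d = np.diff(c)
                h = d.min()
                fine = np.abs(d - h) < 1e-9 * max(1.0, h)
                # longest run of fine spacings
                best_len, best_lo, run_lo = 0, 0, 0
                n = 0
                for i, f in enumerate(fine):
                    if f:
                        if n == 0:
                            run_lo = i
                        n += 1
                        if n > best_len:
                            best_len, best_lo = n, run_lo
                    else:
                        n = 0
                if best_len < 4:
                    self._core = False
                    return None
                slices.append(slice(best_lo, best_lo + best_len + 1))
                orig.append(c[best_lo])
                hs.append(h)
            self._core = (tuple(slices), np.array(orig), np.array(hs))
        return None if self._core is False else self._core

    def at(self, points: np.ndarray, method: str = "linear") -> np.ndarray:
        """Interpolate V at (N, 3) mm points.

        ``method="linear"`` is plain trilinear interpolation anywhere in the
        grid.  ``method="cubic"`` evaluates a tricubic spline over the
        uniformly spaced fine core (where the nerves live); it is C2, so
        spatial second differences of the result are free of the
        cell-boundary derivative kinks a trilinear interpolant would
        introduce.  Points outside the core fall back to trilinear.
        """
        pts = np.atleast_2d(points)
        if method == "linear":
            return self.interpolator()(pts)
        if method != "cubic":
            raise ValueError(f"unknown interpolation method {method!r}")
        core = self._uniform_core()
        if core is None:
            return self.interpolator()(pts)
        slices, orig, hs = core
        idx = (pts - orig) / hs
        hi = np.array([s.stop - s.start - 1 for s in slices], float)
        inside = np.all((idx >= 2.0) & (idx <= hi - 3.0), axis=1)
        if not inside.all():
            out = self.interpolator()(pts)
            if inside.any():
                out[inside] = self.at(pts[inside], method="cubic")
            return out
        from scipy import ndimage

        if not hasattr(self, "_prefiltered"):
            self._prefiltered = ndimage.spline_filter(
                self.values[slices], order=3, mode="mirror"
            )
        return ndimage.map_coordinates(
            self._prefiltered, idx.T, order=3, prefilter=False, mode="mirror"
        )


def _mirror_symmetric_y(model: VoxelModel, source: np.ndarray) -> bool:
    g = model.grid
    if not g.is_mirror_symmetric_y():
        return False
    if not np.array_equal(model.conductivity, model.conductivity[:, ::-1, :]):
        return False
    return np.allclose(source, source[:, ::-1, :], rtol=0, atol=1e-30)


def _half_model(model: VoxelModel) -> VoxelModel:
    g = model.grid
    mid = g.ye.size // 2
    half = VoxelModel(
        grid=g.half_y(),
        labels=model.labels[:, mid:, :],
        conductivity=model.conductivity[:, mid:, :],
        table=model.table,
        params=model.params,
        insulated_faces=frozenset(model.insulated_faces | {"y_min"}),
        contacts=model.contacts,
        electrode=model.electrode,
        depth_cm=model.depth_cm,
        orientation_deg=model.orientation_deg,
    )
    return half


def solve_potential(
    model: VoxelModel,
    current_a: float = 1e-3,
    tol: float = 1e-6,
    maxiter: int = 20000,
    source: np.ndarray | None = None,
    use_symmetry: bool = True,
) -> PotentialField:
    """Solve for the potential under a regulated current of ``current_a`` A.

    The cathodic contact(s) sink ``current_a``; for bipolar configurations the
    anodic contact(s) source the same current (current-balanced).  For a
    model and source mirror-symmetric about the midsagittal plane, only the
    y >= 0 half is solved and the solution is reflected.

    An explicit per-voxel ``source`` array (A, positive = injection) may be
    passed instead of electrode contacts, e.g. for analytic benchmarks.
    """
    if source is None:
        source = source_density(model, current_a)
    if use_symmetry and _mirror_symmetric_y(model, source):
        half = _half_model(model)
        mid = model.grid.ye.size // 2
        f = _solve(half, source[:, mid:, :], current_a, tol, maxiter)
        full = np.concatenate([f.values[:, ::-1, :], f.values], axis=1)
        return PotentialField(
            grid=model.grid,
            values=full,
            current_a=current_a,
            residual=f.residual,
            iterations=f.iterations,
            model=model,
        )
    return _solve(model, source, current_a, tol, maxiter)


def _solve(model, source, current_a, tol, maxiter) -> PotentialField:
    A, diag = assemble_system(model)
    b = source.ravel()
    if not np.any(b):
        raise SolverError("zero source vector")
    inv = 1.0 / diag
    M = LinearOperator(A.shape, matvec=lambda v: inv * v)
    x, info = cg(A, b, rtol=tol, atol=0.0, maxiter=maxiter, M=M)
    if info > 0:
        raise SolverError(f"conjugate gradients did not converge in {info} iterations")
    if info < 0:
        raise SolverError("conjugate gradients failed (singular or ill-posed system)")
    res = float(np.linalg.norm(A @ x - b) / np.linalg.norm(b))
    return PotentialField(
        grid=model.grid,
        values=x.reshape(model.grid.shape),
        current_a=current_a,
        residual=res,
        iterations=0,
        model=model,
    )


def convergence_check(
    build: "callable",
    config: str | ElectrodeConfig,
    depth_cm: float,
    probe_points: np.ndarray,
    tol: float = 1e-6,
    refine_pad_mm: float = 8.0,
    refine_lateral_mm: float = 4.0,
) -> dict[str, float]:
    """Percent change of |V| at probe points under (a) local mesh refinement
    near the electrode and (b) a doubled bounding box.

    ``build`` maps an :class:`~iesim.anatomy.AnatomyParams` to a placed
    :class:`VoxelModel`; it is called with the baseline parameters, with a
    half-spacing refinement window around the electrode, and with doubled
    bounding-box margins.  The report gives
    ``100 * max |V_alt - V_base| / |V_base|`` over the probes.
    """
    from dataclasses import replace

    base_model = build(None)
    params = base_model.params
    probes = np.atleast_2d(probe_points)
    if not base_model.grid.contains(probes).all():
        raise SolverError("probe point outside the grid")
    v_base = solve_potential(base_model, tol=tol).at(probes)

    centre = depth_cm * 10.0
    span = base_model.electrode.span_mm if base_model.electrode else 2.0
    box = (
        centre - span / 2 - refine_pad_mm,
        centre + span / 2 + refine_pad_mm,
        -refine_lateral_mm,
        refine_lateral_mm,
        -refine_lateral_mm,
        refine_lateral_mm,
        params.voxel_mm / 2,
    )
    fine = build(replace(params, refine_boxes=params.refine_boxes + (box,)))
    v_fine = solve_potential(fine, tol=tol).at(probes)

    big = build(replace(params, box_scale=params.box_scale * 2))
    v_big = solve_potential(big, tol=tol).at(probes)

    denom = np.abs(v_base)
    return {
        "refine_pct": float(100 * np.max(np.abs(v_fine - v_base) / denom)),
        "box_double_pct": float(100 * np.max(np.abs(v_big - v_base) / denom)),
    }
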