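import numpy as np
import pytest

import iesim
from iesim.anatomy import VoxelModel
from iesim.conductivity import build_conductivity_table
from iesim.grid import RectilinearGrid
from iesim.solver import SolverError, assemble_system, solve_potential


def toy_model(cond: np.ndarray, h_mm: float = 1.0, insulated=frozenset()) -> VoxelModel:
    nx, ny, nz = cond.shape
    grid = RectilinearGrid(
        h_mm * np.arange(nx + 1), h_mm * np.arange(ny + 1), h_mm * np.arange(nz + 1)
    )
    return VoxelModel(
        grid=grid,
        labels=np.zeros(cond.shape, dtype=np.int8),
        conductivity=cond,
        table=build_conductivity_table(),
        params=iesim.AnatomyParams(),
        insulated_faces=insulated,
    )


def centre_source(shape, current=-1e-3):
    s = np.zeros(shape)
    s[tuple(n // 2 for n in shape)] = current
    return s


class TestAssembly:
    def test_interior_stencil_conserves_current(self):
        """On a homogeneous grid an interior row's off-diagonals sum to the
        negative of the diagonal minus the boundary term; for a fully
        insulated interior cell the row sums to zero."""
        A, _ = assemble_system(toy_model(np.ones((3, 3, 3))))
        row = A[[13], :].toarray().ravel()  # the centre cell
        assert row[13] > 0
        assert np.count_nonzero(row) == 7
        assert row.sum() == pytest.approx(0.0, abs=1e-18)

    def test_face_conductance_is_harmonic_mean(self):
        """sigma 1 and 3 in series give 2*(1*3)/(1+3) = 1.5 per unit cell."""
        cond = np.ones((2, 1, 1))
        cond[1] = 3.0
        A, _ = assemble_system(toy_model(cond))
        # 1 mm cells: G = 1e-3 * harmonic-mean conductivity (the grounded
        # boundary only touches the diagonal)
        assert -A[0, 1] == pytest.approx(1.5e-3, rel=1e-12)

    def test_catheter_faces_carry_no_current(self, session):
        """Faces into the 0.1 nS/m catheter have essentially zero conductance."""
        placed = iesim.place_catheter(session.model, "ring-1mm", 2.0)
        A, _ = assemble_system(placed)
        cath = (placed.labels == placed.labels.max()).ravel()  # catheter is last label
        sub = A[cath][:, ~cath]
        assert abs(sub).max() < 1e-12

    def test_all_insulated_monopolar_is_rejected(self):
        m = toy_model(np.ones((3, 3, 3)), insulated=frozenset(
            {"x_min", "x_max", "y_min", "y_max", "z_min", "z_max"}))
        with pytest.raises(SolverError):
            assemble_system(m)

    def test_matrix_is_symmetric(self):
        rng = np.random.default_rng(0)
        A, _ = assemble_system(toy_model(rng.uniform(0.05, 1.0, (4, 5, 6))))
        assert abs(A - A.T).max() < 1e-18


class TestSolve:
    def test_linearity_in_current(self):
        m = toy_model(np.full((8, 8, 8), 0.05))
        f1 = solve_potential(m, source=centre_source(m.grid.shape, -1e-3), tol=1e-10)
        f2 = solve_potential(m, source=centre_source(m.grid.shape, -2e-3), tol=1e-10)
        assert np.allclose(f2.values, 2 * f1.values, rtol=1e-6)

    def test_inverse_scaling_in_conductivity(self):
        rng = np.random.default_rng(1)
        cond = rng.uniform(0.05, 1.0, (6, 6, 6))
        src = centre_source((6, 6, 6))
        f1 = solve_potential(toy_model(cond), source=src, tol=1e-10)
        f2 = solve_potential(toy_model(2 * cond), source=src, tol=1e-10)
        assert np.allclose(f2.values, f1.values / 2, rtol=1e-6)

    def test_cathodic_field_is_nonpositive(self):
        m = toy_model(np.full((8, 8, 8), 0.05))
        f = solve_potential(m, source=centre_source(m.grid.shape), tol=1e-10)
        assert f.values.max() <= 1e-12
        assert f.residual <= 1e-10

    def test_ground_return_collects_injected_current(self):
        """Discrete conservation: the current leaving through the grounded
        boundary equals the injected current."""
        m = toy_model(np.full((8, 8, 8), 0.05))
        src = centre_source(m.grid.shape)
        f = solve_potential(m, source=src, tol=1e-10)
        A, _ = assemble_system(m)
        ground_current = (A @ f.values.ravel()).sum()
        assert ground_current == pytest.approx(src.sum(), rel=1e-6)

    def test_mirror_symmetric_field(self, session):
        """A left-right symmetric model yields a midsagittally symmetric
        potential, whether or not the half-domain shortcut is used."""
        placed = iesim.place_catheter(session.model, "ring-1mm", 2.0)
        full = solve_potential(placed, use_symmetry=False)
        assert np.allclose(full.values, full.values[:, ::-1, :], atol=5e-4 * abs(full.values).max())
        half = solve_potential(placed, use_symmetry=True)
        assert np.allclose(half.values, full.values, atol=1e-3 * abs(full.values).max())


def test_bipolar_equals_monopolar_superposition(session):
    """A bipolar solve matches the superposition of its two single-contact
    monopolar solves within solver tolerance."""
    from iesim.electrodes import Contact, ElectrodeConfig

    placed = iesim.place_catheter(session.model, "bipolar-ring-1mm", 2.0)
    bi = solve_potential(placed, tol=1e-8)
    parts = []
    for c in placed.electrode.contacts:
        single = ElectrodeConfig("single", (Contact(c.offset_mm, c.length_mm, c.arc_deg, "cathode"),))
        f = solve_potential(iesim.place_catheter(session.model, single, 2.0), tol=1e-8)
        parts.append(-f.values if c.polarity == "anode" else f.values)
    combo = parts[0] + parts[1]
    assert np.allclose(bi.values, combo, atol=2e-4 * abs(bi.values).max())
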