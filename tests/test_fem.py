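"""Finite-element machinery: shape functions, element kernels, pressure
loads, assembly limits and Newton solutions against closed forms."""

import numpy as np
import pytest

from stentbench.fem import (
    HEX_FACES,
    BoundaryConditions,
    FEModel,
    HexMesh,
    SolverConfig,
    apply_pressure,
    element_internal_force,
    shape_functions,
)
from stentbench.geometry import tube_mesh
from stentbench.material import TangentLaw, elastic_matrix, equivalent_stress

from conftest import single_hex_mesh


# ---------------------------------------------------------------------------
# shape functions
# ---------------------------------------------------------------------------

def test_shape_functions_centre_and_corner():
    N, dN = shape_functions([0.0, 0.0, 0.0])
    np.testing.assert_allclose(N, np.full(8, 0.125))
    N, _ = shape_functions([-1.0, -1.0, -1.0])
    expected = np.zeros(8)
    expected[0] = 1.0
    np.testing.assert_allclose(N, expected, atol=1e-14)


def test_shape_functions_partition_of_unity(rng):
    for _ in range(20):
        xi = rng.uniform(-1, 1, 3)
        N, dN = shape_functions(xi)
        assert abs(N.sum() - 1.0) < 1e-14
        np.testing.assert_allclose(dN.sum(axis=0), 0.0, atol=1e-14)


# ---------------------------------------------------------------------------
# element kernels
# ---------------------------------------------------------------------------

def test_element_internal_force_zero_stress():
    mesh = single_hex_mesh()
    D = np.broadcast_to(elastic_matrix(3000.0, 0.3), (8, 6, 6))
    f, K = element_internal_force(mesh.nodes, np.zeros((8, 6)), D)
    np.testing.assert_allclose(f, 0.0, atol=1e-14)
    np.testing.assert_allclose(K, K.T, atol=1e-8 * np.abs(K).max())


def test_element_internal_force_uniform_uniaxial_stress():
    """Unit cube with a uniform uniaxial stress: nodal forces on each loaded
    face sum to sigma * area, distributed over 4 nodes."""
    mesh = single_hex_mesh()
    stress = np.zeros((8, 6))
    stress[:, 2] = 42.0  # sigma_zz on unit cube
    D = np.broadcast_to(elastic_matrix(3000.0, 0.3), (8, 6, 6))
    f, _ = element_internal_force(mesh.nodes, stress, D)
    fz = f.reshape(8, 3)[:, 2]
    top = [4, 5, 6, 7]
    assert fz[top].sum() == pytest.approx(42.0, rel=1e-12)
    np.testing.assert_allclose(fz[top], 42.0 / 4.0, rtol=1e-12)


def test_detj_positive_check():
    nodes = single_hex_mesh().nodes.copy()
    nodes[6] = [0.2, 0.2, 0.2]  # collapse a corner inward -> inverted
    with pytest.raises(ValueError, match="Jacobian"):
        HexMesh(nodes, np.arange(8)[None, :]).validate()


# ---------------------------------------------------------------------------
# pressure loads
# ---------------------------------------------------------------------------

def test_unit_pressure_single_face():
    mesh = single_hex_mesh()
    top = mesh.elements[0, HEX_FACES[5]][None, :]  # +z face
    F = apply_pressure(mesh.nodes, top, 1.0)
    # pressure acts against the outward (+z) normal: total -1 N in z
    assert F[:, 2].sum() == pytest.approx(-1.0, rel=1e-12)
    loaded = F[np.unique(top), 2]
    np.testing.assert_allclose(loaded, -0.25, rtol=1e-12)


def test_closed_surface_pressure_has_zero_resultant():
    mesh = tube_mesh(1.0, 1.3, 2.0, n_theta=20, n_z=4, n_r=2)
    bf = mesh.boundary_faces()
    fn = mesh.face_nodes(bf)
    F = apply_pressure(mesh.nodes, fn, 0.7)
    area = 2 * np.pi * 1.15 * 2.0
    assert np.linalg.norm(F.sum(axis=0)) < 1e-8 * 0.7 * area


# ---------------------------------------------------------------------------
# patch test and analytic solutions
# ---------------------------------------------------------------------------

def _distorted_patch():
    """2x2x2 patch of 8 hexes with a perturbed interior node."""
    g = np.linspace(0.0, 2.0, 3)
    pts = np.array([[x, y, z] for z in g for y in g for x in g])
    pts[13] += [0.17, -0.11, 0.23]  # the interior node
    nid = lambda i, j, k: k * 9 + j * 3 + i
    elems = []
    for k in range(2):
        for j in range(2):
            for i in range(2):
                elems.append(
                    [nid(i, j, k), nid(i + 1, j, k), nid(i + 1, j + 1, k), nid(i, j + 1, k),
                     nid(i, j, k + 1), nid(i + 1, j, k + 1), nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1)]
                )
    return HexMesh(pts, np.array(elems))


def test_patch_test_constant_strain(linear_family, law):
    """Linear displacement BCs on all boundary nodes of a distorted patch
    reproduce the constant stress field to 1e-8 relative."""
    mesh = _distorted_patch()
    grad = np.array([[1e-3, 2e-4, 0.0], [0.0, -5e-4, 1e-4], [3e-4, 0.0, 8e-4]])
    boundary = np.array([n for n in range(27) if n != 13])
    u_presc = mesh.nodes[boundary] @ grad.T
    fixed = (3 * boundary[:, None] + np.arange(3)).ravel()
    cfg = SolverConfig(dt=1.0, newton_tol=1e-12, rate_override=0.01, temperature=37.0)
    model = FEModel(mesh, linear_family, law, cfg)
    model.step(BoundaryConditions(fixed, u_presc.ravel()))

    eps = 0.5 * (grad + grad.T)
    voigt = np.array([eps[0, 0], eps[1, 1], eps[2, 2], 2 * eps[0, 1], 2 * eps[1, 2], 2 * eps[2, 0]])
    expected = elastic_matrix(3000.0, 0.3) @ voigt
    got = model.gauss.stress
    err = np.abs(got - expected).max() / np.abs(expected).max()
    assert err < 1e-8


def test_zero_load_converges_immediately(linear_family, law):
    mesh = single_hex_mesh()
    cfg = SolverConfig(dt=1.0, newton_tol=1e-10, rate_override=0.01)
    model = FEModel(mesh, linear_family, law, cfg)
    fixed = np.arange(12)  # bottom face fully fixed
    info = model.step(BoundaryConditions(fixed, np.zeros(12)))
    assert info.iterations == 0
    np.testing.assert_allclose(model.U, 0.0, atol=1e-15)


def test_elastic_bar_matches_closed_form(linear_family, law):
    """Two-element bar under end displacement: the interior node sits at the
    analytic midpoint and the stress matches E_m * strain."""
    nodes = []
    for z in (0.0, 1.0, 2.0):
        nodes += [[0, 0, z], [1, 0, z], [1, 1, z], [0, 1, z]]
    nodes = np.array(nodes, dtype=float)
    elements = np.array([[0, 1, 2, 3, 4, 5, 6, 7], [4, 5, 6, 7, 8, 9, 10, 11]])
    mesh = HexMesh(nodes, elements)
    cfg = SolverConfig(dt=1.0, newton_tol=1e-12, rate_override=0.01)
    model = FEModel(mesh, linear_family, law, cfg)
    # uniform uniaxial stress state: axial BCs only, lateral contraction
    # free, rigid modes pinned at single nodes
    du = 2e-4
    fixed = [3 * n + 2 for n in range(4)] + [3 * n + 2 for n in range(8, 12)]
    vals = [0.0] * 4 + [du] * 4
    fixed += [0, 1, 4]  # node0 ux,uy; node1 uy: kills lateral rigid modes
    vals += [0.0, 0.0, 0.0]
    info = model.step(BoundaryConditions(np.array(fixed), np.array(vals)))
    assert info.iterations <= 3
    mid_uz = model.U[4:8, 2]
    np.testing.assert_allclose(mid_uz, du / 2, rtol=1e-6)


def test_mass_term_vanishes_for_large_dt(linear_family, law):
    """With the lumped mass term on and a huge time step, the solution
    matches the quasi-static one to 1e-6."""
    mesh = single_hex_mesh()
    fixed = np.arange(12)
    loads = np.zeros(24)
    loads[[14, 17, 20, 23]] = 0.05  # pull the top face up

    def solve(mass):
        cfg = SolverConfig(
            dt=1e6 if mass else 1.0,
            newton_tol=1e-12,
            rate_override=0.01,
            mass_density=1.25e-9 if mass else None,
        )
        m = FEModel(mesh, linear_family, law, cfg)
        m.step(BoundaryConditions(fixed, np.zeros(12), point_loads=loads))
        return m.U

    np.testing.assert_allclose(solve(True), solve(False), atol=1e-6 * 0.05)


def test_thin_tube_hoop_stress_matches_pr_over_t(linear_family, law):
    """Internal pressure on a thin elastic tube: mean hoop stress within 5%
    of p r / t at desk mesh density."""
    r_in, r_out, L = 1.95, 2.05, 2.0
    mesh = tube_mesh(r_in, r_out, L, n_theta=32, n_z=4, n_r=2)
    p = 0.05
    cfg = SolverConfig(dt=1.0, newton_tol=1e-8, rate_override=0.01, stabilization=1e-8)
    model = FEModel(mesh, linear_family, law, cfg)
    fixed = 3 * mesh.node_sets["z_min_end"] + 2
    inner = mesh.face_nodes(mesh.face_sets["inner_faces"])
    model.step(BoundaryConditions(fixed, np.zeros(len(fixed)), pressures=[(inner, p)]))

    # hoop stress from the stress tensor rotated to cylindrical axes
    s = model.gauss.stress
    E = mesh.n_elements
    centers = mesh.element_coords(model.U).mean(axis=1)
    th = np.arctan2(centers[:, 1], centers[:, 0])
    c, si = np.cos(th), np.sin(th)
    sxx, syy, sxy = s.reshape(E, 8, 6)[..., 0], s.reshape(E, 8, 6)[..., 1], s.reshape(E, 8, 6)[..., 3]
    hoop = (si**2)[:, None] * sxx + (c**2)[:, None] * syy - (2 * si * c)[:, None] * sxy
    r_mid, t = 0.5 * (r_in + r_out), r_out - r_in
    expected = p * r_mid / t
    assert hoop.mean() == pytest.approx(expected, rel=0.05)


def test_boundary_faces_closed_count():
    mesh = tube_mesh(1.0, 1.2, 1.0, n_theta=12, n_z=2, n_r=2)
    bf = mesh.boundary_faces()
    # tube boundary: inner + outer (12*2 each) + 2 ends (12*2 each)
    assert len(bf) == 12 * 2 * 2 + 12 * 2 * 2
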