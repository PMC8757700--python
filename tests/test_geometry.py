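"""Parametric scaffold generator: presets, envelope, slots, tools."""

import numpy as np
import pytest

from stentbench.geometry import (
    PRESETS,
    StentDesign,
    cut_slots,
    generate_stent_mesh,
    make_tools,
    preset,
    slot_rectangles,
    tube_mesh,
)
from stentbench.synthetic import make_mini_stent


def _radii(mesh):
    r = np.hypot(mesh.nodes[:, 0], mesh.nodes[:, 1])
    return float(r.min()), float(r.max())


@pytest.fixture(scope="module")
def plla_mesh():
    return generate_stent_mesh(preset("PLLA_prot"))


def test_plla_preset_envelope(plla_mesh):
    r_min, r_max = _radii(plla_mesh)
    assert r_max == pytest.approx(1.62, abs=1e-9)
    assert r_min == pytest.approx(1.50, abs=1e-9)
    z = plla_mesh.nodes[:, 2]
    assert z.max() - z.min() == pytest.approx(15.68, abs=1e-9)


def test_ab_pair_differ_only_in_wall_thickness():
    a = generate_stent_mesh(preset("AB_BVS"))
    b = generate_stent_mesh(preset("AB_BVS_thinner"))
    np.testing.assert_array_equal(a.elements, b.elements)
    _, ra = _radii(a)
    _, rb = _radii(b)
    assert ra - _radii(a)[0] == pytest.approx(0.160, abs=1e-9)
    assert rb - _radii(b)[0] == pytest.approx(0.130, abs=1e-9)


def test_mesh_validity_and_no_duplicate_nodes(plla_mesh):
    plla_mesh.validate()  # positive Jacobians
    rounded = np.round(plla_mesh.nodes / 1e-9).astype(np.int64)
    assert len(np.unique(rounded, axis=0)) == plla_mesh.n_nodes


def test_generation_is_deterministic():
    d = preset("PLLA_prot")
    a, b = generate_stent_mesh(d), generate_stent_mesh(d)
    np.testing.assert_array_equal(a.elements, b.elements)
    np.testing.assert_array_equal(a.nodes, b.nodes)


def test_scaling_design_scales_coordinates_exactly():
    d = StentDesign(outer_radius=1.6, inner_radius=1.44, length=4.0, n_rings=2,
                    crowns_per_ring=4, n_connectors=2, strut_width=0.45)
    m1 = generate_stent_mesh(d)
    m2 = generate_stent_mesh(d.scaled(2.0))
    np.testing.assert_array_equal(m1.elements, m2.elements)
    np.testing.assert_allclose(m2.nodes, 2.0 * m1.nodes, rtol=1e-12, atol=1e-15)


def test_density_refinement_preserves_envelope():
    from dataclasses import replace

    d = StentDesign(outer_radius=1.6, inner_radius=1.44, length=4.0, n_rings=2,
                    crowns_per_ring=4, n_connectors=2, strut_width=0.45)
    for nw in (2, 3, 4):
        m = generate_stent_mesh(replace(d, n_width=nw))
        r_min, r_max = _radii(m)
        assert r_max == pytest.approx(1.6, abs=1e-9)
        assert r_min == pytest.approx(1.44, abs=1e-9)


def test_boundary_face_sets_partition_boundary(plla_mesh):
    bf = plla_mesh.boundary_faces()
    total = sum(len(v) for v in plla_mesh.face_sets.values())
    assert total == len(bf)
    seen = set()
    for v in plla_mesh.face_sets.values():
        for e, f in v:
            key = (int(e), int(f))
            assert key not in seen
            seen.add(key)


def test_design_invariant_violations_raise():
    with pytest.raises(ValueError):
        StentDesign(outer_radius=1.0, inner_radius=1.2, length=4, strut_width=0.3)
    with pytest.raises(ValueError):
        StentDesign(outer_radius=1.6, inner_radius=1.4, length=4, n_rings=1, strut_width=0.3)
    with pytest.raises(ValueError):  # strut wider than ring pitch
        StentDesign(outer_radius=1.6, inner_radius=1.4, length=4, n_rings=4, strut_width=1.2)
    with pytest.raises(ValueError):  # slot wider than strut
        StentDesign(outer_radius=1.6, inner_radius=1.4, length=4, strut_width=0.3,
                    slot_spec={"length": 0.4, "width": 0.35})


# ---------------------------------------------------------------------------
# slots
# ---------------------------------------------------------------------------

def test_slotted_variant_has_strictly_fewer_elements():
    plain = make_mini_stent(n_width=4)
    slotted = make_mini_stent(with_slots=True, n_width=4)
    assert slotted.n_elements < plain.n_elements


def test_slotted_mesh_single_connected_component():
    from scipy.sparse.csgraph import connected_components
    import scipy.sparse as sp
    from stentbench.fem import HEX_FACES

    mesh = make_mini_stent(with_slots=True, n_width=4)
    faces = np.sort(mesh.elements[:, HEX_FACES].reshape(-1, 4), axis=1)
    _, inv, counts = np.unique(faces, axis=0, return_inverse=True, return_counts=True)
    order = np.argsort(inv, kind="stable")
    shared = np.nonzero(counts == 2)[0]
    starts = np.searchsorted(inv[order], shared)
    a, b = order[starts] // 6, order[starts + 1] // 6
    g = sp.coo_matrix((np.ones(len(a)), (a, b)), shape=(mesh.n_elements,) * 2)
    assert connected_components(g, directed=False)[0] == 1


def test_cut_slots_no_centres_is_identity(plla_mesh):
    assert cut_slots(plla_mesh, [], preset("PLLA_prot_slots")) is plla_mesh


def test_disconnecting_slot_raises():
    d = StentDesign(outer_radius=1.6, inner_radius=1.44, length=4.0, n_rings=2,
                    crowns_per_ring=4, n_connectors=2, strut_width=0.45,
                    slot_spec={"length": 0.5, "width": 0.40}, n_width=2)
    with pytest.raises(ValueError, match="disconnect"):
        generate_stent_mesh(d)


def test_slot_rectangles_one_per_connector_segment():
    d = preset("PLLA_prot_slots")
    assert len(slot_rectangles(d)) == d.n_connectors * (d.n_rings - 1)


# ---------------------------------------------------------------------------
# tube + tools
# ---------------------------------------------------------------------------

def test_tube_mesh_sets():
    m = tube_mesh(1.4, 1.6, 4.0, n_theta=16, n_z=4, n_r=2)
    assert len(m.node_sets["inner_surface"]) == 16 * 5
    assert len(m.node_sets["outer_surface"]) == 16 * 5
    assert len(m.node_sets["z_min_end"]) == 16 * 3


def test_make_tools_crimp_schedule_reaches_target():
    d = preset("PLLA_prot")
    tools = make_tools("radial_compression", d, target_radius=1.0)
    assert len(tools) == 1
    assert tools[0].at(1.0).radius == pytest.approx(1.0)
    assert tools[0].at(0.0).radius > d.outer_radius


def test_make_tools_bending_three_rollers_two_static():
    d = preset("PLLA_prot")
    tools = make_tools("three_point_bending", d, deflection=1.0)
    assert len(tools) == 3
    static = [t for t in tools if t.translation_schedule is None]
    assert len(static) == 2
    for t in tools:
        np.testing.assert_allclose(t.tool.direction, [1, 0, 0])


def test_make_tools_crush_plates_antiparallel():
    d = preset("PLLA_prot")
    bottom, top = make_tools("crush", d, deflection=1.0)
    assert np.dot(bottom.tool.direction, top.tool.direction) == pytest.approx(-1.0)
    assert abs(np.dot(bottom.tool.direction, [0, 0, 1])) < 1e-12


def test_make_tools_errors():
    d = preset("PLLA_prot")
    with pytest.raises(ValueError):
        make_tools("torsion", d)
    with pytest.raises(ValueError):
        make_tools("three_point_bending", d, span=2 * d.length)


def test_mini_stent_contract():
    m = make_mini_stent()
    assert m.n_elements <= 1500
    m.validate()
    m2 = make_mini_stent()
    np.testing.assert_array_equal(m.nodes, m2.nodes)
    s2 = make_mini_stent(scale=2.0)
    r = np.hypot(m.nodes[:, 0], m.nodes[:, 1]).max()
    r2 = np.hypot(s2.nodes[:, 0], s2.nodes[:, 1]).max()
    assert r2 == pytest.approx(2 * r, rel=1e-12)
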