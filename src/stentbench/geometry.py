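"""Parametric ring-and-strut scaffold meshes and the rigid test tools.

The true crown/connector patterns of commercial scaffolds are proprietary;
this generator reproduces the *parameters* that drive the design
comparisons (radii, length, strut width and wall thickness, pocket slots)
on a generic pattern: sinusoidal zig-zag rings joined by straight axial
connectors, carved out of a structured cylindrical tube grid of hexahedra.
Carving a structured grid keeps the mesh conforming and all-hex by
construction, makes scale invariance and the cylindrical envelope exact,
and lets slot variants be generated by removing through-thickness element
blocks.

Coordinates: stent axis = Z, origin at mid-length.  Units: mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .contact import RigidTool
from .fem import HEX_FACES, HexMesh

__all__ = [
    "StentDesign",
    "PRESETS",
    "preset",
    "tube_mesh",
    "generate_stent_mesh",
    "cut_slots",
    "slot_rectangles",
    "ScheduledTool",
    "make_tools",
]


@dataclass(frozen=True)
class StentDesign:
    """Parametric scaffold description.

    Wall thickness = outer_radius − inner_radius.  ``slot_spec`` (optional)
    holds ``{"length": mm, "width": mm}`` for pocket slots carved through
    the wall at connector mid-points.  Mesh densities: elements through the
    wall (``n_thickness``) and across the strut width (``n_width``); the
    in-surface cell size is strut_width / n_width in both directions.
    """

    outer_radius: float
    inner_radius: float
    length: float
    n_rings: int = 4
    crowns_per_ring: int = 8
    n_connectors: int = 3
    strut_width: float = 0.19
    slot_spec: dict | None = None
    n_thickness: int = 2
    n_width: int = 2

    def __post_init__(self):
        if not self.outer_radius > self.inner_radius > 0:
            raise ValueError("need outer_radius > inner_radius > 0")
        if self.length <= 0:
            raise ValueError("length must be positive")
        if self.n_rings < 2 or self.crowns_per_ring < 3:
            raise ValueError("need n_rings >= 2 and crowns_per_ring >= 3")
        if not 0 < self.strut_width < self.ring_pitch:
            raise ValueError("strut width must lie in (0, ring pitch)")
        if self.n_thickness < 1 or self.n_width < 1:
            raise ValueError("mesh densities must be >= 1")
        if self.slot_spec is not None:
            sl, sw = self.slot_spec["length"], self.slot_spec["width"]
            if sw >= self.strut_width:
                raise ValueError("slot width must be smaller than the strut width")
            if sl <= 0 or sw <= 0:
                raise ValueError("slot dimensions must be positive")

    @property
    def wall_thickness(self) -> float:
        return self.outer_radius - self.inner_radius

    @property
    def ring_pitch(self) -> float:
        return self.length / self.n_rings

    @property
    def mid_radius(self) -> float:
        return 0.5 * (self.outer_radius + self.inner_radius)

    @property
    def crown_amplitude(self) -> float:
        """Sinusoid amplitude chosen so crown tips touch the stent ends."""
        return 0.5 * self.ring_pitch - 0.5 * self.strut_width

    def scaled(self, s: float) -> "StentDesign":
        slot = None
        if self.slot_spec is not None:
            slot = {"length": self.slot_spec["length"] * s, "width": self.slot_spec["width"] * s}
        return replace(
            self,
            outer_radius=self.outer_radius * s,
            inner_radius=self.inner_radius * s,
            length=self.length * s,
            strut_width=self.strut_width * s,
            slot_spec=slot,
        )


# Published design-family dimensions: two strut-thickness variants of the
# AB-BVS prototype (wall 0.160 vs 0.130 mm at equal inner radius) and the
# PLLA prototype with/without pocket slots (wall 0.115-0.12 mm class,
# strut width 0.184 mm, length 15.68 mm).
PRESETS: dict[str, StentDesign] = {
    "AB_BVS": StentDesign(
        outer_radius=1.65, inner_radius=1.49, length=12.18,
        n_rings=6, crowns_per_ring=8, n_connectors=3, strut_width=0.19,
    ),
    "AB_BVS_thinner": StentDesign(
        outer_radius=1.62, inner_radius=1.49, length=12.18,
        n_rings=6, crowns_per_ring=8, n_connectors=3, strut_width=0.19,
    ),
    "PLLA_prot": StentDesign(
        outer_radius=1.62, inner_radius=1.50, length=15.68,
        n_rings=8, crowns_per_ring=8, n_connectors=3, strut_width=0.184,
    ),
    "PLLA_prot_slots": StentDesign(
        outer_radius=1.62, inner_radius=1.50, length=15.68,
        n_rings=8, crowns_per_ring=8, n_connectors=3, strut_width=0.184,
        slot_spec={"length": 0.5, "width": 0.092}, n_width=4,
    ),
}


def preset(name: str) -> StentDesign:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None


# ---------------------------------------------------------------------------
# structured tube grid
# ---------------------------------------------------------------------------

def _grid_nodes(r_in, r_out, length, n_theta, n_z, n_r, z0):
    ir = np.arange(n_r + 1)
    it = np.arange(n_theta)
    iz = np.arange(n_z + 1)
    r = r_in + (r_out - r_in) * (ir / n_r)
    theta = 2.0 * np.pi * it / n_theta
    z = z0 + length * (iz / n_z)
    # node id = (iz * n_theta + it) * (n_r + 1) + ir
    R, TH, Z = np.meshgrid(r, theta, z, indexing="ij")  # (n_r+1, n_theta, n_z+1)
    nodes = np.stack(
        [R * np.cos(TH), R * np.sin(TH), Z], axis=-1
    ).transpose(2, 1, 0, 3).reshape(-1, 3)
    return nodes


def _cell_elements(n_theta, n_z, n_r, keep_tz: np.ndarray | None = None):
    """Connectivity of kept cells; ``keep_tz`` is an (n_z, n_theta) mask
    applied to all radial layers."""
    def nid(it, iz, ir):
        return (iz * n_theta + (it % n_theta)) * (n_r + 1) + ir

    iz, it, ir = np.meshgrid(
        np.arange(n_z), np.arange(n_theta), np.arange(n_r), indexing="ij"
    )
    if keep_tz is not None:
        mask = keep_tz[iz, it]
        iz, it, ir = iz[mask], it[mask], ir[mask]
    else:
        iz, it, ir = iz.ravel(), it.ravel(), ir.ravel()
    elems = np.stack(
        [
            nid(it, iz, ir), nid(it + 1, iz, ir), nid(it + 1, iz + 1, ir), nid(it, iz + 1, ir),
            nid(it, iz, ir + 1), nid(it + 1, iz, ir + 1), nid(it + 1, iz + 1, ir + 1), nid(it, iz + 1, ir + 1),
        ],
        axis=-1,
    )
    return elems


def _compress(nodes, elements):
    used, inv = np.unique(elements, return_inverse=True)
    return nodes[used], inv.reshape(elements.shape).astype(np.int64)


def _build_sets(nodes, elements, r_in, r_out, z0, z1, tol=1e-9) -> tuple[dict, dict]:
    radius = np.hypot(nodes[:, 0], nodes[:, 1])
    dz_layer = (z1 - z0) * 1e-9
    node_sets = {
        "inner_surface": np.nonzero(np.abs(radius - r_in) <= tol + 1e-9 * r_in)[0],
        "outer_surface": np.nonzero(np.abs(radius - r_out) <= tol + 1e-9 * r_out)[0],
        "z_min_end": np.nonzero(nodes[:, 2] <= z0 + dz_layer)[0],
        "z_max_end": np.nonzero(nodes[:, 2] >= z1 - dz_layer)[0],
    }
    mesh_tmp = HexMesh(nodes, elements)
    bfaces = mesh_tmp.boundary_faces()
    fn = mesh_tmp.face_nodes(bfaces)
    fr = radius[fn]
    fz = nodes[fn, 2]
    inner = np.all(np.abs(fr - r_in) <= tol + 1e-9 * r_in, axis=1)
    outer = np.all(np.abs(fr - r_out) <= tol + 1e-9 * r_out, axis=1)
    ends = (~inner & ~outer) & (
        np.all(fz <= z0 + dz_layer, axis=1) | np.all(fz >= z1 - dz_layer, axis=1)
    )
    cut = ~(inner | outer | ends)
    face_sets = {
        "inner_faces": bfaces[inner],
        "outer_faces": bfaces[outer],
        "end_faces": bfaces[ends],
        "cut_faces": bfaces[cut],
    }
    return node_sets, face_sets


def _connected_component_count(elements: np.ndarray) -> int:
    faces = np.sort(elements[:, HEX_FACES].reshape(-1, 4), axis=1)
    _, inv, counts = np.unique(faces, axis=0, return_inverse=True, return_counts=True)
    order = np.argsort(inv, kind="stable")
    shared = np.nonzero(counts == 2)[0]
    # element ids of each face occurrence, grouped by face key
    elem_of = order // 6
    starts = np.searchsorted(inv[order], shared)
    a, b = elem_of[starts], elem_of[starts + 1]
    n = len(elements)
    g = sp.coo_matrix((np.ones(len(a)), (a, b)), shape=(n, n))
    ncomp, _ = connected_components(g, directed=False)
    return int(ncomp)


def tube_mesh(
    r_in: float,
    r_out: float,
    length: float,
    n_theta: int = 24,
    n_z: int = 8,
    n_r: int = 2,
    z0: float | None = None,
) -> HexMesh:
    """Full (uncarved) cylindrical tube: the elastic verification geometry."""
    if z0 is None:
        z0 = -0.5 * length
    nodes = _grid_nodes(r_in, r_out, length, n_theta, n_z, n_r, z0)
    elements = _cell_elements(n_theta, n_z, n_r)
    nodes, elements = _compress(nodes, elements)
    node_sets, face_sets = _build_sets(nodes, elements, r_in, r_out, z0, z0 + length)
    mesh = HexMesh(nodes, elements, node_sets, face_sets)
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# scaffold pattern
# ---------------------------------------------------------------------------

def _pattern_resolution(design: StentDesign) -> tuple[int, int, float]:
    # the pattern lives on the developed inner cylinder: using the inner
    # radius as the arc-length reference makes designs that differ only in
    # wall thickness share identical connectivity
    cell = design.strut_width / design.n_width
    n_theta = max(12, int(round(2 * np.pi * design.inner_radius / cell)))
    n_z = max(2 * design.n_rings, int(round(design.length / cell)))
    return n_theta, n_z, cell


def _connector_angles(design: StentDesign) -> np.ndarray:
    """Connector angular positions, snapped to sinusoid zeros."""
    c = design.crowns_per_ring
    zeros = np.arange(2 * c) * np.pi / c
    picks = sorted({int(round(j * 2 * c / design.n_connectors)) % (2 * c)
                    for j in range(design.n_connectors)})
    return zeros[picks]


def _ring_centerline(design: StentDesign, theta: np.ndarray, i: int, z0: float) -> np.ndarray:
    p = design.ring_pitch
    return z0 + (i + 0.5) * p + design.crown_amplitude * np.sin(design.crowns_per_ring * theta)


def _keep_mask(design: StentDesign, n_theta: int, n_z: int, z0: float) -> np.ndarray:
    theta_c = 2 * np.pi * (np.arange(n_theta) + 0.5) / n_theta
    z_c = z0 + design.length * (np.arange(n_z) + 0.5) / n_z
    keep = np.zeros((n_z, n_theta), dtype=bool)
    A, c, rm, w = (design.crown_amplitude, design.crowns_per_ring,
                   design.inner_radius, design.strut_width)
    # zig-zag rings: half-width corrected for the local slope so the width
    # perpendicular to the centerline stays the nominal strut width
    slope = A * c * np.cos(c * theta_c) / rm            # dz / d(arc length)
    half_band = 0.5 * w * np.sqrt(1.0 + slope**2)
    for i in range(design.n_rings):
        line = _ring_centerline(design, theta_c, i, z0)
        keep |= np.abs(z_c[:, None] - line[None, :]) <= half_band[None, :]
    # straight axial connectors between adjacent ring centerlines
    half_ang = 0.5 * w / rm
    for tj in _connector_angles(design):
        d_ang = np.abs((theta_c - tj + np.pi) % (2 * np.pi) - np.pi)
        col = d_ang <= half_ang
        if not np.any(col):
            col = d_ang <= d_ang.min() + 1e-12   # guarantee at least one column
        for i in range(design.n_rings - 1):
            lo = _ring_centerline(design, np.array([tj]), i, z0)[0]
            hi = _ring_centerline(design, np.array([tj]), i + 1, z0)[0]
            rows = (z_c >= lo - 1e-12) & (z_c <= hi + 1e-12)
            keep |= rows[:, None] & col[None, :]
    return keep


def generate_stent_mesh(design: StentDesign) -> HexMesh:
    """All-hex scaffold mesh for a parametric design (deterministic).

    Node sets: inner/outer_surface, z_min_end, z_max_end; face sets
    partition the boundary into inner/outer/end/cut faces.  Raises if the
    carved pattern is not a single face-connected component.
    """
    n_theta, n_z, _ = _pattern_resolution(design)
    z0 = -0.5 * design.length
    keep = _keep_mask(design, n_theta, n_z, z0)
    nodes = _grid_nodes(
        design.inner_radius, design.outer_radius, design.length,
        n_theta, n_z, design.n_thickness, z0,
    )
    elements = _cell_elements(n_theta, n_z, design.n_thickness, keep)
    nodes, elements = _compress(nodes, elements)
    if _connected_component_count(elements) != 1:
        raise ValueError("carved scaffold pattern is not a single connected body")
    node_sets, face_sets = _build_sets(
        nodes, elements, design.inner_radius, design.outer_radius, z0, z0 + design.length
    )
    mesh = HexMesh(nodes, elements, node_sets, face_sets)
    mesh.validate()
    if design.slot_spec is not None:
        mesh = cut_slots(mesh, slot_rectangles(design), design)
    return mesh


def slot_rectangles(design: StentDesign) -> list[tuple[float, float]]:
    """(theta, z) centres of pocket slots: one per connector segment,
    centred between adjacent rings."""
    if design.slot_spec is None:
        return []
    z0 = -0.5 * design.length
    p = design.ring_pitch
    out = []
    for tj in _connector_angles(design):
        for i in range(design.n_rings - 1):
            out.append((float(tj), z0 + (i + 1) * p))
    return out


def cut_slots(mesh: HexMesh, centres: list[tuple[float, float]], design: StentDesign) -> HexMesh:
    """Remove through-thickness element blocks forming rectangular pockets
    centred at the given (theta, z) positions.

    The remaining mesh must stay a single connected component (raises
    otherwise); the element count strictly decreases when slots are given.
    """
    if not centres:
        return mesh
    if design.slot_spec is None:
        raise ValueError("design carries no slot_spec")
    sl, sw = design.slot_spec["length"], design.slot_spec["width"]
    ctr = mesh.nodes[mesh.elements].mean(axis=1)
    theta = np.arctan2(ctr[:, 1], ctr[:, 0]) % (2 * np.pi)
    z = ctr[:, 2]
    cell = design.strut_width / design.n_width
    # remove whole through-wall element columns: the k grid columns nearest
    # the slot centre, k = slot width in cells (robust to the slot boundary
    # falling exactly between cell centres)
    k_cols = max(1, int(round(sw / cell)))
    remove = np.zeros(mesh.n_elements, dtype=bool)
    for tj, zj in centres:
        d_ang = np.abs((theta - tj + np.pi) % (2 * np.pi) - np.pi) * design.inner_radius
        in_strip = (np.abs(z - zj) <= 0.5 * sl) & (d_ang <= 0.75 * design.strut_width)
        if not np.any(in_strip):
            continue
        cols = np.round(theta[in_strip] / (2 * np.pi) * 1e9).astype(np.int64)
        uniq = np.unique(cols)
        col_dist = [d_ang[in_strip][cols == c].min() for c in uniq]
        keep_cols = uniq[np.argsort(col_dist)[:k_cols]]
        idx = np.nonzero(in_strip)[0]
        remove[idx[np.isin(cols, keep_cols)]] = True
    if not np.any(remove):
        raise ValueError("slots removed no elements; check slot placement/density")
    elements = mesh.elements[~remove]
    nodes, elements = _compress(mesh.nodes, elements)
    if _connected_component_count(elements) != 1:
        raise ValueError("slot placement disconnects a strut")
    z0, z1 = mesh.nodes[:, 2].min(), mesh.nodes[:, 2].max()
    node_sets, face_sets = _build_sets(
        nodes, elements, design.inner_radius, design.outer_radius, z0, z1
    )
    out = HexMesh(nodes, elements, node_sets, face_sets)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# rigid tools per test
# ---------------------------------------------------------------------------

@dataclass
class ScheduledTool:
    """A rigid tool with a linear motion schedule over the protocol.

    ``at(s)`` returns the tool at fraction ``s`` in [0, 1] of the schedule
    (radius and/or translation interpolated linearly).
    """

    tool: RigidTool
    radius_schedule: tuple[float, float] | None = None
    translation_schedule: tuple[np.ndarray, np.ndarray] | None = None

    def at(self, s: float) -> RigidTool:
        radius = None
        translation = None
        if self.radius_schedule is not None:
            r0, r1 = self.radius_schedule
            radius = r0 + s * (r1 - r0)
        if self.translation_schedule is not None:
            t0, t1 = self.translation_schedule
            translation = np.asarray(t0) + s * (np.asarray(t1) - np.asarray(t0))
        return self.tool.moved(translation=translation, radius=radius)


def make_tools(test: str, design: StentDesign, **config) -> list[ScheduledTool]:
    """Rigid tools (with schedules) for one of the four bench tests.

    radial_compression: a coaxial crimping sleeve closing from just outside
    the scaffold down to ``target_radius`` (default 1.0 mm).  inflation
    (cylinder mode): an expanding internal mandrel.  three_point_bending:
    two fixed lower rollers and one driven upper roller, axes along X.
    crush: two plates normal to Y, top driven, bottom fixed.
    """
    clearance = config.get("clearance", 0.02)
    if test == "radial_compression":
        target = config.get("target_radius", 1.0)
        return [
            ScheduledTool(
                RigidTool("cylinder_inner", name="crimp_sleeve",
                          direction=[0, 0, 1], radius=design.outer_radius + clearance,
                          node_set="outer_surface"),
                radius_schedule=(design.outer_radius + clearance, target),
            )
        ]
    if test == "inflation":
        target = config.get("target_radius", 3.0)
        start = config.get("start_radius", design.inner_radius - clearance)
        return [
            ScheduledTool(
                RigidTool("cylinder_outer", name="mandrel",
                          direction=[0, 0, 1], radius=start, node_set="inner_surface"),
                radius_schedule=(start, target),
            )
        ]
    if test == "three_point_bending":
        span = config.get("span", 0.8 * design.length)
        if span >= design.length:
            raise ValueError("roller span exceeds the stent length")
        roller_r = config.get("roller_radius", 0.5)
        deflection = config.get("deflection", design.outer_radius)
        y_out = design.outer_radius + roller_r
        mk = lambda name, y, z: RigidTool(
            "cylinder_outer", name=name, point=[0.0, y, z],
            direction=[1, 0, 0], radius=roller_r, node_set="outer_surface",
        )
        return [
            ScheduledTool(mk("support_left", -y_out, -0.5 * span)),
            ScheduledTool(mk("support_right", -y_out, 0.5 * span)),
            ScheduledTool(
                mk("pusher", y_out + clearance, 0.0),
                translation_schedule=(np.zeros(3), np.array([0.0, -(deflection + clearance), 0.0])),
            ),
        ]
    if test == "crush":
        # both plates close symmetrically by half the travel each: this is
        # mechanically equivalent to a fixed bottom plate (only the relative
        # motion matters) and keeps the u_Y = 0 mid-plane symmetry condition
        # kinematically consistent
        deflection = config.get("deflection", design.outer_radius)
        half = 0.5 * (deflection + clearance)
        return [
            ScheduledTool(
                RigidTool("plane", name="bottom_plate",
                          point=[0, -(design.outer_radius + clearance), 0],
                          direction=[0, 1, 0], node_set="outer_surface"),
                translation_schedule=(np.zeros(3), np.array([0.0, half, 0.0])),
            ),
            ScheduledTool(
                RigidTool("plane", name="top_plate",
                          point=[0, design.outer_radius + clearance, 0],
                          direction=[0, -1, 0], node_set="outer_surface"),
                translation_schedule=(np.zeros(3), np.array([0.0, -half, 0.0])),
            ),
        ]
    raise ValueError(f"unknown test {test!r}")
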