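"""Node-to-rigid-surface penalty contact (1D elastic support elements).

Whenever a surface node penetrates an analytic rigid tool, a one-
dimensional elastic support element (a penalty spring along the tool's
outward surface normal) is generated; it contributes ``k d dᵀ`` to the
stiffness and ``−k · gap · d`` to the residual, pushing the node back to
the surface.  Springs are regenerated every iteration of every step from
the current geometry.  The tool reaction is the exact negative sum of the
nodal contact forces (symmetric action–reaction by construction).

Tools are analytic rigid surfaces (the physical crimping sleeves, rollers
and plates are rigid in all four bench tests): inner cylinder surface
(crimping sleeve — nodes confined inside), outer cylinder surface
(expansion mandrel / bending roller — nodes kept outside), and half-space
plane (crush plate).  Contact is frictionless and normal-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

__all__ = ["RigidTool", "ContactSpringSet", "detect_contacts", "add_springs_to_system", "tool_reaction"]


@dataclass
class RigidTool:
    """An analytic rigid contact surface.

    kind
        ``cylinder_inner`` — sleeve: nodes must stay at radial distance
        ≤ radius from the axis; ``cylinder_outer`` — mandrel/roller: nodes
        must stay at radial distance ≥ radius; ``plane`` — half-space:
        nodes must stay on the +normal side of the plane point.
    """

    kind: str
    name: str = "tool"
    point: np.ndarray = field(default_factory=lambda: np.zeros(3))   # axis point / plane point
    direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))  # axis / normal
    radius: float = 1.0
    node_set: str = "outer_surface"

    def __post_init__(self):
        if self.kind not in ("cylinder_inner", "cylinder_outer", "plane"):
            raise ValueError(f"unknown tool kind {self.kind!r}")
        self.point = np.asarray(self.point, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("tool direction must be non-zero")
        self.direction = d / n
        if self.kind != "plane" and self.radius <= 0:
            raise ValueError("tool radius must be positive")

    def signed_gap(self, coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Signed gap (negative = penetration) and outward surface normal
        of the tool at the closest point, for node coords (k, 3)."""
        rel = coords - self.point
        if self.kind == "plane":
            gap = rel @ self.direction
            normals = np.broadcast_to(self.direction, coords.shape)
            return gap, normals
        axial = rel @ self.direction
        radial = rel - axial[:, None] * self.direction
        dist = np.linalg.norm(radial, axis=1)
        safe = np.maximum(dist, 1e-30)
        e_r = radial / safe[:, None]
        if self.kind == "cylinder_inner":
            # sleeve inner surface: outward tool normal points toward the axis
            return self.radius - dist, -e_r
        return dist - self.radius, e_r

    def moved(self, translation=None, radius=None) -> "RigidTool":
        """A copy at a new position / radius (schedules mutate copies)."""
        out = replace(self)
        if translation is not None:
            out.point = self.point + np.asarray(translation, dtype=float)
        if radius is not None:
            out.radius = float(radius)
        return out


@dataclass
class ContactSpringSet:
    """Penalty springs of one tool at one configuration: one spring per
    penetrating node, created only where the signed gap is negative.

    The penalty force is regularised near zero penetration: for penetration
    ``p = −gap`` below the smoothing depth ``g0`` the force ramps
    quadratically (``k p² / 2 g0``), beyond it linearly (``k (p − g0/2)``),
    so force and stiffness vanish continuously as a node leaves the surface
    — this removes on/off flapping of barely-touching nodes in the Newton
    loop.  ``g0 = 0`` recovers the plain linear penalty.
    """

    tool: RigidTool
    nodes: np.ndarray       # (m,) node indices
    gaps: np.ndarray        # (m,) signed distances, all < 0
    directions: np.ndarray  # (m, 3) outward tool normals (unit)
    stiffness: float        # N/mm
    smoothing: float = 0.0  # regularisation depth g0 [mm]

    def force_magnitudes(self) -> np.ndarray:
        p = -self.gaps
        if self.smoothing <= 0.0:
            return self.stiffness * p
        g0 = self.smoothing
        # odd extension so a pinned active set can carry mild tension
        return np.where(
            np.abs(p) < g0,
            self.stiffness * p * np.abs(p) / (2.0 * g0),
            self.stiffness * (p - np.sign(p) * 0.5 * g0),
        )

    def stiffness_magnitudes(self) -> np.ndarray:
        p = -self.gaps
        if self.smoothing <= 0.0:
            return np.full(len(p), self.stiffness)
        return self.stiffness * np.minimum(np.abs(p) / self.smoothing, 1.0)

    def nodal_forces(self) -> np.ndarray:
        """Force applied to each penetrating node, (m, 3), along +d."""
        if len(self.nodes) == 0:
            return np.zeros((0, 3))
        return self.force_magnitudes()[:, None] * self.directions


def detect_contacts(
    tool: RigidTool,
    coords: np.ndarray,
    node_ids: np.ndarray,
    stiffness: float,
    smoothing: float = 0.0,
    active_nodes: np.ndarray | None = None,
) -> ContactSpringSet:
    """Generate the penalty springs of ``tool`` against the given nodes on
    the current geometry (gap = 0 produces no spring).

    With ``active_nodes`` the active set is pinned: springs are built for
    exactly those nodes whatever their gap sign (momentarily tied contact)
    — the equilibrium iteration uses this to suppress active-set chatter
    near convergence.
    """
    if active_nodes is not None:
        nodes = np.asarray(active_nodes, dtype=np.int64)
        gap, normals = tool.signed_gap(coords[nodes])
    else:
        node_ids = np.asarray(node_ids, dtype=np.int64)
        gap, normals = tool.signed_gap(coords[node_ids])
        pen = gap < 0
        nodes, gap, normals = node_ids[pen], gap[pen], normals[pen]
    return ContactSpringSet(
        tool=tool,
        nodes=nodes,
        gaps=gap,
        directions=normals,
        stiffness=float(stiffness),
        smoothing=float(smoothing),
    )


def add_springs_to_system(
    springs: ContactSpringSet, K: sp.spmatrix, tangential_factor: float = 0.0
) -> sp.spmatrix:
    """Add each spring's ``k d dᵀ`` block to the system matrix.

    ``tangential_factor`` optionally adds ``τ k (I − d dᵀ)`` per spring —
    a matrix-only regularisation of the tangential directions that removes
    zero-energy rigid modes (e.g. rotation about a cylinder axis under
    frictionless contact).  It contributes no residual force, so converged
    equilibria are unchanged.
    """
    m = len(springs.nodes)
    if m == 0:
        return K
    d = springs.directions
    ddT = np.einsum("mi,mj->mij", d, d)                          # (m, 3, 3)
    k = springs.stiffness_magnitudes()[:, None, None]
    blocks = k * ddT
    if tangential_factor > 0.0:
        eye = np.broadcast_to(np.eye(3), (m, 3, 3))
        blocks = blocks + k * tangential_factor * (eye - ddT)
    dofs = 3 * springs.nodes[:, None] + np.arange(3)             # (m, 3)
    rows = np.repeat(dofs, 3, axis=1).ravel()
    cols = np.tile(dofs, (1, 3)).ravel()
    Kc = sp.coo_matrix((blocks.ravel(), (rows, cols)), shape=K.shape)
    return (K + Kc.tocsr()).tocsr()


def tool_reaction(springs: ContactSpringSet) -> tuple[np.ndarray, float]:
    """Reaction on the tool: the exact negative of the total contact force
    applied to the mesh, plus the total radial force magnitude (the sum of
    per-node normal force magnitudes — the crimping load for cylinders)."""
    f = springs.nodal_forces()
    total = -f.sum(axis=0) if len(f) else np.zeros(3)
    radial = float(springs.force_magnitudes().sum()) if len(f) else 0.0
    return total, radial
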