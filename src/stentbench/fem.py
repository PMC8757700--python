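"""Implicit incremental finite-element machinery for 8-node hexahedra.

Updated-Lagrangian scheme: each load step solves the incremental balance

    (M/Δt² + K) ΔU = F_ext − F_int − (1/Δt²) M (U⁽ⁱ⁻¹⁾ − Uᵗ)

on the geometry committed at the start of the step, with the material's
radially scaled tangent matrix at every Gauss point and (optionally) a
lumped mass term for dynamic regularisation of contact-dominated steps.
Strain increments are accumulated tensorially at the Gauss points, so with
the per-step increment kept small (protocols cap it around 1–2%) the
accumulated measure approximates true (logarithmic) strain.

Quadrature is full 2×2×2 Gauss.  Units: mm, MPa, N, s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .material import (
    CurveFamily,
    GaussStateArray,
    TangentLaw,
    elastic_matrix,
    equivalent_stress,
    stress_update_batch,
)

logger = logging.getLogger(__name__)

__all__ = [
    "HexMesh",
    "SolverConfig",
    "SystemState",
    "BoundaryConditions",
    "NewtonError",
    "FEModel",
    "shape_functions",
    "element_internal_force",
    "apply_pressure",
    "HEX_FACES",
]

# outward-oriented local faces of the VTK hexahedron: -x, +x, -y, +y, -z, +z
HEX_FACES = np.array(
    [[0, 4, 7, 3], [1, 2, 6, 5], [0, 1, 5, 4], [2, 3, 7, 6], [0, 3, 2, 1], [4, 5, 6, 7]],
    dtype=np.int64,
)

_LOCAL_NODES = np.array(
    [
        [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
        [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
    ],
    dtype=float,
)

_G = 1.0 / np.sqrt(3.0)
GAUSS_POINTS = np.array(
    [[sx * _G, sy * _G, sz * _G] for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)]
)
N_GAUSS = 8


def shape_functions(xi) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear hex8 shape functions and their local derivatives.

    Returns ``(N (8,), dN (8, 3))`` at local coordinates ``xi`` in [−1,1]³.
    """
    xi = np.asarray(xi, dtype=float)
    a = _LOCAL_NODES
    N = 0.125 * (1 + a[:, 0] * xi[0]) * (1 + a[:, 1] * xi[1]) * (1 + a[:, 2] * xi[2])
    dN = 0.125 * np.stack(
        [
            a[:, 0] * (1 + a[:, 1] * xi[1]) * (1 + a[:, 2] * xi[2]),
            a[:, 1] * (1 + a[:, 0] * xi[0]) * (1 + a[:, 2] * xi[2]),
            a[:, 2] * (1 + a[:, 0] * xi[0]) * (1 + a[:, 1] * xi[1]),
        ],
        axis=1,
    )
    return N, dN


_DN_TABLE = np.stack([shape_functions(g)[1] for g in GAUSS_POINTS])  # (8gp, 8, 3)
_N_TABLE = np.stack([shape_functions(g)[0] for g in GAUSS_POINTS])   # (8gp, 8)


# ---------------------------------------------------------------------------
# mesh
# ---------------------------------------------------------------------------

@dataclass
class HexMesh:
    """Nodes + hex8 connectivity + named node/face sets.

    ``face_sets`` map names to ``(k, 2)`` arrays of (element, local face).
    """

    nodes: np.ndarray                       # (N, 3) mm
    elements: np.ndarray                    # (E, 8) int
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    face_sets: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        if self.elements.size and (
            self.elements.min() < 0 or self.elements.max() >= len(self.nodes)
        ):
            raise ValueError("element connectivity references missing nodes")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_coords(self, displacements: np.ndarray | None = None) -> np.ndarray:
        x = self.nodes if displacements is None else self.nodes + displacements
        return x[self.elements]  # (E, 8, 3)

    def jacobians(self, displacements: np.ndarray | None = None) -> np.ndarray:
        """det J at every Gauss point, shape (E, 8)."""
        X = self.element_coords(displacements)
        J = np.einsum("gkj,eki->egij", _DN_TABLE, X)
        return np.linalg.det(J)

    def validate(self) -> None:
        detJ = self.jacobians()
        if np.any(detJ <= 0):
            bad = np.unique(np.nonzero(detJ <= 0)[0])
            raise ValueError(f"non-positive Jacobian in elements {bad[:10].tolist()}")

    def boundary_faces(self) -> np.ndarray:
        """All (element, local face) pairs whose face is on the boundary."""
        faces = self.elements[:, HEX_FACES]                    # (E, 6, 4)
        key = np.sort(faces.reshape(-1, 4), axis=1)
        _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        on_boundary = counts[inv] == 1
        e_idx, f_idx = np.divmod(np.nonzero(on_boundary)[0], 6)
        return np.column_stack([e_idx, f_idx])

    def face_nodes(self, face_set: np.ndarray) -> np.ndarray:
        """(k, 4) node indices for a (k, 2) (element, local face) set."""
        return self.elements[face_set[:, 0][:, None], HEX_FACES[face_set[:, 1]]]


# ---------------------------------------------------------------------------
# element kernels
# ---------------------------------------------------------------------------

def _grad_operators(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Shape-function gradients on given element coords (E, 8, 3).

    Returns ``(dNdx (E, 8gp, 8, 3), detJ (E, 8gp))``; raises on non-positive
    Jacobians, naming the offending elements.
    """
    J = np.einsum("gkj,eki->egij", _DN_TABLE, coords)
    detJ = np.linalg.det(J)
    if np.any(detJ <= 0):
        bad = np.unique(np.nonzero(detJ <= 0)[0])
        raise ValueError(f"non-positive Jacobian in elements {bad[:10].tolist()}")
    Jinv = np.linalg.inv(J)
    dNdx = np.einsum("gkj,egji->egki", _DN_TABLE, Jinv)
    return dNdx, detJ


def _b_matrices(dNdx: np.ndarray) -> np.ndarray:
    """Small-strain B operators (E, 8gp, 6, 24), engineering shear rows."""
    E, G, _, _ = dNdx.shape
    B = np.zeros((E, G, 6, 24))
    dx, dy, dz = dNdx[..., 0], dNdx[..., 1], dNdx[..., 2]
    ix = np.arange(8) * 3
    B[..., 0, ix + 0] = dx
    B[..., 1, ix + 1] = dy
    B[..., 2, ix + 2] = dz
    B[..., 3, ix + 0] = dy
    B[..., 3, ix + 1] = dx
    B[..., 4, ix + 1] = dz
    B[..., 4, ix + 2] = dy
    B[..., 5, ix + 0] = dz
    B[..., 5, ix + 2] = dx
    return B


def element_internal_force(
    coords: np.ndarray, stress: np.ndarray, D: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Internal force vector and tangent of a single hex8 element.

    ``coords (8, 3)``, ``stress (8gp, 6)``, ``D (8gp, 6, 6)`` →
    ``(f (24,) = ∫ Bᵀσ dV, K (24, 24) = ∫ Bᵀ D B dV)``.
    """
    dNdx, detJ = _grad_operators(coords[None])
    B = _b_matrices(dNdx)[0]                     # (8gp, 6, 24)
    w = detJ[0]                                  # unit Gauss weights
    f = np.einsum("gai,ga,g->i", B, stress, w)
    K = np.einsum("gai,gab,gbj,g->ij", B, D, B, w)
    return f, K


def apply_pressure(coords: np.ndarray, face_nodes: np.ndarray, pressure: float) -> np.ndarray:
    """Consistent nodal forces of a follower pressure on quad faces.

    ``face_nodes (k, 4)`` must be outward-oriented (element convention);
    the pressure acts against the outward normal (compression onto the
    face).  Evaluated on the supplied (current) geometry with 2×2 Gauss.
    Returns an (N, 3) force array.
    """
    F = np.zeros_like(coords)
    if len(face_nodes) == 0 or pressure == 0.0:
        return F
    X = coords[face_nodes]                      # (k, 4, 3)
    g = 1.0 / np.sqrt(3.0)
    for xi, eta in ((-g, -g), (g, -g), (g, g), (-g, g)):
        N = 0.25 * np.array(
            [(1 - xi) * (1 - eta), (1 + xi) * (1 - eta), (1 + xi) * (1 + eta), (1 - xi) * (1 + eta)]
        )
        dXi = 0.25 * np.array([-(1 - eta), (1 - eta), (1 + eta), -(1 + eta)])
        dEta = 0.25 * np.array([-(1 - xi), -(1 + xi), (1 + xi), (1 - xi)])
        t1 = np.einsum("a,kai->ki", dXi, X)
        t2 = np.einsum("a,kai->ki", dEta, X)
        n = np.cross(t1, t2)                    # outward normal * dA
        contrib = -pressure * np.einsum("a,ki->kai", N, n)
        np.add.at(F, face_nodes, contrib)
    return F


# ---------------------------------------------------------------------------
# configuration / state containers
# ---------------------------------------------------------------------------

@dataclass
class SolverConfig:
    """Newton / stepping configuration.

    mass_density of ``None`` gives the quasi-static reduction (no mass
    term); a value [t/mm³] enables lumped-mass dynamic regularisation.
    ``stabilization`` adds a pure-matrix Tikhonov term (fraction of the
    mean stiffness diagonal) that affects only the linear solve, never the
    converged residual — it selects a solution when rigid-body modes are
    restrained only by frictionless contact.

    ``dynamic_reg`` is a scaled lumped-mass term (the M/Δt² mechanism of the
    incremental balance equation, with the mass diagonal set to the given
    fraction of the mean stiffness diagonal): it enters both matrix and
    residual, penalising per-step motion, and carries the solution through
    local snap-through instabilities of the scaffold pattern.  The inertia
    bias it adds is proportional to the per-step displacement increment and
    vanishes as steps are refined.
    """

    dt: float = 1.0
    newton_tol: float = 1e-6
    max_iters: int = 60
    mass_density: float | None = None
    dynamic_reg: float = 0.0
    stabilization: float = 0.0
    penetration_tol: float = 1e-3
    rate_override: float | None = None
    temperature: float = 37.0
    penalty_stiffness: float | None = None   # N/mm per node; None = auto
    contact_tangent_factor: float = 0.0      # matrix-only tangential contact stiffness
    contact_smoothing: float | None = None   # penalty regularisation depth [mm]; None = penetration_tol/2
    max_update: float | None = None          # mm cap on |ΔU| change per iteration
    freeze_rel: float = 5e-2                 # relative residual below which active sets are frozen

    def __post_init__(self):
        if self.dt <= 0 or self.newton_tol <= 0 or self.max_iters < 1:
            raise ValueError("dt, newton_tol must be positive and max_iters >= 1")


@dataclass
class BoundaryConditions:
    """Prescribed displacement increments, follower pressures and point
    loads for one load step."""

    fixed_dofs: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    fixed_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    pressures: list = field(default_factory=list)      # [(face_nodes (k,4), MPa)]
    point_loads: np.ndarray | None = None              # (ndof,) N

    def __post_init__(self):
        self.fixed_dofs = np.asarray(self.fixed_dofs, dtype=np.int64)
        self.fixed_values = np.asarray(self.fixed_values, dtype=float)
        if self.fixed_dofs.shape != self.fixed_values.shape:
            raise ValueError("fixed_dofs and fixed_values must have equal shape")
        if self.point_loads is not None and len(self.fixed_dofs):
            if np.any(self.point_loads[self.fixed_dofs] != 0):
                raise ValueError("a DOF cannot be both fixed and loaded")


@dataclass
class SystemState:
    """Snapshot of the solution state (for carry-over between protocols)."""

    displacements: np.ndarray
    displacements_prev: np.ndarray
    gauss: GaussStateArray
    time: float
    step_index: int

    def copy(self) -> "SystemState":
        return SystemState(
            self.displacements.copy(),
            self.displacements_prev.copy(),
            self.gauss.copy(),
            self.time,
            self.step_index,
        )


class NewtonError(RuntimeError):
    """Raised when a load step does not converge."""

    def __init__(self, message: str, iterations: int, residual: float):
        super().__init__(message)
        self.iterations = iterations
        self.residual = residual


@dataclass
class StepInfo:
    iterations: int
    residual: float
    tool_reactions: dict        # tool name -> 3-vector reaction on the tool [N]
    tool_radial: dict           # tool name -> total normal-force magnitude [N]
    max_penetration: float
    external_force: np.ndarray


# ---------------------------------------------------------------------------
# the solver
# ---------------------------------------------------------------------------

class FEModel:
    """Incremental implicit solver bound to one mesh and one material."""

    def __init__(
        self,
        mesh: HexMesh,
        family: CurveFamily,
        law: TangentLaw = TangentLaw(),
        config: SolverConfig = None,
    ):
        self.mesh = mesh
        self.family = family
        self.law = law
        self.config = config or SolverConfig()
        mesh.validate()

        E = mesh.n_elements
        self.ndof = 3 * mesh.n_nodes
        self.dofs = (3 * mesh.elements[:, :, None] + np.arange(3)).reshape(E, 24)
        self._rows = np.repeat(self.dofs, 24, axis=1).ravel()
        self._cols = np.tile(self.dofs, (1, 24)).ravel()

        self.U = np.zeros((mesh.n_nodes, 3))
        self.U_prev = np.zeros_like(self.U)
        self.gauss = GaussStateArray.zeros(E * N_GAUSS)
        self.time = 0.0
        self.step_index = 0

        # lumped nodal mass on the reference configuration
        detJ = mesh.jacobians()
        elem_mass = detJ.sum(axis=1) / 8.0
        self.node_mass = np.zeros(mesh.n_nodes)
        np.add.at(self.node_mass, mesh.elements.ravel(), np.repeat(elem_mass, 8))
        self._char_length = float(np.cbrt(np.median(detJ.sum(axis=1))))

    # -- state --------------------------------------------------------------

    def snapshot(self) -> SystemState:
        return SystemState(
            self.U.copy(), self.U_prev.copy(), self.gauss.copy(), self.time, self.step_index
        )

    def restore(self, state: SystemState) -> None:
        self.U = state.displacements.copy()
        self.U_prev = state.displacements_prev.copy()
        self.gauss = state.gauss.copy()
        self.time = state.time
        self.step_index = state.step_index

    def effective_stress(self) -> np.ndarray:
        """Von Mises stress at every Gauss point, shape (E * 8,)."""
        return equivalent_stress(self.gauss.stress)

    def default_penalty(self) -> float:
        E0 = float(self.family.initial_modulus(self.family.strain_rates[0], self.config.temperature))
        return 20.0 * E0 * self._char_length

    # -- assembly -----------------------------------------------------------

    def _internal_force(self, B, detJ, stress):
        E = self.mesh.n_elements
        fe = np.einsum("egai,ega,eg->ei", B, stress.reshape(E, N_GAUSS, 6), detJ)
        Fint = np.zeros(self.ndof)
        np.add.at(Fint, self.dofs.ravel(), fe.ravel())
        return Fint

    def _element_stiffness(self, B, detJ, r_stress, E_T):
        # the assembled tangent is the radially scaled material matrix; the
        # scaling is floored so fully unloaded Gauss points (stress ratio
        # near zero) do not produce zero-stiffness regions — this affects
        # only the iteration matrix, never the converged stress state
        E = self.mesh.n_elements
        r_tan = np.clip(r_stress, 0.05, 20.0)
        D = elastic_matrix(E_T.reshape(E, N_GAUSS), self.law.poisson_ratio)
        D *= r_tan.reshape(E, N_GAUSS, 1, 1)
        DB = np.einsum("egab,egbj->egaj", D, B)
        return np.einsum("egai,egaj,eg->eij", B, DB, detJ)

    def _assemble_system(self, B, detJ, stress, r_stress, E_T):
        """Stiffness (COO parts) and internal force from Gauss quantities."""
        return (
            self._element_stiffness(B, detJ, r_stress, E_T),
            self._internal_force(B, detJ, stress),
        )

    # -- one load step ------------------------------------------------------

    def step(
        self,
        bcs: BoundaryConditions,
        tools: tuple = (),
        temperature: float | None = None,
    ) -> StepInfo:
        """Advance one load step; commits state only on convergence.

        ``tools`` are rigid contact tools already positioned at the step
        target; contact springs are regenerated every iteration on the
        current geometry.
        """
        from .contact import add_springs_to_system, detect_contacts, tool_reaction

        cfg = self.config
        T = cfg.temperature if temperature is None else temperature
        mesh = self.mesh
        coords0 = mesh.nodes + self.U
        dNdx, detJ = _grad_operators(coords0[mesh.elements])
        B = _b_matrices(dNdx)

        free = np.ones(self.ndof, dtype=bool)
        free[bcs.fixed_dofs] = False
        free_idx = np.nonzero(free)[0]

        dU = np.zeros(self.ndof)
        dU[bcs.fixed_dofs] = bcs.fixed_values

        mass_diag = None
        if cfg.mass_density is not None:
            mass_diag = np.repeat(self.node_mass * cfg.mass_density, 3) / cfg.dt**2
        reg_pending = cfg.dynamic_reg > 0.0

        penalty = cfg.penalty_stiffness or (self.default_penalty() if tools else 0.0)
        smoothing = (
            cfg.contact_smoothing
            if cfg.contact_smoothing is not None
            else 0.5 * cfg.penetration_tol
        )

        new_states = self.gauss
        info = None
        relax = 1.0
        relax_cap = 1.0
        fall_streak = 0
        best_res = np.inf
        frozen = False
        frozen_sets: dict[str, np.ndarray] = {}
        base_states = self.gauss
        lu = None
        lu_nc = -1
        lu_age = 0
        rose = False
        prev_phases = None
        flip_count = np.zeros(self.gauss.n, dtype=np.int16)
        stiff_mask = None
        res_hist: list[float] = []
        for it in range(cfg.max_iters + 1):
            dUe = dU[self.dofs]                                  # (E, 24)
            d_eps = np.einsum("egai,ei->ega", B, dUe).reshape(-1, 6)
            new_states, r_stress, E_T = stress_update_batch(
                base_states, d_eps, cfg.dt, T, self.family, self.law,
                rate_override=cfg.rate_override,
                lock_transitions=frozen,
                stiff_mask=stiff_mask,
            )
            # Gauss points whose phase keeps flipping between iterations get
            # the stiff (initial-modulus) tangent on the next pass
            if prev_phases is not None:
                flip_count += new_states.phase != prev_phases
                stiff_mask = flip_count >= 2
            prev_phases = new_states.phase.copy()
            Fint = self._internal_force(B, detJ, new_states.stress)
            if reg_pending:
                # scaled lumped-mass regularisation, sized from the first
                # material tangent of the step
                Ke0 = self._element_stiffness(B, detJ, r_stress, E_T)
                diag = np.einsum("eii->ei", Ke0)
                reg = cfg.dynamic_reg * float(np.abs(diag).mean())
                mass_diag = (mass_diag if mass_diag is not None else 0.0) + np.full(
                    self.ndof, reg
                )
                reg_pending = False

            coords_cur = coords0 + dU.reshape(-1, 3)
            Fext = np.zeros(self.ndof)
            if bcs.point_loads is not None:
                Fext += bcs.point_loads
            for face_nodes, p in bcs.pressures:
                Fext += apply_pressure(coords_cur, face_nodes, p).ravel()

            springs = []
            Fcontact = np.zeros(self.ndof)
            reactions = {}
            radials = {}
            max_pen = 0.0
            for tool in tools:
                node_ids = mesh.node_sets.get(tool.node_set, np.arange(mesh.n_nodes))
                # the smoothed penalty makes contact forces continuous at
                # separation, so the active set is regenerated every
                # iteration even when the material phase set is frozen
                s = detect_contacts(
                    tool, coords_cur, node_ids, stiffness=penalty, smoothing=smoothing,
                )
                springs.append(s)
                f_nodes = s.nodal_forces()
                np.add.at(Fcontact.reshape(-1, 3), s.nodes, f_nodes)
                total, radial = tool_reaction(s)
                reactions[tool.name] = total
                radials[tool.name] = radial
                if len(s.gaps):
                    max_pen = max(max_pen, float(-s.gaps.min()))

            R = Fext + Fcontact - Fint
            if mass_diag is not None:
                R -= mass_diag * dU

            ref = max(
                float(np.linalg.norm(Fext + Fcontact)),
                float(np.linalg.norm(Fint)),
                1e-8,
            )
            res = float(np.linalg.norm(R[free_idx]))
            if logger.isEnabledFor(logging.DEBUG):
                logger.debug(
                    "it=%d res=%.3e ref=%.3e relax=%.3f frozen=%s nc=%d",
                    it, res, ref, relax, frozen,
                    sum(len(s.nodes) for s in springs),
                )
            if res <= cfg.newton_tol * ref:
                info = StepInfo(it, res, reactions, radials, max_pen, Fext + Fcontact)
                break
            # adaptive under-relaxation: a rising residual signals an
            # oscillating/diverging modified-Newton mode (e.g. geometric
            # softening absent from the tangent); damping the update makes
            # the iteration contractive again.  A relaxation level that has
            # produced a rise is not returned to within this step.
            rose = res > 0.999 * best_res
            if rose:
                relax_cap = max(min(relax_cap, 0.7 * relax), 0.02)
                relax = max(0.5 * relax, 0.02)
                fall_streak = 0
            else:
                fall_streak += 1
                if fall_streak >= 3:
                    relax = min(1.4 * relax, relax_cap)
                    fall_streak = 0
            best_res = res  # compare against the previous iteration
            # freeze contact and material-phase active sets once close to
            # equilibrium: suppresses set chatter that otherwise stalls the
            # iteration at a small residual plateau
            froze_now = False
            if not frozen and res <= cfg.freeze_rel * ref and it >= 2:
                frozen = True
                froze_now = True
                frozen_sets = {s.tool.name: s.nodes.copy() for s in springs}
                base_states = self.gauss.copy()
                for name in ("phase", "rev_strain", "rev_stress", "rev_residual", "reload_origin"):
                    getattr(base_states, name)[:] = getattr(new_states, name)
                # the chatter sources are gone: restart the relaxation policy
                relax, relax_cap, fall_streak, best_res = 1.0, 1.0, 0, res
            if it == cfg.max_iters:
                raise NewtonError(
                    f"no convergence in {it} iterations (|R|={res:.3e}, ref={ref:.3e})",
                    it,
                    res,
                )
            res_hist.append(res)

            # the factorized system matrix is lagged across iterations
            # (modified Newton) and rebuilt on events: freshly frozen sets,
            # residual rise, contact-set drift, or simple age
            nc = sum(len(s.nodes) for s in springs)
            refactor = (
                lu is None
                or froze_now
                or rose
                or lu_age >= 8
                or abs(nc - lu_nc) > max(4, 0.05 * max(lu_nc, 1))
            )
            if refactor:
                Ke = self._element_stiffness(B, detJ, r_stress, E_T)
                K = sp.coo_matrix(
                    (Ke.ravel(), (self._rows, self._cols)), shape=(self.ndof, self.ndof)
                ).tocsr()
                if mass_diag is not None:
                    K += sp.diags(mass_diag)
                for s in springs:
                    K = add_springs_to_system(s, K, cfg.contact_tangent_factor)
                Kff = K[free_idx][:, free_idx]
                if cfg.stabilization > 0:
                    scale = cfg.stabilization * float(np.abs(Kff.diagonal()).mean())
                    Kff = Kff + scale * sp.identity(len(free_idx), format="csr")
                try:
                    lu = spla.splu(Kff.tocsc())
                except RuntimeError as err:
                    raise NewtonError(f"singular system: {err}", it, res) from None
                lu_nc = nc
                lu_age = 0
            else:
                lu_age += 1
            delta = lu.solve(R[free_idx])
            if not np.all(np.isfinite(delta)):
                raise NewtonError("singular system (free rigid-body modes?)", it, res)
            if cfg.max_update is not None:
                big = float(np.abs(delta).max())
                if big > cfg.max_update:
                    delta *= cfg.max_update / big
            dU[free_idx] += relax * delta

        # reject steps whose converged geometry has inverted elements: the
        # caller's bisection can then approach the configuration gradually
        U_new = self.U + dU.reshape(-1, 3)
        detJ_new = self.mesh.jacobians(U_new)
        if np.any(detJ_new <= 0):
            bad = np.unique(np.nonzero(np.any(detJ_new <= 0, axis=1))[0])
            raise NewtonError(
                f"converged step inverts elements {bad[:10].tolist()}",
                info.iterations,
                info.residual,
            )

        # commit
        self.U_prev = self.U.copy()
        self.U = U_new
        self.gauss = new_states
        self.time += cfg.dt
        self.step_index += 1
        if info.max_penetration > cfg.penetration_tol:
            logger.warning(
                "step %d: contact penetration %.2e mm exceeds tolerance %.2e",
                self.step_index, info.max_penetration, cfg.penetration_tol,
            )
        return info
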