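"""The four virtual bench tests: radial compression (crimping), inflation,
three-point bending and two-plate crush — orchestrated as pipelines with
residual-stress carry-over between tests.

Each runner drives the rigid tools (or internal pressure) along a linear
schedule with adaptive substepping (a non-converged step is bisected, a few
levels deep), records per-step tool reactions, radii and stress extremes,
and returns a :class:`TestResult` whose final state can seed the next test
in the crimp → inflate → bend/crush sequence.

Sign convention: compressive tool reactions are reported positive (the
``radial_force`` / ``crush_force`` / ``bending_force`` history columns).
Temperature defaults to 37 °C (the clinically relevant condition); the
material is evaluated at the protocol's nominal strain-rate class
(default 0.01 1/s, the middle tested rate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contact import RigidTool
from .fem import BoundaryConditions, FEModel, HexMesh, NewtonError, SolverConfig, SystemState
from .geometry import ScheduledTool, StentDesign, make_tools
from .material import CurveFamily, TangentLaw, equivalent_stress

logger = logging.getLogger(__name__)

__all__ = [
    "TestProtocol",
    "TestResult",
    "run_radial_compression",
    "run_inflation",
    "run_three_point_bending",
    "run_crush",
    "run_sequence",
    "compare_designs",
]

TESTS = ("radial_compression", "inflation", "three_point_bending", "crush")


@dataclass(frozen=True)
class TestProtocol:
    """Configuration of one bench test.

    target
        crimp target radius [mm] | inflation target (mean inner) radius [mm]
        | bending deflection [mm] | crush deflection as a fraction of the
        diameter (in (0, 1)).
    """

    test: str
    target: float
    n_steps: int = 12
    temperature: float = 37.0
    nominal_rate: float = 0.01
    mode: str = "displacement"        # inflation: "pressure"|"cylinder"; crush: "displacement"|"force"
    max_pressure: float = 2.0         # MPa, pressure-mode inflation cap
    release: bool = False             # add an unloading phase (recoil metric)
    newton_tol: float = 1e-5
    stabilization: float = 1e-6
    dynamic_reg: float | None = None  # None = per-test default
    max_bisect: int = 4
    config: dict = field(default_factory=dict)

    # scaled-mass regularisation defaults: the scaffold patterns snap-buckle
    # during crimping (and during re-expansion / flattening of a folded
    # state), which the quasi-static iteration cannot traverse unaided
    _REG_DEFAULTS = {
        "radial_compression": 0.15,
        "inflation": 0.05,
        "three_point_bending": 0.05,
        "crush": 0.05,
    }

    def __post_init__(self):
        if self.test not in TESTS:
            raise ValueError(f"unknown test {self.test!r}")
        if self.dynamic_reg is None:
            object.__setattr__(self, "dynamic_reg", self._REG_DEFAULTS[self.test])
        if self.target <= 0:
            raise ValueError("target must be positive")
        if self.test == "crush" and not 0 < self.target < 1:
            raise ValueError("crush target is a deflection fraction in (0, 1)")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


@dataclass
class TestResult:
    """Outcome of one protocol run."""

    protocol: TestProtocol
    mesh: HexMesh
    final_state: SystemState
    history: pd.DataFrame
    metrics: dict
    flags: dict = field(default_factory=dict)

    @property
    def peak_effective_stress(self) -> float:
        return self.metrics["peak_effective_stress"]


# ---------------------------------------------------------------------------
# runner core
# ---------------------------------------------------------------------------

def _make_model(mesh, family, protocol, prior: TestResult | None) -> FEModel:
    cfg = SolverConfig(
        dt=1.0 / protocol.n_steps,
        newton_tol=protocol.newton_tol,
        stabilization=protocol.stabilization,
        rate_override=protocol.nominal_rate,
        temperature=protocol.temperature,
        max_iters=protocol.config.get("max_iters", 200),
        penalty_stiffness=protocol.config.get("penalty_stiffness"),
        penetration_tol=protocol.config.get("penetration_tol", 1e-3),
        dynamic_reg=protocol.dynamic_reg,
    )
    model = FEModel(mesh, family, TangentLaw(protocol.config.get("poisson_ratio", 0.30)), cfg)
    if prior is not None:
        if prior.mesh.n_nodes != mesh.n_nodes or prior.mesh.n_elements != mesh.n_elements:
            raise ValueError("prior state belongs to a different mesh")
        model.restore(prior.final_state)
    return model


def _outer_radii(model: FEModel) -> tuple[float, float]:
    ids = model.mesh.node_sets.get("outer_surface", np.arange(model.mesh.n_nodes))
    x = model.mesh.nodes[ids] + model.U[ids]
    r = np.hypot(x[:, 0], x[:, 1])
    return float(r.min()), float(r.max())


def _inner_radius_mean(model: FEModel) -> float:
    ids = model.mesh.node_sets.get("inner_surface", np.arange(model.mesh.n_nodes))
    x = model.mesh.nodes[ids] + model.U[ids]
    return float(np.hypot(x[:, 0], x[:, 1]).mean())


def _plane_node_dofs(mesh: HexMesh, axis_zero: int, comp: int, tol: float) -> np.ndarray:
    ids = np.nonzero(np.abs(mesh.nodes[:, axis_zero]) <= tol)[0]
    return 3 * ids + comp


def _run_schedule(
    model: FEModel,
    sched_tools: list[ScheduledTool],
    bcs_at,            # callable s -> BoundaryConditions (increments over [s_prev, s] handled by caller closure)
    record,            # callable (s, info) -> None
    s_values: np.ndarray,
    max_bisect: int,
) -> None:
    """March the schedule fraction s through ``s_values`` with bisection on
    Newton failure (up to ``max_bisect`` levels)."""
    base_dt = model.config.dt
    s_prev = float(s_values[0])
    targets = list(s_values[1:])

    def attempt(s0: float, s1: float, depth: int) -> None:
        # the protocol schedule spans one unit of time: dt = ds
        model.config.dt = max(s1 - s0, 1e-9)
        tools = tuple(st.at(s1) for st in sched_tools)
        snap = model.snapshot()
        try:
            info = model.step(bcs_at(s1), tools=tools)
        except NewtonError:
            model.restore(snap)
            if depth >= max_bisect:
                raise
            mid = 0.5 * (s0 + s1)
            attempt(s0, mid, depth + 1)
            attempt(mid, s1, depth + 1)
            return
        record(s1, info)

    for s in targets:
        attempt(s_prev, float(s), 0)
        s_prev = float(s)
    model.config.dt = base_dt


class _Recorder:
    def __init__(self, model: FEModel):
        self.model = model
        self.rows: list[dict] = []

    def __call__(self, s: float, info, **extra) -> None:
        m = self.model
        r_min, r_max = _outer_radii(m)
        vm = m.effective_stress()
        row = {
            "step": len(self.rows) + 1,
            "s": s,
            "time": m.time,
            "iterations": info.iterations,
            "max_penetration": info.max_penetration,
            "min_outer_radius": r_min,
            "max_outer_radius": r_max,
            "max_effective_stress": float(vm.max()),
            "p99_effective_stress": float(np.quantile(vm, 0.99)),
            "max_plastic_strain": float(m.gauss.equivalent_plastic_strain().max()),
        }
        for name, f in info.tool_reactions.items():
            row[f"{name}_fx"], row[f"{name}_fy"], row[f"{name}_fz"] = map(float, f)
        row.update(extra)
        self.rows.append(row)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def _base_metrics(model: FEModel, history: pd.DataFrame) -> dict:
    vm = model.effective_stress()
    return {
        "peak_effective_stress": float(history["max_effective_stress"].max()),
        "final_max_effective_stress": float(vm.max()),
        "p99_effective_stress": float(np.quantile(vm, 0.99)),
        "max_plastic_strain": float(model.gauss.equivalent_plastic_strain().max()),
    }


# ---------------------------------------------------------------------------
# the four tests
# ---------------------------------------------------------------------------

def run_radial_compression(
    mesh: HexMesh,
    family: CurveFamily,
    protocol: TestProtocol,
    prior: TestResult | None = None,
) -> TestResult:
    """Crimp the scaffold with a closing rigid sleeve down to the target
    radius; axial fixation (u_Z = 0) at the z_min end; the per-step sleeve
    radius and total radial reaction form the load–radius curve."""
    model = _make_model(mesh, family, protocol, prior)
    fixed = 3 * mesh.node_sets["z_min_end"] + 2
    bcs = BoundaryConditions(fixed, np.zeros(len(fixed)))
    r_max0 = _outer_radii(model)[1]
    tools = make_tools(
        "radial_compression",
        _design_stub(mesh),
        target_radius=protocol.target,
        clearance=protocol.config.get("clearance", 0.02),
    )
    tools[0].radius_schedule = (r_max0 + protocol.config.get("clearance", 0.02), protocol.target)

    rec = _Recorder(model)

    def record(s, info):
        tool = tools[0].at(s)
        rec(s, info, sleeve_radius=tool.radius,
            radial_force=info.tool_radial.get("crimp_sleeve", 0.0))

    s_vals = np.linspace(0.0, 1.0, protocol.n_steps + 1)
    _run_schedule(model, tools, lambda s: bcs, record, s_vals, protocol.max_bisect)

    history = rec.frame()
    metrics = _base_metrics(model, history)
    metrics["final_radial_force"] = float(history["radial_force"].iloc[-1])
    metrics["max_penetration"] = float(history["max_penetration"].max())
    return TestResult(protocol, mesh, model.snapshot(), history, metrics)


def run_inflation(
    mesh: HexMesh,
    family: CurveFamily,
    protocol: TestProtocol,
    prior: TestResult | None = None,
) -> TestResult:
    """Inflate the scaffold to the nominal radius, normally starting from
    the crimped state with its residual stresses.

    ``mode='pressure'`` ramps a follower pressure on the inner faces until
    the mean inner radius reaches the target or the pressure cap is hit
    (flagged); ``mode='cylinder'`` expands an internal rigid mandrel (the
    cylinder-based bench setup).  With ``release=True`` the load is removed
    afterwards and the radial recoil fraction is reported.
    """
    model = _make_model(mesh, family, protocol, prior)
    fixed = 3 * mesh.node_sets["z_min_end"] + 2
    bcs0 = BoundaryConditions(fixed, np.zeros(len(fixed)))
    rec = _Recorder(model)
    flags = {}
    s_vals = np.linspace(0.0, 1.0, protocol.n_steps + 1)

    if prior is not None and prior.protocol.test == "radial_compression":
        # the crimping sleeve is opened gradually before loading: removing
        # it in one step releases the whole recoil at once, which the
        # equilibrium iteration cannot absorb
        r_sleeve = float(prior.history["sleeve_radius"].iloc[-1])
        r_open = float(np.hypot(mesh.nodes[:, 0], mesh.nodes[:, 1]).max()) + 0.05
        n_rel = max(protocol.n_steps // 2, 6)
        opener = [
            ScheduledTool(
                RigidTool("cylinder_inner", name="crimp_sleeve",
                          direction=[0, 0, 1], radius=r_sleeve,
                          node_set="outer_surface"),
                radius_schedule=(r_sleeve, r_open),
            )
        ]
        _run_schedule(
            model, opener, lambda s: bcs0,
            lambda s, info: rec(s - 1.0, info, phase="release",
                                mean_inner_radius=_inner_radius_mean(model)),
            np.linspace(0.0, 1.0, n_rel + 1), protocol.max_bisect,
        )

    if protocol.mode == "pressure":
        inner_faces = mesh.face_nodes(mesh.face_sets["inner_faces"])
        p_max = protocol.max_pressure

        def bcs_at(s):
            return replace_pressures(bcs0, [(inner_faces, s * p_max)])

        def record(s, info):
            rec(s, info, pressure=s * p_max, mean_inner_radius=_inner_radius_mean(model))

        target_reached = False
        base_dt = model.config.dt
        s_prev = 0.0
        for s in s_vals[1:]:
            _run_schedule(model, [], bcs_at, record, np.array([s_prev, s]), protocol.max_bisect)
            s_prev = float(s)
            if _inner_radius_mean(model) >= protocol.target:
                target_reached = True
                break
        model.config.dt = base_dt
        if not target_reached:
            flags["target_unreached"] = True
            logger.warning("inflation target radius not reached at max pressure %.3g MPa", p_max)
        p_end = rec.rows[-1]["pressure"] if rec.rows else 0.0
        flags["final_pressure"] = float(p_end)
        if protocol.release and rec.rows:
            r_loaded = _inner_radius_mean(model)
            n_rel = max(protocol.n_steps // 2, 4)
            rel_bcs = lambda s: replace_pressures(bcs0, [(inner_faces, (1.0 - s) * p_end)])
            _run_schedule(
                model, [], rel_bcs,
                lambda s, info: rec(1.0 + s, info, pressure=(1.0 - s) * p_end,
                                    mean_inner_radius=_inner_radius_mean(model)),
                np.linspace(0.0, 1.0, n_rel + 1), protocol.max_bisect,
            )
            r_unloaded = _inner_radius_mean(model)
            flags["recoil"] = (r_loaded - r_unloaded) / r_loaded
            flags["final_pressure"] = 0.0
    else:
        ids = mesh.node_sets.get("inner_surface", np.arange(mesh.n_nodes))
        x = mesh.nodes[ids] + model.U[ids]
        r_min_inner = float(np.hypot(x[:, 0], x[:, 1]).min())
        # seat the mandrel inside the innermost (possibly folded-in) node
        start = max(r_min_inner * 0.98 - 0.02, 0.05)
        tools = make_tools("inflation", _design_stub(mesh), target_radius=protocol.target,
                           start_radius=start)

        def record(s, info):
            rec(s, info, mandrel_radius=tools[0].at(s).radius,
                mean_inner_radius=_inner_radius_mean(model))

        _run_schedule(model, tools, lambda s: bcs0, record, s_vals, protocol.max_bisect)
        flags["final_mandrel_radius"] = float(tools[0].at(1.0).radius)
        flags["mandrel_start_radius"] = float(start)
        if protocol.release:
            r_loaded = _inner_radius_mean(model)
            retract = [ScheduledTool(tools[0].at(1.0),
                                     radius_schedule=(tools[0].at(1.0).radius, start))]
            _run_schedule(model, retract, lambda s: bcs0,
                          lambda s, info: rec(1.0 + s, info,
                                              mandrel_radius=retract[0].at(s).radius,
                                              mean_inner_radius=_inner_radius_mean(model)),
                          np.linspace(0.0, 1.0, max(protocol.n_steps // 2, 4) + 1),
                          protocol.max_bisect)
            r_unloaded = _inner_radius_mean(model)
            flags["recoil"] = (r_loaded - r_unloaded) / r_loaded

    history = rec.frame()
    metrics = _base_metrics(model, history)
    metrics["mean_inner_radius"] = _inner_radius_mean(model)
    if "recoil" in flags:
        metrics["recoil"] = flags["recoil"]
    return TestResult(protocol, mesh, model.snapshot(), history, metrics, flags)


def replace_pressures(bcs: BoundaryConditions, pressures) -> BoundaryConditions:
    return BoundaryConditions(bcs.fixed_dofs, bcs.fixed_values, pressures, bcs.point_loads)


def _unload_prior(model, mesh, prior, protocol, rec) -> None:
    """Gradually remove the load a prior test left applied (deflate the
    inflation pressure or retract the mandrel) before the new tools engage.
    Dropping it in a single step releases the whole spring-back at once,
    which the equilibrium iteration cannot absorb."""
    if prior is None:
        return
    flags = prior.flags or {}
    fixed = 3 * mesh.node_sets["z_min_end"] + 2
    bcs0 = BoundaryConditions(fixed, np.zeros(len(fixed)))
    n_rel = max(protocol.n_steps // 2, 6)
    s_vals = np.linspace(0.0, 1.0, n_rel + 1)
    p_end = float(flags.get("final_pressure", 0.0) or 0.0)
    if p_end > 0.0:
        inner_faces = mesh.face_nodes(mesh.face_sets["inner_faces"])
        _run_schedule(
            model, [],
            lambda s: replace_pressures(bcs0, [(inner_faces, (1.0 - s) * p_end)]),
            lambda s, info: rec(s - 1.0, info, phase="unload_prior"),
            s_vals, protocol.max_bisect,
        )
        return
    r_m = flags.get("final_mandrel_radius")
    if r_m is not None:
        retract = [
            ScheduledTool(
                RigidTool("cylinder_outer", name="mandrel", direction=[0, 0, 1],
                          radius=float(r_m), node_set="inner_surface"),
                radius_schedule=(float(r_m), float(flags.get("mandrel_start_radius", 0.1))),
            )
        ]
        _run_schedule(model, retract, lambda s: bcs0,
                      lambda s, info: rec(s - 1.0, info, phase="unload_prior"),
                      s_vals, protocol.max_bisect)


def run_three_point_bending(
    mesh: HexMesh,
    family: CurveFamily,
    protocol: TestProtocol,
    prior: TestResult | None = None,
) -> TestResult:
    """Three-point bending with rigid rollers (axes along X): two fixed
    supports below, one driven roller at mid-span pushing down (−Y) to the
    target deflection.  Symmetry conditions of the load case: u_X = 0 on
    YZ-plane nodes (lateral symmetry) and u_Z = 0 on XY-plane nodes
    (mid-span symmetry)."""
    model = _make_model(mesh, family, protocol, prior)
    # capture the nodes nearest the symmetry planes: carved patterns rarely
    # have nodes exactly on them
    tol = protocol.config.get("plane_tol") or 0.6 * model._char_length
    dofs = np.concatenate([
        _plane_node_dofs(mesh, 0, 0, tol),   # nodes on YZ plane: u_X = 0
        _plane_node_dofs(mesh, 2, 2, tol),   # nodes on XY plane: u_Z = 0
    ])
    dofs = np.unique(dofs)
    bcs = BoundaryConditions(dofs, np.zeros(len(dofs)))

    rec = _Recorder(model)
    _unload_prior(model, mesh, prior, protocol, rec)

    design = _design_stub(mesh)
    r_now = _outer_radii(model)[1]
    tools = make_tools(
        "three_point_bending", design,
        span=protocol.config.get("span", 0.8 * design.length),
        roller_radius=protocol.config.get("roller_radius", 0.5),
        deflection=protocol.target,
        clearance=protocol.config.get("clearance", 0.02),
    )
    # seat the rollers on the current (possibly inflated) outer surface
    rr = tools[0].tool.radius
    for st in tools[:2]:
        st.tool.point[1] = -(r_now + rr)
    tools[2].tool.point[1] = r_now + rr + protocol.config.get("clearance", 0.02)

    def record(s, info):
        f = np.array(info.tool_reactions.get("pusher", np.zeros(3)))
        rec(s, info, deflection=s * protocol.target, bending_force=float(max(f[1], 0.0)))

    s_vals = np.linspace(0.0, 1.0, protocol.n_steps + 1)
    _run_schedule(model, tools, lambda s: bcs, record, s_vals, protocol.max_bisect)

    history = rec.frame()
    metrics = _base_metrics(model, history)
    metrics["final_bending_force"] = float(history["bending_force"].iloc[-1])
    metrics["secant_stiffness"] = metrics["final_bending_force"] / protocol.target
    return TestResult(protocol, mesh, model.snapshot(), history, metrics)


def run_crush(
    mesh: HexMesh,
    family: CurveFamily,
    protocol: TestProtocol,
    prior: TestResult | None = None,
) -> TestResult:
    """Two-plate crush: bottom plate fixed, top plate driven down until the
    diameter reduction exceeds ``target`` (a fraction of the diameter).
    Quarter-symmetry conditions: u_Z = 0 at the z_min end, u_Y = 0 on
    XZ-plane nodes, u_X = 0 on YZ-plane nodes.

    ``mode='force'`` drives the top plate by a prescribed total load using
    a secant iteration on the plate position.
    """
    model = _make_model(mesh, family, protocol, prior)
    tol = protocol.config.get("plane_tol") or 0.6 * model._char_length
    dofs = np.concatenate([
        3 * mesh.node_sets["z_min_end"] + 2,
        _plane_node_dofs(mesh, 1, 1, tol),   # XZ plane: u_Y = 0
        _plane_node_dofs(mesh, 0, 0, tol),   # YZ plane: u_X = 0
    ])
    dofs = np.unique(dofs)
    bcs = BoundaryConditions(dofs, np.zeros(len(dofs)))

    rec = _Recorder(model)
    _unload_prior(model, mesh, prior, protocol, rec)

    ids = mesh.node_sets["outer_surface"]

    def y_span():
        y = mesh.nodes[ids, 1] + model.U[ids, 1]
        return float(y.max() - y.min())

    span0 = y_span()
    r_now = 0.5 * span0
    travel = protocol.target * span0
    clearance = protocol.config.get("clearance", 0.02)
    tools = make_tools("crush", _design_stub(mesh), deflection=travel, clearance=clearance)
    tools[0].tool.point[1] = -(r_now + clearance)
    tools[1].tool.point[1] = r_now + clearance

    def record(s, info):
        f_top = np.array(info.tool_reactions.get("top_plate", np.zeros(3)))
        # the scaffold pushes the descending plate back up: +y reaction
        rec(s, info, plate_travel=s * (travel + clearance),
            diameter_reduction=(span0 - y_span()) / span0,
            crush_force=float(max(f_top[1], 0.0)))

    s_vals = np.linspace(0.0, 1.0, protocol.n_steps + 1)
    if protocol.mode == "force":
        _run_crush_force(model, tools, bcs, protocol, rec, record, travel, clearance)
    else:
        _run_schedule(model, tools, lambda s: bcs, record, s_vals, protocol.max_bisect)

    history = rec.frame()
    metrics = _base_metrics(model, history)
    metrics["final_crush_force"] = float(history["crush_force"].iloc[-1])
    metrics["final_diameter_reduction"] = float(history["diameter_reduction"].iloc[-1])
    return TestResult(protocol, mesh, model.snapshot(), history, metrics)


def _run_crush_force(model, tools, bcs, protocol, rec, record, travel, clearance):
    """Force-controlled top plate: secant iteration on the plate position
    against the prescribed per-step load levels."""
    f_target_max = protocol.config.get("target_force", 1.0)
    levels = np.linspace(0.0, f_target_max, protocol.n_steps + 1)[1:]
    s_pos = 0.0

    def reaction_at(s1):
        snap = model.snapshot()
        tls = tuple(st.at(s1) for st in tools)
        info = model.step(bcs, tools=tls)
        f = float(max(np.array(info.tool_reactions.get("top_plate", np.zeros(3)))[1], 0.0))
        return f, info, snap

    for f_level in levels:
        lo, f_lo = s_pos, None
        s_try = min(s_pos + 1.0 / protocol.n_steps, 1.0)
        for _ in range(12):
            f, info, snap = reaction_at(s_try)
            if abs(f - f_level) <= max(protocol.newton_tol * 10, 0.02) * max(f_level, 1e-6):
                break
            model.restore(snap)
            if f < f_level:
                lo, f_lo = s_try, f
                s_try = min(s_try + 1.0 / protocol.n_steps, 1.0)
                if s_try == lo:
                    break
            else:
                s_try = 0.5 * (lo + s_try)
        s_pos = s_try
        record(s_pos, info)


def run_sequence(
    mesh: HexMesh,
    family: CurveFamily,
    protocols: list[TestProtocol],
) -> list[TestResult]:
    """Run a chain of tests with residual-stress carry-over (each test is
    initialised from the previous result's final state)."""
    results: list[TestResult] = []
    prior = None
    runners = {
        "radial_compression": run_radial_compression,
        "inflation": run_inflation,
        "three_point_bending": run_three_point_bending,
        "crush": run_crush,
    }
    for p in protocols:
        res = runners[p.test](mesh, family, p, prior=prior)
        results.append(res)
        prior = res
    return results


# ---------------------------------------------------------------------------
# design comparison
# ---------------------------------------------------------------------------

def compare_designs(
    results: list[TestResult], labels: list[str], plot_dir: str | None = None
) -> pd.DataFrame:
    """Tabulate and rank designs tested under identical protocols.

    Reports peak and 99th-percentile effective stress, plastic strain and
    the test's load metric per design, and flags the design with the higher
    stress concentration (by the 99th percentile, which is less sensitive
    to single re-entrant-corner Gauss points than the raw peak).  With
    ``plot_dir`` set (and matplotlib installed), bar charts of the stress
    metrics and overlaid load-history curves are written there.
    """
    if len(results) != len(labels):
        raise ValueError("one label per result required")
    p0 = results[0].protocol
    for r in results[1:]:
        if (r.protocol.test, r.protocol.target, r.protocol.n_steps) != (
            p0.test, p0.target, p0.n_steps
        ):
            raise ValueError("results come from different protocols")
    rows = []
    for label, r in zip(labels, results):
        row = {"design": label, "test": r.protocol.test}
        row.update({k: v for k, v in r.metrics.items() if np.isscalar(v)})
        rows.append(row)
    df = pd.DataFrame(rows).set_index("design")
    df["stress_rank"] = df["p99_effective_stress"].rank(ascending=False).astype(int)
    df["higher_stress_concentration"] = df["stress_rank"] == 1
    if plot_dir is not None:
        _plot_comparison(df, results, labels, plot_dir)
    return df


def _plot_comparison(df, results, labels, plot_dir) -> None:
    import pathlib

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = pathlib.Path(plot_dir)
    out.mkdir(parents=True, exist_ok=True)
    test = results[0].protocol.test
    fig, ax = plt.subplots(figsize=(5, 3.2))
    df[["peak_effective_stress", "p99_effective_stress"]].plot.bar(ax=ax, rot=0)
    ax.set_ylabel("effective stress [MPa]")
    ax.set_title(f"{test}: stress concentration by design")
    fig.tight_layout()
    fig.savefig(out / f"{test}_stress.png", dpi=120)
    plt.close(fig)

    load_cols = {"radial_force", "bending_force", "crush_force", "pressure"}
    fig, ax = plt.subplots(figsize=(5, 3.2))
    for label, r in zip(labels, results):
        col = next((c for c in r.history.columns if c in load_cols), None)
        if col:
            ax.plot(r.history["s"], r.history[col], label=label)
            ax.set_ylabel(col.replace("_", " "))
    ax.set_xlabel("schedule fraction")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / f"{test}_load.png", dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _design_stub(mesh: HexMesh) -> StentDesign:
    """Reconstruct the envelope dimensions make_tools needs from a mesh."""
    r = np.hypot(mesh.nodes[:, 0], mesh.nodes[:, 1])
    z = mesh.nodes[:, 2]
    r_out, r_in = float(r.max()), float(r.min())
    length = float(z.max() - z.min())
    return StentDesign(
        outer_radius=r_out,
        inner_radius=max(r_in, 0.5 * r_out),
        length=length,
        n_rings=2,
        crowns_per_ring=4,
        strut_width=0.4 * length / 2,
    )
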