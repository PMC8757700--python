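"""Rate- and temperature-dependent multilinear constitutive model for PLLA.

The model drives 3D stress states directly from families of uniaxial
true-strain / true-stress curves measured at a grid of temperatures and
strain rates.  At every Gauss point an equivalent (von Mises) stress and
equivalent strain are computed, the curve family is interpolated at the
current equivalent strain, strain rate and temperature, and the trial
stress tensor is scaled radially so that its equivalent measure lands on
the interpolated curve (the "stress ratio" update).  Deformation history
is tracked through a three-phase machine: loading on the rate/temperature
envelope, unloading on anchored hysteresis branches, reloading back up the
branch until the envelope is rejoined.

Conventions
-----------
* Voigt order ``[11, 22, 33, 12, 23, 31]``; stress shear components are
  tensor shears, strain shear components are engineering shears ``γ_ij``.
* Units: MPa for stress, dimensionless true strain, 1/s strain rate, °C.
* The tangent constitutive matrix is isotropic and built from the curve
  tangent modulus ``E_T`` and a configured Poisson ratio with shear modulus
  ``G = E_T / 3``, so the elastic identity ``σ̄ = 3 G ē`` holds exactly and
  the stress ratio is 1 throughout the elastic segment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Phase",
    "UniaxialCurve",
    "CurveFamily",
    "TangentLaw",
    "MaterialPointState",
    "GaussStateArray",
    "equivalent_stress",
    "equivalent_strain",
    "curve_value",
    "interpolate_equivalent_stress",
    "rate_out_of_range_stress",
    "tangent_modulus",
    "stress_update",
    "stress_update_batch",
    "phase_transition",
    "unloading_stress",
    "elastic_matrix",
    "elastic_compliance",
]

_EQ_TOL = 1e-12  # equivalent-strain increments below this are treated as neutral


# ---------------------------------------------------------------------------
# equivalent measures
# ---------------------------------------------------------------------------

def equivalent_stress(s: np.ndarray) -> np.ndarray:
    """Von Mises equivalent stress of Voigt stress vector(s) ``(..., 6)``.

    ``sqrt(1/2 [(σ11-σ22)² + (σ22-σ33)² + (σ33-σ11)² + 6(σ12²+σ23²+σ31²)])``
    """
    s = np.asarray(s, dtype=float)
    d1 = s[..., 0] - s[..., 1]
    d2 = s[..., 1] - s[..., 2]
    d3 = s[..., 2] - s[..., 0]
    sh = s[..., 3] ** 2 + s[..., 4] ** 2 + s[..., 5] ** 2
    return np.sqrt(0.5 * (d1**2 + d2**2 + d3**2 + 6.0 * sh))


def equivalent_strain(e: np.ndarray) -> np.ndarray:
    """Equivalent strain of Voigt strain vector(s) with engineering shears.

    ``[2/3 (e11²+e22²+e33²) + 1/3 (γ12²+γ23²+γ31²)]^(1/2)``
    """
    e = np.asarray(e, dtype=float)
    n = e[..., 0] ** 2 + e[..., 1] ** 2 + e[..., 2] ** 2
    g = e[..., 3] ** 2 + e[..., 4] ** 2 + e[..., 5] ** 2
    return np.sqrt(2.0 / 3.0 * n + g / 3.0)


def deviatoric_equivalent_strain(e: np.ndarray) -> np.ndarray:
    """Equivalent strain of the deviatoric part of ``e``.

    This is the measure used internally for curve lookup: the uniaxial
    experimental abscissa maps onto the 3D state under the plastic
    incompressibility assumption, which the deviatoric projection enforces.
    Identical to :func:`equivalent_strain` for traceless tensors.
    """
    e = np.asarray(e, dtype=float)
    m = (e[..., 0] + e[..., 1] + e[..., 2]) / 3.0
    d = e.copy()
    d[..., 0] -= m
    d[..., 1] -= m
    d[..., 2] -= m
    return equivalent_strain(d)


# ---------------------------------------------------------------------------
# curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UniaxialCurve:
    """A multilinear true-strain / true-stress loading curve at one
    (temperature, strain rate) grid point, optionally with an unloading
    branch.

    Invariants: strains strictly increasing starting at (0, 0), stresses
    non-negative, at least two points.
    """

    strains: np.ndarray
    stresses: np.ndarray
    temperature: float
    strain_rate: float
    unloading_strains: np.ndarray | None = None
    unloading_stresses: np.ndarray | None = None

    def __post_init__(self):
        strains = np.asarray(self.strains, dtype=float)
        stresses = np.asarray(self.stresses, dtype=float)
        object.__setattr__(self, "strains", strains)
        object.__setattr__(self, "stresses", stresses)
        if strains.ndim != 1 or strains.shape != stresses.shape:
            raise ValueError("strains and stresses must be 1D arrays of equal length")
        if len(strains) < 2:
            raise ValueError("a multilinear curve needs at least 2 points")
        if strains[0] != 0.0 or stresses[0] != 0.0:
            raise ValueError("first curve point must be (0, 0)")
        if np.any(np.diff(strains) <= 0):
            raise ValueError("curve strains must be strictly increasing")
        if np.any(stresses < 0):
            raise ValueError("curve stresses must be non-negative")
        if self.strain_rate <= 0:
            raise ValueError("strain rate must be positive")
        if (self.unloading_strains is None) != (self.unloading_stresses is None):
            raise ValueError("unloading strains and stresses must be given together")
        if self.unloading_strains is not None:
            us = np.asarray(self.unloading_strains, dtype=float)
            uv = np.asarray(self.unloading_stresses, dtype=float)
            object.__setattr__(self, "unloading_strains", us)
            object.__setattr__(self, "unloading_stresses", uv)
            if np.any(np.diff(us) <= 0):
                raise ValueError("unloading strains must be strictly increasing")
            if us[0] < strains[0] - 1e-12 or us[-1] > strains[-1] + 1e-12:
                raise ValueError("unloading strain range must lie within the loading range")

    # -- evaluation ---------------------------------------------------------

    def value(self, strain) -> np.ndarray:
        """Piecewise-linear evaluation; extrapolates beyond the last knot
        with the final segment's slope.  Negative strains are an error."""
        strain = np.asarray(strain, dtype=float)
        if np.any(strain < 0):
            raise ValueError("strain must be non-negative")
        y = np.interp(strain, self.strains, self.stresses)
        x_last, y_last = self.strains[-1], self.stresses[-1]
        slope = (self.stresses[-1] - self.stresses[-2]) / (self.strains[-1] - self.strains[-2])
        return np.where(strain > x_last, y_last + slope * (strain - x_last), y)

    @property
    def has_unloading(self) -> bool:
        return self.unloading_strains is not None

    def unloading_shape(self, u) -> np.ndarray:
        """Normalized unloading branch ``g(u)``: ``u`` is the fractional
        unload distance from the branch anchor (0 = anchor, 1 = zero-stress
        intercept); returns the fractional remaining stress, g(0)=1, g(1)=0.

        Falls back to a linear branch when no unloading data is stored.
        """
        u = np.clip(np.asarray(u, dtype=float), 0.0, 1.0)
        if not self.has_unloading:
            return 1.0 - u
        us, uv = self.unloading_strains, self.unloading_stresses
        top_s, top_v = us[-1], uv[-1]
        bot_s = us[0]
        span = top_s - bot_s
        if span <= 0 or top_v <= 0:
            return 1.0 - u
        # map u onto the stored branch abscissa (measured downward from the top)
        x = top_s - u * span
        g = np.interp(x, us, uv) / top_v
        return np.clip(g, 0.0, 1.0)


def curve_value(curve: UniaxialCurve, strain) -> np.ndarray:
    """Multilinear evaluation of a single curve (module-level alias)."""
    return curve.value(strain)


class CurveFamily:
    """A full (temperature × strain rate) grid of uniaxial curves.

    Every grid cell must hold exactly one curve.  Evaluation interpolates
    linearly in strain rate between bracketing curves (per temperature) and
    then linearly in temperature; strain rates outside the tested range use
    proportional scaling below the minimum rate and linear extrapolation
    from the two highest-rate curves above the maximum.  Temperatures
    outside the grid are clamped.
    """

    def __init__(self, curves: Sequence[UniaxialCurve]):
        if not curves:
            raise ValueError("empty curve family")
        self.temperatures = np.array(sorted({c.temperature for c in curves}), dtype=float)
        self.strain_rates = np.array(sorted({c.strain_rate for c in curves}), dtype=float)
        grid: dict[tuple[float, float], UniaxialCurve] = {}
        for c in curves:
            key = (c.temperature, c.strain_rate)
            if key in grid:
                raise ValueError(f"duplicate curve at {key}")
            grid[key] = c
        expected = len(self.temperatures) * len(self.strain_rates)
        if len(grid) != expected:
            raise ValueError("curves do not cover the full temperature x rate grid")
        self._grid = [
            [grid[(t, r)] for r in self.strain_rates] for t in self.temperatures
        ]

    # -- access -------------------------------------------------------------

    def curve(self, temperature: float, strain_rate: float) -> UniaxialCurve:
        it = int(np.argmin(np.abs(self.temperatures - temperature)))
        ir = int(np.argmin(np.abs(self.strain_rates - strain_rate)))
        return self._grid[it][ir]

    @property
    def curves(self) -> list[UniaxialCurve]:
        return [c for row in self._grid for c in row]

    @property
    def rate_min(self) -> float:
        return float(self.strain_rates[0])

    @property
    def rate_max(self) -> float:
        return float(self.strain_rates[-1])

    @property
    def max_strain(self) -> float:
        return min(c.strains[-1] for c in self.curves)

    def initial_modulus(self, rate: float | np.ndarray, temperature: float) -> np.ndarray:
        """Initial (elastic) slope of the interpolated equivalent curve."""
        return tangent_modulus(self, 0.0, rate, temperature)

    # -- evaluation ---------------------------------------------------------

    def _grid_values(self, strain: np.ndarray) -> np.ndarray:
        """Evaluate every grid curve at ``strain``; shape (nT, nR, n)."""
        return np.stack(
            [np.stack([c.value(strain) for c in row]) for row in self._grid]
        )

    def _combine_rate(self, S: np.ndarray, rate: np.ndarray) -> np.ndarray:
        """Collapse the rate axis of ``S`` (nT, nR, n) at per-point rates."""
        R = self.strain_rates
        nR = len(R)
        if nR == 1:
            base = S[:, 0, :]
            # single tested rate: proportional below it, clamped above
            scale = np.where(rate < R[0], rate / R[0], 1.0)
            return base * scale
        idx = np.clip(np.searchsorted(R, rate, side="left"), 1, nR - 1)
        w = (rate - R[idx - 1]) / (R[idx] - R[idx - 1])
        lo = np.take_along_axis(S, idx[None, None, :] - 1, axis=1)[:, 0, :]
        hi = np.take_along_axis(S, idx[None, None, :], axis=1)[:, 0, :]
        val = lo * (1.0 - w) + hi * w
        below = rate < R[0]
        if np.any(below):
            val = np.where(below, S[:, 0, :] * (rate / R[0]), val)
        above = rate > R[-1]
        if np.any(above):
            slope_num = S[:, -1, :] - S[:, -2, :]
            extra = S[:, -1, :] + (rate - R[-1]) / (R[-1] - R[-2]) * slope_num
            val = np.where(above, extra, val)
        return val

    def _combine_temperature(self, V: np.ndarray, temperature: float) -> np.ndarray:
        T = self.temperatures
        if len(T) == 1 or temperature <= T[0]:
            return V[0]
        if temperature >= T[-1]:
            return V[-1]
        i = int(np.searchsorted(T, temperature, side="left"))
        i = min(max(i, 1), len(T) - 1)
        w = (temperature - T[i - 1]) / (T[i] - T[i - 1])
        return V[i - 1] * (1.0 - w) + V[i] * w

    def stress(self, strain, rate, temperature: float) -> np.ndarray:
        """Equivalent stress at (strain, rate, temperature); handles both
        in-range and out-of-range strain rates.  ``strain`` and ``rate``
        broadcast; ``temperature`` is a scalar (clamped to the grid)."""
        strain = np.atleast_1d(np.asarray(strain, dtype=float))
        rate = np.broadcast_to(np.asarray(rate, dtype=float), strain.shape).copy()
        if np.any(strain < 0):
            raise ValueError("strain must be non-negative")
        if np.any(rate <= 0):
            raise ValueError("strain rate must be positive")
        S = self._grid_values(strain)
        V = self._combine_rate(S, rate)
        return self._combine_temperature(V, float(temperature))

    def unloading_shape(self, u, rate, temperature: float) -> np.ndarray:
        """Normalized unloading-branch value g(u) interpolated across the
        grid (rates clamped to the tested range for the shape)."""
        u = np.atleast_1d(np.asarray(u, dtype=float))
        rate = np.broadcast_to(np.asarray(rate, dtype=float), u.shape)
        rate = np.clip(rate, self.rate_min, self.rate_max)
        if not any(c.has_unloading for c in self.curves):
            if not getattr(self, "_warned_no_unloading", False):
                logger.warning(
                    "curve family has no unloading branches; using linear elastic unloading"
                )
                self._warned_no_unloading = True
            return 1.0 - np.clip(u, 0.0, 1.0)
        G = np.stack(
            [np.stack([c.unloading_shape(u) for c in row]) for row in self._grid]
        )
        V = self._combine_rate(G, rate)
        return np.clip(self._combine_temperature(V, float(temperature)), 0.0, 1.0)


def interpolate_equivalent_stress(family: CurveFamily, strain, rate, temperature) -> np.ndarray:
    """Bilinear (rate then temperature) interpolation of the equivalent
    stress for strain rates within the tested range."""
    rate_arr = np.atleast_1d(np.asarray(rate, dtype=float))
    if np.any(rate_arr < family.rate_min * (1 - 1e-9)) or np.any(rate_arr > family.rate_max * (1 + 1e-9)):
        raise ValueError("rate outside the tested range; use rate_out_of_range_stress")
    out = family.stress(strain, rate, temperature)
    return out if np.ndim(strain) or np.ndim(rate) else float(out[0])


def rate_out_of_range_stress(family: CurveFamily, strain, rate, temperature) -> np.ndarray:
    """Equivalent stress for strain rates outside the tested range:
    proportional scaling of the lowest-rate curve below the minimum,
    linear extrapolation from the two highest-rate curves above the
    maximum.  Continuous with the in-range interpolation at the bounds."""
    rate_arr = np.atleast_1d(np.asarray(rate, dtype=float))
    if np.any(rate_arr <= 0):
        raise ValueError("strain rate must be positive")
    out = family.stress(strain, rate, temperature)
    return out if np.ndim(strain) or np.ndim(rate) else float(out[0])


def tangent_modulus(family: CurveFamily, strain, rate, temperature, h: float = 1e-7) -> np.ndarray:
    """Slope of the interpolated equivalent curve at ``strain`` (central
    finite difference, one-sided at zero strain)."""
    strain = np.atleast_1d(np.asarray(strain, dtype=float))
    lo = np.maximum(strain - h, 0.0)
    hi = strain + h
    f_hi = family.stress(hi, rate, temperature)
    f_lo = family.stress(lo, rate, temperature)
    out = (f_hi - f_lo) / (hi - lo)
    return out if out.shape != (1,) else float(out[0])


# ---------------------------------------------------------------------------
# elastic tangent matrix
# ---------------------------------------------------------------------------

def elastic_matrix(E_T, nu: float) -> np.ndarray:
    """Isotropic tangent constitutive matrix built from the equivalent-curve
    tangent modulus ``E_T`` and Poisson ratio ``nu``.

    The shear modulus is ``G = E_T / 3`` so that the von Mises stress of the
    elastic response to any strain state equals ``E_T`` times the equivalent
    strain (σ̄ = 3 G ē); ``nu`` sets the volumetric stiffness.  Accepts a
    scalar (returns (6, 6)) or an array (returns (..., 6, 6)).
    """
    if not 0.0 < nu < 0.5:
        raise ValueError("Poisson ratio must lie in (0, 0.5)")
    E_T = np.asarray(E_T, dtype=float)
    G = E_T / 3.0
    lam = 2.0 * G * nu / (1.0 - 2.0 * nu)
    C = np.zeros(E_T.shape + (6, 6))
    for i in range(3):
        for j in range(3):
            C[..., i, j] = lam
        C[..., i, i] = lam + 2.0 * G
    for i in range(3, 6):
        C[..., i, i] = G
    return C


def elastic_compliance(E_T, nu: float) -> np.ndarray:
    """Inverse of :func:`elastic_matrix` (engineering-shear convention)."""
    E_T = np.asarray(E_T, dtype=float)
    G = E_T / 3.0
    Em = 2.0 * (1.0 + nu) * G  # Young's modulus of the matrix
    S = np.zeros(E_T.shape + (6, 6))
    for i in range(3):
        for j in range(3):
            S[..., i, j] = (-nu / Em) if i != j else (1.0 / Em)
    for i in range(3, 6):
        S[..., i, i] = 1.0 / G
    return S


@dataclass(frozen=True)
class TangentLaw:
    """Configured constants of the tangent constitutive matrix."""

    poisson_ratio: float = 0.30

    def matrix(self, E_T) -> np.ndarray:
        return elastic_matrix(E_T, self.poisson_ratio)

    def compliance(self, E_T) -> np.ndarray:
        return elastic_compliance(E_T, self.poisson_ratio)


# ---------------------------------------------------------------------------
# material point state
# ---------------------------------------------------------------------------

class Phase(IntEnum):
    LOADING = 0
    UNLOADING = 1
    RELOADING = 2


@dataclass
class GaussStateArray:
    """Struct-of-arrays state for ``n`` material (Gauss) points."""

    stress: np.ndarray          # (n, 6) MPa
    strain: np.ndarray          # (n, 6) total strain, engineering shears
    plastic: np.ndarray         # (n, 6) accumulated plastic strain
    eq: np.ndarray              # (n,) equivalent strain (deviatoric measure)
    eq_prev: np.ndarray         # (n,)
    phase: np.ndarray           # (n,) int8
    rev_strain: np.ndarray      # (n,) equivalent strain at unloading onset
    rev_stress: np.ndarray      # (n,) equivalent stress at unloading onset
    rev_residual: np.ndarray    # (n,) zero-stress intercept of the branch
    reload_origin: np.ndarray   # (n,) equivalent strain where unloading ended

    @classmethod
    def zeros(cls, n: int) -> "GaussStateArray":
        return cls(
            stress=np.zeros((n, 6)),
            strain=np.zeros((n, 6)),
            plastic=np.zeros((n, 6)),
            eq=np.zeros(n),
            eq_prev=np.zeros(n),
            phase=np.zeros(n, dtype=np.int8),
            rev_strain=np.zeros(n),
            rev_stress=np.zeros(n),
            rev_residual=np.zeros(n),
            reload_origin=np.zeros(n),
        )

    @property
    def n(self) -> int:
        return len(self.eq)

    def copy(self) -> "GaussStateArray":
        return GaussStateArray(
            **{k: getattr(self, k).copy() for k in self.__dataclass_fields__}
        )

    def equivalent_plastic_strain(self) -> np.ndarray:
        return deviatoric_equivalent_strain(self.plastic)


@dataclass
class MaterialPointState:
    """Single-point view of the phase machine (thin wrapper over a
    one-element :class:`GaussStateArray`)."""

    array: GaussStateArray = field(default_factory=lambda: GaussStateArray.zeros(1))

    @property
    def phase(self) -> Phase:
        return Phase(int(self.array.phase[0]))

    @property
    def stress(self) -> np.ndarray:
        return self.array.stress[0]

    @property
    def total_strain(self) -> np.ndarray:
        return self.array.strain[0]

    @property
    def plastic_strain(self) -> np.ndarray:
        return self.array.plastic[0]

    @property
    def equivalent_strain(self) -> float:
        return float(self.array.eq[0])

    @property
    def equivalent_strain_prev(self) -> float:
        return float(self.array.eq_prev[0])

    @property
    def reversal_strain(self) -> float:
        return float(self.array.rev_strain[0])

    @property
    def reversal_stress(self) -> float:
        return float(self.array.rev_stress[0])

    @property
    def reload_origin_strain(self) -> float:
        return float(self.array.reload_origin[0])

    def copy(self) -> "MaterialPointState":
        return MaterialPointState(self.array.copy())


# ---------------------------------------------------------------------------
# phase machine
# ---------------------------------------------------------------------------

def _transition(states: GaussStateArray, eq_new: np.ndarray, active: np.ndarray) -> None:
    """Vectorized in-place phase transitions for points flagged ``active``.

    loading → unloading when the equivalent strain drops (reversal anchor
    recorded); unloading → reloading when it rises again (reload origin
    recorded); reloading → unloading on a further drop (new anchor at the
    current point); unloading/reloading → loading once the reversal strain
    is exceeded (the branch has been retraced to the envelope).
    """
    d = eq_new - states.eq
    decreasing = active & (d < 0)
    increasing = active & (d > 0)

    to_unload = decreasing & (
        (states.phase == Phase.LOADING) | (states.phase == Phase.RELOADING)
    )
    if np.any(to_unload):
        states.rev_strain[to_unload] = states.eq[to_unload]
        states.rev_stress[to_unload] = equivalent_stress(states.stress[to_unload])
        states.rev_residual[to_unload] = deviatoric_equivalent_strain(
            states.plastic[to_unload]
        )
        states.phase[to_unload] = Phase.UNLOADING

    to_reload = increasing & (states.phase == Phase.UNLOADING)
    if np.any(to_reload):
        states.reload_origin[to_reload] = states.eq[to_reload]
        states.phase[to_reload] = Phase.RELOADING

    rejoin = increasing & (states.phase == Phase.RELOADING) & (
        eq_new >= states.rev_strain - _EQ_TOL
    )
    if np.any(rejoin):
        states.phase[rejoin] = Phase.LOADING


def phase_transition(state: MaterialPointState, new_equivalent_strain: float) -> MaterialPointState:
    """Apply the phase machine to a single point for a prospective new
    equivalent strain (state otherwise unchanged)."""
    out = state.copy()
    arr = out.array
    eq_new = np.array([float(new_equivalent_strain)])
    active = np.abs(eq_new - arr.eq) > _EQ_TOL
    _transition(arr, eq_new, active)
    arr.eq_prev[:] = arr.eq
    arr.eq[:] = eq_new
    return out


# ---------------------------------------------------------------------------
# unloading / reloading branch
# ---------------------------------------------------------------------------

def _branch_stress(
    family: CurveFamily,
    rev_strain: np.ndarray,
    rev_stress: np.ndarray,
    rev_residual: np.ndarray,
    eq: np.ndarray,
    rate: np.ndarray,
    temperature: float,
) -> np.ndarray:
    """Stress on the anchored unloading branch at equivalent strain ``eq``.

    The branch runs from the reversal anchor (rev_strain, rev_stress) down
    to zero stress at the residual strain (the equivalent plastic strain at
    reversal); its shape comes from the family's normalized unloading
    branches, interpolated across rate and temperature.  An elastic
    reversal (zero residual) retraces the loading segment linearly.
    """
    span = rev_strain - rev_residual
    safe = span > _EQ_TOL
    u = np.zeros_like(eq)
    np.divide(rev_strain - eq, span, out=u, where=safe)
    u = np.clip(u, 0.0, 1.0)
    g = family.unloading_shape(u, rate, temperature)
    elastic = rev_residual <= _EQ_TOL
    g = np.where(elastic, 1.0 - u, g)
    out = rev_stress * g
    # degenerate branch (reversal at the residual strain itself)
    out = np.where(~safe, np.where(eq >= rev_strain, rev_stress, 0.0), out)
    return out


def unloading_stress(
    family: CurveFamily,
    state: MaterialPointState,
    strain: float,
    rate: float,
    temperature: float,
) -> float:
    """Equivalent stress on the unloading branch of a single point."""
    arr = state.array
    out = _branch_stress(
        family,
        arr.rev_strain,
        arr.rev_stress,
        arr.rev_residual,
        np.array([float(strain)]),
        np.array([float(rate)]),
        temperature,
    )
    return float(out[0])


# ---------------------------------------------------------------------------
# stress update
# ---------------------------------------------------------------------------

def stress_update_batch(
    states: GaussStateArray,
    d_strain: np.ndarray,
    dt: float,
    temperature: float,
    family: CurveFamily,
    law: TangentLaw,
    rate_override: float | None = None,
    lock_transitions: bool = False,
    stiff_mask: np.ndarray | None = None,
) -> tuple[GaussStateArray, np.ndarray, np.ndarray]:
    """Vectorized three-phase stress update for ``n`` material points.

    For each point: (1) the tangent modulus and constitutive matrix are
    evaluated at the previous equivalent strain and the current equivalent
    strain rate; (2) a trial stress ``σ_t + C^E Δe`` is formed; (3) the
    target equivalent stress at the updated equivalent strain is read from
    the loading envelope (or the anchored unloading branch), and the stress
    ratio ``r = σ̄_target / σ̄_trial`` computed; (4) the final stress is the
    radially scaled trial stress; (5) the scaled tangent ``r C^E`` is
    reported for assembly.  The elastic/plastic split ``Δe = Δe^E + Δe^P``
    with ``Δe^E = (C^E)^{-1}(σ_final − σ_t)`` is accumulated exactly.

    Parameters
    ----------
    rate_override
        When given, the equivalent strain rate used for curve lookup is
        this nominal value rather than ``|Δē|/dt`` (the protocols' nominal
        rate-class mode).
    lock_transitions
        Skip the phase machine (phases and reversal anchors stay as
        committed) — used by the equilibrium iteration to freeze the active
        phase set near convergence and suppress iteration chatter.

    Returns
    -------
    (new_states, r_stress, E_T) — the scaled tangent matrix for point ``i``
    is ``r_stress[i] * elastic_matrix(E_T[i], nu)``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    d_strain = np.asarray(d_strain, dtype=float)
    n = states.n
    out = states.copy()

    e_new = states.strain + d_strain
    eq_new = deviatoric_equivalent_strain(e_new)
    d_eq = eq_new - states.eq
    active = np.abs(d_eq) > _EQ_TOL

    r_all = np.ones(n)
    if rate_override is not None:
        rate = np.full(n, float(rate_override))
    else:
        rate = np.maximum(np.abs(d_eq) / dt, 1e-16)
    E0 = float(family.initial_modulus(float(np.median(rate)), temperature))
    E_T = np.full(n, E0)

    if not np.any(active):
        return out, r_all, E_T

    if not lock_transitions:
        _transition(out, eq_new, active)

    idx = np.nonzero(active)[0]
    ph = out.phase[idx]
    loading = ph == Phase.LOADING

    # tangent modulus: envelope slope at the previous equivalent strain for
    # loading points, initial modulus for unloading/reloading points.
    # Points flagged in ``stiff_mask`` (the equilibrium iteration marks
    # Gauss points whose phase keeps flipping between iterations) get the
    # initial modulus as well: their one-sided stiffness in the unloading
    # direction is the elastic one, and assembling the softer envelope
    # slope there makes the iteration non-contractive.
    E_T[idx[loading]] = np.atleast_1d(
        tangent_modulus(family, states.eq[idx[loading]], rate[idx[loading]], temperature)
    )
    if stiff_mask is not None and np.any(stiff_mask):
        E_T[stiff_mask] = E0
    E_T = np.maximum(E_T, 1e-9 * max(E0, 1.0))

    C = law.matrix(E_T[idx])                       # (m, 6, 6)
    d_e = d_strain[idx]
    sigma_trial = states.stress[idx] + np.einsum("nij,nj->ni", C, d_e)
    vm_trial = equivalent_stress(sigma_trial)

    target = np.empty(len(idx))
    if np.any(loading):
        target[loading] = family.stress(
            eq_new[idx[loading]], rate[idx[loading]], temperature
        )
    branch = ~loading
    if np.any(branch):
        j = idx[branch]
        target[branch] = _branch_stress(
            family,
            out.rev_strain[j],
            out.rev_stress[j],
            out.rev_residual[j],
            eq_new[j],
            rate[j],
            temperature,
        )

    r = np.where(vm_trial > 1e-12, target / np.where(vm_trial > 1e-12, vm_trial, 1.0), 1.0)
    sigma_final = r[:, None] * sigma_trial

    # elastic/plastic split with the *initial* (elastic) modulus at each
    # point's rate: on the hardening plateau the tangent modulus would count
    # nearly all deformation as elastic, which is not the physical split
    E0_pt = np.atleast_1d(tangent_modulus(family, np.zeros(len(idx)), rate[idx], temperature))
    S = law.compliance(np.maximum(E0_pt, 1e-9 * max(E0, 1.0)))
    d_elastic = np.einsum("nij,nj->ni", S, sigma_final - states.stress[idx])
    d_plastic = d_e - d_elastic

    out.stress[idx] = sigma_final
    out.strain[idx] = e_new[idx]
    out.plastic[idx] = states.plastic[idx] + d_plastic
    out.eq_prev[idx] = states.eq[idx]
    out.eq[idx] = eq_new[idx]
    r_all[idx] = r
    return out, r_all, E_T


def stress_update(
    state: MaterialPointState,
    strain_increment: np.ndarray,
    dt: float,
    temperature: float,
    family: CurveFamily,
    law: TangentLaw,
    rate_override: float | None = None,
) -> MaterialPointState:
    """Single-point stress update (see :func:`stress_update_batch`)."""
    arr, _, _ = stress_update_batch(
        state.array,
        np.asarray(strain_increment, dtype=float).reshape(1, 6),
        dt,
        temperature,
        family,
        law,
        rate_override=rate_override,
    )
    return MaterialPointState(arr)
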