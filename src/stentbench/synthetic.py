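"""Synthetic fixtures: PLLA-like curve families, strain paths, mini meshes.

The curve generator emulates the qualitative behaviour of semi-crystalline
PLLA under uniaxial tension: a stiff initial elastic segment (~3 GPa), a
yield point near 2% strain and ~60 MPa, a mildly hardening plastic region,
with stress increasing with strain rate and decreasing with temperature.
Reference condition is 25 °C at 0.01 1/s.  These are representative
magnitudes for the polymer class, not measurements of any proprietary
material.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .material import CurveFamily, UniaxialCurve

__all__ = ["SyntheticMaterialSpec", "make_curve_family", "make_strain_path", "make_mini_stent"]

DEFAULT_TEMPERATURES = (25.0, 37.0, 48.0)
DEFAULT_RATES = (0.001, 0.01, 0.1)


@dataclass(frozen=True)
class SyntheticMaterialSpec:
    """Parameters of the synthetic PLLA-like material.

    elastic_modulus
        Initial slope E0 [MPa] at the reference condition.
    yield_strain
        True strain at yield; yield stress = E0 * yield_strain.
    hardening_modulus
        Post-yield slope [MPa].
    rate_factor
        Multiplicative stress increase per decade of strain rate.
    temperature_softening
        Fractional stress decrease per °C above the reference temperature.
    knots
        Number of curve points (>= 3: origin, yield, hardening knots).
    max_strain
        Final knot strain.
    unloading_curvature
        Exponent c of the unloading branch sigma ~ s^c; the branch's initial
        slope is pinned to E0 by stretching its strain span by c.
    """

    elastic_modulus: float = 3000.0
    yield_strain: float = 0.02
    hardening_modulus: float = 40.0
    rate_factor: float = 0.08
    temperature_softening: float = 0.008
    knots: int = 6
    max_strain: float = 0.30
    unloading_curvature: float = 1.5
    reference_temperature: float = 25.0
    reference_rate: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.elastic_modulus <= 0:
            raise ValueError("elastic modulus must be positive")
        if not 0 < self.yield_strain < 0.1:
            raise ValueError("yield strain must lie in (0, 0.1)")
        if self.hardening_modulus < 0 or self.rate_factor <= 0:
            raise ValueError("hardening modulus and rate factor must be positive")
        if self.knots < 3:
            raise ValueError("need at least 3 knots")


def _stress_multiplier(spec: SyntheticMaterialSpec, temperature: float, rate: float) -> float:
    m_rate = 1.0 + spec.rate_factor * np.log10(rate / spec.reference_rate)
    m_temp = 1.0 - spec.temperature_softening * (temperature - spec.reference_temperature)
    return max(float(m_rate * m_temp), 1e-3)


def _base_curve(spec: SyntheticMaterialSpec) -> tuple[np.ndarray, np.ndarray]:
    ey, E0, H = spec.yield_strain, spec.elastic_modulus, spec.hardening_modulus
    sy = E0 * ey
    plastic_knots = np.geomspace(2 * ey, spec.max_strain, spec.knots - 2)
    strains = np.concatenate([[0.0, ey], plastic_knots])
    stresses = np.concatenate([[0.0, sy], sy + H * (plastic_knots - ey)])
    return strains, stresses


def _unloading_branch(
    spec: SyntheticMaterialSpec, strains: np.ndarray, stresses: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Unloading branch attached at the curve end: power-law shape with
    exponent c, strain span c * sigma_top / E0 so the initial (top) slope
    equals the elastic modulus, zero-stress intercept strictly inside the
    loading strain range."""
    c = spec.unloading_curvature
    e_top, s_top = float(strains[-1]), float(stresses[-1])
    span = min(c * s_top / spec.elastic_modulus, 0.9 * e_top)
    e_res = e_top - span
    s = np.linspace(0.0, 1.0, 12)
    ue = e_res + s * span
    uv = s_top * s**c
    uv[0] = 0.0
    return ue, uv


def make_curve_family(
    spec: SyntheticMaterialSpec | None = None,
    temperatures=DEFAULT_TEMPERATURES,
    rates=DEFAULT_RATES,
    with_unloading: bool = True,
) -> CurveFamily:
    """Full (temperature x rate) grid of multilinear curves.

    Stress is pointwise non-decreasing in rate and non-increasing in
    temperature by construction (whole-curve multipliers); deterministic.
    """
    spec = spec or SyntheticMaterialSpec()
    base_e, base_s = _base_curve(spec)
    curves = []
    for T in temperatures:
        for r in rates:
            m = _stress_multiplier(spec, T, r)
            e, s = base_e, base_s * m
            if with_unloading:
                ue, uv = _unloading_branch(spec, e, s)
                curves.append(
                    UniaxialCurve(e, s, temperature=T, strain_rate=r,
                                  unloading_strains=ue, unloading_stresses=uv)
                )
            else:
                curves.append(UniaxialCurve(e, s, temperature=T, strain_rate=r))
    return CurveFamily(curves)


def make_strain_path(kind: str, amplitude: float, n_steps: int, n_cycles: int = 2) -> np.ndarray:
    """Deterministic scalar strain path for the material-point driver.

    ``monotonic``: 0 -> amplitude; ``load_unload``: 0 -> amplitude -> 0;
    ``cyclic``: ``n_cycles`` triangles 0 -> amplitude -> 0.  The returned
    array excludes the initial zero state.
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    if n_steps < 2:
        raise ValueError("need at least 2 steps")
    if kind == "monotonic":
        return np.linspace(0.0, amplitude, n_steps + 1)[1:]
    if kind == "load_unload":
        up = np.linspace(0.0, amplitude, n_steps // 2 + 1)[1:]
        down = np.linspace(amplitude, 0.0, n_steps - n_steps // 2 + 1)[1:]
        return np.concatenate([up, down])
    if kind == "cyclic":
        per = max(n_steps // n_cycles, 2)
        one = make_strain_path("load_unload", amplitude, per)
        return np.concatenate([one] * n_cycles)
    raise ValueError(f"unknown path kind: {kind!r}")


def make_mini_stent(n_crowns: int = 4, n_rings: int = 2, scale: float = 1.0,
                    wall_thickness: float = 0.16, with_slots: bool = False,
                    n_width: int | None = None):
    """Tiny but valid scaffold mesh for fast end-to-end protocol tests.

    A scaled-down two-ring design (outer radius ``1.6 * scale`` mm) meshed
    at desk density; deterministic; <= ~1500 elements.  For slot-pair
    comparisons pass the same explicit ``n_width`` (>= 4) to both variants
    so the meshes differ only by the removed slot elements.
    """
    from .geometry import StentDesign, generate_stent_mesh

    if n_width is None:
        n_width = 4 if with_slots else 2
    design = StentDesign(
        outer_radius=1.6 * scale,
        inner_radius=(1.6 - wall_thickness) * scale,
        length=4.0 * scale,
        n_rings=n_rings,
        crowns_per_ring=n_crowns,
        n_connectors=min(2, n_crowns),
        strut_width=0.45 * scale,
        slot_spec={"length": 0.5 * scale, "width": 0.15 * scale} if with_slots else None,
        n_thickness=2,
        n_width=n_width,
    )
    return generate_stent_mesh(design)
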