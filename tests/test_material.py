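"""Constitutive model: equivalent measures, curve evaluation, the phase
machine and the radial stress-ratio update."""

import numpy as np
import pytest

from stentbench.material import (
    MaterialPointState,
    Phase,
    TangentLaw,
    UniaxialCurve,
    curve_value,
    deviatoric_equivalent_strain,
    elastic_compliance,
    elastic_matrix,
    equivalent_strain,
    equivalent_stress,
    phase_transition,
    stress_update,
    tangent_modulus,
    unloading_stress,
)
from stentbench.synthetic import make_curve_family


def _voigt_to_tensor(v):
    return np.array(
        [[v[0], v[3], v[5]], [v[3], v[1], v[4]], [v[5], v[4], v[2]]]
    )


# ---------------------------------------------------------------------------
# equivalent measures
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "voigt,expected",
    [
        ([50.0, 0, 0, 0, 0, 0], 50.0),                 # uniaxial
        ([7.0, 7.0, 7.0, 0, 0, 0], 0.0),               # hydrostatic
        ([0, 0, 0, 4.0, 0, 0], 4.0 * np.sqrt(3.0)),    # pure shear
    ],
)
def test_equivalent_stress_closed_forms(voigt, expected):
    assert equivalent_stress(np.array(voigt)) == pytest.approx(expected, abs=1e-12)


def test_equivalent_stress_matches_principal_value_oracle(rng):
    """Von Mises from components equals the principal-stress formula
    computed by eigen-decomposition (brute force) on random tensors."""
    v = rng.normal(scale=80.0, size=(10_000, 6))
    got = equivalent_stress(v)
    for i in rng.choice(10_000, size=200, replace=False):
        s1, s2, s3 = np.linalg.eigvalsh(_voigt_to_tensor(v[i]))
        ref = np.sqrt(0.5 * ((s1 - s2) ** 2 + (s2 - s3) ** 2 + (s3 - s1) ** 2))
        assert abs(got[i] - ref) <= 1e-9 * max(ref, 1.0)


def test_equivalent_stress_hydrostatic_invariance(rng):
    v = rng.normal(scale=50.0, size=(500, 6))
    shifted = v.copy()
    shifted[:, :3] += 123.456
    np.testing.assert_allclose(equivalent_stress(v), equivalent_stress(shifted), atol=1e-9)


@pytest.mark.parametrize(
    "voigt,expected",
    [
        ([0.03, -0.015, -0.015, 0, 0, 0], 0.03),       # incompressible uniaxial
        ([0, 0, 0, 0, 0, 0], 0.0),
        ([0, 0, 0, 0.06, 0, 0], 0.06 / np.sqrt(3.0)),  # engineering shear
    ],
)
def test_equivalent_strain_closed_forms(voigt, expected):
    assert equivalent_strain(np.array(voigt)) == pytest.approx(expected, abs=1e-14)


def test_equivalent_strain_matches_formula_oracle(rng):
    e = rng.normal(scale=0.05, size=(10_000, 6))
    ref = np.sqrt(
        2.0 / 3.0 * (e[:, 0] ** 2 + e[:, 1] ** 2 + e[:, 2] ** 2)
        + (e[:, 3] ** 2 + e[:, 4] ** 2 + e[:, 5] ** 2) / 3.0
    )
    np.testing.assert_allclose(equivalent_strain(e), ref, atol=1e-12)


def test_deviatoric_measure_equals_plain_measure_for_traceless(rng):
    e = rng.normal(scale=0.05, size=(100, 6))
    e[:, 2] = -(e[:, 0] + e[:, 1])  # traceless
    np.testing.assert_allclose(
        deviatoric_equivalent_strain(e), equivalent_strain(e), atol=1e-14
    )


# ---------------------------------------------------------------------------
# curves
# ---------------------------------------------------------------------------

@pytest.fixture
def simple_curve():
    return UniaxialCurve([0.0, 0.02, 0.1], [0.0, 60.0, 70.0], temperature=25.0, strain_rate=0.01)


def test_curve_value_interpolation_and_extrapolation(simple_curve):
    assert curve_value(simple_curve, 0.01) == pytest.approx(30.0)
    assert curve_value(simple_curve, 0.02) == pytest.approx(60.0)
    # beyond the last knot: final segment slope 125 MPa x 0.04 extra
    assert curve_value(simple_curve, 0.14) == pytest.approx(75.0)
    with pytest.raises(ValueError):
        curve_value(simple_curve, -0.01)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(strains=[0.0], stresses=[0.0]),                     # too few points
        dict(strains=[0.01, 0.02], stresses=[1.0, 2.0]),         # no origin
        dict(strains=[0.0, 0.02, 0.01], stresses=[0, 1, 2]),     # not increasing
        dict(strains=[0.0, 0.02], stresses=[0.0, -5.0]),         # negative stress
    ],
)
def test_curve_invariants_rejected(kwargs):
    with pytest.raises(ValueError):
        UniaxialCurve(temperature=25.0, strain_rate=0.01, **kwargs)


def test_tangent_modulus_single_curve_segment_slopes(simple_curve):
    from stentbench.material import CurveFamily

    fam = CurveFamily([simple_curve])
    assert tangent_modulus(fam, 0.01, 0.01, 25.0) == pytest.approx(3000.0, rel=1e-4)
    assert tangent_modulus(fam, 0.05, 0.01, 25.0) == pytest.approx(125.0, rel=1e-4)


def test_tangent_modulus_matches_central_difference(family):
    h = 1e-5
    for e in (0.005, 0.03, 0.12):
        ref = (family.stress(e + h, 0.03, 30.0) - family.stress(e - h, 0.03, 30.0)) / (2 * h)
        got = tangent_modulus(family, e, 0.03, 30.0)
        assert got == pytest.approx(float(ref[0]), rel=1e-3)


# ---------------------------------------------------------------------------
# tangent matrix
# ---------------------------------------------------------------------------

def test_elastic_matrix_spd_and_vonmises_consistent(rng):
    C = elastic_matrix(3000.0, 0.3)
    assert np.allclose(C, C.T)
    assert np.all(np.linalg.eigvalsh(C) > 0)
    # elastic identity: vm(C e) = E_T * deviatoric equivalent strain
    e = rng.normal(scale=0.01, size=(50, 6))
    s = e @ C.T
    np.testing.assert_allclose(
        equivalent_stress(s), 3000.0 * deviatoric_equivalent_strain(e), rtol=1e-12
    )
    with pytest.raises(ValueError):
        elastic_matrix(3000.0, 0.6)


def test_compliance_is_inverse(law):
    C = elastic_matrix(1234.0, 0.3)
    S = elastic_compliance(1234.0, 0.3)
    np.testing.assert_allclose(C @ S, np.eye(6), atol=1e-12)


# ---------------------------------------------------------------------------
# stress update
# ---------------------------------------------------------------------------

def _drive_uniaxial(family, law, strains, rate, T):
    """Drive a single point along an incompressible uniaxial strain path at
    a fixed equivalent strain rate; returns (eq strain, vm stress) trace."""
    state = MaterialPointState()
    prev = 0.0
    out = []
    for e in strains:
        de = e - prev
        prev = e
        inc = np.array([de, -de / 2.0, -de / 2.0, 0.0, 0.0, 0.0])
        dt = max(abs(de) / rate, 1e-12)
        state = stress_update(state, inc, dt, T, family, law)
        out.append((state.equivalent_strain, float(equivalent_stress(state.stress)), state))
    return out


def test_zero_increment_is_identity(family, law):
    state = MaterialPointState()
    state = stress_update(state, np.array([0.01, -0.005, -0.005, 0, 0, 0]), 1.0, 25.0, family, law)
    before = state.copy()
    after = stress_update(state, np.zeros(6), 1.0, 25.0, family, law)
    np.testing.assert_array_equal(after.stress, before.stress)
    np.testing.assert_array_equal(after.plastic_strain, before.plastic_strain)
    assert after.phase == before.phase


def test_uniaxial_drive_reproduces_grid_curve(family, law):
    """The model's defining property: a point driven at a tested (rate, T)
    reproduces the input multilinear curve."""
    rate, T = 0.01, 25.0
    trace = _drive_uniaxial(family, law, np.linspace(0, 0.12, 60)[1:], rate, T)
    for eq, vm, _ in trace[1:]:
        target = float(family.stress(eq, rate, T)[0])
        assert vm == pytest.approx(target, rel=5e-3)


def test_elastic_segment_accumulates_no_plastic_strain(family, law):
    trace = _drive_uniaxial(family, law, np.linspace(0, 0.012, 12)[1:], 0.01, 25.0)
    _, _, state = trace[-1]
    assert np.linalg.norm(state.plastic_strain) < 1e-9


def test_plastic_strain_monotone_under_monotonic_loading(family, law):
    trace = _drive_uniaxial(family, law, np.linspace(0, 0.12, 40)[1:], 0.01, 37.0)
    norms = [np.linalg.norm(s.plastic_strain) for _, _, s in trace]
    assert all(b >= a - 1e-14 for a, b in zip(norms, norms[1:]))
    assert norms[-1] > 1e-4  # well past yield


def test_strain_decomposition_exact_in_loading(family, law):
    """Per-step: the plastic increment equals the total increment minus the
    compliance times the stress increment (to machine precision)."""
    rate, T = 0.01, 25.0
    state = MaterialPointState()
    prev_e, prev_sig, prev_p = 0.0, np.zeros(6), np.zeros(6)
    E0 = float(tangent_modulus(family, 0.0, rate, T))
    for e in np.linspace(0, 0.08, 30)[1:]:
        de_ax = e - prev_e
        inc = np.array([de_ax, -de_ax / 2, -de_ax / 2, 0, 0, 0])
        new = stress_update(state, inc, de_ax / rate, T, family, law)
        if new.phase == Phase.LOADING:
            d_el = elastic_compliance(E0, law.poisson_ratio) @ (
                new.stress - prev_sig
            )
            d_pl = new.plastic_strain - prev_p
            np.testing.assert_allclose(d_el + d_pl, inc, atol=1e-13)
        prev_e, prev_sig, prev_p = e, new.stress.copy(), new.plastic_strain.copy()
        state = new


# ---------------------------------------------------------------------------
# phase machine / hysteresis
# ---------------------------------------------------------------------------

def test_phase_transitions_follow_strain_direction(family, law):
    state = MaterialPointState()
    state = phase_transition(state, 0.05)
    assert state.phase == Phase.LOADING
    state = phase_transition(state, 0.03)
    assert state.phase == Phase.UNLOADING
    assert state.reversal_strain == pytest.approx(0.05)
    state = phase_transition(state, 0.04)
    assert state.phase == Phase.RELOADING
    assert state.reload_origin_strain == pytest.approx(0.03)
    state = phase_transition(state, 0.06)
    assert state.phase == Phase.LOADING


def test_monotonic_path_stays_loading(family, law):
    trace = _drive_uniaxial(family, law, np.linspace(0, 0.1, 25)[1:], 0.01, 25.0)
    assert all(s.phase == Phase.LOADING for _, _, s in trace)


def test_postyield_unloading_has_positive_residual_strain(family, law):
    """Unloading from beyond yield reaches zero stress at positive strain."""
    up = np.linspace(0, 0.08, 30)[1:]
    down = np.linspace(0.08, 0.0, 40)[1:]
    trace = _drive_uniaxial(family, law, np.concatenate([up, down]), 0.01, 25.0)
    eqs = np.array([t[0] for t in trace])
    vms = np.array([t[1] for t in trace])
    # the stress first vanishes while the equivalent strain is still
    # clearly positive: the plastic residual
    first_zero = int(np.argmax(vms < 1e-3 * vms.max()))
    assert vms[first_zero] < 1e-3 * vms.max()
    assert eqs[first_zero] > 0.02


def test_elastic_reversal_retraces_loading_line(family, law):
    up = np.linspace(0, 0.012, 10)[1:]
    down = np.linspace(0.012, 0.002, 10)[1:]
    trace = _drive_uniaxial(family, law, np.concatenate([up, down]), 0.01, 25.0)
    E0 = float(tangent_modulus(family, 0.0, 0.01, 25.0))
    for eq, vm, s in trace:
        assert vm == pytest.approx(E0 * eq, rel=1e-6)


def test_reload_rejoins_loading_envelope(family, law):
    """Closed load-unload-reload loop rejoins the envelope within 1% at a
    strain 20% beyond the reversal point."""
    rate, T = 0.01, 25.0
    up = np.linspace(0, 0.06, 30)[1:]
    down = np.linspace(0.06, 0.035, 15)[1:]
    re_up = np.linspace(0.035, 0.075, 25)[1:]
    trace = _drive_uniaxial(family, law, np.concatenate([up, down, re_up]), rate, T)
    eq_end, vm_end, state_end = trace[-1]
    envelope = float(family.stress(eq_end, rate, T)[0])
    assert vm_end == pytest.approx(envelope, rel=1e-2)
    assert state_end.phase == Phase.LOADING


def test_unloading_stress_anchor_continuity(family):
    state = MaterialPointState()
    arr = state.array
    arr.phase[0] = Phase.UNLOADING
    arr.rev_strain[0] = 0.06
    arr.rev_stress[0] = 62.0
    arr.rev_residual[0] = 0.04
    assert unloading_stress(family, state, 0.06, 0.01, 25.0) == pytest.approx(62.0)
    assert unloading_stress(family, state, 0.04, 0.01, 25.0) == pytest.approx(0.0, abs=1e-9)
    mid = unloading_stress(family, state, 0.05, 0.01, 25.0)
    assert 0.0 < mid < 62.0


def test_unloading_without_branches_falls_back_linear(law):
    fam = make_curve_family(with_unloading=False)
    up = np.linspace(0, 0.06, 20)[1:]
    down = np.linspace(0.06, 0.02, 20)[1:]
    trace = _drive_uniaxial(fam, law, np.concatenate([up, down]), 0.01, 25.0)
    assert trace[-1][1] >= 0.0  # runs, non-negative stress


# ---------------------------------------------------------------------------
# property-based invariants
# ---------------------------------------------------------------------------

from hypothesis import given, settings, strategies as st

_component = st.floats(-200.0, 200.0, allow_nan=False)
_tensor6 = st.tuples(*([_component] * 6)).map(np.array)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(_tensor6, st.floats(-100.0, 100.0))
def test_equivalent_stress_invariances(v, p):
    """Von Mises: non-negative, invariant to hydrostatic shifts, and
    1-homogeneous under scaling."""
    vm = float(equivalent_stress(v))
    assert vm >= 0.0
    shifted = v.copy()
    shifted[:3] += p
    assert float(equivalent_stress(shifted)) == pytest.approx(vm, abs=1e-9)
    assert float(equivalent_stress(2.0 * v)) == pytest.approx(2.0 * vm, rel=1e-12)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.floats(0.0, 0.28, allow_nan=False),
    st.floats(1e-4, 1.0, allow_nan=False),
    st.floats(10.0, 60.0, allow_nan=False),
)
def test_family_lookup_bracketed_by_extreme_curves(strain, rate, temperature):
    """For rates within the tested range the interpolated stress lies
    between the slowest and fastest curves at the clamped temperature."""
    family = make_curve_family()
    got = float(family.stress(strain, rate, temperature)[0])
    T = float(np.clip(temperature, family.temperatures[0], family.temperatures[-1]))
    lo_T, hi_T = family.temperatures[0], family.temperatures[-1]
    lo = min(float(family.curve(t, family.strain_rates[0]).value(strain)) for t in (lo_T, hi_T))
    hi = max(float(family.curve(t, family.strain_rates[-1]).value(strain)) for t in (lo_T, hi_T))
    if rate < family.rate_min:
        lo = 0.0
    if rate > family.rate_max:
        hi *= rate / family.rate_max  # crude bound above the tested range
    assert lo - 1e-9 <= got <= hi + 1e-9
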