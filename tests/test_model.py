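"""Unit and property tests for the switched model core."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lvadopt.model import (
    CANONICAL_PHASES,
    Contraction,
    ModelParameters,
    PhaseMode,
    PhaseSchedule,
    PumpSpeedProfile,
    Scenario,
    Valve,
    aortic_flow,
    contraction_force,
    dwell_residuals,
    enumerate_subsystems,
    evaluate_rhs,
    mitral_flow,
    phase_conditions,
    rhs_matrices,
    volume_weights,
)


@pytest.fixture(scope="module")
def params():
    return ModelParameters()


# ---------------------------------------------------------------------------
# valve laws
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "fn,up,down,r,expected",
    [
        (mitral_flow, 10.0, 10.0, 0.1, 0.0),        # equal pressures
        (mitral_flow, 11.0, 10.0, 0.1, 10.0),       # forward drop
        (mitral_flow, 10.0, 11.0, 0.1, 0.0),        # reverse drop: diode blocks
        (aortic_flow, 100.0, 100.0, 0.5, 0.0),
        (aortic_flow, 100.0, 90.0, 0.5, 20.0),
        (aortic_flow, 80.0, 100.0, 0.5, 0.0),
    ],
)
def test_valve_diode_law(fn, up, down, r, expected):
    assert fn(up, down, r) == pytest.approx(expected)


def test_valve_fixed_regimes_ignore_pressure_ordering():
    # closed valve blocks a forward drop; open valve conducts a reverse drop
    assert mitral_flow(11.0, 10.0, 0.1, regime=Valve.CLOSED) == 0.0
    assert mitral_flow(10.0, 11.0, 0.1, regime=Valve.OPEN) == pytest.approx(-10.0)
    assert aortic_flow(80.0, 100.0, 0.5, regime=Valve.OPEN) == pytest.approx(-40.0)


@pytest.mark.parametrize("bad_r", [0.0, -0.1])
def test_valve_rejects_nonpositive_resistance(bad_r):
    with pytest.raises(ValueError):
        mitral_flow(11.0, 10.0, bad_r)
    with pytest.raises(ValueError):
        aortic_flow(100.0, 90.0, bad_r)


# ---------------------------------------------------------------------------
# contraction force
# ---------------------------------------------------------------------------

def test_contraction_force_magnitudes_and_signs(params):
    # atrial contraction pulls toward -S_D (negative), ventricular toward +S_D
    assert contraction_force(Contraction.ZERO, params) == 0.0
    assert contraction_force(Contraction.VC, params) == pytest.approx(4709.0)
    assert abs(contraction_force(Contraction.AC, params)) == pytest.approx(900.0)
    assert contraction_force(Contraction.AC, params) < 0.0


def test_contraction_force_unknown_mode_rejected(params):
    with pytest.raises(ValueError):
        contraction_force("sustained", params)


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------

def test_rhs_position_rate_is_velocity(params):
    x = np.array([12.0, 8.0, 70.0, 68.0, 16.0, 50.0, 10.0, 3.2, 0.1])
    dx = evaluate_rhs(x, 8000.0, params, CANONICAL_PHASES[0])
    assert dx[8] == pytest.approx(3.2)


def test_rhs_venous_pressure_stationary_when_equilibrated(params):
    # P_S = P_V and P_LA = P_V: both venous exchange terms vanish
    x = np.array([16.0, 8.0, 70.0, 16.0, 16.0, 50.0, 10.0, 0.0, 0.1])
    dx = evaluate_rhs(x, 0.0, params, CANONICAL_PHASES[6])
    assert dx[4] == pytest.approx(0.0, abs=1e-12)


def test_rhs_aortic_pressure_stationary_without_flows(params):
    # closed aortic valve, no pump or aortic flow
    mode = PhaseMode(Contraction.ZERO, Valve.CLOSED, Valve.CLOSED)
    x = np.array([12.0, 8.0, 70.0, 68.0, 16.0, 0.0, 0.0, 0.0, 0.1])
    A, b0, b_u = rhs_matrices(params, mode, include_lvad=False)
    dx = A @ x + b0
    assert dx[2] == pytest.approx(0.0, abs=1e-12)


def test_rhs_rejects_nonfinite_input(params):
    x = np.full(9, np.nan)
    with pytest.raises(ValueError):
        evaluate_rhs(x, 0.0, params, CANONICAL_PHASES[0])


_state = st.tuples(
    st.floats(0.0, 40.0), st.floats(0.0, 150.0), st.floats(20.0, 150.0),
    st.floats(20.0, 150.0), st.floats(0.0, 40.0), st.floats(-200.0, 500.0),
    st.floats(-100.0, 300.0), st.floats(-20.0, 20.0), st.floats(-0.5, 0.5),
).map(np.array)


@given(x=_state, u=st.floats(0.0, 15000.0), mode_idx=st.integers(0, 11))
def test_volume_bookkeeping_identity(x, u, mode_idx):
    """Total stressed volume w^T x is conserved by every subsystem: the sum
    of compartment volume rates C_i dP_i equals (A_LA + (1+k)A_LV) v."""
    params = ModelParameters()
    mode = enumerate_subsystems()[mode_idx]
    dx = evaluate_rhs(x, u, params, mode)
    w = volume_weights(params)
    assert w @ dx == pytest.approx(0.0, abs=1e-8 * max(1.0, np.max(np.abs(dx))))
    piston = (params.A_LA + (1 + params.k_RAD) * params.A_LV) * x[7]
    compart = (
        params.C_LA * dx[0] + params.C_LV * dx[1] + params.C_A * dx[2]
        + params.C_S * dx[3] + params.C_V * dx[4]
    )
    assert compart == pytest.approx(piston, rel=1e-9, abs=1e-6)


@given(x=_state, u=st.floats(0.0, 15000.0), phase_idx=st.integers(0, 6))
def test_fixed_mode_rhs_matches_free_regime_when_conditions_hold(x, u, phase_idx):
    """On states satisfying a canonical mode's validity conditions, the
    phase-fixed dynamics coincide with the free (diode-law) dynamics."""
    params = ModelParameters()
    mode = CANONICAL_PHASES[phase_idx]
    conds = phase_conditions(mode, params)
    if not all(fn(x) > 1e-9 for _, fn in conds):
        return  # state outside the mode's validity region
    fixed = evaluate_rhs(x, u, params, mode)
    free = evaluate_rhs(x, u, params, None, contraction=mode.contraction)
    np.testing.assert_allclose(fixed, free, rtol=1e-12, atol=1e-12)


def test_free_regime_valve_flows_never_negative(params):
    rng = np.random.default_rng(0)
    for _ in range(200):
        p_la, p_lv, p_a = rng.uniform(0, 150, 3)
        assert mitral_flow(p_la, p_lv, params.R_M) >= 0.0
        assert aortic_flow(p_lv, p_a, params.R_AoV) >= 0.0


# ---------------------------------------------------------------------------
# mode combinatorics and phase conditions
# ---------------------------------------------------------------------------

def test_subsystem_enumeration():
    modes = enumerate_subsystems()
    assert len(modes) == 12
    assert len(set(modes)) == 12  # each combination exactly once
    assert set(CANONICAL_PHASES) <= set(modes)
    assert len(set(CANONICAL_PHASES)) == 7


def test_phase_conditions_examples(params):
    ac = CANONICAL_PHASES[0]
    x = np.zeros(9)
    x[8] = -params.S_D + 0.01
    name_to_fn = dict(phase_conditions(ac, params))
    assert name_to_fn["s_above_base"](x) > 0  # AC valid just above the stop

    closed_mv = dict(phase_conditions(CANONICAL_PHASES[2], params))
    x = np.zeros(9)
    x[0] = x[1] = 15.0  # equal pressures sit on the closed-valve boundary
    assert closed_mv["mitral_no_drop"](x) == pytest.approx(0.0)

    open_aov = dict(phase_conditions(CANONICAL_PHASES[3], params))
    x = np.zeros(9)
    x[1], x[2] = 80.0, 100.0
    assert open_aov["aortic_forward_drop"](x) < 0  # violated


# ---------------------------------------------------------------------------
# schedules and speed profiles
# ---------------------------------------------------------------------------

def test_schedule_requires_strict_ordering():
    with pytest.raises(ValueError):
        PhaseSchedule(t0=0.0, tf=0.89, tau=(0.1, 0.1, 0.2, 0.3, 0.4, 0.5))
    sched = PhaseSchedule(t0=0.0, tf=0.89, tau=(0.1, 0.15, 0.2, 0.3, 0.4, 0.5))
    assert np.all(sched.durations > 0)
    assert sched.durations.sum() == pytest.approx(0.89)


def test_speed_profile_validation_and_evaluation():
    with pytest.raises(ValueError):
        PumpSpeedProfile.constant(20000.0, u_ub=18000.0)
    pwc = PumpSpeedProfile(
        scenario=Scenario.PWC, levels=(9000.0, 4000.0, 11000.0),
        switch_times=(0.2, 0.4, 0.7), tf=0.89,
    )
    t = np.array([0.1, 0.3, 0.5, 0.8])
    np.testing.assert_allclose(pwc(t), [9000.0, 4000.0, 11000.0, 9000.0])
    with pytest.raises(ValueError):
        PumpSpeedProfile(
            scenario=Scenario.PWC, levels=(9000.0, 4000.0, 11000.0),
            switch_times=(0.4, 0.2, 0.7), tf=0.89,
        )


def test_dwell_residuals_wrap_around_cycle_end():
    # level-1 dwell wraps: t1 - t0 + tf - t3 >= D1
    res = dwell_residuals(0.2, 0.5, 0.8, 0.0, 0.88, (0.25, 0.3, 0.3))
    assert res[0] == pytest.approx(0.2 + 0.08 - 0.25)
    assert res[0] > 0
    res = dwell_residuals(0.2, 0.5, 0.8, 0.0, 0.88, (0.25, 0.3, 0.31))
    assert res[2] < 0  # third dwell violated
    res = dwell_residuals(0.2, 0.5, 0.8, 0.0, 0.88, (0.25, 0.3, 0.3))
    assert res[1] == pytest.approx(0.0)  # boundary-satisfied


def test_parameter_validation_and_estimated_roundtrip(params):
    with pytest.raises(ValueError):
        ModelParameters(C_LV=-0.1)
    with pytest.raises(ValueError):
        ModelParameters(beta=1e-7)  # positive beta would invert the pump head
    p = params.estimated_vector()
    np.testing.assert_allclose(
        p, [324.2, 0.6, 20.4, 4709.0, 900.0, 42.0, 25.0, 1.35, 0.5]
    )
    again = params.with_estimated(p * 1.1).with_estimated(p)
    assert again == params
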