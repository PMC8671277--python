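"""Tests of the Gauss-Newton personalization and Fisher identifiability."""

import numpy as np
import pytest

from lvadopt.collocation import TranscriptionConfig
from lvadopt.estimate import (
    MeasurementSet,
    PEProblem,
    default_parameter_bounds,
    fisher_sd,
    residual_vector,
    solve_pe,
)
from lvadopt.model import ESTIMATED_NAMES
from lvadopt.synthetic import generate_measurements


@pytest.fixture(scope="module")
def problem(patient, pe_setup):
    data, durations, x_ref = pe_setup
    return PEProblem(
        data, durations, patient.params, x_ref, tcfg=TranscriptionConfig(dt=0.005)
    )


# ---------------------------------------------------------------------------
# residuals
# ---------------------------------------------------------------------------

def test_residuals_vanish_on_noiseless_data_at_truth(problem, patient):
    r = problem.residuals(patient.params.estimated_vector())
    # data misfit ~ discretization mismatch between simulator and transcription
    assert np.max(np.abs(r[:27])) < 0.05


def test_residual_weighting_is_linear_in_sigma(problem, patient, pe_setup):
    data, durations, x_ref = pe_setup
    doubled = MeasurementSet(data.times, data.values, 2.0 * data.sigmas)
    p2 = PEProblem(
        doubled, durations, patient.params, x_ref,
        tcfg=TranscriptionConfig(dt=0.005), include_switching=False,
    )
    p1 = PEProblem(
        data, durations, patient.params, x_ref,
        tcfg=TranscriptionConfig(dt=0.005), include_switching=False,
    )
    p = patient.params.estimated_vector() * 1.02
    np.testing.assert_allclose(p1.residuals(p), 2.0 * p2.residuals(p), rtol=1e-12)


def test_objective_is_half_squared_residual_norm(problem, patient):
    p = patient.params.estimated_vector() * 0.97
    r = problem.residuals(p)
    assert problem.objective(p) == pytest.approx(0.5 * float(r @ r), rel=1e-12)


def test_objective_invariant_to_measurement_record_order(
    tmp_path, patient, pe_setup
):
    data, durations, x_ref = pe_setup
    import pandas as pd

    df = pd.DataFrame({"t": data.times, "value": data.values, "sigma": data.sigmas})
    shuffled = df.sample(frac=1.0, random_state=5)
    path_a, path_b = tmp_path / "a.csv", tmp_path / "b.csv"
    df.to_csv(path_a, index=False)
    shuffled.to_csv(path_b, index=False)
    pa = PEProblem(MeasurementSet.from_csv(path_a), durations, patient.params, x_ref,
                   tcfg=TranscriptionConfig(dt=0.01))
    pb = PEProblem(MeasurementSet.from_csv(path_b), durations, patient.params, x_ref,
                   tcfg=TranscriptionConfig(dt=0.01))
    p = patient.params.estimated_vector()
    assert pa.objective(p) == pytest.approx(pb.objective(p), rel=1e-12)


def test_measurement_validation():
    with pytest.raises(ValueError):
        MeasurementSet(np.array([0.1, 0.1]), np.array([1.0, 2.0]), np.ones(2))
    with pytest.raises(ValueError):
        MeasurementSet(np.array([0.1, 0.2]), np.array([1.0, 2.0]), np.zeros(2))
    with pytest.raises(ValueError):
        MeasurementSet(np.array([0.1]), np.array([1.0]), np.ones(1))


def test_measurement_times_outside_cycle_rejected(patient, pe_setup):
    data, durations, x_ref = pe_setup
    bad = MeasurementSet(
        np.array([0.1, 1.5]), np.array([10.0, 20.0]), np.ones(2)
    )
    with pytest.raises(ValueError, match="outside"):
        PEProblem(bad, durations, patient.params, x_ref)


def test_residual_vector_functional_form(patient, pe_setup):
    data, durations, x_ref = pe_setup
    p = patient.params.estimated_vector()
    r = residual_vector(p, data, durations, patient.params, x_ref,
                        tcfg=TranscriptionConfig(dt=0.01))
    assert r.shape[0] >= data.n_m


# ---------------------------------------------------------------------------
# Gauss-Newton solve
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def recovery(problem, patient):
    truth = patient.params.estimated_vector()
    rng = np.random.default_rng(7)
    lb, ub = default_parameter_bounds()
    p0 = np.clip(truth * (1 + 0.10 * rng.uniform(-1, 1, 9)), lb, ub)
    result = solve_pe(problem, p0, (lb, ub), max_iter=25)
    return truth, p0, result


def test_gauss_newton_descends(problem, recovery):
    truth, p0, result = recovery
    assert result.objective <= problem.objective(p0)
    assert all(b <= a + 1e-12 for a, b in zip(result.history, result.history[1:]))


def test_noiseless_recovery_within_one_percent(recovery):
    """Known-truth round trip: all identifiable components recovered to <= 1%
    from a 10% perturbed start."""
    truth, _, result = recovery
    assert result.converged
    rel = np.abs(result.p_star - truth) / np.abs(truth)
    well = result.identifiable
    assert well.any()
    assert np.max(rel[well]) <= 0.01


def test_estimates_stay_within_bounds(recovery):
    _, _, result = recovery
    lb, ub = default_parameter_bounds()
    assert np.all(result.p_star >= lb) and np.all(result.p_star <= ub)


def test_rmsd_algebra_for_unit_weights(patient, pe_setup):
    data, durations, x_ref = pe_setup
    prob = PEProblem(
        data, durations, patient.params, x_ref,
        tcfg=TranscriptionConfig(dt=0.01), include_switching=False,
    )
    truth = patient.params.estimated_vector()
    res = solve_pe(prob, truth, max_iter=2)
    assert res.rmsd == pytest.approx(np.sqrt(2 * res.objective / data.n_m), rel=1e-12)


def test_p0_outside_bounds_rejected(problem, patient):
    lb, ub = default_parameter_bounds()
    with pytest.raises(ValueError):
        solve_pe(problem, ub * 1.5, (lb, ub))


def test_noisy_replicates_fall_within_three_sigma(patient, pe_setup):
    """Scaled-down identifiability check: with unit measurement noise and 27
    samples, estimates of the identifiable parameters lie within 3 estimated
    SDs of truth in nearly all seeded replicates."""
    _, durations, x_ref = pe_setup
    truth = patient.params.estimated_vector()
    lb, ub = default_parameter_bounds()
    tcfg = TranscriptionConfig(dt=0.01)
    n_rep, n_ok = 8, 0
    for rep in range(n_rep):
        data = generate_measurements(patient, n_m=27, noise_sd=1.0, seed=100 + rep)
        prob = PEProblem(data, durations, patient.params, x_ref, tcfg=tcfg)
        rng = np.random.default_rng(200 + rep)
        p0 = np.clip(truth * (1 + 0.05 * rng.uniform(-1, 1, 9)), lb, ub)
        res = solve_pe(prob, p0, (lb, ub), max_iter=15)
        sd_abs = np.abs(res.p_star) * res.sd_percent / 100.0
        ok = np.abs(res.p_star - truth)[res.identifiable] <= (
            3.0 * sd_abs[res.identifiable] + 1e-9
        )
        n_ok += bool(np.all(ok))
    assert n_ok >= n_rep - 1


# ---------------------------------------------------------------------------
# Fisher information
# ---------------------------------------------------------------------------

def test_fisher_sd_closed_form_for_scalar_linear_model():
    # r_i = a t_i - y_i at sigma = 1: %SD = 100 / (|a| sqrt(sum t_i^2))
    t = np.array([0.5, 1.0, 1.5, 2.5])
    a = 4.0
    J = t.reshape(-1, 1)  # d r_i / d a
    sd, ident = fisher_sd(np.array([a]), jacobian=J)
    assert ident.all()
    assert sd[0] == pytest.approx(100.0 / (a * np.sqrt(np.sum(t**2))), rel=1e-12)


def test_fisher_sd_scales_linearly_with_sigma():
    rng = np.random.default_rng(2)
    J = rng.normal(size=(30, 4))
    p = rng.uniform(1, 3, 4)
    sd1, _ = fisher_sd(p, jacobian=J)
    c = 2.5
    sd2, _ = fisher_sd(p, jacobian=J / c)  # sigma -> c sigma weights J by 1/c
    np.testing.assert_allclose(sd2, c * sd1, rtol=1e-10)


def test_fisher_flags_rank_deficiency():
    J = np.zeros((10, 3))
    J[:, 0] = np.linspace(1, 2, 10)
    J[:, 1] = 2.0 * J[:, 0]  # exactly collinear pair, third column dead
    sd, ident = fisher_sd(np.array([1.0, 1.0, 1.0]), jacobian=J)
    assert not ident[2]
    assert np.isinf(sd[2])


def test_jacobian_matches_independent_difference_oracle(problem, patient):
    """GN Jacobian (central differences, internal step) against a
    Richardson-extrapolated fourth-order difference oracle."""
    truth = patient.params.estimated_vector()
    J = problem.jacobian(truth)

    def fourth_order_column(i, h):
        e = np.zeros(9)
        e[i] = h
        rm2, rm1 = problem.residuals(truth - 2 * e), problem.residuals(truth - e)
        rp1, rp2 = problem.residuals(truth + e), problem.residuals(truth + 2 * e)
        return (rm2 - 8 * rm1 + 8 * rp1 - rp2) / (12 * h)

    for i in (0, 1, 3, 8):  # spot-check columns across parameter magnitudes
        h = 2e-4 * max(abs(truth[i]), 1e-3)
        col = fourth_order_column(i, h)
        scale = np.max(np.abs(col))
        assert np.max(np.abs(J[:, i] - col)) <= 1e-4 * max(scale, 1e-9)
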