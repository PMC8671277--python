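"""Model personalization by weighted nonlinear least squares on LV pressure.

The subject has no implanted device during data acquisition, so the pump
flow is frozen at zero and the speed control is absent.  The phase durations
are extracted from the pressure series beforehand and held fixed; the nine
high-sensitivity parameters p = [R_AVP, C_LV, L_AVP, F_VC, F_AC, A_LV, A_LA,
k_RAD, S_D] are then fitted by a damped Gauss-Newton method (no Hessians)
with bound projection and Armijo backtracking.  Identifiability is assessed
through relative standard deviations from the Fisher information in the
Gauss-Newton approximation (J^T J).

The model response P_LV(t_i; p) is evaluated on the multiphase Radau
transcription with fixed schedule and exact periodic closure on the
stressed-volume slice anchored at a reference state, so the periodicity
constraint holds by construction for every tolerance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .collocation import MultiphaseNLP, TranscriptionConfig, build_nlp
from .model import ESTIMATED_NAMES, I_PLV, ModelParameters, volume_weights

__all__ = [
    "MeasurementSet",
    "PEResult",
    "PEProblem",
    "default_parameter_bounds",
    "residual_vector",
    "solve_pe",
    "fisher_sd",
]


@dataclass(frozen=True)
class MeasurementSet:
    """LV-pressure samples over one cycle: times, values, standard deviations."""

    times: np.ndarray         # s, strictly increasing within [t0, tf]
    values: np.ndarray        # mmHg
    sigmas: np.ndarray        # mmHg, weighting SDs (default 1)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        s = np.asarray(self.sigmas, dtype=float)
        if t.ndim != 1 or t.shape != v.shape or t.shape != s.shape:
            raise ValueError("times, values, sigmas must be equal-length 1-d arrays")
        if len(t) < 2:
            raise ValueError("need at least two measurements")
        if np.any(np.diff(t) <= 0):
            raise ValueError("measurement times must be strictly increasing")
        if np.any(s <= 0):
            raise ValueError("measurement standard deviations must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "sigmas", s)

    @property
    def n_m(self) -> int:
        return len(self.times)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"t": self.times, "value": self.values, "sigma": self.sigmas}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MeasurementSet":
        df = pd.read_csv(path)
        missing = {"t", "value"} - set(df.columns)
        if missing:
            raise ValueError(f"measurement CSV lacks columns: {sorted(missing)}")
        if "sigma" not in df.columns:
            df["sigma"] = 1.0
        df = df.sort_values("t")  # record order carries no information
        return cls(
            df["t"].to_numpy(), df["value"].to_numpy(), df["sigma"].to_numpy()
        )


def default_parameter_bounds() -> tuple[np.ndarray, np.ndarray]:
    """Physiological box for the estimated subvector p."""
    lb = np.array([50.0, 0.1, 2.0, 1000.0, 100.0, 20.0, 10.0, 0.3, 0.2])
    ub = np.array([1000.0, 3.0, 100.0, 12000.0, 4000.0, 80.0, 50.0, 3.0, 1.2])
    return lb, ub


class PEProblem:
    """Weighted least-squares fit of p on a fixed-schedule cycle.

    ``schedule_durations`` are the seven phase durations extracted from the
    data (held fixed).  ``x_ref`` plays one of two roles depending on
    ``start_state``: with ``"fixed"`` (default) it is the given initial state
    of the cycle, matching the point-estimation formulation in which x(t0) is
    data and periodicity holds only loosely; with ``"periodic"`` only its
    stressed volume V = w(p)^T x_ref is used to anchor an exact periodic
    closure (periodicity tight by construction, but several AVP parameters
    become practically non-identifiable from P_LV alone).  An optional
    Gaussian prior contributes phi(p) = 1/2 (p-mu)^T W (p-mu) (default
    absent, phi = 0).
    """

    def __init__(
        self,
        data: MeasurementSet,
        schedule_durations: np.ndarray,
        base_params: ModelParameters,
        x_ref: np.ndarray,
        tcfg: TranscriptionConfig | None = None,
        prior_mean: np.ndarray | None = None,
        prior_weight: np.ndarray | None = None,
        start_state: str = "fixed",
        include_switching: bool = True,
        sigma_sw_avp: float = 0.01,
        sigma_sw_pressure: float = 0.5,
    ) -> None:
        self.data = data
        self.durations = np.asarray(schedule_durations, dtype=float)
        if self.durations.shape != (7,) or np.any(self.durations <= 0):
            raise ValueError("schedule needs 7 positive phase durations")
        tf = float(self.durations.sum())
        if data.times[0] < 0 or data.times[-1] > tf + 1e-12:
            raise ValueError("measurement times outside the cycle [0, tf]")
        self.base_params = base_params
        self.x_ref = np.asarray(x_ref, dtype=float)
        self.tcfg = tcfg if tcfg is not None else TranscriptionConfig(dt=0.002)
        self.prior_mean = prior_mean
        self.prior_weight = prior_weight
        if start_state not in ("fixed", "periodic"):
            raise ValueError("start_state must be 'fixed' or 'periodic'")
        self.start_state = start_state
        # switching conditions at the fixed phase boundaries, kept as tightly
        # weighted residuals: they tie S_D (absent from the phase dynamics)
        # and the valve timings to the trajectory
        self.include_switching = include_switching
        self.sigma_sw_avp = sigma_sw_avp
        self.sigma_sw_pressure = sigma_sw_pressure

    def _params(self, p: np.ndarray) -> ModelParameters:
        return self.base_params.with_estimated(p)

    def _solve(self, p: np.ndarray):
        params = self._params(p)
        V_anchor = float(volume_weights(params) @ self.x_ref)
        nlp = build_nlp(
            params, None, self.durations, self.tcfg,
            include_lvad=False, V_anchor=V_anchor,
        )
        x0 = self.x_ref if self.start_state == "fixed" else None
        traj = nlp.solve_trajectory(self.durations, x0=x0, keep_stages=True)
        return nlp, traj

    def model_response(self, p: np.ndarray) -> np.ndarray:
        """P_LV at the measurement times for parameter vector p."""
        _, traj = self._solve(p)
        return traj.sample_states(self.data.times)[:, I_PLV]

    def residuals(self, p: np.ndarray) -> np.ndarray:
        """Weighted residuals r_i = (P_hat(t_i) - P_LV(t_i; p)) / sigma_i,
        optionally followed by the weighted switching-condition residuals and
        the prior contribution."""
        nlp, traj = self._solve(p)
        p_lv = traj.sample_states(self.data.times)[:, I_PLV]
        r = (self.data.values - p_lv) / self.data.sigmas
        if self.include_switching:
            sw = nlp.switching_residuals(traj)
            r_sw = np.array([
                v / (self.sigma_sw_avp if name.startswith("avp")
                     else self.sigma_sw_pressure)
                for name, v in sw.items()
            ])
            r = np.concatenate([r, r_sw])
        if self.prior_mean is not None:
            W = self.prior_weight if self.prior_weight is not None else np.eye(9)
            L = np.linalg.cholesky(np.atleast_2d(W))
            r = np.concatenate([r, L.T @ (np.asarray(p) - self.prior_mean)])
        return r

    def objective(self, p: np.ndarray) -> float:
        """1/2 sum r_i^2 (+ phi(p), folded into the residuals)."""
        r = self.residuals(p)
        return 0.5 * float(r @ r)

    def jacobian(self, p: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
        """Central finite-difference Jacobian of the residual vector."""
        p = np.asarray(p, dtype=float)
        r0 = self.residuals(p)
        J = np.empty((len(r0), len(p)))
        for i in range(len(p)):
            h = rel_step * max(abs(p[i]), 1e-3)
            pp, pm = p.copy(), p.copy()
            pp[i] += h
            pm[i] -= h
            J[:, i] = (self.residuals(pp) - self.residuals(pm)) / (2 * h)
        return J


def residual_vector(
    p,
    data: MeasurementSet,
    schedule_durations,
    base_params: ModelParameters,
    x_ref,
    tcfg: TranscriptionConfig | None = None,
) -> np.ndarray:
    """Functional form of :meth:`PEProblem.residuals`."""
    prob = PEProblem(data, schedule_durations, base_params, x_ref, tcfg)
    return prob.residuals(np.asarray(p, dtype=float))


@dataclass
class PEResult:
    p_star: np.ndarray
    objective: float
    rmsd: float                      # mmHg, sqrt(2*objective/n_m) at sigma == 1
    sd_percent: np.ndarray           # Fisher relative SDs (%)
    identifiable: np.ndarray         # per-parameter rank flags
    schedule_durations: np.ndarray
    converged: bool
    n_iter: int
    history: list = field(default_factory=list)
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "p_star": dict(zip(ESTIMATED_NAMES, map(float, self.p_star))),
            "objective": float(self.objective),
            "rmsd_mmhg": float(self.rmsd),
            "sd_percent": dict(zip(ESTIMATED_NAMES, map(float, self.sd_percent))),
            "identifiable": dict(zip(ESTIMATED_NAMES, map(bool, self.identifiable))),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "objective_history": [float(v) for v in self.history],
            "message": self.message,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def solve_pe(
    problem: PEProblem,
    p0: np.ndarray,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
    max_iter: int = 30,
    gtol: float = 1e-6,
    xtol: float = 1e-8,
    lm_lambda0: float = 1e-3,
) -> PEResult:
    """Damped Gauss-Newton with bound projection and Armijo backtracking.

    Accepted steps never increase the objective; if a full Gauss-Newton step
    fails the line search, Levenberg-Marquardt damping is increased.
    Non-convergence is reported (with the iterate history), not raised: the
    problem is known to be initialization sensitive.
    """
    lb, ub = bounds if bounds is not None else default_parameter_bounds()
    p = np.clip(np.asarray(p0, dtype=float), lb, ub)
    if not np.all((lb <= p0) & (np.asarray(p0) <= ub)):
        raise ValueError("p0 outside bounds")

    scale = np.maximum(np.abs(p), 1e-6)
    history = []
    converged = False
    message = "max_iter reached"
    lam = lm_lambda0
    n_it = 0
    r = problem.residuals(p)
    F = 0.5 * float(r @ r)
    history.append(F)
    for n_it in range(1, max_iter + 1):
        J = problem.jacobian(p)
        g = J.T @ r
        if np.max(np.abs(g) * scale) < gtol * max(F, 1.0):
            converged, message = True, "small projected gradient"
            break
        accepted = False
        for _ in range(8):  # escalate LM damping until a descent step is found
            JtJ = J.T @ J + lam * np.diag(np.maximum(np.diag(J.T @ J), 1e-12))
            try:
                step = -np.linalg.solve(JtJ, g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            alpha = 1.0
            for _ in range(12):  # Armijo backtracking on the projected step
                trial = np.clip(p + alpha * step, lb, ub)
                try:
                    r_t = problem.residuals(trial)
                    F_t = 0.5 * float(r_t @ r_t)
                except Exception:
                    F_t = np.inf
                if F_t <= F - 1e-4 * alpha * float(g @ (p - trial)) and F_t < F:
                    break
                alpha *= 0.5
            else:
                lam *= 10.0
                continue
            step_size = np.max(np.abs(trial - p) / scale)
            p, r, F = trial, r_t, F_t
            history.append(F)
            lam = max(lam * 0.3, 1e-12)
            accepted = True
            break
        if not accepted:
            message = "no descent step found (Levenberg damping exhausted)"
            break
        if step_size < xtol:
            converged, message = True, "step below xtol"
            break

    J = problem.jacobian(p)
    sd, ident = fisher_sd(p, jacobian=J)
    pure = (not problem.include_switching) and problem.prior_mean is None
    sigma1 = np.allclose(problem.data.sigmas, 1.0)
    if pure and sigma1:
        rmsd = float(np.sqrt(2.0 * F / problem.data.n_m))
    else:
        rmsd = float(
            np.sqrt(np.mean((problem.data.values - problem.model_response(p)) ** 2))
        )
    return PEResult(
        p_star=p,
        objective=F,
        rmsd=rmsd,
        sd_percent=sd,
        identifiable=ident,
        schedule_durations=problem.durations,
        converged=converged,
        n_iter=n_it,
        history=history,
        message=message,
    )


def fisher_sd(
    p_star,
    problem: PEProblem | None = None,
    jacobian: np.ndarray | None = None,
    rank_rtol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Relative standard deviations (%) from the Fisher information.

    Uses the Gauss-Newton approximation: covariance = (J^T J)^{-1} with J the
    sigma-weighted residual Jacobian at the estimate, so
    %SD_i = 100 sqrt([(J^T J)^{-1}]_ii) / |p*_i|.  Near-singular directions
    (relative singular value below ``rank_rtol``) are flagged as
    non-identifiable and reported as inf.
    """
    p_star = np.asarray(p_star, dtype=float)
    if jacobian is None:
        if problem is None:
            raise ValueError("need either a PEProblem or a precomputed Jacobian")
        jacobian = problem.jacobian(p_star)
    U, s, Vt = np.linalg.svd(jacobian, full_matrices=False)
    good = s > rank_rtol * s[0]
    # covariance restricted to the identifiable subspace
    cov = (Vt[good].T * (1.0 / s[good] ** 2)) @ Vt[good]
    var = np.diag(cov).copy()
    identifiable = np.ones(len(p_star), dtype=bool)
    if not np.all(good):
        null_dirs = Vt[~good]
        affected = np.any(np.abs(null_dirs) > 1e-6, axis=0)
        identifiable &= ~affected
        var[affected] = np.inf
    denom = np.where(np.abs(p_star) > 0, np.abs(p_star), np.nan)
    return 100.0 * np.sqrt(var) / denom, identifiable


def extract_phase_durations(
    data: MeasurementSet, tf: float, fallback: np.ndarray
) -> np.ndarray:
    """Heuristic phase-duration extraction from an LV pressure series.

    Feature detection on the pressure waveform: the steep upstroke marks the
    onset of ventricular contraction, the downstroke end of relaxation.
    Only the coarse contraction/relaxation split is observable from pressure
    alone, so interior valve-phase boundaries are scaled from ``fallback``
    proportions (operator-supplied boundaries take precedence in practice).
    """
    t, v = data.times, data.values
    dv = np.gradient(v, t)
    t_up = t[np.argmax(dv)]      # steepest rise ~ onset of VC (tau_1)
    fb = np.asarray(fallback, dtype=float)
    out = fb.copy()
    if 0.02 < t_up < 0.5 * tf:
        out[0] = t_up
        rest = tf - t_up - fb[1:].sum() + fb[0] - fb[0]
        scalefac = (tf - t_up) / fb[1:].sum()
        out[1:] = fb[1:] * scalefac
    return out * (tf / out.sum())
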