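"""Optimal pump-speed computation for the three control scenarios.

The objective trades ventricular unloading against aortic-valve flow,

    J = int [rho1 rho2 P_LV (Q_AoV + Q_LVAD - Q_MV) - (1-rho1) rho3 Q_AoV] dt,

minimized over one periodic cycle subject to the physiological constraints
(flow balance, periodicity, partial support, bounded pump backflow, desired
cardiac output, state/control bounds) under one of three speed structures:
a single constant speed, an unrestricted per-interval speed, or a
piecewise-constant profile with three levels, three switch times and minimum
dwell times.

The problem is posed on the switching-time transcription: phase durations
(and, for the pwc scenario, the speed switch times realized as extra phase
boundaries) are the geometric decision variables; states are eliminated
through the per-phase affine collocation solve with exact periodic closure,
so periodicity holds by construction.  The resulting dense reduced problem
is solved with SQP (scipy SLSQP).  Solutions are local; optional seeded
multi-start perturbs the warm start.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
from scipy.optimize import minimize

from .collocation import MultiphaseNLP, PhasedTrajectory, TranscriptionConfig, build_nlp
from .model import (
    CANONICAL_PHASES,
    I_QLVAD,
    Contraction,
    ModelParameters,
    PhaseSchedule,
    PumpSpeedProfile,
    Scenario,
    dwell_residuals,
    volume_weights,
)
from .simulate import (
    ConstraintConfig,
    SimulationError,
    Trajectory,
    derived_metrics,
    evaluate_constraints,
    find_periodic_state,
    simulate_cycle,
)

__all__ = [
    "OCPConfig",
    "OCPResult",
    "WarmStart",
    "initialize",
    "solve_ocp",
    "compare_scenarios",
    "embed_pwc_in_continuous",
]

_U_SCALE = 1.0e4  # rpm; speed variables are scaled to O(1) for the SQP


@dataclass(frozen=True)
class OCPConfig:
    """Objective weights, constraint tolerances and bounds of the OCP."""

    rho1: float = 0.5            # unloading-vs-valve-opening weight in [0, 1]
    rho2: float = 1.0e-4         # scales hydraulic work (~1e4 mmHg*mL) to O(1)
    rho3: float = 1.0e-2         # scales valve volume (~1e2 mL) to O(1)
    constraints: ConstraintConfig = field(default_factory=ConstraintConfig)
    dwell: tuple[float, float, float] = (0.10, 0.10, 0.10)  # pwc level dwell (s)
    vc_min_duration: float = 0.20   # s, minimum ventricular-contraction span
    phase_min_duration: float = 0.01
    u_lb: float = 2000.0
    u_ub: float = 18000.0
    tf_bounds: tuple[float, float] = (0.84, 0.94)
    # state box (suction prevention through the P_LV lower bound)
    x_lb: tuple = (0.0, 2.0, 20.0, 20.0, 0.0, -300.0, -150.0, -40.0, -1.0)
    x_ub: tuple = (40.0, 180.0, 180.0, 160.0, 40.0, 800.0, 400.0, 40.0, 1.0)
    eps_sw: float = 0.5          # mmHg, valve-event residual tolerance
    eps_sw_avp: float = 0.02     # cm, AVP-event residual tolerance

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho1 <= 1.0:
            raise ValueError("rho1 must lie in [0, 1]")
        if any(d <= 0 for d in self.dwell):
            raise ValueError("dwell times must be positive")
        if not self.u_lb < self.u_ub:
            raise ValueError("require u_lb < u_ub")
        if not self.eps_sw > 0 or not self.eps_sw_avp > 0:
            raise ValueError("switching tolerances must be positive")


@dataclass
class WarmStart:
    """Simulator-produced initialization of the OCP variables."""

    x0: np.ndarray
    durations: np.ndarray        # 7 canonical phase durations (s)
    V_anchor: float
    u_init: float
    tf: float
    trajectory: Trajectory
    J_init: float


@dataclass
class OCPResult:
    scenario: Scenario
    J: float
    J_unloading: float
    J_aov: float
    trajectory: PhasedTrajectory
    schedule: PhaseSchedule
    tf: float
    u_const: float | None
    levels: tuple | None
    switch_times: tuple | None
    success: bool
    status_message: str
    n_iter: int
    constraint_report: object
    pulsation_mode: str
    counts: dict

    def summary(self) -> dict:
        m = derived_metrics(self.trajectory)
        out = {
            "scenario": self.scenario.value,
            "J": float(self.J),
            "J_unloading": float(self.J_unloading),
            "J_aov": float(self.J_aov),
            "tf_s": float(self.tf),
            "success": bool(self.success),
            "pulsation_mode": self.pulsation_mode,
            "constraints_satisfied": bool(self.constraint_report.all_satisfied),
        }
        if self.u_const is not None:
            out["u_const_rpm"] = float(self.u_const)
        if self.levels is not None:
            out["levels_rpm"] = [float(u) for u in self.levels]
            out["speed_switch_times_s"] = [float(t) for t in self.switch_times]
        out.update(m)
        return out


def initialize(
    params: ModelParameters,
    cfg: OCPConfig,
    u_init: float = 8000.0,
    tf: float = 0.89,
    x0_guess: np.ndarray | None = None,
) -> WarmStart:
    """Warm start: simulated periodic cycle at constant ``u_init``.

    The realized switching times give the initial phase durations; the
    simulated states give the stressed-volume anchor and the initial point of
    the transcription.  Simulation failure propagates.
    """
    if x0_guess is None:
        x0_guess = np.array([14.0, 9.0, 70.0, 68.0, 17.0, 55.0, 20.0, 0.0, -0.25])
    profile = PumpSpeedProfile.constant(u_init, u_lb=0.0, u_ub=max(cfg.u_ub, u_init))
    x0 = find_periodic_state(params, profile, x0_guess, tf=tf)
    traj = simulate_cycle(params, profile, x0, tf=tf)
    from .simulate import evaluate_objective

    return WarmStart(
        x0=x0,
        durations=traj.schedule.durations,
        V_anchor=float(volume_weights(params) @ x0),
        u_init=u_init,
        tf=tf,
        trajectory=traj,
        J_init=evaluate_objective(traj, cfg.rho1, cfg.rho2, cfg.rho3),
    )


# ---------------------------------------------------------------------------
# Reduced NLP assembly and solve
# ---------------------------------------------------------------------------

class _ReducedOCP:
    """Objective/constraint closures over z = [phase durations, speed vars]."""

    def __init__(self, nlp: MultiphaseNLP, cfg: OCPConfig):
        self.nlp = nlp
        self.cfg = cfg
        self.n_phases = len(nlp.modes)
        self.scenario = nlp.scenario
        if self.scenario is Scenario.CONSTANT:
            self.n_u = 1
        elif self.scenario is Scenario.PWC:
            self.n_u = 3
        else:
            self.n_u = nlp.n_total_intervals
        self._cache_key = None
        self._cache_val = None
        self._grad_key = None
        self._grad_val = None

    # -- variable packing --
    def pack(self, durations, speeds) -> np.ndarray:
        return np.concatenate([durations, np.asarray(speeds) / _U_SCALE])

    def unpack(self, z):
        d = np.asarray(z[: self.n_phases], dtype=float)
        u = np.asarray(z[self.n_phases:], dtype=float) * _U_SCALE
        return d, u

    def bounds(self):
        cfg = self.cfg
        lo = [cfg.phase_min_duration] * self.n_phases + [cfg.u_lb / _U_SCALE] * self.n_u
        hi = [cfg.tf_bounds[1]] * self.n_phases + [cfg.u_ub / _U_SCALE] * self.n_u
        return list(zip(lo, hi))

    def evaluate(self, z):
        key = z.tobytes()
        if key == self._cache_key:
            return self._cache_val
        d, u = self.unpack(z)
        traj = self.nlp.solve_trajectory(d, u)
        self._cache_key, self._cache_val = key, (traj, d, u)
        return self._cache_val

    def objective(self, z) -> float:
        traj, _, _ = self.evaluate(z)
        I = traj.integrals
        cfg = self.cfg
        return (
            cfg.rho1 * cfg.rho2 * I["unloading"]
            - (1.0 - cfg.rho1) * cfg.rho3 * I["q_aov"]
        )

    def inequality(self, z) -> np.ndarray:
        """All constraints as g(z) >= 0."""
        traj, d, u = self.evaluate(z)
        cfg, nlp = self.cfg, self.nlp
        cc = cfg.constraints
        I = traj.integrals
        tf = float(d.sum())
        rows = [tf - cfg.tf_bounds[0], cfg.tf_bounds[1] - tf]

        # minimum total ventricular-contraction span
        vc = sum(
            dd for dd, m in zip(d, nlp.modes) if m.contraction is Contraction.VC
        )
        rows.append(vc - cfg.vc_min_duration)

        # switching residuals |r| <= eps at the transformed boundaries
        for name, r in nlp.switching_residuals(traj).items():
            eps = cfg.eps_sw_avp if name.startswith("avp") else cfg.eps_sw
            rows.extend([eps - r, eps + r])

        # physiological functionals
        flow = I["q_mv"] - I["q_aov"] - I["q_lvad"]
        rows.extend([cc.eps_flow - flow, cc.eps_flow + flow])
        rows.append(I["q_aov"] - cc.eps_partial)
        co = 60.0 / tf * (I["q_aov"] + I["q_lvad"])
        rows.extend([cc.eps_co - (co - cc.V_CO), cc.eps_co + (co - cc.V_CO)])

        # pwc dwell times (speed switches sit at the extra phase boundaries)
        if self.scenario is Scenario.PWC:
            t1, t2, t3 = self._pwc_switch_times(d)
            rows.extend(dwell_residuals(t1, t2, t3, 0.0, tf, cfg.dwell))

        g = np.array(rows, dtype=float)
        # path constraints at the grid nodes
        x = traj.states
        back = x[:, I_QLVAD] + cc.eps_back
        lb = x - np.asarray(cfg.x_lb)
        ub = np.asarray(cfg.x_ub) - x
        return np.concatenate([g, back, lb.ravel(), ub.ravel()])

    @staticmethod
    def _pwc_switch_times(d10: np.ndarray) -> tuple[float, float, float]:
        c = np.cumsum(d10)
        return float(c[2]), float(c[6]), float(c[8])  # ends of phases 3a, 6a, 7a

    # -- shared forward-difference derivatives (one sweep for J and g) --
    def _derivatives(self, z, eps: float = 1e-7):
        key = z.tobytes()
        if key == self._grad_key:
            return self._grad_val
        f0 = self.objective(z)
        g0 = self.inequality(z)
        grad = np.empty(len(z))
        jac = np.empty((len(g0), len(z)))
        for i in range(len(z)):
            zp = z.copy()
            zp[i] += eps
            grad[i] = (self.objective(zp) - f0) / eps
            jac[:, i] = (self.inequality(zp) - g0) / eps
        self._grad_key, self._grad_val = key, (grad, jac)
        return self._grad_val

    def objective_grad(self, z) -> np.ndarray:
        return self._derivatives(np.asarray(z, dtype=float))[0]

    def inequality_jac(self, z) -> np.ndarray:
        return self._derivatives(np.asarray(z, dtype=float))[1]


def _initial_speeds(scenario, nlp, u0):
    if scenario is Scenario.CONSTANT:
        return np.array([u0], dtype=float)
    if scenario is Scenario.PWC:
        return np.asarray(u0, dtype=float) if np.ndim(u0) else np.full(3, float(u0))
    N = nlp.n_total_intervals
    return np.asarray(u0, dtype=float) if np.ndim(u0) else np.full(N, float(u0))


def solve_ocp(
    scenario: Scenario,
    params: ModelParameters,
    cfg: OCPConfig,
    warm: WarmStart,
    tcfg: TranscriptionConfig | None = None,
    u0=None,
    durations0: np.ndarray | None = None,
    max_iter: int = 400,
    ftol: float = 1e-9,
    multistart: int = 0,
    seed: int | None = None,
) -> OCPResult:
    """Solve the cycle OCP for one speed scenario from a warm start.

    ``u0``/``durations0`` override the warm start's initialization (used by
    :func:`compare_scenarios` to chain scenarios).  ``multistart`` adds
    seeded perturbations of the initialization and keeps the best feasible
    local solution (the problem is initialization sensitive).
    """
    if tcfg is None:
        tcfg = TranscriptionConfig(dt=0.01)
    init_durations = (
        np.asarray(durations0, dtype=float)
        if durations0 is not None
        else warm.durations
    )
    nlp = build_nlp(params, scenario, init_durations, tcfg, V_anchor=warm.V_anchor)
    red = _ReducedOCP(nlp, cfg)
    d0 = np.asarray(nlp.durations_init, dtype=float)
    u_start = _initial_speeds(scenario, nlp, warm.u_init if u0 is None else u0)

    rng = np.random.default_rng(seed)
    starts = [(d0, u_start)]
    for _ in range(multistart):
        dd = d0 * np.exp(rng.normal(0.0, 0.05, size=d0.shape))
        dd *= warm.tf / dd.sum()
        uu = np.clip(
            u_start + rng.normal(0.0, 500.0, size=u_start.shape),
            cfg.u_lb, cfg.u_ub,
        )
        starts.append((dd, uu))

    best = None
    last_res = None
    for dd, uu in starts:
        z0 = red.pack(dd, np.clip(uu, cfg.u_lb, cfg.u_ub))
        res = minimize(
            red.objective,
            z0,
            method="SLSQP",
            jac=red.objective_grad,
            bounds=red.bounds(),
            constraints=[
                {"type": "ineq", "fun": red.inequality, "jac": red.inequality_jac}
            ],
            options={"maxiter": max_iter, "ftol": ftol, "eps": 1e-7},
        )
        last_res = res
        feas = float(np.min(red.inequality(res.x)))
        cand = (res.success and feas > -1e-6, -res.fun, res)
        if best is None or (cand[0], cand[1]) > (best[0], best[1]):
            best = (cand[0], cand[1], res)
    res = best[2] if best is not None else last_res

    d_opt, u_opt = red.unpack(res.x)
    traj = nlp.solve_trajectory(d_opt, u_opt, keep_stages=True)
    I = traj.integrals
    J_unl = cfg.rho1 * cfg.rho2 * I["unloading"]
    J_aov = (1.0 - cfg.rho1) * cfg.rho3 * I["q_aov"]
    report = evaluate_constraints(
        traj, cfg.constraints, x_lb=np.asarray(cfg.x_lb), x_ub=np.asarray(cfg.x_ub)
    )

    u_const = float(u_opt[0]) if scenario is Scenario.CONSTANT else None
    levels = tuple(map(float, u_opt)) if scenario is Scenario.PWC else None
    switch_times = (
        red._pwc_switch_times(d_opt) if scenario is Scenario.PWC else None
    )

    # counterpulsative / copulsative diagnostic: correlation of the realized
    # speed with the ventricular-contraction indicator along the grid
    u_nodes = np.concatenate([traj.controls, traj.controls[-1:]])
    vc_flag = np.array(
        [nlp.modes[p].contraction is Contraction.VC for p in traj.phase_of_interval]
        + [False],
        dtype=float,
    )
    if np.std(u_nodes) < 1e-9:
        mode_label = "constant"
    else:
        corr = float(np.corrcoef(u_nodes, vc_flag)[0, 1])
        mode_label = (
            "counterpulsative" if corr < -0.2
            else "copulsative" if corr > 0.2
            else "mixed"
        )

    return OCPResult(
        scenario=scenario,
        J=float(res.fun),
        J_unloading=float(J_unl),
        J_aov=float(J_aov),
        trajectory=traj,
        schedule=PhaseSchedule.from_durations(0.0, d_opt, modes=nlp.modes),
        tf=float(d_opt.sum()),
        u_const=u_const,
        levels=levels,
        switch_times=switch_times,
        success=bool(res.success),
        status_message=str(res.message),
        n_iter=int(res.nit),
        constraint_report=report,
        pulsation_mode=mode_label,
        counts=nlp.counts(),
    )


def _merge_pwc_durations(d10: np.ndarray) -> np.ndarray:
    """Collapse the ten pwc phases back to the canonical seven."""
    return np.array(
        [d10[0], d10[1], d10[2] + d10[3], d10[4], d10[5],
         d10[6] + d10[7], d10[8] + d10[9]]
    )


def compare_scenarios(
    params: ModelParameters,
    cfg: OCPConfig,
    tcfg: TranscriptionConfig | None = None,
    warm: WarmStart | None = None,
    chain: bool = True,
    multistart: int = 0,
    seed: int | None = None,
) -> dict:
    """Solve all three scenarios and return a ranked comparison report.

    With ``chain=True`` (default) the pwc solve is initialized from the
    constant solution and the continuous solve from the pwc solution in
    addition to the common simulated warm start; this nested initialization
    respects the inclusion of the feasible control sets.  Partial failures
    are annotated rather than raised.
    """
    if tcfg is None:
        tcfg = TranscriptionConfig(dt=0.01)
    if warm is None:
        warm = initialize(params, cfg)

    results: dict[str, OCPResult | None] = {}
    errors: dict[str, str] = {}

    def attempt(name, **kw):
        try:
            results[name] = solve_ocp(params=params, cfg=cfg, warm=warm,
                                      tcfg=tcfg, multistart=multistart,
                                      seed=seed, **kw)
        except Exception as exc:  # keep going; report partial results
            results[name] = None
            errors[name] = f"{type(exc).__name__}: {exc}"

    attempt("constant", scenario=Scenario.CONSTANT)

    const = results.get("constant")
    if chain and const is not None and const.success:
        attempt("pwc", scenario=Scenario.PWC,
                durations0=const.schedule.durations,
                u0=np.full(3, const.u_const))
    else:
        attempt("pwc", scenario=Scenario.PWC)

    pwc = results.get("pwc")
    if chain and pwc is not None and pwc.success:
        d7 = _merge_pwc_durations(pwc.schedule.durations)
        # evaluate the pwc step profile at the continuous grid's midpoints
        probe = build_nlp(params, Scenario.CONTINUOUS, d7, tcfg,
                          V_anchor=warm.V_anchor)
        edges = np.concatenate([[0.0], np.cumsum(
            np.repeat(probe.durations_init / probe.n_intervals,
                      probe.n_intervals))])
        mid = 0.5 * (edges[:-1] + edges[1:])
        t1, t2, t3 = pwc.switch_times
        u1, u2, u3 = pwc.levels
        u_cont0 = np.where(mid < t1, u1,
                           np.where(mid < t2, u2, np.where(mid < t3, u3, u1)))
        attempt("continuous", scenario=Scenario.CONTINUOUS,
                durations0=d7, u0=u_cont0)
    else:
        attempt("continuous", scenario=Scenario.CONTINUOUS)

    rows = []
    for name, r in results.items():
        if r is None:
            rows.append({"scenario": name, "error": errors.get(name, "failed")})
        else:
            rows.append(r.summary())
    rows.sort(key=lambda d: d.get("J", np.inf))
    return {
        "initial_objective": float(warm.J_init),
        "initial_speed_rpm": float(warm.u_init),
        "ranking": rows,
        "errors": errors,
    }


def embed_pwc_in_continuous(
    pwc_result: OCPResult,
    params: ModelParameters,
    cfg: OCPConfig,
    V_anchor: float,
) -> tuple[float, float]:
    """Re-evaluate a pwc solution inside the continuous control class.

    The pwc profile is a feasible continuous control; on the identical
    ten-phase grid the per-interval expansion of the three levels must give
    the same trajectory and objective.  Returns (J_pwc, J_reevaluated).
    """
    nlp_pwc_traj = pwc_result.trajectory
    modes = nlp_pwc_traj.modes
    d10 = pwc_result.schedule.durations
    tcfg = TranscriptionConfig(dt=0.01)
    n_int = np.array([
        max(1, len([p for p in nlp_pwc_traj.phase_of_interval if p == i]))
        for i in range(len(modes))
    ])
    nlp = MultiphaseNLP(
        params=params, modes=modes, n_intervals=n_int,
        scenario=Scenario.CONTINUOUS, cfg=tcfg, V_anchor=V_anchor,
    )
    traj = nlp.solve_trajectory(d10, nlp_pwc_traj.controls)
    I = traj.integrals
    J = cfg.rho1 * cfg.rho2 * I["unloading"] - (1 - cfg.rho1) * cfg.rho3 * I["q_aov"]
    return float(pwc_result.J), float(J)
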