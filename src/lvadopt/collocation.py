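"""Radau direct collocation and the switching-time transcription.

The multiphase optimal-control and personalization problems are transcribed
with Radau IIA collocation (default degree 3) on an equidistant per-phase
grid.  Each phase is rescaled to [0, 1] (switching-time transformation), so
phase durations appear as continuous decision variables multiplying the
right-hand side; switching conditions become algebraic residuals at the
transformed phase boundaries.

Because the phase-fixed right-hand side is affine in the state
(``xdot = A x + b0 + b_u u^2``, see :mod:`lvadopt.model`), the collocation
equations of one interval form a linear system in the stage states.  Each
interval therefore reduces to an exact affine step map

    x_{k+1} = E x_k + F b_k,

with E, F precomputed once per phase (all intervals of a phase share the
same length).  Chaining the maps around the cycle gives an affine cycle map
``x(tf) = M x0 + m``; since the dynamics conserve the total stressed volume
``w^T x`` exactly (also in the discrete scheme), the periodic start state is
obtained from ``[I - M; w^T] x0 = [m; V_anchor]``.  The remaining nonlinear
program — phase durations, pump-speed parameters, switching residuals,
physiological constraint functionals — is small and dense, and is solved by
an SQP method in :mod:`lvadopt.control`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    CANONICAL_PHASES,
    I_PA,
    I_PLA,
    I_PLV,
    I_QLVAD,
    I_S,
    ModelParameters,
    PhaseMode,
    Scenario,
    rhs_matrices,
    volume_weights,
)

__all__ = [
    "radau_points",
    "collocation_coefficients",
    "transform_time",
    "interval_maps",
    "TranscriptionConfig",
    "MultiphaseNLP",
    "PhasedTrajectory",
    "build_nlp",
    "switching_constraints",
    "SWITCH_RESIDUALS",
]


def radau_points(degree: int) -> np.ndarray:
    """Radau IIA collocation points on (0, 1], right endpoint included.

    The points are the roots of P_d(2t-1) - P_{d-1}(2t-1) with Legendre
    polynomials P; for degree 3 these are 0.15505, 0.64495, 1.
    """
    if degree < 1:
        raise ValueError("collocation degree must be >= 1")
    c = np.zeros(degree + 1)
    c[degree] = 1.0
    c[degree - 1] = -1.0
    roots = np.polynomial.legendre.Legendre(c).roots()
    pts = np.sort((np.real(roots) + 1.0) / 2.0)
    pts[-1] = 1.0
    return pts


def collocation_coefficients(degree: int):
    """Lagrange-basis coefficients over nodes (0, c_1..c_d).

    Returns ``(tau, C, D, B)`` with tau the d+1 interpolation nodes,
    ``C[r, j]`` the derivative of basis polynomial r at collocation point j
    (j = 1..d), ``D[r]`` its value at 1 (continuity map) and ``B[r]`` its
    integral over [0, 1] (quadrature weights).
    """
    d = degree
    tau = np.concatenate(([0.0], radau_points(d)))
    C = np.zeros((d + 1, d + 1))
    D = np.zeros(d + 1)
    B = np.zeros(d + 1)
    for r in range(d + 1):
        # Lagrange basis polynomial through node r
        poly = np.polynomial.Polynomial([1.0])
        for j in range(d + 1):
            if j != r:
                poly *= np.polynomial.Polynomial(
                    [-tau[j] / (tau[r] - tau[j]), 1.0 / (tau[r] - tau[j])]
                )
        D[r] = poly(1.0)
        dpoly = poly.deriv()
        for j in range(1, d + 1):
            C[r, j] = dpoly(tau[j])
        B[r] = poly.integ()(1.0)
    return tau, C, D, B


def lagrange_basis_values(tau_nodes: np.ndarray, t: float) -> np.ndarray:
    """Values of the Lagrange basis over ``tau_nodes`` at local time t."""
    n = len(tau_nodes)
    out = np.empty(n)
    for r in range(n):
        val = 1.0
        for j in range(n):
            if j != r:
                val *= (t - tau_nodes[j]) / (tau_nodes[r] - tau_nodes[j])
        out[r] = val
    return out


def transform_time(rhs, t1: float, t2: float):
    """Rescale a RHS from [t1, t2] to the unit interval.

    Integrating the returned function over tau in [0, 1] reproduces the
    integration of ``rhs`` over [t1, t2]: xdot(tau) = (t2-t1) f(t1+(t2-t1)tau).
    """
    if not t2 > t1:
        raise ValueError("require t2 > t1 for the time transformation")
    h = t2 - t1
    return lambda tau, x: h * np.asarray(rhs(t1 + h * tau, x))


# ---------------------------------------------------------------------------
# Affine interval step maps
# ---------------------------------------------------------------------------

def interval_maps(A: np.ndarray, h: float, coeffs):
    """Exact Radau-step maps for the affine system xdot = A x + b on length h.

    Returns ``(E, F, G, H)``: node step ``x1 = E x0 + F b`` and stage states
    ``X = G x0 + H b`` (stacked, d blocks of 9).
    """
    tau, C, D, B = coeffs
    d = len(tau) - 1
    n = A.shape[0]
    K = C[1:, 1:].T                     # K[j-1, r-1] = C[r, j]
    M = np.kron(K, np.eye(n)) - h * np.kron(np.eye(d), A)
    R0 = -np.kron(C[0, 1:].reshape(-1, 1), np.eye(n))   # multiplies x0
    Minv = np.linalg.inv(M)
    G = Minv @ R0
    H = h * (Minv @ np.kron(np.ones((d, 1)), np.eye(n)))
    Dtail = D[1:]
    E = D[0] * np.eye(n) + np.einsum("j,jab->ab", Dtail, G.reshape(d, n, n))
    F = np.einsum("j,jab->ab", Dtail, H.reshape(d, n, n))
    return E, F, G, H


#: Switching residual after canonical phase i (1-based): (name, callable).
#: Residuals are |r| <= eps_sw constraints at the transformed boundaries.
SWITCH_RESIDUALS = {
    1: ("avp_reaches_base", lambda x, sd: x[I_S] + sd),
    2: ("mitral_closes", lambda x, sd: x[I_PLA] - x[I_PLV]),
    3: ("aortic_opens", lambda x, sd: x[I_PLV] - x[I_PA]),
    4: ("avp_reaches_apex", lambda x, sd: x[I_S] - sd),
    5: ("aortic_closes", lambda x, sd: x[I_PLV] - x[I_PA]),
    6: ("mitral_opens", lambda x, sd: x[I_PLA] - x[I_PLV]),
}


def switching_constraints(schedule_phases: int = 7):
    """Boundary-index -> residual mapping for a canonical 7-phase schedule."""
    return {i: SWITCH_RESIDUALS[i] for i in range(1, schedule_phases)}


@dataclass(frozen=True)
class TranscriptionConfig:
    """Discretization settings for the multiphase transcription.

    ``dt`` is the nominal node spacing used to fix per-phase interval counts
    from the initialization schedule; counts then stay fixed while durations
    vary.  ``degree`` selects the Radau scheme.  ``eps_sw`` bounds the
    switching residuals at phase boundaries, ``tf_bounds`` the admissible
    cycle length.
    """

    dt: float = 0.001
    degree: int = 3
    eps_sw: float = 0.5
    tf_bounds: tuple[float, float] = (0.84, 0.94)

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.degree < 1:
            raise ValueError("degree must be >= 1")
        if not (0 < self.tf_bounds[0] < self.tf_bounds[1]):
            raise ValueError("tf_bounds must be a positive interval")
        if not self.eps_sw > 0:
            raise ValueError("eps_sw must be positive")


@dataclass
class PhasedTrajectory:
    """Collocation trajectory over all phases of one cycle."""

    times: np.ndarray          # node times, global (s)
    states: np.ndarray         # node states (N+1, 9)
    controls: np.ndarray       # pump speed per interval (N,)
    phase_of_interval: np.ndarray
    boundary_states: np.ndarray  # states at phase ends (n_phases, 9)
    durations: np.ndarray
    integrals: dict
    modes: tuple = ()
    stage_cache: tuple = ()    # per interval: (t_left, h, tau_nodes, stage states (d+1, 9))

    # aliases so trajectory functionals accept both simulator and collocation output
    @property
    def t(self) -> np.ndarray:
        return self.times

    @property
    def x(self) -> np.ndarray:
        return self.states

    @property
    def schedule(self):
        from .model import PhaseSchedule

        return PhaseSchedule.from_durations(0.0, self.durations, modes=self.modes)

    def sample_states(self, t) -> np.ndarray:
        """Evaluate the collocation polynomial at arbitrary times."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty((len(t), self.states.shape[1]))
        lefts = np.array([c[0] for c in self.stage_cache])
        for k, tk in enumerate(t):
            i = int(np.clip(np.searchsorted(lefts, tk, side="right") - 1,
                            0, len(self.stage_cache) - 1))
            t_left, h, tau_nodes, X = self.stage_cache[i]
            loc = np.clip((tk - t_left) / h, 0.0, 1.0)
            out[k] = lagrange_basis_values(tau_nodes, loc) @ X
        return out


class MultiphaseNLP:
    """Switching-time transcription of one cardiac cycle.

    Holds the fixed combinatorial structure (phase modes, per-phase interval
    counts, control parameterization) and evaluates trajectories, switching
    residuals and constraint functionals for given phase durations and
    control parameters.  States are eliminated through the per-phase affine
    collocation solve with exact periodic closure on the stressed-volume
    slice ``w^T x0 = V_anchor``, so the decision variables exposed to the
    optimizer are durations and controls only.
    """

    def __init__(
        self,
        params: ModelParameters,
        modes: tuple[PhaseMode, ...],
        n_intervals: np.ndarray,
        scenario: Scenario | None,
        cfg: TranscriptionConfig,
        control_map: np.ndarray | None = None,
        switch_map: dict | None = None,
        include_lvad: bool = True,
        V_anchor: float = 0.0,
    ) -> None:
        self.params = params
        self.modes = tuple(modes)
        self.n_intervals = np.asarray(n_intervals, dtype=int)
        if np.any(self.n_intervals < 1):
            raise ValueError("each phase needs at least one interval")
        self.scenario = scenario
        self.cfg = cfg
        self.coeffs = collocation_coefficients(cfg.degree)
        self.include_lvad = include_lvad
        self.V_anchor = float(V_anchor)
        self.w = volume_weights(params)
        # phase systems
        self.systems = [
            rhs_matrices(params, m, include_lvad=include_lvad) for m in self.modes
        ]
        # control_map: for PWC, level index per phase; None otherwise
        self.control_map = control_map
        self.switch_map = switch_map if switch_map is not None else {}
        self.n_total_intervals = int(self.n_intervals.sum())

    # -- bookkeeping ---------------------------------------------------------
    def counts(self) -> dict:
        """Variable/constraint counts of the underlying NLP (for dumps/tests).

        Counts describe the full simultaneous transcription (states at nodes
        and collocation points plus durations and controls), even though the
        state block is eliminated analytically in the solve.
        """
        d = self.cfg.degree
        N = self.n_total_intervals
        n_phases = len(self.modes)
        if self.scenario is Scenario.CONSTANT:
            n_controls = 1
            n_switch_vars = n_phases - 1
        elif self.scenario is Scenario.PWC:
            n_controls = 3
            n_switch_vars = n_phases - 1  # 6 tau + 3 pump switch times = 9
        elif self.scenario is Scenario.CONTINUOUS:
            n_controls = N
            n_switch_vars = n_phases - 1
        else:  # simulation / PE: no control degrees of freedom
            n_controls = 0
            n_switch_vars = 0
        return {
            "phases": n_phases,
            "intervals": N,
            "collocation_degree": d,
            "state_node_vars": 9 * (N + n_phases),  # per-phase node chains
            "stage_vars": 9 * d * N,
            "duration_vars": n_phases,
            "switching_time_vars": n_switch_vars,
            "control_vars": n_controls,
            "switching_residual_constraints": len(self.switch_map),
            "collocation_constraints": 9 * d * N,
            "continuity_constraints": 9 * (N + n_phases - 1),
        }

    # -- control expansion ----------------------------------------------------
    def expand_controls(self, controls: np.ndarray) -> np.ndarray:
        """Pump speed per interval from scenario control parameters."""
        N = self.n_total_intervals
        if self.scenario is None:
            return np.zeros(N)
        controls = np.asarray(controls, dtype=float)
        if self.scenario is Scenario.CONSTANT:
            return np.full(N, float(controls[0]))
        if self.scenario is Scenario.PWC:
            per_phase = controls[self.control_map]
            return np.repeat(per_phase, self.n_intervals)
        if self.scenario is Scenario.CONTINUOUS:
            if controls.shape != (N,):
                raise ValueError("continuous scenario needs one speed per interval")
            return controls
        raise ValueError(f"unknown scenario {self.scenario}")

    # -- core solve -----------------------------------------------------------
    def solve_trajectory(
        self,
        durations: np.ndarray,
        controls: np.ndarray = (),
        x0: np.ndarray | None = None,
        keep_stages: bool = False,
    ) -> PhasedTrajectory:
        """Solve the linear collocation system phase by phase.

        With ``x0=None`` the start state is the exact periodic point on the
        stressed-volume slice; otherwise the given state is propagated
        forward (pure simulation mode).
        """
        durations = np.asarray(durations, dtype=float)
        if durations.shape != (len(self.modes),):
            raise ValueError("one duration per phase required")
        if np.any(durations <= 0):
            raise ValueError("phase durations must be strictly positive")
        u_int = self.expand_controls(controls)
        tau_nodes, C, D, B = self.coeffs
        d = self.cfg.degree

        # per-phase maps
        phase_maps = []
        for p, (A, b0, b_u) in enumerate(self.systems):
            h = durations[p] / self.n_intervals[p]
            E, F, G, H = interval_maps(A, h, self.coeffs)
            phase_maps.append((h, E, F, G, H, b0, b_u))

        # interval-level b vectors
        b_int = []
        k = 0
        for p in range(len(self.modes)):
            _, _, _, _, _, b0, b_u = phase_maps[p]
            for _ in range(self.n_intervals[p]):
                b_int.append(b0 + b_u * u_int[k] ** 2)
                k += 1
        phase_of_interval = np.repeat(np.arange(len(self.modes)), self.n_intervals)

        if x0 is None:
            M = np.eye(9)
            m = np.zeros(9)
            for k in range(self.n_total_intervals):
                p = phase_of_interval[k]
                _, E, F, _, _, _, _ = phase_maps[p]
                M = E @ M
                m = E @ m + F @ b_int[k]
            lhs = np.vstack([np.eye(9) - M, self.w])
            rhs = np.concatenate([m, [self.V_anchor]])
            x0, *_ = np.linalg.lstsq(lhs, rhs, rcond=None)

        # forward pass
        N = self.n_total_intervals
        states = np.empty((N + 1, 9))
        states[0] = x0
        times = np.empty(N + 1)
        times[0] = 0.0
        integrals = {k: 0.0 for k in ("q_mv", "q_aov", "q_lvad", "unloading")}
        boundary_states = np.empty((len(self.modes), 9))
        stage_cache = []
        k = 0
        for p in range(len(self.modes)):
            h, E, F, G, H, b0, b_u = phase_maps[p]
            A, _, _ = self.systems[p]
            mode = self.modes[p]
            gm = (1.0 / self.params.R_M) if mode.mitral.value == "open" else 0.0
            ga = (1.0 / self.params.R_AoV) if mode.aortic.value == "open" else 0.0
            for _ in range(self.n_intervals[p]):
                xk = states[k]
                b = b_int[k]
                Xs = (G @ xk + H @ b).reshape(d, 9)
                Xall = np.vstack([xk, Xs])          # values at tau_nodes
                states[k + 1] = E @ xk + F @ b
                times[k + 1] = times[k] + h
                # quadrature of flow functionals on this interval
                q_mv = gm * (Xall[:, I_PLA] - Xall[:, I_PLV])
                q_aov = ga * (Xall[:, I_PLV] - Xall[:, I_PA])
                q_lvad = Xall[:, I_QLVAD] if self.include_lvad else np.zeros(d + 1)
                unload = Xall[:, I_PLV] * (q_aov + q_lvad - q_mv)
                integrals["q_mv"] += h * B @ q_mv
                integrals["q_aov"] += h * B @ q_aov
                integrals["q_lvad"] += h * B @ q_lvad
                integrals["unloading"] += h * B @ unload
                if keep_stages:
                    stage_cache.append((times[k], h, tau_nodes, Xall))
                k += 1
            boundary_states[p] = states[k]

        return PhasedTrajectory(
            times=times,
            states=states,
            controls=u_int,
            phase_of_interval=phase_of_interval,
            boundary_states=boundary_states,
            durations=durations,
            integrals=integrals,
            modes=self.modes,
            stage_cache=tuple(stage_cache),
        )

    def switching_residuals(self, traj: PhasedTrajectory) -> dict:
        """Residuals of the phase-boundary switching conditions."""
        out = {}
        for boundary, (name, fn) in self.switch_map.items():
            x = traj.boundary_states[boundary - 1]
            out[name] = float(fn(x, self.params.S_D))
        return out


def build_nlp(
    params: ModelParameters,
    scenario: Scenario | None,
    schedule_init,
    cfg: TranscriptionConfig,
    include_lvad: bool = True,
    V_anchor: float = 0.0,
) -> MultiphaseNLP:
    """Construct the multiphase transcription for a scenario.

    For CONSTANT/CONTINUOUS (and pure simulation / personalization with
    ``scenario=None``) the canonical 7 phases are used.  For PWC the third,
    sixth and seventh phases are split, so the pump-speed switches t1, t2, t3
    fall between mitral closing and aortic opening, between aortic closing
    and mitral opening, and between mitral opening and the cycle end; this
    yields nine switching-time variables across ten phases.
    """
    durations0 = np.asarray(schedule_init, dtype=float)
    if durations0.shape != (7,) or np.any(durations0 <= 0):
        raise ValueError("schedule initialization needs 7 positive durations")

    if scenario is Scenario.PWC:
        modes = []
        durations = []
        for i, m in enumerate(CANONICAL_PHASES):
            if i in (2, 5, 6):  # split phases 3, 6, 7 at t1, t2, t3
                modes.extend([m, m])
                durations.extend([durations0[i] / 2] * 2)
            else:
                modes.append(m)
                durations.append(durations0[i])
        modes = tuple(modes)
        durations = np.asarray(durations)
        # speed level active in each of the 10 phases: u1 | t1 | u2 | t2 | u3 | t3 | u1
        control_map = np.array([0, 0, 0, 1, 1, 1, 1, 2, 2, 0])
        # canonical switching residuals at the ends of phases 1,2,3b,4,5,6b
        switch_map = {
            1: SWITCH_RESIDUALS[1],
            2: SWITCH_RESIDUALS[2],
            4: SWITCH_RESIDUALS[3],
            5: SWITCH_RESIDUALS[4],
            6: SWITCH_RESIDUALS[5],
            8: SWITCH_RESIDUALS[6],
        }
    else:
        modes = CANONICAL_PHASES
        durations = durations0
        control_map = None
        switch_map = switching_constraints()

    n_intervals = np.maximum(1, np.round(durations / cfg.dt).astype(int))
    nlp = MultiphaseNLP(
        params=params,
        modes=modes,
        n_intervals=n_intervals,
        scenario=scenario,
        cfg=cfg,
        control_map=control_map,
        switch_map=switch_map,
        include_lvad=include_lvad,
        V_anchor=V_anchor,
    )
    nlp.durations_init = durations
    return nlp
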