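"""Switched lumped model of the left heart, systemic circulation and a rotary LVAD.

The cardiovascular system is reduced to five compliant compartments (left
atrium LA, left ventricle LV, aorta A, systemic artery S, venous system V)
whose pressures interact with the aortic flow ``Q_A``, the pump flow
``Q_LVAD`` and the motion of the atrioventricular plane (AVP).  The AVP acts
as a piston of cross sections ``A_LA``/``A_LV`` sliding between the basal
stop ``-S_D`` and the apical stop ``+S_D``; its position ``s`` and velocity
``v`` are differential states.  A piecewise constant contraction force moves
the piston: during atrial contraction it pulls the plane toward the base
(``s -> -S_D``), during ventricular contraction toward the apex
(``s -> +S_D``), and it vanishes during relaxation.

Within one cardiac cycle the system switches between subsystems defined by
the contraction mode and the open/closed states of the mitral and aortic
valves.  The canonical cycle visits seven of the twelve combinatorially
possible subsystems, in a fixed physiological order (atrial contraction,
ventricular contraction with progressive valve events, relaxation, filling).

Crucially for the numerics downstream, the right-hand side is *affine in the
state* once a subsystem (phase mode) is fixed: ``xdot = A x + b0 + b_u u^2``.
:func:`rhs_matrices` exposes this structure.

Units: pressures mmHg, flows mL/s, volumes mL, compliances mL/mmHg,
resistances mmHg*s/mL, inertances mmHg*s^2/mL, AVP position cm, velocity
cm/s, areas cm^2, pump speed rpm.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "STATE_NAMES",
    "ESTIMATED_NAMES",
    "ModelParameters",
    "Contraction",
    "Valve",
    "PhaseMode",
    "PhaseSchedule",
    "PumpSpeedProfile",
    "Scenario",
    "CANONICAL_PHASES",
    "PHASE_EVENTS",
    "mitral_flow",
    "aortic_flow",
    "contraction_force",
    "evaluate_rhs",
    "rhs_matrices",
    "enumerate_subsystems",
    "phase_conditions",
    "volume_weights",
]

#: State ordering x = [P_LA, P_LV, P_A, P_S, P_V, Q_A, Q_LVAD, v, s]
STATE_NAMES = ("P_LA", "P_LV", "P_A", "P_S", "P_V", "Q_A", "Q_LVAD", "v", "s")
I_PLA, I_PLV, I_PA, I_PS, I_PV, I_QA, I_QLVAD, I_V, I_S = range(9)

#: Estimated subvector p (high LV-pressure sensitivity), in canonical order.
ESTIMATED_NAMES = (
    "R_AVP", "C_LV", "L_AVP", "F_VC", "F_AC", "A_LV", "A_LA", "k_RAD", "S_D",
)

_POSITIVE = (
    "C_LA", "C_LV", "C_A", "C_S", "C_V",
    "R_V", "R_S", "R_C", "R_M", "R_AoV", "R_LVAD", "R_AVP",
    "L_S", "L_LVAD", "L_AVP",
    "A_LA", "A_LV", "S_D",
)


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter set of the lumped model.

    Defaults describe a dilated left-heart-failure subject (enlarged, highly
    compliant LV, weakened contraction forces, reduced AVP excursion) with an
    axial rotary pump between LV and aorta.  ``beta`` is stored negative so
    that the printed pump-flow term ``-beta u^2`` acts as a forward pressure
    head growing with speed.
    """

    # Compliances (mL/mmHg)
    C_LA: float = 3.0
    C_LV: float = 0.6
    C_A: float = 0.6
    C_S: float = 1.5
    C_V: float = 30.0
    # Resistances (mmHg*s/mL)
    R_V: float = 0.05     # venous return into the LA
    R_S: float = 1.0      # systemic peripheral resistance
    R_C: float = 0.06     # characteristic aortic resistance
    R_M: float = 0.025    # open mitral valve
    R_AoV: float = 0.02   # open aortic valve
    R_LVAD: float = 0.35  # pump cannula + rotor resistance
    R_AVP: float = 324.2  # AVP viscous damping
    # Inertances (mmHg*s^2/mL)
    L_S: float = 0.008
    L_LVAD: float = 0.022
    L_AVP: float = 20.4
    # AVP piston geometry
    A_LA: float = 25.0    # atrial cross section (cm^2)
    A_LV: float = 42.0    # ventricular cross section (cm^2)
    k_RAD: float = 1.35   # radial-pumping amplification of A_LV
    S_D: float = 0.5      # switching distance (cm); AVPD amplitude = 2*S_D
    # Pump speed-to-pressure coefficient (mmHg/rpm^2), stored negative.
    beta: float = -8.0e-7
    # Contraction force magnitudes (piston force units, mmHg*cm^2)
    F_AC: float = 900.0
    F_VC: float = 4709.0

    def __post_init__(self) -> None:
        for name in _POSITIVE:
            if not getattr(self, name) > 0.0:
                raise ValueError(f"parameter {name} must be strictly positive")
        if self.k_RAD <= 0.0:
            raise ValueError("parameter k_RAD must be strictly positive")
        if self.beta >= 0.0:
            raise ValueError(
                "beta must be negative: the -beta*u^2 term is the forward pump head"
            )

    # -- estimated subvector ------------------------------------------------
    def estimated_vector(self) -> np.ndarray:
        """Return p = [R_AVP, C_LV, L_AVP, F_VC, F_AC, A_LV, A_LA, k_RAD, S_D]."""
        return np.array([getattr(self, n) for n in ESTIMATED_NAMES], dtype=float)

    def with_estimated(self, p: np.ndarray) -> "ModelParameters":
        p = np.asarray(p, dtype=float)
        if p.shape != (9,):
            raise ValueError("estimated parameter vector must have length 9")
        return replace(self, **dict(zip(ESTIMATED_NAMES, p)))

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown model parameters: {sorted(unknown)}")
        return cls(**d)


class Contraction(enum.Enum):
    AC = "AC"
    VC = "VC"
    ZERO = "0"


class Valve(enum.Enum):
    OPEN = "open"
    CLOSED = "closed"


@dataclass(frozen=True)
class PhaseMode:
    """One subsystem: contraction mode plus both valve states."""

    contraction: Contraction
    mitral: Valve
    aortic: Valve

    def label(self) -> str:
        return (
            f"{self.contraction.value}/MV-{self.mitral.value}/AoV-{self.aortic.value}"
        )


#: Canonical seven-phase cycle (atrial contraction; ventricular contraction
#: through mitral closure and aortic opening; relaxation through aortic
#: closure and mitral opening; passive filling).
CANONICAL_PHASES: tuple[PhaseMode, ...] = (
    PhaseMode(Contraction.AC, Valve.OPEN, Valve.CLOSED),
    PhaseMode(Contraction.VC, Valve.OPEN, Valve.CLOSED),
    PhaseMode(Contraction.VC, Valve.CLOSED, Valve.CLOSED),
    PhaseMode(Contraction.VC, Valve.CLOSED, Valve.OPEN),
    PhaseMode(Contraction.ZERO, Valve.CLOSED, Valve.OPEN),
    PhaseMode(Contraction.ZERO, Valve.CLOSED, Valve.CLOSED),
    PhaseMode(Contraction.ZERO, Valve.OPEN, Valve.CLOSED),
)

#: Switching event closing phase i (1-based): (name, residual description).
#: The residual r(x) crosses zero at the event, with the given direction.
PHASE_EVENTS = (
    ("avp_reaches_base", "s + S_D", -1),       # tau_1: s hits -S_D
    ("mitral_closes", "P_LA - P_LV", -1),      # tau_2
    ("aortic_opens", "P_LV - P_A", +1),        # tau_3
    ("avp_reaches_apex", "s - S_D", +1),       # tau_4: s hits +S_D
    ("aortic_closes", "P_LV - P_A", -1),       # tau_5
    ("mitral_opens", "P_LA - P_LV", +1),       # tau_6
)


@dataclass(frozen=True)
class PhaseSchedule:
    """Ordered cycle decomposition: t0 < tau_1 < ... < tau_6 < tf."""

    t0: float
    tf: float
    tau: tuple[float, ...]
    modes: tuple[PhaseMode, ...] = CANONICAL_PHASES

    def __post_init__(self) -> None:
        if len(self.tau) != len(self.modes) - 1:
            raise ValueError("need one switching time fewer than phases")
        pts = (self.t0, *self.tau, self.tf)
        if not all(a < b for a, b in zip(pts, pts[1:])):
            raise ValueError(
                "switching times must be strictly increasing within (t0, tf); "
                "zero-duration phases are not representable"
            )

    @property
    def boundaries(self) -> np.ndarray:
        return np.array((self.t0, *self.tau, self.tf), dtype=float)

    @property
    def durations(self) -> np.ndarray:
        b = self.boundaries
        return np.diff(b)

    @classmethod
    def from_durations(
        cls, t0: float, durations, modes: tuple[PhaseMode, ...] = CANONICAL_PHASES
    ) -> "PhaseSchedule":
        durations = np.asarray(durations, dtype=float)
        b = t0 + np.concatenate(([0.0], np.cumsum(durations)))
        return cls(t0=t0, tf=float(b[-1]), tau=tuple(b[1:-1]), modes=modes)


class Scenario(enum.Enum):
    CONSTANT = "constant"
    CONTINUOUS = "continuous"
    PWC = "pwc"


@dataclass(frozen=True)
class PumpSpeedProfile:
    """Pump speed u(t) in rpm for one of the three control scenarios.

    CONSTANT: ``u_const`` everywhere.  PWC: step function with levels
    ``u1, u2, u3`` active on [t0,t1), [t1,t2), [t2,t3) and back to ``u1`` on
    [t3,tf].  CONTINUOUS: values on an explicit time grid, interpolated
    piecewise linearly.
    """

    scenario: Scenario
    u_lb: float = 0.0
    u_ub: float = 18000.0
    u_const: float | None = None
    levels: tuple[float, float, float] | None = None
    switch_times: tuple[float, float, float] | None = None
    t0: float = 0.0
    tf: float | None = None
    grid_t: np.ndarray | None = None
    grid_u: np.ndarray | None = None
    dwell_min: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if not self.u_lb < self.u_ub:
            raise ValueError("require u_lb < u_ub")
        if self.scenario is Scenario.CONSTANT:
            if self.u_const is None:
                raise ValueError("CONSTANT profile needs u_const")
            self._check_bounds(np.array([self.u_const]))
        elif self.scenario is Scenario.PWC:
            if self.levels is None or self.switch_times is None or self.tf is None:
                raise ValueError("PWC profile needs levels, switch_times and tf")
            t1, t2, t3 = self.switch_times
            if not (self.t0 < t1 < t2 < t3 < self.tf):
                raise ValueError("require t0 < t1 < t2 < t3 < tf")
            self._check_bounds(np.asarray(self.levels))
            if self.dwell_min is not None:
                res = dwell_residuals(
                    t1, t2, t3, self.t0, self.tf, np.asarray(self.dwell_min)
                )
                if np.any(res < 0):
                    raise ValueError("minimum dwell-time requirements violated")
        elif self.scenario is Scenario.CONTINUOUS:
            if self.grid_t is None or self.grid_u is None:
                raise ValueError("CONTINUOUS profile needs grid_t and grid_u")
            gt = np.asarray(self.grid_t, dtype=float)
            if gt.ndim != 1 or len(gt) < 2 or np.any(np.diff(gt) <= 0):
                raise ValueError("grid_t must be strictly increasing, length >= 2")
            self._check_bounds(np.asarray(self.grid_u))

    def _check_bounds(self, u: np.ndarray) -> None:
        if np.any(u < self.u_lb - 1e-9) or np.any(u > self.u_ub + 1e-9):
            raise ValueError("pump speed outside [u_lb, u_ub]")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if self.scenario is Scenario.CONSTANT:
            out = np.full(t.shape, float(self.u_const))
        elif self.scenario is Scenario.PWC:
            t1, t2, t3 = self.switch_times
            u1, u2, u3 = self.levels
            out = np.where(
                t < t1, u1, np.where(t < t2, u2, np.where(t < t3, u3, u1))
            )
        else:
            out = np.interp(t, self.grid_t, self.grid_u)
        return out if out.ndim else float(out)

    @classmethod
    def constant(cls, u: float, u_lb: float = 0.0, u_ub: float = 18000.0):
        return cls(scenario=Scenario.CONSTANT, u_const=u, u_lb=u_lb, u_ub=u_ub)

    @classmethod
    def off(cls):
        """Pump absent / switched off (personalization setting)."""
        return cls(scenario=Scenario.CONSTANT, u_const=0.0, u_lb=-1.0, u_ub=1.0)


def dwell_residuals(t1, t2, t3, t0, tf, dwell) -> np.ndarray:
    """Dwell-time residuals (>= 0 when satisfied).

    Level 1 is active both at the start and after t3, so its dwell wraps
    around the cycle end: t1 - t0 + tf - t3 >= D1.
    """
    d1, d2, d3 = np.asarray(dwell, dtype=float)
    return np.array([(t1 - t0) + (tf - t3) - d1, (t2 - t1) - d2, (t3 - t2) - d3])


# ---------------------------------------------------------------------------
# Constitutive laws
# ---------------------------------------------------------------------------

def mitral_flow(P_LA, P_LV, R_M, regime="free"):
    """Mitral valve flow (mL/s).

    ``regime='free'`` applies the diode law: (P_LA-P_LV)/R_M when the atrium
    is at higher pressure, else 0.  A fixed :class:`Valve` regime returns that
    branch unconditionally (phase-fixed dynamics).
    """
    if not R_M > 0:
        raise ValueError("R_M must be strictly positive")
    if regime == "free":
        return (P_LA - P_LV) / R_M if P_LA > P_LV else 0.0
    if regime is Valve.OPEN:
        return (P_LA - P_LV) / R_M
    if regime is Valve.CLOSED:
        return 0.0
    raise ValueError(f"unknown valve regime: {regime!r}")


def aortic_flow(P_LV, P_A, R_AoV, regime="free"):
    """Aortic valve flow (mL/s); diode law between LV and aorta."""
    if not R_AoV > 0:
        raise ValueError("R_AoV must be strictly positive")
    if regime == "free":
        return (P_LV - P_A) / R_AoV if P_LV > P_A else 0.0
    if regime is Valve.OPEN:
        return (P_LV - P_A) / R_AoV
    if regime is Valve.CLOSED:
        return 0.0
    raise ValueError(f"unknown valve regime: {regime!r}")


def contraction_force(mode: Contraction, params: ModelParameters) -> float:
    """Signed effective AVP contraction force for Eq-(1h)-style dynamics.

    Sign convention: atrial contraction pulls the plane toward the base
    (s -> -S_D), so the effective force is ``-F_AC``; ventricular contraction
    pushes toward the apex (s -> +S_D) with ``+F_VC``; relaxation is 0.
    ``F_AC``/``F_VC`` themselves are magnitudes.
    """
    if mode is Contraction.AC:
        return -params.F_AC
    if mode is Contraction.VC:
        return +params.F_VC
    if mode is Contraction.ZERO:
        return 0.0
    raise ValueError(f"unknown contraction mode: {mode!r}")


# ---------------------------------------------------------------------------
# Right-hand side
# ---------------------------------------------------------------------------

def rhs_matrices(params: ModelParameters, mode: PhaseMode, include_lvad: bool = True):
    """Affine structure of the phase-fixed RHS: xdot = A x + b0 + b_u * u**2.

    With a fixed phase mode both valve flows are linear in the pressures (or
    zero) and the contraction force is a constant, so the entire RHS is
    affine in the state; only the pump head contributes a u^2 term (in b_u).
    ``include_lvad=False`` freezes Q_LVAD at zero (personalization setting,
    no device implanted).
    """
    q = params
    A = np.zeros((9, 9))
    b0 = np.zeros(9)
    b_u = np.zeros(9)

    gm = (1.0 / q.R_M) if mode.mitral is Valve.OPEN else 0.0    # MV conductance
    ga = (1.0 / q.R_AoV) if mode.aortic is Valve.OPEN else 0.0  # AoV conductance

    # P_LA: venous inflow, mitral outflow, piston term
    A[I_PLA, I_PV] += 1.0 / (q.C_LA * q.R_V)
    A[I_PLA, I_PLA] += -1.0 / (q.C_LA * q.R_V)
    A[I_PLA, I_PLA] += -gm / q.C_LA
    A[I_PLA, I_PLV] += +gm / q.C_LA
    A[I_PLA, I_V] += q.A_LA / q.C_LA

    # P_LV: piston term, mitral in, aortic + pump out
    A[I_PLV, I_V] += (1.0 + q.k_RAD) * q.A_LV / q.C_LV
    A[I_PLV, I_PLA] += +gm / q.C_LV
    A[I_PLV, I_PLV] += -gm / q.C_LV
    A[I_PLV, I_PLV] += -ga / q.C_LV
    A[I_PLV, I_PA] += +ga / q.C_LV
    if include_lvad:
        A[I_PLV, I_QLVAD] += -1.0 / q.C_LV

    # P_A: aortic valve + pump in, systemic flow out
    A[I_PA, I_PLV] += +ga / q.C_A
    A[I_PA, I_PA] += -ga / q.C_A
    if include_lvad:
        A[I_PA, I_QLVAD] += 1.0 / q.C_A
    A[I_PA, I_QA] += -1.0 / q.C_A

    # P_S, P_V: peripheral exchange
    A[I_PS, I_PV] += 1.0 / (q.C_S * q.R_S)
    A[I_PS, I_PS] += -1.0 / (q.C_S * q.R_S)
    A[I_PS, I_QA] += 1.0 / q.C_S
    A[I_PV, I_PS] += 1.0 / (q.C_V * q.R_S)
    A[I_PV, I_PV] += -1.0 / (q.C_V * q.R_S)
    A[I_PV, I_PLA] += 1.0 / (q.C_V * q.R_V)
    A[I_PV, I_PV] += -1.0 / (q.C_V * q.R_V)

    # Q_A: aortic inertance branch
    A[I_QA, I_PA] += 1.0 / q.L_S
    A[I_QA, I_PS] += -1.0 / q.L_S
    A[I_QA, I_QA] += -q.R_C / q.L_S

    # Q_LVAD: pump branch; -beta*u^2 is the speed-driven head (beta < 0)
    if include_lvad:
        A[I_QLVAD, I_PLV] += 1.0 / q.L_LVAD
        A[I_QLVAD, I_PA] += -1.0 / q.L_LVAD
        A[I_QLVAD, I_QLVAD] += -q.R_LVAD / q.L_LVAD
        b_u[I_QLVAD] = -q.beta / q.L_LVAD

    # AVP momentum and kinematics
    A[I_V, I_V] += -q.R_AVP / q.L_AVP
    A[I_V, I_PLV] += -q.A_LV / q.L_AVP
    A[I_V, I_PLA] += +q.A_LA / q.L_AVP
    b0[I_V] = contraction_force(mode.contraction, params) / q.L_AVP
    A[I_S, I_V] = 1.0

    return A, b0, b_u


def evaluate_rhs(
    x,
    u,
    params: ModelParameters,
    mode: PhaseMode | None = None,
    contraction: Contraction = Contraction.ZERO,
):
    """Time derivative of the nine states.

    ``mode=None`` evaluates the free regime: valves follow the diode laws of
    the instantaneous pressures, while the contraction mode (an implicit
    switch driven by the trajectory's history, not by the current state) is
    supplied via ``contraction``.  With a :class:`PhaseMode`, valve branches
    and the force are fixed by the mode regardless of the pressures.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (9,):
        raise ValueError("state vector must have length 9")
    if not (np.all(np.isfinite(x)) and np.isfinite(u)):
        raise ValueError("non-finite state or control")
    if mode is None:
        mv = Valve.OPEN if x[I_PLA] > x[I_PLV] else Valve.CLOSED
        av = Valve.OPEN if x[I_PLV] > x[I_PA] else Valve.CLOSED
        mode = PhaseMode(contraction, mv, av)
    A, b0, b_u = rhs_matrices(params, mode)
    return A @ x + b0 + b_u * float(u) ** 2


def volume_weights(params: ModelParameters) -> np.ndarray:
    """Left null direction w of the dynamics: d/dt (w^T x) = 0 identically.

    w^T x = sum_i C_i P_i - (A_LA + (1+k_RAD) A_LV) s is the total stressed
    volume; all inter-compartment flows cancel pairwise and the piston terms
    cancel against s.  It is conserved by every subsystem and every control.
    """
    q = params
    w = np.zeros(9)
    w[[I_PLA, I_PLV, I_PA, I_PS, I_PV]] = (q.C_LA, q.C_LV, q.C_A, q.C_S, q.C_V)
    w[I_S] = -(q.A_LA + (1.0 + q.k_RAD) * q.A_LV)
    return w


# ---------------------------------------------------------------------------
# Mode combinatorics and phase conditions
# ---------------------------------------------------------------------------

def enumerate_subsystems() -> list[PhaseMode]:
    """All 12 subsystems: {AC, VC, 0} x mitral {open, closed} x aortic ditto."""
    return [
        PhaseMode(c, m, a)
        for c, m, a in itertools.product(Contraction, Valve, Valve)
    ]


def phase_conditions(mode: PhaseMode, params: ModelParameters):
    """Validity residuals of a mode: each returned g satisfies g(x) >= 0
    while the mode is active (usable as path constraints).

    AC requires the plane above the basal stop (s > -S_D), VC below the
    apical stop (s < S_D); an open valve requires a forward pressure drop, a
    closed valve a non-positive one.
    """
    conds: list[tuple[str, callable]] = []
    S_D = params.S_D
    if mode.contraction is Contraction.AC:
        conds.append(("s_above_base", lambda x: x[..., I_S] + S_D))
    elif mode.contraction is Contraction.VC:
        conds.append(("s_below_apex", lambda x: S_D - x[..., I_S]))
    if mode.mitral is Valve.OPEN:
        conds.append(("mitral_forward_drop", lambda x: x[..., I_PLA] - x[..., I_PLV]))
    else:
        conds.append(("mitral_no_drop", lambda x: x[..., I_PLV] - x[..., I_PLA]))
    if mode.aortic is Valve.OPEN:
        conds.append(("aortic_forward_drop", lambda x: x[..., I_PLV] - x[..., I_PA]))
    else:
        conds.append(("aortic_no_drop", lambda x: x[..., I_PA] - x[..., I_PLV]))
    return conds
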