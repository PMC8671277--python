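# Methods

## Model

The circulation is lumped into five compliant compartments — left atrium
(LA), left ventricle (LV), aorta (A), systemic artery (S), venous system (V)
— connected by resistances (venous return `R_V`, peripheral `R_S`,
characteristic aortic `R_C`, open-valve `R_M`/`R_AoV`, pump `R_LVAD`) and two
inertant branches (aortic flow `Q_A`, pump flow `Q_LVAD`).  Ventricular
pumping comes from the atrioventricular plane (AVP), modeled as a damped
piston (`R_AVP`, `L_AVP`) between the chambers: its velocity `v` obeys a
momentum balance of the pressure loads `A_LA P_LA − A_LV P_LV` and a
piecewise-constant contraction force, and its motion exchanges volume with
the chambers at rates `A_LA v` and `(1+k_RAD) A_LV v`, where `k_RAD`
amplifies the longitudinal contribution by radial wall squeezing.

Sign conventions chosen here (the force enters the momentum equation as a
single signed term):

* atrial contraction applies `−F_AC`, driving `s` toward the basal stop
  `−S_D`; ventricular contraction applies `+F_VC`, driving `s` toward
  `+S_D`; relaxation applies zero.  `F_AC`, `F_VC` are magnitudes.
* the pump head is `−β u²` with `β < 0` stored, so raising the speed `u`
  (rpm) raises forward pump flow.  The shipped `β = −8·10⁻⁷ mmHg/rpm²`
  gives an 80 mmHg head at 10,000 rpm, in the range of axial pumps.

Valves are ideal diodes.  Fixing a contraction mode and both valve states
selects one of 12 subsystems; a physiological cycle uses seven of them in a
fixed order (AC with mitral open; VC with mitral open, both closed, aortic
open; relaxation with aortic open, both closed, mitral open).  Within any
fixed subsystem the right-hand side is **affine in the state**,
`ẋ = A x + b₀ + b_u u²` — the property every numerical layer exploits.

### Conservation and the stressed-volume slice

The dynamics conserve `wᵀx = Σ C_i P_i − (A_LA + (1+k_RAD)A_LV) s` exactly,
for every subsystem and every control: all inter-compartment flows cancel
pairwise and the piston terms cancel against `ṡ = v`.  This quantity is the
total stressed volume; like blood volume in a closed circulation it is set
by the initial condition, and mean pressures scale with it.  Consequences:

* the cycle map has a unit eigenvalue, so periodic states form a
  one-parameter family indexed by the stressed volume;
* the transcription closes the cycle *exactly* on the slice
  `wᵀx₀ = V_anchor` (the anchor comes from the warm-start state), which is
  stricter than any finite periodicity band — returned optima satisfy the
  periodicity constraint for every tolerance;
* the degree-3 Radau scheme inherits the conservation law exactly (the
  discrete step satisfies `wᵀx_{k+1} = wᵀx_k` to rounding), so the closure
  is well posed at any grid resolution.

## Default parameters

The nine AVPD parameters default to a personalized dilated-heart-failure
subject: `p = [R_AVP, C_LV, L_AVP, F_VC, F_AC, A_LV, A_LA, k_RAD, S_D] =
[324.2, 0.6, 20.4, 4709, 900, 42, 25, 1.35, 0.5]` — an enlarged, highly
compliant ventricle, weakened contraction forces and an AVPD amplitude of
only `2 S_D = 1 cm` (10 mm).  The circulation parameters are the package's
own calibration, chosen once so that the no-device periodic cycle reproduces
the subject's reported characteristics at a 0.89 s cycle (67 bpm): systemic
resistance 1.0 mmHg·s/mL and venous compliance 30 mL/mmHg set the working
point; aortic/systemic compliances 0.6/1.5 mL/mmHg shape the arterial pulse;
open-valve resistances 0.025/0.02 mmHg·s/mL give physiological filling and
ejection gradients; pump resistance 0.35 and inertance 0.022 place average
pump flows in the clinical 2–10 L/min corridor over the speed range.  The
resulting cycle: LV pressure 6.7–110 mmHg (target: end-systolic near 120,
end-diastolic near 5), left atrial pressure 10.7–20.1 mmHg (reported range
10–20), cardiac output 3.18 L/min (reported ≈ 3.5), AVPD amplitude
10.3 mm.  The calibration was not revisited afterwards.

The synthetic measurement generator samples this cycle's LV pressure at 27
evenly spaced times (the clinical series' count over one cycle) and adds
independent Gaussian noise, default SD 1 mmHg with unit weighting sigmas.
It emulates the *structure* of conductance-catheter data — one measured
state, sparse in time, one cycle — but not acquisition physics, beat-to-beat
variability, or model misfit: the generating model is the fitted model, so
passing recovery tests demonstrates correctness of the estimator, not
clinical validity of the model.

## Simulation

One cycle is integrated phase by phase (LSODA, rtol = atol = 1e-8) with
terminal events locating the implicit switches: `s = −S_D`, `P_LA = P_LV`
(mitral), `P_LV = P_A` (aortic), `s = +S_D`.  A missing event means the
canonical sequence is infeasible for the given parameters/control (e.g. full
support at very high speed suppresses aortic opening); the simulator raises
naming the missing event rather than reordering phases.  Four quadrature
states accumulate `∫Q_MV`, `∫Q_AoV`, `∫Q_LVAD` and the unloading integrand
`∫P_LV(Q_AoV+Q_LVAD−Q_MV)` alongside the dynamics, so functionals need no
re-quadrature.  Periodic steady states are found by damped cycling followed
by Newton on the cycle map with corrections projected onto the
stressed-volume slice.

## Transcription and optimization

Each phase is rescaled to `[0,1]` (so durations multiply the right-hand
side and become continuous variables) and discretized with Radau IIA
collocation of degree 3.  The nominal node spacing fixes per-phase interval
counts from the initialization schedule; counts then stay fixed while
durations vary — the standard switching-time practice.  Because the phase
dynamics are affine, each interval reduces to an exact affine step
`x_{k+1} = E x_k + F b_k` with `E, F` computed once per phase; chaining the
steps gives the affine cycle map, the periodic start state by a 10×9 least
squares solve on the volume slice, and collocation-order quadrature of all
functionals from the stage states.  The states are thereby eliminated and
the remaining dense problem — 7 durations (10 for the piecewise-constant
scenario, whose three speed-switch times are realized as extra phase
boundaries splitting phases 3, 6 and 7) plus the speed parameters (one
value; three levels; or one value per interval) — is solved with SQP
(scipy's SLSQP) under:

* switching residuals at the transformed boundaries, `|s(1)+S_D| ≤ ε`,
  `|P_LA−P_LV| ≤ ε` at mitral events, `|P_LV−P_A| ≤ ε` at aortic events,
  `|s(4)−S_D| ≤ ε` — with separate tolerances per unit (0.5 mmHg for
  pressure events, 0.02 cm for AVP events) since a single scalar tolerance
  cannot serve both;
* cycle length within [0.84, 0.94] s (±50 ms around the subject's cycle);
* LV inflow–outflow balance within 3 mL; partial support `∫Q_AoV ≥ 10 mL`;
  pump backflow `Q_LVAD ≥ −15 mL/s` at every node; cardiac output within
  300 mL/min of the 4200 mL/min target; state boxes (suction prevented by
  `P_LV ≥ 2 mmHg`); speed within [2000, 18000] rpm;
* for the piecewise-constant scenario, minimum dwell times of 0.1 s per
  level (the first level's dwell wraps around the cycle end) and a minimum
  total ventricular-contraction span of 0.2 s.

Objective weights default to `ρ₁ = 0.5` with unit-scaling factors
`ρ₂ = 10⁻⁴` (hydraulic work ~10⁴ mmHg·mL per beat) and `ρ₃ = 10⁻²`
(valve volume ~10²... tens of mL per beat), normalizing both terms to order
one.  The default optimization grid is 10 ms (890-interval millisecond grids
are used for the simulator-vs-collocation cross-checks; the test suite's
scenario comparisons run at 20 ms) — these problem sizes are the package's
accuracy/runtime choice.  Solutions are local; `compare_scenarios` chains
initializations (constant → pwc → continuous) so the nested control classes
are explored from feasible points, which also makes the attained objectives
respect J(continuous) ≤ J(pwc) ≤ J(constant).  Seeded multi-start around the
warm start is available because convergence is initialization sensitive.
A solution is labelled counterpulsative/copulsative by the sign of the
correlation between the realized speed and the ventricular-contraction
indicator (threshold ±0.2).

## Personalization

The estimator fits the nine AVPD parameters to LV-pressure samples by
weighted least squares, with the pump flow frozen at zero (no implanted
device), phase durations extracted from the data and held fixed, and the
cycle start state given (`start_state="fixed"`, the point-estimation
formulation); the switching conditions at the fixed boundaries are kept as
tightly weighted residuals (0.01 cm / 0.5 mmHg).  The latter matters:
without them `S_D` has zero sensitivity (fixed durations replace the events
it defines), and with a free periodic start state the AVP parameters are
practically non-identifiable from single-state pressure data (rank-deficient
Fisher matrix) — both variants are available and flagged.  The solver is
damped Gauss–Newton (Levenberg fallback, Armijo backtracking, bound
projection); Jacobians are central finite differences of the residuals
through the transcription (relative step 1e-5).  Identifiability is reported
as `%SD_i = 100·sqrt([(JᵀJ)⁻¹]_ii)/|p_i|` (the Gauss–Newton Fisher
approximation), with near-null singular directions flagged per parameter.
On noiseless 27-sample synthetic data all nine parameters are recovered to
≤ 0.15 % from a 10 % perturbed start; with unit noise the %SDs range from
about 2.5 % (`S_D`) to 80 % (`k_RAD`).

## Known limitations

Right heart, pulmonary circulation, baroreflex, valve regurgitation, blood
rheology and rotor inertia are out of scope.  The atrial pressure waveform
lacks the end-diastolic a-wave rise (the piston formulation lowers `P_LA`
during atrial contraction), so atrial-side fits should be read with care;
relatedly, optimal pump support *lengthens* the atrial-contraction phase
relative to the no-device cycle in this calibration, although the ordering
across scenarios (continuous < pwc < constant duration) behaves as expected
for counterpulsative unloading.  The exact periodic closure restricts the
feasible set relative to a banded periodicity constraint; a solution of the
restricted problem is feasible but possibly conservative.  All optima are
local.  Cycle lengths prefer the upper bound of the admissible window under
the default weights.
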