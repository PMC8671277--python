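"""Reference patients and synthetic LV-pressure series.

The clinical series behind the personalization study (27 pressure samples
over a 0.89 s cycle from a dilated, systolic-heart-failure subject) is not
publicly deposited.  This module generates stand-ins with the structure the
estimation assumes: a named parameter preset whose no-device simulation
reproduces the subject's hemodynamic characteristics (end-systolic LV
pressure near 120 mmHg, end-diastolic near 5 mmHg, left atrial pressure
between 10 and 20 mmHg, cardiac output near 3.5 L/min at 67 bpm), and noisy
pressure samples over one cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .estimate import MeasurementSet
from .model import ModelParameters, PumpSpeedProfile
from .simulate import Trajectory, find_periodic_state, simulate_cycle

__all__ = ["ReferencePatient", "make_reference_patient", "generate_measurements"]

#: Subject characteristics: end-systolic / end-diastolic targets.
_PAPER_SUBJECT_TARGETS = {
    "lv_volume_ml": (228.0, 281.0),
    "lv_pressure_mmhg": (120.0, 5.0),
    "pcw_pressure_mmhg": (28.0, 14.0),
    "aortic_pressure_mmhg": (121.0, 53.0),
    "cardiac_output_l_min": 3.5,
    "heart_rate_bpm": 67.0,
}

#: Start-of-cycle (late diastole) state guesses per preset.
_X0_GUESS = {
    "paper_subject": np.array(
        [14.0, 9.0, 70.0, 68.0, 17.0, 55.0, 0.0, 0.0, -0.25]
    ),
}


@dataclass(frozen=True)
class ReferencePatient:
    """Named parameter preset plus the hemodynamic targets it emulates."""

    name: str
    params: ModelParameters
    h_cycle: float
    targets: dict
    x0_guess: np.ndarray

    def periodic_state(self, include_lvad: bool = False, u: float = 0.0) -> np.ndarray:
        profile = (
            PumpSpeedProfile.off() if not include_lvad
            else PumpSpeedProfile.constant(u)
        )
        return find_periodic_state(
            self.params, profile, self.x0_guess,
            tf=self.h_cycle, include_lvad=include_lvad,
        )

    def simulate(self, include_lvad: bool = False, u: float = 0.0) -> Trajectory:
        profile = (
            PumpSpeedProfile.off() if not include_lvad
            else PumpSpeedProfile.constant(u)
        )
        x0 = self.periodic_state(include_lvad=include_lvad, u=u)
        return simulate_cycle(
            self.params, profile, x0, tf=self.h_cycle, include_lvad=include_lvad
        )

    def to_yaml(self, path) -> None:
        doc = {
            "name": self.name,
            "h_cycle_s": float(self.h_cycle),
            "parameters": self.params.to_dict(),
            "targets": {
                k: (list(map(float, v)) if isinstance(v, tuple) else float(v))
                for k, v in self.targets.items()
            },
            "x0_guess": [float(v) for v in self.x0_guess],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def make_reference_patient(profile: str = "paper_subject") -> ReferencePatient:
    """Construct a named reference patient.

    ``paper_subject``: dilated left-heart failure, cycle length 0.89 s, with
    the personalized nine-parameter subvector
    p* = [324.2, 0.6, 20.4, 4709, 900, 42, 25, 1.35, 0.5] and calibrated
    circulation parameters (see the package defaults).
    """
    if profile != "paper_subject":
        raise ValueError(f"unknown patient preset: {profile!r}")
    params = ModelParameters()  # defaults carry p* and the calibrated circulation
    return ReferencePatient(
        name=profile,
        params=params,
        h_cycle=0.89,
        targets=dict(_PAPER_SUBJECT_TARGETS),
        x0_guess=_X0_GUESS[profile].copy(),
    )


def generate_measurements(
    patient: ReferencePatient,
    n_m: int = 27,
    noise_sd: float = 1.0,
    seed: int | None = None,
    layout: str = "even",
    params: ModelParameters | None = None,
) -> MeasurementSet:
    """Sample a noisy LV-pressure series from one simulated cycle.

    The patient's no-device periodic cycle is simulated and P_LV is read at
    ``n_m`` sample times (default evenly spaced over (0, tf); the
    ``systole_dense`` layout concentrates half the samples in the first 45%
    of the cycle where contraction dynamics live).  Independent Gaussian
    noise with standard deviation ``noise_sd`` is added; the recorded
    weighting sigmas are max(noise_sd, 1) as in unit-weighted fitting.
    ``params`` overrides the patient's parameter set (known-truth studies).
    """
    if n_m < 2:
        raise ValueError("need at least two measurements")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    p = params if params is not None else patient.params
    prof = PumpSpeedProfile.off()
    x0 = find_periodic_state(p, prof, patient.x0_guess, tf=patient.h_cycle,
                             include_lvad=False)
    traj = simulate_cycle(p, prof, x0, tf=patient.h_cycle, include_lvad=False)

    tf = patient.h_cycle
    if layout == "even":
        times = np.linspace(tf / n_m, tf, n_m) - tf / (2 * n_m)
    elif layout == "systole_dense":
        n_sys = n_m // 2
        t_sys = np.linspace(0.01, 0.45 * tf, n_sys)
        t_dia = np.linspace(0.45 * tf + 0.02, tf - 0.01, n_m - n_sys)
        times = np.concatenate([t_sys, t_dia])
    else:
        raise ValueError(f"unknown sampling layout: {layout!r}")

    p_lv = np.interp(times, traj.t, traj.x[:, 1])
    rng = np.random.default_rng(seed)
    values = p_lv + rng.normal(0.0, noise_sd, size=n_m)
    sigmas = np.full(n_m, max(noise_sd, 1.0))
    return MeasurementSet(times=times, values=values, sigmas=sigmas)
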