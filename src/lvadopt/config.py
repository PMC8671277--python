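"""Run configuration: schema-validated YAML in, reproducible artifacts out.

A run configuration bundles the model parameter overrides, constraint
tolerances, transcription settings and run controls (seed, scenarios,
output directory).  Loading is strict: unknown keys are rejected with the
offending field named, and all numeric validation is delegated to the
underlying typed configuration objects, so a loaded config is usable as is.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .collocation import TranscriptionConfig
from .control import OCPConfig
from .model import ModelParameters
from .simulate import ConstraintConfig

__all__ = ["RunConfig", "load_config", "save_config"]

_SECTIONS = ("model", "constraints", "ocp", "transcription", "pe", "run")


@dataclass(frozen=True)
class PESettings:
    n_m: int = 27
    noise_sd: float = 1.0
    dt: float = 0.002
    max_iter: int = 30
    p0_relative_perturbation: float = 0.10

    def __post_init__(self) -> None:
        if self.n_m < 2:
            raise ValueError("pe.n_m must be at least 2")
        if self.noise_sd < 0:
            raise ValueError("pe.noise_sd must be non-negative")
        if not self.dt > 0:
            raise ValueError("pe.dt must be positive")


@dataclass(frozen=True)
class RunSettings:
    seed: int = 0
    scenarios: tuple[str, ...] = ("constant", "continuous", "pwc")
    out_dir: str = "runs"
    verbosity: int = 1
    simulate_speed_rpm: float = 0.0   # 0 -> pump absent in `simulate`

    def __post_init__(self) -> None:
        valid = {"constant", "continuous", "pwc"}
        bad = set(self.scenarios) - valid
        if bad:
            raise ValueError(f"unknown scenarios: {sorted(bad)}")


@dataclass(frozen=True)
class RunConfig:
    model: ModelParameters = field(default_factory=ModelParameters)
    constraints: ConstraintConfig = field(default_factory=ConstraintConfig)
    ocp: OCPConfig = field(default_factory=OCPConfig)
    transcription: TranscriptionConfig = field(default_factory=TranscriptionConfig)
    pe: PESettings = field(default_factory=PESettings)
    run: RunSettings = field(default_factory=RunSettings)

    def to_dict(self) -> dict:
        def clean(obj):
            d = dataclasses.asdict(obj)
            return {
                k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()
            }

        out = {name: clean(getattr(self, name)) for name in _SECTIONS}
        # nested ConstraintConfig inside OCPConfig is serialized at top level
        out["ocp"].pop("constraints", None)
        return out


def _build_section(cls, data: dict, section: str, **extra):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown key(s) in section '{section}': {sorted(unknown)}")
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            v = data[f.name]
            coerced[f.name] = tuple(v) if isinstance(v, list) else v
    coerced.update(extra)
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid section '{section}': {exc}") from exc


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Missing sections fall back to documented defaults; unknown sections or
    keys raise with a field-level message.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError("configuration root must be a mapping")
    unknown = set(doc) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown configuration section(s): {sorted(unknown)}")

    model = (
        ModelParameters.from_dict(doc["model"]) if "model" in doc
        else ModelParameters()
    )
    constraints = _build_section(
        ConstraintConfig, doc.get("constraints", {}), "constraints"
    )
    ocp = _build_section(
        OCPConfig, doc.get("ocp", {}), "ocp", constraints=constraints
    )
    transcription = _build_section(
        TranscriptionConfig, doc.get("transcription", {}), "transcription"
    )
    pe = _build_section(PESettings, doc.get("pe", {}), "pe")
    run = _build_section(RunSettings, doc.get("run", {}), "run")
    return RunConfig(
        model=model, constraints=constraints, ocp=ocp,
        transcription=transcription, pe=pe, run=run,
    )


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
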