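"""Run configuration: structured-text (YAML) loading, validation, fixtures.

A configuration file has up to four flat sections::

    parameters:      # ParameterSet fields, conventional symbol names
      q0: 28.0
      n: 5
    solver:
      step: 0.01
    protocol:
      kind: dex      # simulate | dex | acth | two_stage
      basin: normal
      measurement_mode: period_averaged
    output:
      directory: runs
      write_trajectory: true

Unknown keys are rejected with the offending key named.  An empty file (or
no file) yields the reference defaults.  Every CLI run re-serializes its
fully resolved configuration next to its outputs, and reloading that file
reproduces the run bit for bit (there is no randomness anywhere).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .parameters import ParameterSet
from .solver import DEFAULT_STEP

__all__ = ["RunConfig", "load_config", "make_fixture", "FIXTURE_NAMES"]

_SOLVER_KEYS = {"step"}
_PROTOCOL_KEYS = {
    "kind", "basin", "measurement_mode", "t_end",
    "dex_height", "dex_width", "post_measure_time",
    "acth_height", "acth_width", "response_window",
    "reactivity", "phase_at_dose", "n_phases",
    "stressor_amplitude", "stressor_start", "stressor_duration",
}
_OUTPUT_KEYS = {"directory", "prefix", "write_trajectory"}
_KINDS = {"simulate", "dex", "acth", "two_stage"}


@dataclass(frozen=True)
class RunConfig:
    """A fully resolved, validated run configuration (seedless by design)."""

    parameters: ParameterSet = field(default_factory=ParameterSet)
    solver: dict = field(default_factory=lambda: {"step": DEFAULT_STEP})
    protocol: dict = field(default_factory=lambda: {"kind": "simulate", "basin": "normal"})
    output: dict = field(default_factory=lambda: {"directory": "runs", "write_trajectory": True})

    def __post_init__(self) -> None:
        _check_keys("solver", self.solver, _SOLVER_KEYS)
        _check_keys("protocol", self.protocol, _PROTOCOL_KEYS)
        _check_keys("output", self.output, _OUTPUT_KEYS)
        step = self.solver.get("step", DEFAULT_STEP)
        if not (isinstance(step, (int, float)) and step > 0):
            raise ValueError("solver.step must be a positive number")
        kind = self.protocol.get("kind", "simulate")
        if kind not in _KINDS:
            raise ValueError(f"protocol.kind must be one of {sorted(_KINDS)}, got {kind!r}")
        basin = self.protocol.get("basin", "normal")
        if basin not in ("normal", "diseased"):
            raise ValueError("protocol.basin must be 'normal' or 'diseased'")

    @property
    def step(self) -> float:
        return float(self.solver.get("step", DEFAULT_STEP))

    def to_dict(self) -> dict:
        return {
            "parameters": self.parameters.to_dict(),
            "solver": dict(self.solver),
            "protocol": dict(self.protocol),
            "output": dict(self.output),
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml())

    def with_overrides(
        self,
        parameters: Mapping[str, Any] | None = None,
        solver: Mapping[str, Any] | None = None,
        protocol: Mapping[str, Any] | None = None,
        output: Mapping[str, Any] | None = None,
    ) -> "RunConfig":
        """Layer (e.g. CLI) overrides on top of this configuration."""
        params = self.parameters
        if parameters:
            params = params.replace(**{k: float(v) for k, v in parameters.items()})
        return RunConfig(
            parameters=params,
            solver={**self.solver, **(solver or {})},
            protocol={**self.protocol, **(protocol or {})},
            output={**self.output, **(output or {})},
        )


def _check_keys(section: str, d: Mapping[str, Any], allowed: set[str]) -> None:
    if not isinstance(d, Mapping):
        raise ValueError(f"config section {section!r} must be a mapping")
    unknown = set(d) - allowed
    if unknown:
        raise KeyError(
            f"unknown key(s) {sorted(unknown)} in config section {section!r}; "
            f"valid keys: {sorted(allowed)}"
        )


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    ``None`` or an empty file yields pure defaults (the reference parameter
    set).  Validation errors name the offending section and key.
    """
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if raw is None:
        return RunConfig()
    if not isinstance(raw, Mapping):
        raise ValueError(f"config file {path} must contain a mapping of sections")
    unknown = set(raw) - {"parameters", "solver", "protocol", "output"}
    if unknown:
        raise KeyError(
            f"unknown config section(s) {sorted(unknown)}; "
            "valid sections: parameters, solver, protocol, output"
        )
    params = ParameterSet.from_dict(raw.get("parameters", {}) or {})
    return RunConfig(
        parameters=params,
        solver=dict(raw.get("solver", {}) or {"step": DEFAULT_STEP}),
        protocol=dict(raw.get("protocol", {}) or {"kind": "simulate", "basin": "normal"}),
        output=dict(raw.get("output", {}) or {"directory": "runs", "write_trajectory": True}),
    )


#: Ready-to-run scenario configurations.
FIXTURE_NAMES = (
    "bistable_reference",
    "monostable_low_n",
    "dst_normal",
    "dst_diseased",
    "acth_hypo",
    "two_stage",
)


def make_fixture(name: str) -> RunConfig:
    """Return the named scenario as a ready-to-run configuration.

    * ``bistable_reference`` -- the reference set; three nullcline
      intersections, two stable.
    * ``monostable_low_n`` -- Hill coefficient lowered to n = 4, below the
      fold onset: monotone c-nullcline, single intersection.
    * ``dst_normal`` / ``dst_diseased`` -- the DST from either basin;
      identical parameters, different starting basin.
    * ``acth_hypo`` -- cosyntropin stimulation with 10% adrenal
      hyporeactivity.
    * ``two_stage`` -- DEX followed by a 60-min I_ext = 0.5 stressor at the
      9-h draw.
    """
    base = RunConfig()
    if name == "bistable_reference":
        return base.with_overrides(protocol={"kind": "simulate", "t_end": 100.0})
    if name == "monostable_low_n":
        return base.with_overrides(parameters={"n": 4.0},
                                   protocol={"kind": "simulate", "t_end": 100.0})
    if name == "dst_normal":
        return base.with_overrides(protocol={"kind": "dex", "basin": "normal"})
    if name == "dst_diseased":
        return base.with_overrides(protocol={"kind": "dex", "basin": "diseased"})
    if name == "acth_hypo":
        return base.with_overrides(protocol={"kind": "acth", "reactivity": 0.9,
                                             "phase_at_dose": 0.0})
    if name == "two_stage":
        return base.with_overrides(protocol={
            "kind": "two_stage", "basin": "diseased",
            "stressor_amplitude": 0.5,
        })
    raise ValueError(f"unknown fixture {name!r}; valid names: {list(FIXTURE_NAMES)}")
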