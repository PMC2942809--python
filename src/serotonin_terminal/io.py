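"""Configuration loading and deterministic result serialization.

Run configurations are TOML; results are written as CSV (tables and
trajectories, header row with units encoded in the column names) and JSON
(reports and summaries, snake-case keys).  Field ordering and decimal
formatting are fixed so two runs with the same config produce byte-identical
output.
"""

from __future__ import annotations

import dataclasses
import difflib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .model import AutoreceptorConfig, KineticParameters
from .solvers import SteadyStateReport, Trajectory

__all__ = ["RunConfig", "load_config", "write_outputs", "dump_toml"]

#: experiments the `experiment` entry may name
KNOWN_EXPERIMENTS = ("table4", "pulse", "meals", "homeostasis", "ssri",
                     "agonist")

_PARAM_NAMES = tuple(f.name for f in dataclasses.fields(KineticParameters))
#: constants whose defaults come from calibration rather than measurement
_CALIBRATED = {"mat_k_out", "pool_k1", "pool_k_catab"}


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration: parameter overrides, autoreceptor
    flags, constant-driver values, experiment selection and options."""

    parameters: dict[str, float] = field(default_factory=dict)
    synthesis_feedback: bool = True
    release_feedback: bool = True
    fire: float = 1.0
    fluox: float = 1.0
    btrp: float = 96.0
    experiment: str | None = None
    experiment_options: dict = field(default_factory=dict)
    output_dir: str = "results"
    rtol: float = 1e-8

    def build_parameters(self) -> KineticParameters:
        return KineticParameters().replace(**self.parameters)

    def autoreceptors(self) -> AutoreceptorConfig:
        return AutoreceptorConfig(self.synthesis_feedback,
                                  self.release_feedback)

    def provenance(self) -> dict[str, str]:
        """Per-parameter provenance tags for the effective config echo."""
        tags = {}
        for name in _PARAM_NAMES:
            if name in self.parameters:
                tags[name] = "user"
            elif name in _CALIBRATED:
                tags[name] = "calibrated"
            else:
                tags[name] = "resolved-default"
        return tags

    def effective(self) -> dict:
        """The full effective configuration (defaults + overrides)."""
        p = self.build_parameters()
        return {
            "parameters": {n: getattr(p, n) for n in _PARAM_NAMES},
            "provenance": self.provenance(),
            "autoreceptors": {"synthesis_feedback": self.synthesis_feedback,
                              "release_feedback": self.release_feedback},
            "drivers": {"fire": self.fire, "fluox": self.fluox,
                        "btrp": self.btrp},
            "experiment": self.experiment or "",
            "experiment_options": dict(self.experiment_options),
            "output_dir": self.output_dir,
            "rtol": self.rtol,
        }


def _reject_unknown(given: dict, allowed: tuple[str, ...], where: str) -> None:
    for key in given:
        if key not in allowed:
            hint = difflib.get_close_matches(key, allowed, n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValueError(f"unknown key {key!r} in {where}{suffix}")


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a TOML run configuration.

    Every section and key is optional; omitted fields fall back to the
    calibrated defaults.  Unknown keys are rejected with the nearest valid
    name suggested.
    """
    raw = tomllib.loads(Path(path).read_text())
    top_keys = ("parameters", "autoreceptors", "drivers", "experiment",
                "experiment_options", "output_dir", "rtol")
    _reject_unknown(raw, top_keys, "config")

    params = dict(raw.get("parameters", {}))
    _reject_unknown(params, _PARAM_NAMES, "[parameters]")
    auto = raw.get("autoreceptors", {})
    _reject_unknown(auto, ("synthesis_feedback", "release_feedback"),
                    "[autoreceptors]")
    drv = raw.get("drivers", {})
    _reject_unknown(drv, ("fire", "fluox", "btrp"), "[drivers]")
    exp = raw.get("experiment")
    if exp is not None and exp not in KNOWN_EXPERIMENTS:
        hint = difflib.get_close_matches(exp, KNOWN_EXPERIMENTS, n=1)
        suffix = f"; did you mean {hint[0]!r}?" if hint else ""
        raise ValueError(f"unknown experiment {exp!r}{suffix}")
    return RunConfig(
        parameters={k: float(v) for k, v in params.items()},
        synthesis_feedback=bool(auto.get("synthesis_feedback", True)),
        release_feedback=bool(auto.get("release_feedback", True)),
        fire=float(drv.get("fire", 1.0)),
        fluox=float(drv.get("fluox", 1.0)),
        btrp=float(drv.get("btrp", 96.0)),
        experiment=exp,
        experiment_options=dict(raw.get("experiment_options", {})),
        output_dir=str(raw.get("output_dir", "results")),
        rtol=float(raw.get("rtol", 1e-8)),
    )


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(float(v)) if isinstance(v, float) else str(v)
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def dump_toml(data: dict, prefix: str = "") -> str:
    """Minimal deterministic TOML emitter for nested dicts of scalars."""
    lines, tables = [], []
    for key in data:
        value = data[key]
        if isinstance(value, dict):
            tables.append(key)
        else:
            lines.append(f"{key} = {_toml_value(value)}")
    for key in tables:
        name = f"{prefix}{key}"
        lines.append(f"\n[{name}]")
        lines.append(dump_toml(data[key], prefix=f"{name}."))
    return "\n".join(lines).strip() + "\n"


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True,
                               allow_nan=False) + "\n")


def write_outputs(result, out_dir: str | Path,
                  config_echo: dict | None = None) -> list[Path]:
    """Write an ExperimentResult, SteadyStateReport, or Trajectory.

    Returns the list of files written.  CSV for tables and trajectories,
    JSON for reports and summaries, plus a TOML config echo when given.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit_csv(df: pd.DataFrame, name: str) -> None:
        path = out / f"{name}.csv"
        _write_csv(df, path)
        written.append(path)

    def emit_json(obj, name: str) -> None:
        path = out / f"{name}.json"
        _write_json(obj, path)
        written.append(path)

    if isinstance(result, SteadyStateReport):
        emit_json(result.to_dict(), "steady_state")
    elif isinstance(result, Trajectory):
        emit_csv(result.to_dataframe(), "trajectory")
    else:  # ExperimentResult (duck-typed to avoid a hard import cycle)
        for name, df in result.tables.items():
            emit_csv(df, name)
        for name, traj in result.trajectories.items():
            emit_csv(traj.to_dataframe(), f"trajectory_{name}")
        emit_json({"name": result.name, "config": result.config,
                   "summary": result.summary}, "summary")
    if config_echo is not None:
        path = out / "config.toml"
        path.write_text(dump_toml(config_echo))
        written.append(path)
    return written
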