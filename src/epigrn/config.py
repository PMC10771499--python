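"""Configuration files, validation and unit conversion.

A run configuration is a YAML (or JSON) document with four blocks::

    experiment: reprogram        # differentiate | reprogram | compare
    model:                       # any DimensionlessParams field, plus the
      eps_d: 0.2                 # shorthands p_bar and alpha_prime
      mu_tilde_prime: 0.5
    schedule:                    # constant level or [[start, end, level], ...]
      u_O: 320
      u_T: [[0.0, 100.8, 160]]
    init: repressed              # active | repressed | explicit 18-count list
    run:
      N: 100
      seed: 0
      tau_end: 201.6
      threshold_on: 40
      threshold_off: 0
      division_mode: off
      sample_step: 0.96

Unknown keys are rejected with an error naming the offending key.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .experiments import ExperimentSpec
from .params import DimensionlessParams, GENES, ParameterError, TAU_PER_DAY
from .schedules import OverexpressionSchedule

_TOP_KEYS = {"experiment", "name", "model", "schedule", "init", "run"}
_RUN_KEYS = {"N", "seed", "tau_end", "threshold_on", "threshold_off",
             "division_mode", "division_period", "sample_step"}
_KINDS = ("differentiate", "reprogram", "compare")


def day_tau_convert(value: float, direction: str) -> float:
    """Convert between days and normalized time (21 days == tau 201.6)."""
    if value < 0:
        raise ParameterError(f"value must be >= 0, got {value}")
    if direction in ("to_tau", "days_to_tau"):
        return value * TAU_PER_DAY
    if direction in ("to_days", "tau_to_days"):
        return value / TAU_PER_DAY
    raise ParameterError(f"direction must be 'to_tau' or 'to_days', got {direction!r}")


def _schedule_from_config(block: dict, tau_end: float) -> OverexpressionSchedule:
    if not isinstance(block, dict):
        raise ParameterError("schedule block must be a mapping")
    unknown = set(block) - {f"u_{g}" for g in GENES}
    if unknown:
        raise ParameterError(f"unknown schedule key(s): {sorted(unknown)}")
    segments = {g: [] for g in GENES}
    for g in GENES:
        val = block.get(f"u_{g}", 0)
        if isinstance(val, (int, float)):
            if val < 0:
                raise ParameterError(f"u_{g} must be >= 0, got {val}")
            if val > 0:
                segments[g] = [(0.0, float(tau_end), float(val))]
        else:
            segments[g] = [tuple(map(float, seg)) for seg in val]
    return OverexpressionSchedule(segments)


def spec_from_dict(doc: dict) -> ExperimentSpec:
    """Build a fully validated :class:`ExperimentSpec` from a config mapping."""
    if not isinstance(doc, dict):
        raise ParameterError("configuration must be a mapping")
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise ParameterError(f"unknown configuration key(s): {sorted(unknown)}")
    kind = doc.get("experiment", "reprogram")
    if kind not in _KINDS:
        raise ParameterError(
            f"experiment must be one of {_KINDS}, got {kind!r}")
    run = dict(doc.get("run") or {})
    unknown = set(run) - _RUN_KEYS
    if unknown:
        raise ParameterError(f"unknown run key(s): {sorted(unknown)}")
    model = dict(doc.get("model") or {})
    params = DimensionlessParams().with_updates(**model)
    tau_end = float(run.get("tau_end", 201.6))
    schedule = _schedule_from_config(doc.get("schedule") or {}, tau_end)
    init = doc.get("init", "active" if kind == "differentiate" else "repressed")
    if not isinstance(init, str):
        init = np.asarray(init, dtype=np.int64)
    spec = ExperimentSpec(
        name=str(doc.get("name", kind)),
        kind=kind,
        params=params,
        init=init,
        schedule=schedule,
        N=int(run.get("N", 100)),
        seed=int(run.get("seed", 0)),
        tau_end=tau_end,
        threshold_on=int(run.get("threshold_on", 40)),
        threshold_off=int(run.get("threshold_off", 0)),
        division_mode=str(run.get("division_mode", "off")),
        division_period=run.get("division_period"),
        sample_step=float(run.get("sample_step", 0.96)),
    )
    return spec.validate()


def spec_to_dict(spec: ExperimentSpec) -> dict:
    """Serialize a spec to the config mapping (inverse of spec_from_dict)."""
    defaults = DimensionlessParams()
    model = {k: v for k, v in spec.params.to_dict().items()
             if v != getattr(defaults, k)}
    init = spec.init if isinstance(spec.init, str) else [int(v) for v in spec.init]
    doc = {
        "experiment": spec.kind,
        "name": spec.name,
        "model": model,
        "schedule": spec.schedule.to_config(),
        "init": init,
        "run": {
            "N": spec.N, "seed": spec.seed, "tau_end": spec.tau_end,
            "threshold_on": spec.threshold_on,
            "threshold_off": spec.threshold_off,
            "division_mode": spec.division_mode,
            "sample_step": spec.sample_step,
        },
    }
    if spec.division_period is not None:
        doc["run"]["division_period"] = spec.division_period
    return doc


def load_config(path) -> ExperimentSpec:
    """Load and validate a YAML/JSON experiment configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return spec_from_dict(doc or {})


def dump_config(spec: ExperimentSpec, path) -> None:
    """Write a spec back out as YAML; load(dump(spec)) == spec."""
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)
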