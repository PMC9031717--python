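"""Experiment configuration: defaults, YAML/JSON loading, strict resolution.

The default experiment mirrors the instrument protocol: nine working
electrodes (four alleles in duplicate plus one control), a 25 -> 95 degC
ramp at 1 degC per step, and SWV scans over 0 - 0.7 V with a 10 mV step,
0.1 V modulation amplitude and 25 Hz frequency.  Unknown keys are
rejected so typos never pass silently; the fully resolved configuration
is written beside the outputs of every run.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Dict, Mapping, Optional

import yaml

from .melt import ALLELES, DuplexSpec, MismatchPenaltySet
from .simulate import ArrayLayout, Electrode, ExperimentConfig
from .swv import FerrocenePeakModel, SWVParams
from .thermal import FOPDTModel, PIGains, PWMActuator, RampProtocol

__all__ = [
    "ConfigError",
    "DEMO_PLANT",
    "PUBLISHED_GAINS",
    "default_config_dict",
    "resolve_config",
    "load_plant",
    "dump_config",
]


class ConfigError(ValueError):
    pass


#: Stand-in heating plate used by examples and the ``tune`` command.  The
#: real plate coefficients are not published; this plant is chosen to be
#: stable and non-overshooting under the published controller gains
#: (Kc = 55.85, Ki = 1.33) with the 10-bit, 5 V PWM actuator when
#: simulated at a sample interval of <= 0.1 s.
DEMO_PLANT = FOPDTModel(gain=15.0, time_constant=500.0, dead_time=0.1, ambient=25.0)

#: Published PI controller gains.
PUBLISHED_GAINS = PIGains(proportional=55.85, integral=1.33)


def _default_electrodes() -> list:
    rows = []
    i = 1
    for allele in ALLELES:
        for _ in range(2):
            rows.append({"id": f"e{i}", "role": "assay", "allele": allele})
            i += 1
    rows.append({"id": f"e{i}", "role": "control", "allele": None})
    return rows


def default_config_dict() -> Dict[str, Any]:
    """The full default experiment as a plain dict (what ``emca config
    --show`` prints)."""
    return {
        "seed": 0,
        "ramp": {
            "start": 25.0,
            "end": 95.0,
            "step": 1.0,
            "dwell": 30.0,
            "sample_interval": 1.0,
        },
        "layout": {"electrodes": _default_electrodes()},
        "duplexes": {
            allele: {
                "name": f"{allele}-duplex",
                "surface_tm": 37.0,
                "vant_hoff_enthalpy": 300.0,
                "solution_offset": 10.0,
            }
            for allele in ALLELES
        },
        "penalties": {"full": 0.0, "bottom": 0.8, "top": 2.1, "middle": 4.3},
        "peak_model": {
            "peak_potential": 0.35,
            "peak_width_sigma": 0.05,
            "max_current": 1.0,
            "baseline_intercept": 0.0,
            "baseline_slope": 0.0,
            "noise_sd": 0.0,
        },
        "swv": {
            "potential_start": 0.0,
            "potential_end": 0.7,
            "step_potential": 0.010,
            "modulation_amplitude": 0.1,
            "frequency": 25.0,
        },
        "electrode_scale_sd": 0.0,
    }


def _merge(defaults: Any, user: Any, path: str) -> Any:
    """Deep-merge ``user`` onto ``defaults``, rejecting unknown keys."""
    if user is None:
        return defaults
    if isinstance(defaults, Mapping):
        if not isinstance(user, Mapping):
            raise ConfigError(f"{path or 'config'}: expected a mapping, got {user!r}")
        merged = dict(defaults)
        for key, value in user.items():
            if key not in defaults:
                raise ConfigError(f"unknown config key {path + key!r}")
            merged[key] = _merge(defaults[key], value, f"{path}{key}.")
        return merged
    return user  # leaves (including lists) replace wholesale


def _load_file(path) -> Dict[str, Any]:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such config file: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return data


def resolve_config(
    path=None,
    overrides: Optional[Mapping[str, Any]] = None,
    seed: Optional[int] = None,
) -> ExperimentConfig:
    """Load YAML/JSON config, fill defaults, apply overrides last.

    ``overrides`` uses dotted keys (``{"ramp.step": 0.5}``) or nested
    dicts; an explicit ``seed`` wins over both.
    """
    merged = default_config_dict()
    if path is not None:
        merged = _merge(merged, _load_file(path), "")
    if overrides:
        nested: Dict[str, Any] = {}
        for key, value in overrides.items():
            parts = key.split(".")
            node = nested
            for p in parts[:-1]:
                node = node.setdefault(p, {})
            node[parts[-1]] = value
        merged = _merge(merged, nested, "")
    if seed is not None:
        merged["seed"] = int(seed)
    return build_experiment_config(merged)


def build_experiment_config(d: Mapping[str, Any]) -> ExperimentConfig:
    try:
        electrodes = tuple(
            Electrode(id=str(e["id"]), role=e["role"], allele=e.get("allele"))
            for e in d["layout"]["electrodes"]
        )
        layout = ArrayLayout(electrodes=electrodes)
        ramp = RampProtocol(**d["ramp"])
        duplexes = {
            allele: DuplexSpec(allele=allele, **spec)
            for allele, spec in d["duplexes"].items()
        }
        penalties = MismatchPenaltySet(delta_tm=dict(d["penalties"]))
        peak = FerrocenePeakModel(**d["peak_model"])
        swv = SWVParams(**d["swv"])
        return ExperimentConfig(
            seed=int(d["seed"]),
            layout=layout,
            ramp=ramp,
            duplexes=duplexes,
            penalties=penalties,
            peak_model=peak,
            swv=swv,
            electrode_scale_sd=float(d["electrode_scale_sd"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(f"invalid configuration: {exc}") from exc


def config_to_dict(config: ExperimentConfig) -> Dict[str, Any]:
    return {
        "seed": config.seed,
        "ramp": {
            "start": config.ramp.start,
            "end": config.ramp.end,
            "step": config.ramp.step,
            "dwell": config.ramp.dwell,
            "sample_interval": config.ramp.sample_interval,
        },
        "layout": {
            "electrodes": [
                {"id": e.id, "role": e.role, "allele": e.allele}
                for e in config.layout.electrodes
            ]
        },
        "duplexes": {
            allele: {
                "name": spec.name,
                "surface_tm": spec.surface_tm,
                "vant_hoff_enthalpy": spec.vant_hoff_enthalpy,
                "solution_offset": spec.solution_offset,
            }
            for allele, spec in config.duplexes.items()
        },
        "penalties": dict(config.penalties.delta_tm),
        "peak_model": {
            "peak_potential": config.peak_model.peak_potential,
            "peak_width_sigma": config.peak_model.peak_width_sigma,
            "max_current": config.peak_model.max_current,
            "baseline_intercept": config.peak_model.baseline_intercept,
            "baseline_slope": config.peak_model.baseline_slope,
            "noise_sd": config.peak_model.noise_sd,
        },
        "swv": {
            "potential_start": config.swv.potential_start,
            "potential_end": config.swv.potential_end,
            "step_potential": config.swv.step_potential,
            "modulation_amplitude": config.swv.modulation_amplitude,
            "frequency": config.swv.frequency,
        },
        "electrode_scale_sd": config.electrode_scale_sd,
    }


def dump_config(config: ExperimentConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def load_plant(path_or_demo) -> FOPDTModel:
    """Load an FOPDT plant from YAML/JSON; the literal string ``"demo"``
    returns the built-in demo plant."""
    if str(path_or_demo) == "demo":
        return DEMO_PLANT
    data = _load_file(path_or_demo)
    allowed = {"gain", "time_constant", "dead_time", "ambient"}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown plant key(s): {sorted(unknown)}")
    try:
        return FOPDTModel(**data)
    except ValueError as exc:
        raise ConfigError(f"invalid plant: {exc}") from exc


def default_actuator() -> PWMActuator:
    return PWMActuator(bits=10, full_scale=5.0)
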