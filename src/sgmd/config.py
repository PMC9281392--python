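"""Declarative run configuration: a YAML mapping validated into RunConfig.

Unknown keys are rejected with their location so typos fail loudly; the
Methods defaults (dt 0.005, gamma 0.1, cutoff 3.5, image radius 2) are
applied when omitted. A config round-trips losslessly through
``write_config``/``read_config``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .integrators import ThermoParams
from .npt import NPTParams

__all__ = ["RunConfig", "OutputConfig", "read_config", "write_config",
           "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class OutputConfig:
    log: str | None = None
    structure: str | None = None
    interval: int = 100
    expand: bool = False


@dataclass
class RunConfig:
    group: str
    dimension: int = 2
    n_asym: int = 1
    wyckoff_sites: list[str] = field(default_factory=list)
    ensemble: str = "nve"
    density: float | None = None
    box: list | None = None
    steps: int = 1000
    image_radius: int = 2
    cutoff: float = 3.5
    start_temperature: float | None = None
    seed: int = 0
    thermo: ThermoParams = field(default_factory=ThermoParams)
    npt: NPTParams | None = None
    output: OutputConfig = field(default_factory=OutputConfig)

    def __post_init__(self):
        if self.ensemble not in ("nve", "nvt", "npt"):
            raise ConfigError(f"unknown ensemble {self.ensemble!r}")
        if self.ensemble == "npt" and self.npt is None:
            raise ConfigError("ensemble 'npt' requires an 'npt' section")
        if self.ensemble == "nvt" and self.thermo.temperature <= 0:
            raise ConfigError("ensemble 'nvt' requires thermo.temperature > 0")
        if self.density is None and self.box is None:
            raise ConfigError("one of 'density' or 'box' is required")


def _build(cls, data: dict, where: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{where}: expected a mapping")
    fields = {f for f in cls.__dataclass_fields__}
    unknown = set(data) - fields
    if unknown:
        raise ConfigError(
            f"{where}: unknown key(s) {sorted(unknown)}; valid: {sorted(fields)}"
        )
    return data


def read_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    data = dict(_build(RunConfig, raw, str(path)))
    if "thermo" in data:
        data["thermo"] = ThermoParams(
            **_build(ThermoParams, data["thermo"], f"{path}:thermo")
        )
    if data.get("npt") is not None:
        data["npt"] = NPTParams(**_build(NPTParams, data["npt"], f"{path}:npt"))
    if "output" in data:
        data["output"] = OutputConfig(
            **_build(OutputConfig, data["output"], f"{path}:output")
        )
    try:
        return RunConfig(**data)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from None


def write_config(config: RunConfig, path) -> None:
    data = asdict(config)
    if data.get("npt") is None:
        data.pop("npt", None)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
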