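"""YAML configuration loading with strict schema validation.

The configuration mirrors :class:`cinemotion.study.StudyConfig`: one
section per stage (phantom, breathing, acquisition, coefficients,
registration) plus top-level pipeline settings.  Unknown keys are
rejected with their full key path so typos cannot silently fall back to
defaults.
"""

from __future__ import annotations

import dataclasses

import yaml

from .exceptions import ConfigurationError
from .study import StudyConfig

__all__ = ["load_config", "config_to_dict", "dump_default_config"]


def _coerce(value, template):
    if isinstance(template, tuple):
        if not isinstance(value, (list, tuple)):
            raise TypeError(f"expected a sequence, got {type(value).__name__}")
        return tuple(
            tuple(v) if isinstance(v, (list, tuple)) else v for v in value
        )
    if isinstance(template, bool):
        return bool(value)
    if isinstance(template, int) and not isinstance(value, bool):
        return int(value)
    if isinstance(template, float):
        return float(value)
    return value


def _build(dc_value, data: dict, path: str):
    cls = type(dc_value)
    field_map = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        where = f"{path}.{key}" if path else key
        if key not in field_map:
            raise ConfigurationError(f"unknown configuration key: {where}")
        current = getattr(dc_value, key)
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            kwargs[key] = _build(current, value, where)
        else:
            try:
                kwargs[key] = _coerce(value, current)
            except (TypeError, ValueError) as err:
                raise ConfigurationError(f"invalid value for {where}: {err}") from err
    return dataclasses.replace(dc_value, **kwargs)


def load_config(path) -> StudyConfig:
    """Load a YAML study configuration, validating every key."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: configuration must be a mapping")
    return _build(StudyConfig(), data, "")


def config_to_dict(config: StudyConfig) -> dict:
    def clean(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: clean(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, tuple):
            return [clean(v) for v in obj]
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        return obj

    return clean(config)


def dump_default_config(path) -> None:
    """Write the full default configuration (every tunable, with defaults)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(StudyConfig()), fh, sort_keys=False)
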