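"""Structured (YAML) configuration for the front end and detector."""

from __future__ import annotations

import dataclasses
from typing import Tuple

import yaml

from .detection import DetectionConfig
from .errors import ConfigurationError
from .features import FeatureConfig


def load_config(path) -> Tuple[FeatureConfig, DetectionConfig]:
    """Read a YAML config with optional ``features:`` and ``detection:``
    sections; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = []
    for section, cls in (("features", FeatureConfig), ("detection", DetectionConfig)):
        kwargs = raw.get(section, {}) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(kwargs) - valid
        if unknown:
            raise ConfigurationError(f"unknown {section} config keys: {sorted(unknown)}")
        out.append(cls(**kwargs))
    return out[0], out[1]


def save_config(path, feature_cfg: FeatureConfig, detection_cfg: DetectionConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({
            "features": dataclasses.asdict(feature_cfg),
            "detection": dataclasses.asdict(detection_cfg),
        }, fh, sort_keys=True)
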