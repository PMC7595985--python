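"""Scenario configuration.

A :class:`ScenarioConfig` collects everything a single in-silico fermentation
needs: initial glucose (mM), the hexanoic-acid feed (clamped extracellular
concentration in mM, or off), which enzyme variants to apply, the simulation
horizon, and a seed for anything stochastic downstream.  Configs are loaded
from / saved to a flat YAML mapping; unknown keys are rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml

from .errors import ConfigError, UnsupportedScenarioError
from .variants import DEFAULT_VARIANT_LABELS

__all__ = ["ScenarioConfig", "GLUCOSE_MM_PER_G_PER_L"]

log = logging.getLogger("cannakin")

#: 1 g/L glucose in mM (mw 180.16); 20 g/L ~ 111 mM, the default batch start.
GLUCOSE_MM_PER_G_PER_L = 1000.0 / 180.16


@dataclass
class ScenarioConfig:
    """Settings for one simulated batch fermentation.

    ``ha_feed_mM=None`` switches the feed off entirely.  Feeds above
    ``ha_warn_threshold_mM`` (growth is unaffected up to 1 mM hexanoic acid;
    above that, cells are impaired) log a warning but are simulated anyway —
    the model itself carries no toxicity feedback.
    """

    glucose_mM: float = 111.0
    ha_feed_mM: Optional[float] = 1.0
    variants: tuple[str, ...] = DEFAULT_VARIANT_LABELS
    t_end_h: float = 40.0
    dt_out_h: float = 0.05
    seed: int = 0
    params_path: Optional[str] = None
    ha_warn_threshold_mM: float = 1.0
    fas_route: bool = False

    def __post_init__(self) -> None:
        if self.glucose_mM < 0:
            raise ConfigError(f"glucose_mM must be >= 0, got {self.glucose_mM}")
        if self.ha_feed_mM is not None and self.ha_feed_mM < 0:
            raise ConfigError(f"ha_feed_mM must be >= 0 or None, got {self.ha_feed_mM}")
        if self.t_end_h <= 0:
            raise ConfigError(f"t_end_h must be > 0, got {self.t_end_h}")
        if self.fas_route:
            raise UnsupportedScenarioError(
                "the native fatty-acid-synthase route to hexanoyl-CoA is not "
                "modeled; hexanoyl-CoA is supplied from the hexanoic-acid feed")
        if self.ha_feed_mM is not None and self.ha_feed_mM > self.ha_warn_threshold_mM:
            log.warning(
                "hexanoic-acid feed %.3g mM exceeds the %.3g mM growth-safe "
                "threshold; simulating anyway (no toxicity feedback is modeled)",
                self.ha_feed_mM, self.ha_warn_threshold_mM)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "variants" in d and d["variants"] is not None:
            d["variants"] = tuple(d["variants"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["variants"] = list(self.variants)
        return d

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text
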