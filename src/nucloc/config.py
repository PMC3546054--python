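"""Pipeline configuration: one validated object carrying every stage's parameters.

Defaults are the standard analysis settings for 4 s/frame light-stress
recordings: detection threshold 0.28 on the localization value, 5-frame moving
average, 5-frame minimum run, 3-pixel nucleus radius, 90 cytosol pixels, and a
60-minute observation window.  Unknown keys in a config file are rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .dynamics import AnalysisParams
from .quantify import QuantParams
from .synthetic import SimScenario

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    quant: QuantParams = field(default_factory=QuantParams)
    scenario: SimScenario = field(default_factory=SimScenario)
    seed: int = 0
    label: str = "condition"

    def with_seed(self, seed: int) -> "PipelineConfig":
        return dataclasses.replace(
            self, seed=seed, scenario=dataclasses.replace(self.scenario, seed=seed)
        )

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "seed": self.seed,
            "analysis": dataclasses.asdict(self.analysis),
            "quant": dataclasses.asdict(self.quant),
            "scenario": dataclasses.asdict(self.scenario),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        known = {"label", "seed", "analysis", "quant", "scenario"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sections = {}
        for key, typ in (("analysis", AnalysisParams), ("quant", QuantParams),
                         ("scenario", SimScenario)):
            sub = dict(data.get(key) or {})
            allowed = {f.name for f in fields(typ)}
            bad = set(sub) - allowed
            if bad:
                raise ValueError(f"unknown keys in {key!r}: {sorted(bad)}")
            for name in ("archetype_weights", "burst_duration_range"):
                if name in sub and isinstance(sub[name], list):
                    sub[name] = tuple(sub[name])
            sections[key] = typ(**sub)
        return cls(
            analysis=sections["analysis"],
            quant=sections["quant"],
            scenario=sections["scenario"],
            seed=int(data.get("seed", 0)),
            label=str(data.get("label", "condition")),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open("r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
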