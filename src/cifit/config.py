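"""Pipeline configuration: one validated object covering every module's knobs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cohort import CohortConfig
from .fat import RuleSet
from .tonotopy import GreenwoodParams

__all__ = ["PipelineConfig", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    greenwood: GreenwoodParams = GreenwoodParams()
    rules: RuleSet = RuleSet()
    cohort: CohortConfig = CohortConfig()
    standard_fat_lower_bounds: tuple[float, ...] | None = None  # None -> log default
    mismatch_representative: str = "geometric_mean"  # or "lower_bound"
    n_boot: int = 10_000
    alpha: float = 0.05
    analysis_seed: int = 0

    def __post_init__(self) -> None:
        if self.mismatch_representative not in ("geometric_mean", "lower_bound"):
            raise ValueError(
                f"unknown mismatch representative {self.mismatch_representative!r}"
            )
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["learning_models"] = {
            m: {arm: dataclasses.asdict(am) if dataclasses.is_dataclass(am) else am
                for arm, am in arms.items()}
            for m, arms in d["cohort"]["learning_models"].items()
        }
        return d

    def digest(self) -> str:
        """Stable hash of the full configuration, for run logs."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file plus keyword overrides.

    The YAML mirrors the dataclass nesting, e.g.::

        greenwood: {A: 165.4, a: 2.1, K: 0.88}
        cohort: {n_subjects: 14, master_seed: 7}
        n_boot: 10000
    """
    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update(overrides)
    kwargs: dict = {}
    if "greenwood" in raw:
        kwargs["greenwood"] = GreenwoodParams(**raw.pop("greenwood"))
    if "rules" in raw:
        r = raw.pop("rules")
        kwargs["rules"] = RuleSet(
            min_channels_below=tuple(tuple(p) for p in r.get("min_channels_below", ())) or
            RuleSet().min_channels_below,
            basal_max=r.get("basal_max", RuleSet().basal_max),
        )
    if "cohort" in raw:
        kwargs["cohort"] = CohortConfig(**raw.pop("cohort"))
    kwargs.update(raw)
    return PipelineConfig(**kwargs)
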