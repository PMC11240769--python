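"""Structured run configuration (YAML) for the filter pipeline.

A run config exposes every filter threshold plus the normalization options;
all defaults are the published values, so an empty file is a valid config.

Example::

    filter:
      min_norm_count: 10
      fc_down: 0.5
      frac_down: 0.5
      fc_recur: 1.0
      recur_rule: any
      tumor_requirement: auto
      pre_rule: each
    normalization:
      scope: per_patient      # or: cohort
      positive_subset: false
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from liqtrace.filtering import FilterConfig, NormalizationScope


@dataclass
class RunConfig:
    filter: FilterConfig = field(default_factory=FilterConfig)
    scope: NormalizationScope = NormalizationScope.PER_PATIENT
    positive_subset: bool = False


def load_run_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - {"filter", "normalization"}
    if unknown:
        raise ValueError(f"unknown run-config sections: {sorted(unknown)}")
    cfg = FilterConfig(**(raw.get("filter") or {}))
    norm = raw.get("normalization") or {}
    unknown = set(norm) - {"scope", "positive_subset"}
    if unknown:
        raise ValueError(f"unknown normalization options: {sorted(unknown)}")
    return RunConfig(
        filter=cfg,
        scope=NormalizationScope(norm.get("scope", "per_patient")),
        positive_subset=bool(norm.get("positive_subset", False)),
    )


__all__ = ["RunConfig", "load_run_config"]
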