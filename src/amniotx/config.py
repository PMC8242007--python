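"""Pipeline-wide thresholds and settings.

Defaults encode the analysis conventions the pipeline implements: a
differential-expression call requires fold change > 1.25 and q < 0.1;
gene-set enrichment and signature comparisons use q < 0.05; a gene is
tissue-specific when its tissue-vs-rest median ratio is at least 30 and
signatures average Z scores over the top 20 genes; prediction uses a
1000-tree random forest with risk horizons at 24 h, 1 week and 2 weeks.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

logger = logging.getLogger("amniotx")

HOURS_24_WEEKS = 24.0 / 168.0


@dataclass
class PipelineConfig:
    fc_threshold: float = 1.25
    de_q_threshold: float = 0.1
    enrich_q_threshold: float = 0.05
    signature_q_threshold: float = 0.05
    specificity_ratio: float = 30.0
    top_n_signature: int = 20
    n_trees: int = 1000
    auroc_horizons_weeks: list[float] = field(
        default_factory=lambda: [HOURS_24_WEEKS, 1.0, 2.0]
    )
    selection_target_size: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("de_q_threshold", "enrich_q_threshold", "signature_q_threshold",
                     "specificity_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must exceed 1 (linear-scale fold change)")
        if self.top_n_signature < 1 or self.n_trees < 1 or self.selection_target_size < 1:
            raise ValueError("counts must be >= 1")


def read_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML or JSON config; unspecified keys take the defaults.

    Unknown keys raise a warning but do not fail, so configs written for
    newer versions stay usable.
    """
    if path is None:
        return PipelineConfig()
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        warnings.warn(f"ignoring unknown config keys: {unknown}", stacklevel=2)
    return PipelineConfig(**{k: v for k, v in data.items() if k in known})
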