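"""Top-level pipeline configuration."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Any, Dict

from .classify import CvConfig
from .features import DtwParams, LstmSpec
from .select import SelectionConfig


@dataclass
class PipelineConfig:
    """Bundle of all stage configurations plus pipeline-level switches.

    ``stats_on`` picks which preprocessed variant feeds the statistical
    descriptors (``translated`` avoids the sigma/mu degeneracy of Z-scored
    data); ``trial_aggregation`` controls per-subject averaging of trial
    feature vectors; ``selection_scope`` decides whether the hybrid filter
    runs inside each CV training fold (leakage-safe) or once globally.
    ``template_scope='global'`` pools all controls into one healthy template
    (the single-pass protocol); ``'per_fold'`` rebuilds the template from
    training-fold controls only, removing the slight control self-reference
    bias of a pooled template.
    """

    dtw: DtwParams = field(default_factory=DtwParams)
    lstm: LstmSpec = field(default_factory=LstmSpec)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    cv: CvConfig = field(default_factory=CvConfig)
    stats_on: str = "translated"
    trial_aggregation: str = "mean"
    selection_scope: str = "per_fold"
    template_scope: str = "global"

    def __post_init__(self) -> None:
        if self.template_scope not in ("global", "per_fold"):
            raise ValueError("template_scope must be 'global' or 'per_fold'")
        if self.stats_on not in ("translated", "standardized"):
            raise ValueError("stats_on must be 'translated' or 'standardized'")
        if self.trial_aggregation not in ("mean", "per_trial"):
            raise ValueError("trial_aggregation must be 'mean' or 'per_trial'")
        if self.selection_scope not in ("per_fold", "global"):
            raise ValueError("selection_scope must be 'per_fold' or 'global'")

    def to_dict(self) -> Dict[str, Any]:
        d = asdict(self)
        d["cv"]["classifiers"] = list(self.cv.classifiers)
        d["cv"]["repeat_seeds"] = list(self.cv.repeat_seeds)
        return d

    @classmethod
    def from_dict(cls, d: Dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        if "dtw" in d and isinstance(d["dtw"], dict):
            d["dtw"] = DtwParams(**d["dtw"])
        if "lstm" in d and isinstance(d["lstm"], dict):
            d["lstm"] = LstmSpec(**d["lstm"])
        if "selection" in d and isinstance(d["selection"], dict):
            d["selection"] = SelectionConfig(**d["selection"])
        if "cv" in d and isinstance(d["cv"], dict):
            cv = dict(d["cv"])
            if "classifiers" in cv:
                cv["classifiers"] = tuple(cv["classifiers"])
            if "repeat_seeds" in cv:
                cv["repeat_seeds"] = tuple(cv["repeat_seeds"])
            d["cv"] = CvConfig(**cv)
        return cls(**d)
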