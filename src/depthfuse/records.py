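"""Case-level record shared by the generator, I/O layer and evaluators."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

from .metrics import POSITIVE, validate_label

SM_STAGES = ("SM1", "SM2")
HISTOLOGIES = ("differentiated", "undifferentiated")

__all__ = ["CaseRecord", "SM_STAGES", "HISTOLOGIES"]


@dataclass(frozen=True)
class CaseRecord:
    """One lesion: ground truth, AI probability, per-rater votes, covariates.

    ``sm_stage`` (SM1: submucosal invasion < 500 um; SM2: >= 500 um) is
    present exactly when the truth label is SM. ``p_sm`` is the AI
    classifier's probability that the lesion invades the submucosa.
    """

    case_id: str
    truth: str
    p_sm: float
    votes: Dict[str, str] = field(default_factory=dict)
    sm_stage: Optional[str] = None
    diameter_mm: float = 20.0
    histology: str = "differentiated"

    def __post_init__(self) -> None:
        validate_label(self.truth)
        if not 0.0 <= self.p_sm <= 1.0:
            raise ValueError(f"p_sm must lie in [0, 1], got {self.p_sm!r} ({self.case_id})")
        if self.truth == POSITIVE:
            if self.sm_stage not in SM_STAGES:
                raise ValueError(
                    f"SM case {self.case_id} needs sm_stage in {SM_STAGES}, got {self.sm_stage!r}"
                )
        elif self.sm_stage is not None:
            raise ValueError(f"M case {self.case_id} must not carry an sm_stage")
        for rater, vote in self.votes.items():
            try:
                validate_label(vote)
            except ValueError as exc:
                raise ValueError(f"rater {rater!r}, case {self.case_id}: {exc}") from exc
        if self.diameter_mm <= 0:
            raise ValueError(f"diameter_mm must be positive ({self.case_id})")
        if self.histology not in HISTOLOGIES:
            raise ValueError(
                f"histology must be one of {HISTOLOGIES}, got {self.histology!r} ({self.case_id})"
            )
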