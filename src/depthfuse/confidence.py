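"""Confidence-stratified depth calls from an AI probability or a vote panel.

Two diagnostic sources produce a ``(label, confidence)`` pair:

* the AI classifier, whose softmax-style probability of SM is thresholded
  at 0.5 for the label, and whose *diagnostic probability* — the
  probability assigned to its chosen class, ``max(p_sm, 1 - p_sm)`` —
  defines confidence: above 0.75 is high, otherwise low;
* an odd panel of endoscopists, whose majority vote gives the label and
  whose unanimity defines high confidence.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .metrics import NEGATIVE, POSITIVE, validate_label

LOW = "low"
HIGH = "high"
CONFIDENCE_LEVELS = (LOW, HIGH)

HIGH_CONFIDENCE_THRESHOLD = 0.75

__all__ = [
    "LOW",
    "HIGH",
    "CONFIDENCE_LEVELS",
    "HIGH_CONFIDENCE_THRESHOLD",
    "ConfidentDiagnosis",
    "stratify_ai",
    "aggregate_panel",
]


@dataclass(frozen=True)
class ConfidentDiagnosis:
    """A binary depth call (M/SM) paired with a low/high confidence level."""

    label: str
    confidence: str

    def __post_init__(self) -> None:
        validate_label(self.label)
        if self.confidence not in CONFIDENCE_LEVELS:
            raise ValueError(
                f"invalid confidence {self.confidence!r}: expected one of {CONFIDENCE_LEVELS}"
            )


def stratify_ai(p_sm: float, tie_positive: bool = False) -> ConfidentDiagnosis:
    """Turn an AI probability of SM into a confidence-stratified call.

    The label is SM when ``p_sm > 0.5`` (at exactly 0.5 the negative class
    M is chosen unless ``tie_positive``). Confidence is high when the
    diagnostic probability ``max(p_sm, 1 - p_sm)`` strictly exceeds 0.75,
    low otherwise — so the unit interval partitions into four bands:
    M-high [0, 0.25), M-low [0.25, 0.5], SM-low (0.5, 0.75], SM-high
    (0.75, 1].
    """
    if not 0.0 <= p_sm <= 1.0:
        raise ValueError(f"p_sm must lie in [0, 1], got {p_sm!r}")
    if p_sm > 0.5:
        label = POSITIVE
    elif p_sm < 0.5:
        label = NEGATIVE
    else:
        label = POSITIVE if tie_positive else NEGATIVE
    q = max(p_sm, 1.0 - p_sm)
    confidence = HIGH if q > HIGH_CONFIDENCE_THRESHOLD else LOW
    return ConfidentDiagnosis(label=label, confidence=confidence)


def aggregate_panel(votes: Sequence[str]) -> ConfidentDiagnosis:
    """Majority vote of an odd panel, with unanimity as high confidence.

    A panel of one is permitted (degenerate: always unanimous).
    """
    if len(votes) == 0 or len(votes) % 2 == 0:
        raise ValueError(
            f"panel must have an odd number of votes >= 1, got {len(votes)}"
        )
    for v in votes:
        validate_label(v)
    counts = Counter(votes)
    label, top = counts.most_common(1)[0]
    confidence = HIGH if top == len(votes) else LOW
    return ConfidentDiagnosis(label=label, confidence=confidence)
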