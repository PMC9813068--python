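"""Cooperative decision table fusing the AI call with the panel call.

The fusion rule operates on two confidence-stratified calls per case:

1. if the labels agree the shared label is final (*agreement*);
2. if the labels differ and the confidence levels differ, the
   higher-confidence source wins (*confidence_override*);
3. if the labels differ at equal confidence the case is a *mismatch*:
   mismatch 1 when the AI says SM and the panel says M, mismatch 2 when
   the AI says M and the panel says SM. Four fixed patterns resolve the
   mismatches:

   ========  ==========  ==========
   pattern   mismatch 1  mismatch 2
   ========  ==========  ==========
   I         AI          AI
   II        panel       AI
   III       AI          panel
   IV        panel       panel
   ========  ==========  ==========

The pattern actually deployed is the one with the best F1 measure on
training data (:func:`select_pattern`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

from .confidence import ConfidentDiagnosis
from .metrics import (
    POSITIVE,
    ConfusionCounts,
    DiagnosticMetrics,
    confusion_from_labels,
    metrics_from_confusion,
)

PATTERNS = ("I", "II", "III", "IV")

AGREEMENT = "agreement"
CONFIDENCE_OVERRIDE = "confidence_override"
MISMATCH1 = "mismatch1"
MISMATCH2 = "mismatch2"
ROUTES = (AGREEMENT, CONFIDENCE_OVERRIDE, MISMATCH1, MISMATCH2)

# (pattern, mismatch route) -> winning source
_MISMATCH_WINNER = {
    ("I", MISMATCH1): "ai",
    ("I", MISMATCH2): "ai",
    ("II", MISMATCH1): "panel",
    ("II", MISMATCH2): "ai",
    ("III", MISMATCH1): "ai",
    ("III", MISMATCH2): "panel",
    ("IV", MISMATCH1): "panel",
    ("IV", MISMATCH2): "panel",
}

__all__ = [
    "PATTERNS",
    "ROUTES",
    "AGREEMENT",
    "CONFIDENCE_OVERRIDE",
    "MISMATCH1",
    "MISMATCH2",
    "FusionOutcome",
    "fuse_case",
    "fuse_cohort",
    "select_pattern",
]


@dataclass(frozen=True)
class FusionOutcome:
    """Final fused label for one case plus the decision route taken."""

    final_label: str
    route: str


def validate_pattern(pattern: str) -> str:
    if pattern not in PATTERNS:
        raise ValueError(f"invalid fusion pattern {pattern!r}: expected one of {PATTERNS}")
    return pattern


def fuse_case(
    ai: ConfidentDiagnosis, panel: ConfidentDiagnosis, pattern: str
) -> FusionOutcome:
    """Fuse one case's AI and panel calls under a mismatch pattern."""
    validate_pattern(pattern)
    if ai.label == panel.label:
        return FusionOutcome(final_label=ai.label, route=AGREEMENT)
    if ai.confidence != panel.confidence:
        winner = ai if ai.confidence == "high" else panel
        return FusionOutcome(final_label=winner.label, route=CONFIDENCE_OVERRIDE)
    # equal confidence, conflicting labels: mismatch 1 or 2 by label pair
    route = MISMATCH1 if ai.label == POSITIVE else MISMATCH2
    source = ai if _MISMATCH_WINNER[(pattern, route)] == "ai" else panel
    return FusionOutcome(final_label=source.label, route=route)


def fuse_cohort(
    cases: Sequence[Tuple[ConfidentDiagnosis, ConfidentDiagnosis]], pattern: str
) -> List[FusionOutcome]:
    """Apply :func:`fuse_case` elementwise, preserving order."""
    validate_pattern(pattern)
    return [fuse_case(ai, panel, pattern) for ai, panel in cases]


def select_pattern(
    truth: Sequence[str],
    cases: Sequence[Tuple[ConfidentDiagnosis, ConfidentDiagnosis]],
) -> Tuple[str, Dict[str, DiagnosticMetrics]]:
    """Score all four mismatch patterns and return the F1-best one.

    Returns the winning pattern and the full per-pattern metric table.
    Ties break toward the lowest-numbered pattern. The cohort must
    contain both depth classes, otherwise an F1 comparison is
    meaningless and a ``ValueError`` is raised.
    """
    if len(truth) != len(cases):
        raise ValueError(
            f"truth and cases have different lengths ({len(truth)} vs {len(cases)})"
        )
    if len(truth) == 0:
        raise ValueError("cannot select a pattern on an empty cohort")
    classes = set(truth)
    if classes != {"M", "SM"}:
        raise ValueError(
            f"pattern selection needs both depth classes present, got {sorted(classes)}"
        )
    table: Dict[str, DiagnosticMetrics] = {}
    for pattern in PATTERNS:
        outcomes = fuse_cohort(cases, pattern)
        predicted = [o.final_label for o in outcomes]
        table[pattern] = metrics_from_confusion(confusion_from_labels(truth, predicted))
    best = max(PATTERNS, key=lambda p: (table[p].f1 or 0.0, -PATTERNS.index(p)))
    return best, table
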