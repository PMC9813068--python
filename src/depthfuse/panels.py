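"""Rater-subset enumeration and F1-best majority-vote panel selection.

Every diagnostic source — each endoscopist, and the AI — is treated as a
marker, and markers are screened in combination rather than one by one:
all odd-sized subsets of a rater pool are enumerated, each subset's
majority vote is scored against ground truth, and the subset with the
highest F1 measure is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .confidence import aggregate_panel
from .metrics import (
    DiagnosticMetrics,
    confusion_from_labels,
    metrics_from_confusion,
)

__all__ = [
    "RaterSet",
    "enumerate_majority_combinations",
    "majority_vote",
    "select_best_panel",
]


@dataclass(frozen=True)
class RaterSet:
    """A pool of raters, optionally tagged by experience class."""

    rater_ids: Tuple[str, ...]
    experience_class: Optional[Mapping[str, str]] = field(default=None)

    def __post_init__(self) -> None:
        if len(set(self.rater_ids)) != len(self.rater_ids):
            raise ValueError("rater ids must be unique")
        if self.experience_class is not None:
            unknown = set(self.experience_class) - set(self.rater_ids)
            if unknown:
                raise ValueError(f"experience classes for unknown raters: {sorted(unknown)}")


def _rater_ids(raters) -> Tuple[str, ...]:
    if isinstance(raters, RaterSet):
        return raters.rater_ids
    return tuple(raters)


def enumerate_majority_combinations(raters, k: int) -> List[Tuple[str, ...]]:
    """All C(n, k) odd-sized rater subsets in lexicographic id order."""
    ids = _rater_ids(raters)
    if len(set(ids)) != len(ids):
        raise ValueError("rater ids must be unique")
    if k % 2 == 0 or not 1 <= k <= len(ids):
        raise ValueError(f"panel size must be odd and within 1..{len(ids)}, got {k}")
    return list(combinations(sorted(ids), k))


def majority_vote(
    votes_by_rater: Mapping[str, Sequence[str]], subset: Sequence[str]
) -> List[str]:
    """Per-case majority label of the raters in *subset*."""
    missing = [r for r in subset if r not in votes_by_rater]
    if missing:
        raise ValueError(f"no votes recorded for raters: {missing}")
    columns = [votes_by_rater[r] for r in subset]
    lengths = {len(c) for c in columns}
    if len(lengths) != 1:
        raise ValueError(f"vote sequences have unequal lengths: {sorted(lengths)}")
    return [aggregate_panel(case_votes).label for case_votes in zip(*columns)]


def select_best_panel(
    truth: Sequence[str],
    votes_by_rater: Mapping[str, Sequence[str]],
    k: int,
) -> Tuple[Tuple[str, ...], Dict[Tuple[str, ...], DiagnosticMetrics]]:
    """Score every k-subset's majority vote; return the F1-argmax subset.

    All vote sequences must align with *truth* case for case — missing
    votes are an error, never imputed. Ties in F1 break lexicographically
    by sorted rater ids. Returns the winning subset and the full
    per-subset metric table.
    """
    subsets = enumerate_majority_combinations(tuple(votes_by_rater), k)
    table: Dict[Tuple[str, ...], DiagnosticMetrics] = {}
    for subset in subsets:
        predicted = majority_vote(votes_by_rater, subset)
        if len(predicted) != len(truth):
            raise ValueError(
                f"votes cover {len(predicted)} cases but truth has {len(truth)}"
            )
        table[subset] = metrics_from_confusion(confusion_from_labels(truth, predicted))
    # subsets are in lexicographic order; strict > keeps the first on ties
    best = subsets[0]
    for subset in subsets[1:]:
        if (table[subset].f1 or 0.0) > (table[best].f1 or 0.0):
            best = subset
    return best, table
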