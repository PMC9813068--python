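"""Confusion-matrix construction and diagnostic-accuracy statistics.

Submucosal invasion (``SM``) is the positive class throughout the package:
sensitivity is the fraction of SM cancers called SM, specificity the
fraction of intramucosal (``M``) cancers called M. The F1 measure — the
harmonic mean of sensitivity and positive predictive value,
``2 * sens * PPV / (sens + PPV)`` — is the model-selection criterion used
by every downstream stage (panel selection, fusion-pattern selection).

Ratios whose denominator is zero (e.g. PPV when no SM call was made) are
reported as ``None`` rather than silently coerced to 0, so a degenerate
classifier can never masquerade as a perfect one. The single exception is
F1, which is 0 when there are no true positives but the positive class is
present somewhere (truth or predictions), matching the convention that a
classifier that never finds an SM cancer has no balanced diagnostic value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

POSITIVE = "SM"
NEGATIVE = "M"
LABELS = (NEGATIVE, POSITIVE)

__all__ = [
    "POSITIVE",
    "NEGATIVE",
    "LABELS",
    "ConfusionCounts",
    "DiagnosticMetrics",
    "StrataComparison",
    "validate_label",
    "confusion_from_labels",
    "metrics_from_confusion",
    "confusion_from_operating_point",
    "chi_square_2x2",
]


def validate_label(label: str) -> str:
    """Check that *label* is one of the two depth classes and return it."""
    if label not in LABELS:
        raise ValueError(f"invalid depth label {label!r}: expected one of {LABELS}")
    return label


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts with SM as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {value!r}")
        if self.n < 1:
            raise ValueError("confusion counts must cover at least one case")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_positive(self) -> int:
        """Cases whose ground truth is SM."""
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        """Cases whose ground truth is M."""
        return self.tn + self.fp


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Diagnostic-accuracy summary; ``None`` marks an undefined ratio."""

    accuracy: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    f1: Optional[float]

    def as_dict(self, percent: bool = False) -> dict:
        """Plain-dict view; with ``percent=True`` proportions are scaled to %."""
        out = {}
        for name in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
            value = getattr(self, name)
            out[name] = None if value is None else (100.0 * value if percent else value)
        out["f1"] = self.f1
        return out


@dataclass
class StrataComparison:
    """Pearson chi-square comparison of two proportions in a 2x2 table."""

    chi_square_statistic: float
    p_value: float
    table: np.ndarray

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=np.int64)


def confusion_from_labels(
    truth: Sequence[str], predicted: Sequence[str]
) -> ConfusionCounts:
    """Tabulate predicted depth labels against ground truth.

    Both sequences must have equal length >= 1 and contain only ``"M"`` /
    ``"SM"``.
    """
    if len(truth) != len(predicted):
        raise ValueError(
            f"truth and predicted have different lengths ({len(truth)} vs {len(predicted)})"
        )
    if len(truth) == 0:
        raise ValueError("cannot tabulate an empty cohort")
    tp = fp = fn = tn = 0
    for t, p in zip(truth, predicted):
        validate_label(t)
        validate_label(p)
        if t == POSITIVE:
            if p == POSITIVE:
                tp += 1
            else:
                fn += 1
        else:
            if p == POSITIVE:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: int, den: int) -> Optional[float]:
    return None if den == 0 else num / den


def metrics_from_confusion(c: ConfusionCounts) -> DiagnosticMetrics:
    """All diagnostic-accuracy statistics derivable from a 2x2 table.

    F1 is the harmonic mean of sensitivity and PPV. It is 0 when tp == 0
    but positives exist on either axis, and undefined (``None``) only in
    the fully degenerate case where the positive class is absent from both
    truth and predictions.
    """
    sens = _ratio(c.tp, c.tp + c.fn)
    spec = _ratio(c.tn, c.tn + c.fp)
    ppv = _ratio(c.tp, c.tp + c.fp)
    npv = _ratio(c.tn, c.tn + c.fn)
    accuracy = (c.tp + c.tn) / c.n

    if sens is not None and ppv is not None:
        f1: Optional[float] = 0.0 if sens + ppv == 0 else 2 * sens * ppv / (sens + ppv)
    elif c.tp == 0 and (c.fp > 0 or c.fn > 0):
        # no true positives, but SM appears in truth or predictions
        f1 = 0.0
    else:
        f1 = None
    return DiagnosticMetrics(
        accuracy=accuracy, sensitivity=sens, specificity=spec, ppv=ppv, npv=npv, f1=f1
    )


def _round_half_away(x: float) -> int:
    # round-half-away-from-zero; x is non-negative here
    return int(math.floor(x + 0.5))


def confusion_from_operating_point(
    sensitivity: float, specificity: float, n_pos: int, n_neg: int
) -> ConfusionCounts:
    """Reconstruct integer confusion counts from an operating point.

    Given a printed (sensitivity, specificity) pair and the class sizes of
    the design, the implied counts are ``tp = round(sens * n_pos)``,
    ``tn = round(spec * n_neg)`` with round-half-away-from-zero, the
    convention under which every internally consistent published cell of a
    balanced-design accuracy table reconstructs exactly.
    """
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("both class sizes must be >= 1")
    tp = _round_half_away(sensitivity * n_pos)
    tn = _round_half_away(specificity * n_neg)
    return ConfusionCounts(tp=tp, fp=n_neg - tn, fn=n_pos - tp, tn=tn)


def chi_square_2x2(table, correction: bool = False) -> StrataComparison:
    """Pearson chi-square test for a 2x2 contingency table (1 df).

    Parameters
    ----------
    table
        2x2 array-like of non-negative counts; every row and column
        marginal must be >= 1.
    correction
        Apply the Yates continuity correction. Off by default; the
        uncorrected Pearson statistic is the package convention.
    """
    arr = np.asarray(table, dtype=np.int64)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    rows = arr.sum(axis=1)
    cols = arr.sum(axis=0)
    if (rows < 1).any() or (cols < 1).any():
        raise ValueError("every row and column marginal must be >= 1")
    a, b = arr[0]
    c, d = arr[1]
    n = int(arr.sum())
    diff = abs(float(a) * d - float(b) * c)
    if correction:
        diff = max(0.0, diff - n / 2.0)
    denom = float(rows[0]) * rows[1] * cols[0] * cols[1]
    statistic = n * diff**2 / denom
    p_value = float(stats.chi2.sf(statistic, df=1))
    return StrataComparison(chi_square_statistic=statistic, p_value=p_value, table=arr)
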