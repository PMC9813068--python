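"""Leave-one-out and train/test evaluation, generic over a classifier.

The harness mirrors the internal-evaluation protocol of a reader study:
each of the n cases is held out in turn, the classifier is refit on the
remaining n - 1, and the held-out case is scored; the n out-of-sample
probabilities are then pooled into one diagnostic report, including a
comparison of accuracy between the high- and low-confidence strata.

The deep-learning classifier the protocol was designed around is out of
scope here; the harness accepts any object with ``fit(records, seed)``
and ``predict_proba(record) -> float``, and the module ships simple
reference classifiers (stored-probability pass-through, k-nearest
neighbours on a feature map, prevalence and constant baselines, and a
memorizing classifier used as a leakage canary).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Protocol, Sequence

import numpy as np

from .confidence import HIGH, stratify_ai
from .metrics import (
    DiagnosticMetrics,
    StrataComparison,
    chi_square_2x2,
    confusion_from_labels,
    metrics_from_confusion,
)
from .records import CaseRecord

__all__ = [
    "Classifier",
    "EvaluationReport",
    "FoldError",
    "report_from_predictions",
    "leave_one_out",
    "evaluate_holdout",
    "StoredProbabilityClassifier",
    "MemorizingClassifier",
    "ConstantClassifier",
    "PrevalenceClassifier",
    "NearestNeighborClassifier",
]


class Classifier(Protocol):
    """Anything that can be refit per fold and score one case."""

    def fit(self, records: Sequence[CaseRecord], seed: int) -> None: ...

    def predict_proba(self, record: CaseRecord) -> float: ...


class FoldError(RuntimeError):
    """A cross-validation fold could not be evaluated."""

    def __init__(self, fold: int, message: str):
        super().__init__(f"fold {fold}: {message}")
        self.fold = fold


@dataclass
class EvaluationReport:
    """Pooled out-of-sample predictions with metrics and confidence strata."""

    predictions: List[float]
    metrics: DiagnosticMetrics
    strata: Optional[StrataComparison]
    high_confidence_accuracy: Optional[float]
    low_confidence_accuracy: Optional[float]

    @property
    def n(self) -> int:
        return len(self.predictions)


def report_from_predictions(
    truth: Sequence[str], probabilities: Sequence[float]
) -> EvaluationReport:
    """Score per-case SM probabilities against ground truth.

    Labels are taken at the 0.5 cut; the strata table crosses correctness
    with the high/low confidence band of the diagnostic probability and is
    tested with the Pearson chi-square when all marginals are non-empty.
    """
    if len(truth) != len(probabilities):
        raise ValueError("truth and probabilities must align")
    calls = [stratify_ai(p) for p in probabilities]
    predicted = [c.label for c in calls]
    metrics = metrics_from_confusion(confusion_from_labels(truth, predicted))
    # rows: high/low confidence; cols: correct/incorrect
    table = np.zeros((2, 2), dtype=np.int64)
    for t, call in zip(truth, calls):
        row = 0 if call.confidence == HIGH else 1
        col = 0 if call.label == t else 1
        table[row, col] += 1
    high_n, low_n = int(table[0].sum()), int(table[1].sum())
    high_acc = table[0, 0] / high_n if high_n else None
    low_acc = table[1, 0] / low_n if low_n else None
    strata = None
    if min(table.sum(axis=0)) >= 1 and min(table.sum(axis=1)) >= 1:
        strata = chi_square_2x2(table)
    return EvaluationReport(
        predictions=list(map(float, probabilities)),
        metrics=metrics,
        strata=strata,
        high_confidence_accuracy=high_acc,
        low_confidence_accuracy=low_acc,
    )


def _fold_seeds(seed: int, n: int) -> np.ndarray:
    # deterministic schedule derived from the master seed, one per fold
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def leave_one_out(
    records: Sequence[CaseRecord], classifier: Classifier, seed: int = 0
) -> EvaluationReport:
    """Leave-one-out evaluation: n folds, case i never in its own training set.

    The classifier is refit from scratch on every fold with a seed drawn
    from a deterministic schedule; per-case predictions are assembled in
    input order and pooled into one report. A fold whose training part
    lacks one of the two classes, or whose classifier raises, aborts with
    the fold index.
    """
    n = len(records)
    if n < 2:
        raise ValueError("leave-one-out needs at least two cases")
    seeds = _fold_seeds(seed, n)
    probs: List[float] = []
    for i in range(n):
        train = list(records[:i]) + list(records[i + 1 :])
        if len({r.truth for r in train}) < 2:
            raise FoldError(i, "training part lacks one of the two classes")
        try:
            classifier.fit(train, seed=int(seeds[i]))
            p = float(classifier.predict_proba(records[i]))
        except FoldError:
            raise
        except Exception as exc:  # surface which fold broke
            raise FoldError(i, str(exc)) from exc
        if not 0.0 <= p <= 1.0:
            raise FoldError(i, f"classifier returned an invalid probability {p!r}")
        probs.append(p)
    return report_from_predictions([r.truth for r in records], probs)


def evaluate_holdout(
    train: Sequence[CaseRecord],
    test: Sequence[CaseRecord],
    classifier: Classifier,
    seed: int = 0,
) -> EvaluationReport:
    """Fit once on *train*, score every *test* case. Case ids must be disjoint."""
    overlap = {r.case_id for r in train} & {r.case_id for r in test}
    if overlap:
        raise ValueError(f"train and test share case ids: {sorted(overlap)[:5]}")
    classifier.fit(list(train), seed=int(seed) % (2**31))
    probs = [float(classifier.predict_proba(r)) for r in test]
    for p in probs:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"classifier returned an invalid probability {p!r}")
    return report_from_predictions([r.truth for r in test], probs)


# ---------------------------------------------------------------------------
# reference classifiers


class StoredProbabilityClassifier:
    """Pass-through of the AI probability already stored on each record.

    Models the common situation where out-of-sample classifier outputs
    were computed upstream and shipped in the case table; ``fit`` is a
    no-op.
    """

    def fit(self, records: Sequence[CaseRecord], seed: int = 0) -> None:
        pass

    def predict_proba(self, record: CaseRecord) -> float:
        return record.p_sm


class MemorizingClassifier:
    """Leakage canary: knows only the exact cases it was trained on.

    Predicts a seen case's own label with certainty and 0.5 otherwise, so
    any cross-validation harness that leaks the held-out case into
    training is immediately visible as non-chance performance.
    """

    def __init__(self) -> None:
        self._seen: dict = {}

    def fit(self, records: Sequence[CaseRecord], seed: int = 0) -> None:
        self._seen = {r.case_id: r.truth for r in records}

    def predict_proba(self, record: CaseRecord) -> float:
        label = self._seen.get(record.case_id)
        if label is None:
            return 0.5
        return 1.0 if label == "SM" else 0.0


class ConstantClassifier:
    """Always outputs the same probability."""

    def __init__(self, p: float = 0.5):
        if not 0.0 <= p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        self.p = p

    def fit(self, records: Sequence[CaseRecord], seed: int = 0) -> None:
        pass

    def predict_proba(self, record: CaseRecord) -> float:
        return self.p


class PrevalenceClassifier:
    """Outputs the SM prevalence of its training fold (chance baseline)."""

    def __init__(self) -> None:
        self._p = 0.5

    def fit(self, records: Sequence[CaseRecord], seed: int = 0) -> None:
        if not records:
            raise ValueError("cannot fit on an empty training set")
        self._p = sum(r.truth == "SM" for r in records) / len(records)

    def predict_proba(self, record: CaseRecord) -> float:
        return self._p


class NearestNeighborClassifier:
    """k-nearest-neighbour vote on a numeric feature map.

    ``feature`` maps a record to a 1-D feature vector; the predicted
    probability is the SM fraction among the k nearest training cases
    (Euclidean distance, ties broken by training order).
    """

    def __init__(self, feature: Callable[[CaseRecord], Sequence[float]], k: int = 1):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.feature = feature
        self.k = k
        self._X: Optional[np.ndarray] = None
        self._y: Optional[np.ndarray] = None

    def fit(self, records: Sequence[CaseRecord], seed: int = 0) -> None:
        if len(records) < self.k:
            raise ValueError(f"need at least k={self.k} training cases")
        self._X = np.asarray([self.feature(r) for r in records], dtype=float)
        self._y = np.asarray([r.truth == "SM" for r in records], dtype=float)

    def predict_proba(self, record: CaseRecord) -> float:
        if self._X is None or self._y is None:
            raise RuntimeError("classifier is not fitted")
        x = np.asarray(self.feature(record), dtype=float)
        d = np.linalg.norm(self._X - x[None, :], axis=1)
        nearest = np.argsort(d, kind="stable")[: self.k]
        return float(self._y[nearest].mean())
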