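"""Case-level CSV interchange and the end-to-end cooperative pipeline.

CSV schema (UTF-8, comma-separated, header required)::

    case_id,truth,sm_stage,p_sm,vote_<rater>...,diameter_mm,histology

Labels are the literal strings ``M`` / ``SM``; ``sm_stage`` is ``SM1`` or
``SM2`` for SM cases and empty for M cases; probabilities are decimals in
[0, 1]. One rater column per rater, prefixed ``vote_``.

:func:`run_pipeline` chains the stages of the cooperative-diagnosis
analysis: per-rater accuracy, F1-best majority panel, confidence
stratification of both sources, F1-best fusion pattern on training data,
and (optionally) application of the frozen panel + pattern to an
independent test cohort — with every table and the seed echoed into the
report for reproducibility.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .confidence import HIGH, ConfidentDiagnosis, aggregate_panel, stratify_ai
from .crossval import report_from_predictions
from .fusion import fuse_cohort, select_pattern
from .metrics import (
    DiagnosticMetrics,
    chi_square_2x2,
    confusion_from_labels,
    metrics_from_confusion,
)
from .panels import select_best_panel
from .records import HISTOLOGIES, SM_STAGES, CaseRecord
from .simulate import generate_cohort, paper_preset

logger = logging.getLogger("depthfuse")

FIXED_LEFT = ["case_id", "truth", "sm_stage", "p_sm"]
FIXED_RIGHT = ["diameter_mm", "histology"]
VOTE_PREFIX = "vote_"

__all__ = [
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "PipelineConfig",
    "run_pipeline",
]


class CohortValidationError(ValueError):
    """A cohort file violated the schema; names the offending row/column."""


def write_cohort(records: Sequence[CaseRecord], path) -> None:
    """Serialize records to the case-level CSV schema."""
    if not records:
        raise ValueError("refusing to write an empty cohort")
    raters = sorted(records[0].votes)
    rows = []
    for r in records:
        if sorted(r.votes) != raters:
            raise ValueError(f"case {r.case_id} has a different rater set")
        row = {
            "case_id": r.case_id,
            "truth": r.truth,
            "sm_stage": r.sm_stage or "",
            "p_sm": repr(r.p_sm),
            **{VOTE_PREFIX + k: r.votes[k] for k in raters},
            "diameter_mm": repr(r.diameter_mm),
            "histology": r.histology,
        }
        rows.append(row)
    columns = FIXED_LEFT + [VOTE_PREFIX + r for r in raters] + FIXED_RIGHT
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def _cell_error(row_idx: int, column: str, message: str) -> CohortValidationError:
    return CohortValidationError(f"row {row_idx + 2}, column {column!r}: {message}")


def read_cohort(path) -> List[CaseRecord]:
    """Read and validate a case-level CSV; errors name row and column."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in FIXED_LEFT + FIXED_RIGHT if c not in df.columns]
    if missing:
        raise CohortValidationError(f"missing required columns: {missing}")
    unknown = [
        c
        for c in df.columns
        if c not in FIXED_LEFT + FIXED_RIGHT and not c.startswith(VOTE_PREFIX)
    ]
    if unknown:
        raise CohortValidationError(f"unknown columns: {unknown}")
    raters = [c[len(VOTE_PREFIX) :] for c in df.columns if c.startswith(VOTE_PREFIX)]
    if len(df) == 0:
        raise CohortValidationError("cohort file has no data rows")
    dupes = df["case_id"][df["case_id"].duplicated()].unique()
    if len(dupes):
        raise CohortValidationError(f"duplicate case_id values: {list(dupes)[:5]}")

    records: List[CaseRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        data = dict(zip(df.columns, row))
        truth = data["truth"]
        if truth not in ("M", "SM"):
            raise _cell_error(i, "truth", f"invalid label {truth!r}")
        sm_stage = data["sm_stage"] or None
        if truth == "SM" and sm_stage not in SM_STAGES:
            raise _cell_error(i, "sm_stage", f"SM case needs one of {SM_STAGES}")
        if truth == "M" and sm_stage is not None:
            raise _cell_error(i, "sm_stage", "must be empty for an M case")
        try:
            p_sm = float(data["p_sm"])
        except ValueError:
            raise _cell_error(i, "p_sm", f"not a number: {data['p_sm']!r}") from None
        if not 0.0 <= p_sm <= 1.0:
            raise _cell_error(i, "p_sm", f"probability {p_sm} outside [0, 1]")
        votes = {}
        for r in raters:
            vote = data[VOTE_PREFIX + r]
            if vote not in ("M", "SM"):
                raise _cell_error(i, VOTE_PREFIX + r, f"invalid label {vote!r}")
            votes[r] = vote
        try:
            diameter = float(data["diameter_mm"])
        except ValueError:
            raise _cell_error(i, "diameter_mm", f"not a number: {data['diameter_mm']!r}") from None
        if diameter <= 0:
            raise _cell_error(i, "diameter_mm", "must be positive")
        histology = data["histology"]
        if histology not in HISTOLOGIES:
            raise _cell_error(i, "histology", f"expected one of {HISTOLOGIES}")
        records.append(
            CaseRecord(
                case_id=data["case_id"],
                truth=truth,
                sm_stage=sm_stage,
                p_sm=p_sm,
                votes=votes,
                diameter_mm=diameter,
                histology=histology,
            )
        )
    return records


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """Inputs and knobs for :func:`run_pipeline`.

    A training cohort comes either from ``train_path`` (CSV) or, when
    unset, from the generator preset named by ``preset``; likewise the
    optional test cohort. ``rater_pool`` restricts panel-subset search
    (default: every rater in the table); ``panel_size`` must be odd.
    """

    preset: str = "training_like"
    train_path: Optional[str] = None
    test_preset: Optional[str] = None
    test_path: Optional[str] = None
    panel_size: int = 3
    rater_pool: Optional[Sequence[str]] = None
    rho: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.panel_size % 2 == 0 or self.panel_size < 1:
            raise ValueError(f"panel_size must be odd and >= 1, got {self.panel_size}")


def ai_calls(records: Sequence[CaseRecord]) -> List[ConfidentDiagnosis]:
    return [stratify_ai(r.p_sm) for r in records]


def panel_calls(
    records: Sequence[CaseRecord], subset: Sequence[str]
) -> List[ConfidentDiagnosis]:
    return [aggregate_panel([r.votes[s] for s in subset]) for r in records]


def _metrics_row(m: DiagnosticMetrics) -> Dict[str, Optional[float]]:
    row = m.as_dict(percent=True)
    # percentages to one decimal, F1 to three, matching table convention
    for k, v in row.items():
        if v is None:
            continue
        row[k] = round(v, 3) if k == "f1" else round(v, 1)
    return row


def _strata_report(truth: Sequence[str], calls: Sequence[ConfidentDiagnosis]) -> dict:
    table = np.zeros((2, 2), dtype=np.int64)
    for t, call in zip(truth, calls):
        row = 0 if call.confidence == HIGH else 1
        col = 0 if call.label == t else 1
        table[row, col] += 1
    out: dict = {
        "table_high_low_x_correct_incorrect": table.tolist(),
        "high_confidence_accuracy_pct": (
            round(float(100 * table[0, 0] / table[0].sum()), 1) if table[0].sum() else None
        ),
        "low_confidence_accuracy_pct": (
            round(float(100 * table[1, 0] / table[1].sum()), 1) if table[1].sum() else None
        ),
    }
    if min(table.sum(axis=0)) >= 1 and min(table.sum(axis=1)) >= 1:
        comp = chi_square_2x2(table)
        out["chi_square_statistic"] = round(float(comp.chi_square_statistic), 4)
        out["p_value"] = float(comp.p_value)
    else:
        out["chi_square_statistic"] = None
        out["p_value"] = None
    return out


def _source_metrics(truth: Sequence[str], predicted: Sequence[str]) -> DiagnosticMetrics:
    return metrics_from_confusion(confusion_from_labels(truth, predicted))


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Run the full cooperative-diagnosis analysis; optionally write reports.

    Stages: (1) per-rater metrics; (2) F1-best k-rater majority panel;
    (3) AI and panel confidence stratification with chi-square strata
    comparison; (4) F1-best fusion pattern on the training cohort;
    (5) AI vs panel vs cooperation comparison, repeated on the test
    cohort (if any) with the training-frozen panel and pattern.
    Returns the report as a JSON-serializable dict; with ``out_dir`` it
    is also written to ``report.json`` plus one CSV per table.
    """
    if config.train_path:
        train = read_cohort(config.train_path)
        train_source = str(config.train_path)
    else:
        train = generate_cohort(paper_preset(config.preset, seed=config.seed, rho=config.rho))
        train_source = f"preset:{config.preset}"
    truth = [r.truth for r in train]
    logger.info(
        "training cohort: %d cases (%d SM / %d M) from %s",
        len(train), truth.count("SM"), truth.count("M"), train_source,
    )

    raters = sorted(train[0].votes)
    pool = list(config.rater_pool) if config.rater_pool else raters
    missing = set(pool) - set(raters)
    if missing:
        raise ValueError(f"rater_pool names unknown raters: {sorted(missing)}")

    votes_by_rater = {r: [rec.votes[r] for rec in train] for r in pool}
    rater_table = {
        r: _metrics_row(_source_metrics(truth, votes_by_rater[r])) for r in pool
    }

    best_subset, subset_table = select_best_panel(truth, votes_by_rater, config.panel_size)
    logger.info("selected panel %s by best F1", "".join(best_subset))

    ai = ai_calls(train)
    panel = panel_calls(train, best_subset)
    best_pattern, pattern_table = select_pattern(truth, list(zip(ai, panel)))
    logger.info("selected fusion pattern %s by best F1", best_pattern)

    fused = fuse_cohort(list(zip(ai, panel)), best_pattern)
    train_comparison = {
        "ai": _metrics_row(_source_metrics(truth, [c.label for c in ai])),
        "endoscopists": _metrics_row(_source_metrics(truth, [c.label for c in panel])),
        "cooperation": _metrics_row(
            _source_metrics(truth, [o.final_label for o in fused])
        ),
    }

    report: dict = {
        "config": {
            "train": train_source,
            "panel_size": config.panel_size,
            "rater_pool": pool,
            "rho": config.rho,
            "seed": config.seed,
        },
        "n_train": len(train),
        "rater_metrics": rater_table,
        "panel_subsets": {"".join(s): _metrics_row(m) for s, m in subset_table.items()},
        "selected_panel": list(best_subset),
        "fusion_patterns": {p: _metrics_row(m) for p, m in pattern_table.items()},
        "selected_pattern": best_pattern,
        "train_comparison": train_comparison,
        "train_strata": {
            "ai": _strata_report(truth, ai),
            "endoscopists": _strata_report(truth, panel),
        },
    }

    test: Optional[List[CaseRecord]] = None
    if config.test_path:
        test = read_cohort(config.test_path)
        report["config"]["test"] = str(config.test_path)
    elif config.test_preset:
        # offset the seed so test cases are independent of training ones
        test = generate_cohort(
            paper_preset(config.test_preset, seed=config.seed + 1, rho=config.rho)
        )
        report["config"]["test"] = f"preset:{config.test_preset}"
    if test is not None:
        test_truth = [r.truth for r in test]
        test_raters = sorted(test[0].votes)
        subset = best_subset
        if not set(subset) <= set(test_raters):
            # preset rater ids may differ; fall back to the first k raters
            subset = tuple(test_raters[: config.panel_size])
            logger.warning(
                "test cohort lacks training panel %s; using %s",
                "".join(best_subset), "".join(subset),
            )
        t_ai = ai_calls(test)
        t_panel = panel_calls(test, subset)
        t_fused = fuse_cohort(list(zip(t_ai, t_panel)), best_pattern)
        report["n_test"] = len(test)
        report["test_panel"] = list(subset)
        report["test_comparison"] = {
            "ai": _metrics_row(_source_metrics(test_truth, [c.label for c in t_ai])),
            "endoscopists": _metrics_row(
                _source_metrics(test_truth, [c.label for c in t_panel])
            ),
            "cooperation": _metrics_row(
                _source_metrics(test_truth, [o.final_label for o in t_fused])
            ),
        }
        report["test_strata"] = {
            "ai": _strata_report(test_truth, t_ai),
            "endoscopists": _strata_report(test_truth, t_panel),
        }

    for section in ("train_comparison",):
        for source, row in report[section].items():
            if any(v is None for v in row.values()):
                logger.warning("%s/%s has undefined metrics", section, source)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        pd.DataFrame(report["rater_metrics"]).T.to_csv(out / "rater_metrics.csv")
        pd.DataFrame(report["panel_subsets"]).T.to_csv(out / "panel_subsets.csv")
        pd.DataFrame(report["fusion_patterns"]).T.to_csv(out / "fusion_patterns.csv")
        pd.DataFrame(report["train_comparison"]).T.to_csv(out / "train_comparison.csv")
        if "test_comparison" in report:
            pd.DataFrame(report["test_comparison"]).T.to_csv(out / "test_comparison.csv")
    return report
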