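"""Placebo-response labeling: the binary target for propensity modeling.

A placebo-arm subject is a responder when the total score at end of study
(EOS) has fallen by at least 50% from the randomization-visit (week 0)
baseline.  Subjects with a missing EOS assessment are excluded from the label
set (no imputation) and counted; subjects with a zero baseline total have an
undefined percent change and are likewise excluded and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .simulate import SubjectTrajectory

__all__ = [
    "ResponseLabel",
    "LabelingResult",
    "UndefinedBaselineError",
    "DegenerateLabelsWarning",
    "RESPONSE_THRESHOLD_PCT",
    "percent_change",
    "label_placebo_responders",
]

RESPONSE_THRESHOLD_PCT = 50.0  # ">= 50%" is inclusive


class UndefinedBaselineError(ValueError):
    """Percent change is undefined for a zero baseline total."""


class DegenerateLabelsWarning(UserWarning):
    """All labels fell in one class; a propensity model cannot be trained."""


@dataclass(frozen=True)
class ResponseLabel:
    subject_id: str
    percent_change: float
    responder: int

    def __post_init__(self) -> None:
        expected = int(self.percent_change >= RESPONSE_THRESHOLD_PCT)
        if self.responder != expected:
            raise ValueError("responder flag inconsistent with percent change")


@dataclass(frozen=True)
class LabelingResult:
    labels: tuple[ResponseLabel, ...]
    n_excluded_missing_eos: int
    n_excluded_zero_baseline: int
    degenerate: bool  # all labels one class

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [l.subject_id for l in self.labels],
                "percent_change": [l.percent_change for l in self.labels],
                "responder": [l.responder for l in self.labels],
            }
        )


def percent_change(baseline_total: float, eos_total: float) -> float:
    """Percent reduction from baseline; positive values are improvement."""
    if baseline_total <= 0:
        raise UndefinedBaselineError(
            f"baseline total {baseline_total} gives an undefined percent change"
        )
    return 100.0 * (baseline_total - eos_total) / baseline_total


def label_placebo_responders(
    placebo_subjects: Sequence[SubjectTrajectory], eos_week: float
) -> LabelingResult:
    """Label each placebo-arm subject as EOS responder (>=50% reduction) or not.

    Subjects missing the EOS visit or with zero baseline are excluded and
    tallied separately so the intention-to-treat accounting stays complete.
    """
    if not placebo_subjects:
        raise ValueError("empty placebo arm: nothing to label")
    arms = {s.arm for s in placebo_subjects}
    if len(arms) > 1:
        raise ValueError(f"labeling expects a single (placebo) arm, got {sorted(arms)}")

    labels: list[ResponseLabel] = []
    n_missing = 0
    n_zero_baseline = 0
    for s in placebo_subjects:
        if 0.0 not in s.item_scores:
            raise ValueError(f"subject {s.subject_id} has no baseline visit")
        if eos_week not in s.item_scores:
            n_missing += 1
            continue
        baseline_total = s.total(0.0)
        if baseline_total <= 0:
            n_zero_baseline += 1
            continue
        pc = percent_change(baseline_total, s.total(eos_week))
        labels.append(
            ResponseLabel(s.subject_id, pc, int(pc >= RESPONSE_THRESHOLD_PCT))
        )

    degenerate = len({l.responder for l in labels}) < 2
    return LabelingResult(
        labels=tuple(labels),
        n_excluded_missing_eos=n_missing,
        n_excluded_zero_baseline=n_zero_baseline,
        degenerate=degenerate,
    )
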