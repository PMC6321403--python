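"""Confusion statistics and external validation of pharmacophore models.

Conventions: P and N are the numbers of active and inactive compounds
in the evaluated set; TP the actives matched by a model, FP the
inactives matched.  recall = TP/P, precision = TP/(TP+FP),
FPR = FP/N, and the F-score is the β-weighted harmonic mean

    F_β = (1 + β²)·precision·recall / (β²·precision + recall)

with β = 0.5 favouring precision and β = 2 favouring recall.  Undefined
quantities (zero denominators) are reported as None and rendered as
empty fields in TSV output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .screening import PharmModel, ScreenResult, screen_dataset

__all__ = ["f_beta", "confusion_metrics", "ValidationReport", "validate"]


def f_beta(precision: float, recall: float, beta: float) -> float:
    """β-weighted F-score of a precision/recall pair.

    Returns 0 when precision and recall are both 0 (the harmonic-mean
    limit convention).
    """
    if not 0 <= precision <= 1 or not 0 <= recall <= 1:
        raise ValueError("precision and recall must lie in [0, 1]")
    if beta <= 0:
        raise ValueError("beta must be positive")
    denom = beta * beta * precision + recall
    if denom == 0:
        return 0.0
    return (1 + beta * beta) * precision * recall / denom


def confusion_metrics(tp: int, fp: int, p: int, n: int) -> dict:
    """recall/precision/FPR/F0.5/F2 from a confusion table.

    ``None`` marks undefined values: precision when TP+FP = 0, recall
    when P = 0, FPR when N = 0; F-scores are None when either input is.
    """
    recall = tp / p if p > 0 else None
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    fpr = fp / n if n > 0 else None
    if precision is None or recall is None:
        f05 = f2 = None
    else:
        f05 = f_beta(precision, recall, 0.5)
        f2 = f_beta(precision, recall, 2.0)
    return {
        "recall": recall,
        "precision": precision,
        "fpr": fpr,
        "f05": f05,
        "f2": f2,
    }


@dataclass(frozen=True)
class ValidationReport:
    """External (or internal) performance of one model or the consensus."""

    model_id: str
    p: int
    n: int
    tp: int
    fp: int
    recall: float | None
    precision: float | None
    fpr: float | None
    f05: float | None
    f2: float | None

    @classmethod
    def from_counts(cls, model_id: str, tp: int, fp: int, p: int, n: int):
        return cls(model_id=model_id, p=p, n=n, tp=tp, fp=fp,
                   **confusion_metrics(tp, fp, p, n))


def _activity_sets(activities: Mapping[str, str]):
    actives = {c for c, a in activities.items() if str(a).lower() == "active"}
    inactives = {c for c, a in activities.items() if str(a).lower() == "inactive"}
    return actives, inactives


def validate(
    models: Sequence[PharmModel],
    db: Iterable,
    activities: Mapping[str, str],
    screen_result: ScreenResult | None = None,
) -> list[ValidationReport]:
    """Screen a labelled set and report per-model plus consensus metrics.

    ``activities`` maps compound_id to ``"active"``/``"inactive"``; the
    evaluated set should be disjoint from each model's training set for
    an external estimate.  The consensus row (model_id ``"consensus"``)
    scores the de-duplicated union of all hit lists; by union
    monotonicity its recall and FPR are at least every individual
    model's.  A precomputed :class:`ScreenResult` may be passed to skip
    re-screening.
    """
    actives, inactives = _activity_sets(activities)
    p, n = len(actives), len(inactives)
    if screen_result is None:
        screen_result = screen_dataset(models, db)
    reports = []
    union: set = set()
    for m in models:
        hits = screen_result.compounds(m.model_id)
        union |= hits
        reports.append(
            ValidationReport.from_counts(
                m.model_id, tp=len(hits & actives), fp=len(hits & inactives), p=p, n=n
            )
        )
    reports.append(
        ValidationReport.from_counts(
            "consensus", tp=len(union & actives), fp=len(union & inactives), p=p, n=n
        )
    )
    return reports


def reports_to_tsv(reports: Sequence[ValidationReport], path=None) -> str:
    """Render validation reports as a TSV table (None → empty field)."""
    cols = ["model_id", "P", "N", "TP", "FP", "recall", "precision", "FPR", "F05", "F2"]
    lines = ["\t".join(cols)]
    for r in reports:
        vals = [r.model_id, r.p, r.n, r.tp, r.fp, r.recall, r.precision, r.fpr,
                r.f05, r.f2]
        lines.append(
            "\t".join("" if v is None else (f"{v:.4f}" if isinstance(v, float) else str(v))
                      for v in vals)
        )
    s = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s
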