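"""Discrimination metrics in the by-visit and by-patient settings.

By-visit: AUPRC on the raw probabilities (step-curve integration, the
average-precision convention — no trapezoidal interpolation, which is
optimistically biased on imbalanced data), and precision / recall / F1
after thresholding.  Uncertain decisions (−1) are excluded from the
counted population before computing the confusion matrix.

By-patient: visit decisions are aggregated per patient with an OR —
positive if any certain-positive visit, else negative if any
certain-negative visit, else the patient is fully uncertain and is
excluded (and counted).  AUPRC is not defined in this setting because
patient labels only exist after thresholding.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score

from .thresholds import ThresholdRule, apply_rule

__all__ = [
    "auprc",
    "prf1",
    "PRF1",
    "by_patient_decisions",
    "EvaluationReport",
    "evaluate_rules",
    "reports_to_frame",
]


def auprc(probabilities, labels) -> float:
    """Area under the precision-recall step curve."""
    y = np.asarray(labels)
    if y.min() == y.max():
        raise ValueError("AUPRC needs both classes present")
    return float(average_precision_score(y, np.asarray(probabilities, dtype=np.float64)))


class PRF1(NamedTuple):
    precision: float
    recall: float
    f1: float
    #: True when a zero denominator forced a metric to 0
    degenerate: bool
    n_excluded: int


def prf1(decisions, labels, exclude_uncertain: bool = True) -> PRF1:
    """Precision, recall, F1 from decisions in {1, 0, −1}.

    Uncertain units (−1) are removed before counting when
    ``exclude_uncertain`` is set.  Metrics with a zero denominator are
    reported as 0 with the ``degenerate`` flag raised, so reports stay
    total.
    """
    d = np.asarray(decisions, dtype=np.int64)
    y = np.asarray(labels, dtype=np.int64)
    n_excluded = 0
    if exclude_uncertain:
        keep = d != -1
        n_excluded = int((~keep).sum())
        d, y = d[keep], y[keep]
    tp = int(np.sum((d == 1) & (y == 1)))
    fp = int(np.sum((d == 1) & (y == 0)))
    fn = int(np.sum((d != 1) & (y == 1)))
    degenerate = False
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        precision, degenerate = 0.0, True
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        recall, degenerate = 0.0, True
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1, degenerate = 0.0, True
    return PRF1(precision, recall, f1, degenerate, n_excluded)


def by_patient_decisions(decisions, patient_ids) -> tuple[pd.Series, int]:
    """OR-aggregate visit decisions per patient.

    A patient is 1 with any certain-positive visit, else 0 with any
    certain-negative visit, else −1 (fully uncertain, to be excluded).
    Returns ``(patient_decisions, n_fully_uncertain)``.
    """
    df = pd.DataFrame({"patient_id": np.asarray(patient_ids), "d": np.asarray(decisions)})
    agg = df.groupby("patient_id")["d"].agg(
        lambda s: 1 if (s == 1).any() else (0 if (s == 0).any() else -1)
    )
    return agg.astype(np.int64), int((agg == -1).sum())


@dataclass(frozen=True)
class EvaluationReport:
    """Metrics for one (setting, window, uncertainty level)."""

    setting: str
    window: str
    uncertainty_level: float
    precision: float
    recall: float
    f1: float
    n_units: int
    n_uncertain_excluded: int
    auprc: float | None = None
    achieved_uncertainty: float | None = None
    n_patients_fully_uncertain: int | None = None
    degenerate: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def evaluate_rules(
    probabilities,
    labels,
    patient_ids,
    rules: dict[float, ThresholdRule],
    window: str = "",
) -> list[EvaluationReport]:
    """One by-visit and one by-patient report per uncertainty level.

    ``rules`` maps uncertainty level (0 for the single-threshold rule)
    to the rule optimised for it.  AUPRC appears in by-visit reports
    only; it is threshold-free, so the same value is carried on each.
    """
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    pid = np.asarray(patient_ids)
    area = auprc(p, y) if y.min() != y.max() else None
    patient_labels = pd.Series(y).groupby(pd.Series(pid)).max()

    reports: list[EvaluationReport] = []
    for level, rule in sorted(rules.items()):
        d = apply_rule(p, rule)
        res = prf1(d, y)
        reports.append(
            EvaluationReport(
                setting="by_visit",
                window=window,
                uncertainty_level=level,
                precision=res.precision,
                recall=res.recall,
                f1=res.f1,
                n_units=len(y) - res.n_excluded,
                n_uncertain_excluded=res.n_excluded,
                auprc=area,
                achieved_uncertainty=res.n_excluded / max(len(y), 1),
                degenerate=res.degenerate,
            )
        )
        pdec, n_full = by_patient_decisions(d, pid)
        ply = patient_labels.loc[pdec.index]
        keep = pdec != -1
        pres = prf1(pdec[keep].to_numpy(), ply[keep].to_numpy(), exclude_uncertain=False)
        reports.append(
            EvaluationReport(
                setting="by_patient",
                window=window,
                uncertainty_level=level,
                precision=pres.precision,
                recall=pres.recall,
                f1=pres.f1,
                n_units=int(keep.sum()),
                n_uncertain_excluded=n_full,
                n_patients_fully_uncertain=n_full,
                degenerate=pres.degenerate,
            )
        )
    return reports


def reports_to_frame(reports: list[EvaluationReport]) -> pd.DataFrame:
    """Flat table, one row per setting × window × uncertainty level."""
    return pd.DataFrame([r.to_dict() for r in reports])
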