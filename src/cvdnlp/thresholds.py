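"""Decision thresholds with an optional reject (uncertainty) band.

Two schemes turn the classifier's probabilities into decisions:

* **single threshold** ``th``: positive iff ``p >= th``; the threshold
  maximising F1 over all unique validation probabilities is chosen;
* **double threshold** ``(th_low, th_high)``: positive iff
  ``p >= th_high``, negative iff ``p <= th_low``, otherwise *uncertain*
  (coded −1, e.g. routed to manual review).  For a target uncertain
  fraction ``U`` the pair minimising the cost

      J = |F1 − 1| + |U_achieved − U|

  is selected on the validation set, with F1 computed on the
  non-uncertain decisions only.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "ThresholdRule",
    "ThresholdSearchResult",
    "TARGET_UNCERTAINTY_LEVELS",
    "apply_rule",
    "cost",
    "optimise_single",
    "optimise_double",
]

#: target uncertain fractions explored for the double-threshold scheme
TARGET_UNCERTAINTY_LEVELS = (0.05, 0.10, 0.15, 0.20)


@dataclass(frozen=True)
class ThresholdRule:
    """A single (``th``) or double (``th_low`` < ``th_high``) cut-off."""

    kind: str
    th: float | None = None
    th_low: float | None = None
    th_high: float | None = None
    target_uncertainty: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "single":
            if self.th is None or not 0.0 <= self.th <= 1.0:
                raise ValueError("single rule needs th in [0, 1]")
        elif self.kind == "double":
            if self.th_low is None or self.th_high is None:
                raise ValueError("double rule needs th_low and th_high")
            if not (0.0 <= self.th_low < self.th_high <= 1.0):
                raise ValueError("double rule needs 0 <= th_low < th_high <= 1")
        else:
            raise ValueError(f"unknown rule kind {self.kind!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdRule":
        return cls(**d)


@dataclass(frozen=True)
class ThresholdSearchResult:
    """A rule plus what it achieved on the validation set."""

    rule: ThresholdRule
    f1: float
    achieved_uncertainty: float
    cost: float

    def to_dict(self) -> dict:
        return {
            "rule": self.rule.to_dict(),
            "f1": self.f1,
            "achieved_uncertainty": self.achieved_uncertainty,
            "cost": self.cost,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def apply_rule(probabilities, rule: ThresholdRule) -> np.ndarray:
    """Decisions in {1, 0, −1}; −1 (uncertain) only for double rules."""
    p = np.asarray(probabilities, dtype=np.float64)
    if rule.kind == "single":
        return (p >= rule.th).astype(np.int64)
    out = np.full(p.shape, -1, dtype=np.int64)
    out[p >= rule.th_high] = 1
    out[p <= rule.th_low] = 0
    return out


def cost(f1: float, achieved_uncertainty: float, target_uncertainty: float) -> float:
    """J = |F1 − 1| + |U_achieved − U_target|."""
    return abs(f1 - 1.0) + abs(achieved_uncertainty - target_uncertainty)


def _check_two_classes(y: np.ndarray) -> None:
    if y.min() == y.max():
        raise ValueError("validation labels contain a single class")


def optimise_single(probabilities, labels) -> ThresholdSearchResult:
    """Scan every unique validation probability as a cut-off, maximise F1.

    Ties are resolved toward the lowest threshold (favouring recall).
    """
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    _check_two_classes(y)
    order = np.argsort(p, kind="stable")
    ps, ys = p[order], y[order]
    uniq, first = np.unique(ps, return_index=True)
    # suffix sums at each unique value: counts / positives with p >= u
    total_pos = ys.sum()
    suffix_pos = np.concatenate([np.cumsum(ys[::-1])[::-1], [0]])
    n = len(ps)
    tp = suffix_pos[first]
    pred_pos = n - first
    fp = pred_pos - tp
    fn = total_pos - tp
    denom = 2 * tp + fp + fn
    f1 = np.where(denom > 0, 2 * tp / np.maximum(denom, 1), 0.0)
    best = np.flatnonzero(f1 == f1.max())[0]  # uniq ascending -> lowest threshold
    rule = ThresholdRule(kind="single", th=float(uniq[best]))
    return ThresholdSearchResult(rule, float(f1[best]), 0.0, float(abs(f1[best] - 1.0)))


def optimise_double(
    probabilities,
    labels,
    target_uncertainty: float,
    n_candidates: int = 500_000,
    seed: int = 0,
) -> ThresholdSearchResult:
    """Find the (th_low, th_high) pair minimising J on the validation set.

    Candidate pairs are all ordered pairs of unique validation
    probabilities when their number does not exceed ``n_candidates``;
    otherwise ``n_candidates`` pairs are subsampled uniformly with a
    fixed seed.  F1 counts only non-uncertain decisions.  Ties are
    resolved toward the smaller achieved uncertainty, then the smaller
    ``th_low``.
    """
    if not 0.0 <= target_uncertainty < 1.0:
        raise ValueError("target_uncertainty must be in [0, 1)")
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    _check_two_classes(y)
    n = len(p)
    order = np.argsort(p, kind="stable")
    ps, ys = p[order], y[order]
    uniq, first = np.unique(ps, return_index=True)
    m = len(uniq)
    counts = np.bincount(np.searchsorted(uniq, ps), minlength=m)
    pos_at = np.bincount(np.searchsorted(uniq, ps), weights=ys, minlength=m)
    # at unique value u_k: #(p <= u_k), positives with p <= u_k, and >= variants
    le_count = np.cumsum(counts)
    le_pos = np.cumsum(pos_at)
    ge_count = n - np.concatenate([[0], le_count[:-1]])
    ge_pos = y.sum() - np.concatenate([[0], le_pos[:-1]])

    n_pairs = m * (m - 1) // 2
    if n_pairs <= n_candidates:
        i_idx, j_idx = np.triu_indices(m, k=1)
    else:
        rng = np.random.default_rng(seed)
        a = rng.integers(0, m, size=int(2.5 * n_candidates))
        b = rng.integers(0, m, size=int(2.5 * n_candidates))
        keep = a < b
        i_idx, j_idx = a[keep][:n_candidates], b[keep][:n_candidates]
        if len(i_idx) == 0:
            raise ValueError("no candidate pairs available")

    tp = ge_pos[j_idx]
    pred_pos = ge_count[j_idx]
    fp = pred_pos - tp
    fn = le_pos[i_idx]
    uncertain = n - pred_pos - le_count[i_idx]
    u_th = uncertain / n
    denom = 2 * tp + fp + fn
    f1 = np.where(denom > 0, 2 * tp / np.maximum(denom, 1), 0.0)
    if not np.any(pred_pos > 0):
        raise ValueError("no candidate pair yields a certain positive prediction")
    j_cost = np.abs(f1 - 1.0) + np.abs(u_th - target_uncertainty)
    best_mask = j_cost == j_cost.min()
    cand = np.flatnonzero(best_mask)
    cand = cand[u_th[cand] == u_th[cand].min()]
    cand = cand[uniq[i_idx[cand]] == uniq[i_idx[cand]].min()]
    k = cand[0]
    rule = ThresholdRule(
        kind="double",
        th_low=float(uniq[i_idx[k]]),
        th_high=float(uniq[j_idx[k]]),
        target_uncertainty=float(target_uncertainty),
    )
    return ThresholdSearchResult(rule, float(f1[k]), float(u_th[k]), float(j_cost[k]))
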