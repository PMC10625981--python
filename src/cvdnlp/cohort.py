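"""Cohort construction: harmonisation, CVD code matching, look-back
window labelling, by-patient aggregation and patient-grouped splits.

A visit is positive under a look-back window of width ``w`` months when a
qualifying CVD hospital discharge for the same patient falls in
``[visit_date - w months, visit_date]`` (both endpoints inclusive; a
discharge on the visit date counts as prior).  With an infinite window
any discharge up to the visit date qualifies, regardless of time
distance.  Visits whose patient was not observably enrolled for the full
window duration before the visit (eligibility started too late) are
removed, because their label could not be determined reliably.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CodePolicy",
    "WindowSpec",
    "INFINITE",
    "STANDARD_WINDOWS",
    "expand_intervention_ranges",
    "is_cvd_hospitalisation",
    "qualifying_discharges",
    "harmonise",
    "label_visits",
    "aggregate_by_patient",
    "split_by_patient",
    "build_labelled_dataset",
]

#: revascularisation procedure codes; ranges expand at load time
_INTERVENTION_RANGES = [
    ("0061", "0066"),
    ("3603", "3603"),
    ("3606", "3607"),
    ("3610", "3619"),
    ("0055", "0055"),
    ("3950", "3950"),
    ("3952", "3952"),
    ("3848", "3848"),
    ("3971", "3971"),
    ("3990", "3990"),
]


def expand_intervention_ranges(ranges: list[tuple[str, str]] | None = None) -> frozenset[str]:
    """Expand inclusive code ranges like ("3610", "3619") to explicit sets."""
    out: set[str] = set()
    for lo, hi in ranges if ranges is not None else _INTERVENTION_RANGES:
        if len(lo) != len(hi) or lo[:-2] != hi[:-2]:
            raise ValueError(f"malformed intervention range {lo}-{hi}")
        for v in range(int(lo), int(hi) + 1):
            out.add(str(v).zfill(len(lo)))
    return frozenset(out)


@dataclass(frozen=True)
class CodePolicy:
    """Which ICD-9-CM codes mark a discharge as cardiovascular.

    ``diagnosis_range`` is an inclusive range of 3-digit category codes
    (default 390-459, the circulatory-system chapter); longer codes
    inherit their leading category.  ``intervention_codes`` are matched
    as prefixes at each entry's stated precision, after dot removal.
    """

    diagnosis_range: tuple[int, int] = (390, 459)
    intervention_codes: frozenset[str] = field(default_factory=expand_intervention_ranges)

    def __post_init__(self) -> None:
        lo, hi = self.diagnosis_range
        if lo > hi:
            raise ValueError("diagnosis_range must be (lo, hi) with lo <= hi")


@dataclass(frozen=True)
class WindowSpec:
    """Look-back window width in months; ``None`` means infinite."""

    width_months: int | None

    def __post_init__(self) -> None:
        if self.width_months is not None and self.width_months < 1:
            raise ValueError("window width must be a positive number of months")

    @property
    def infinite(self) -> bool:
        return self.width_months is None

    @property
    def name(self) -> str:
        return "infinite" if self.infinite else f"{self.width_months}m"


INFINITE = WindowSpec(None)
#: the four widths studied: infinite, then increasingly narrow
STANDARD_WINDOWS = (INFINITE, WindowSpec(24), WindowSpec(12), WindowSpec(6))


def _clean_code(code: str) -> str:
    return str(code).replace(".", "").strip()


def is_cvd_hospitalisation(
    diagnosis_codes: list[str],
    intervention_codes: list[str],
    policy: CodePolicy | None = None,
) -> bool:
    """True iff any diagnosis category falls in the circulatory range or
    any intervention code matches a revascularisation entry."""
    policy = policy or CodePolicy()
    lo, hi = policy.diagnosis_range
    for code in diagnosis_codes:
        c = _clean_code(code)
        if len(c) < 3 or not c[:3].isdigit():
            if not c:
                logger.warning("empty diagnosis code skipped")
            continue
        if lo <= int(c[:3]) <= hi:
            return True
    for code in intervention_codes:
        c = _clean_code(code)
        if not c:
            logger.warning("empty intervention code skipped")
            continue
        for entry in policy.intervention_codes:
            if c.startswith(entry):
                return True
    return False


def qualifying_discharges(registry: pd.DataFrame, policy: CodePolicy | None = None) -> pd.DataFrame:
    """Subset of the registry whose discharges qualify as CVD."""
    policy = policy or CodePolicy()
    if len(registry) == 0:
        return registry.copy()
    mask = [
        is_cvd_hospitalisation(d, i, policy)
        for d, i in zip(registry["diagnosis_codes"], registry["intervention_codes"])
    ]
    return registry.loc[mask]


def harmonise(
    visits: pd.DataFrame,
    eligibility: pd.DataFrame,
    observation_interval: tuple[pd.Timestamp, pd.Timestamp] | None = None,
    min_active_years: int = 3,
) -> pd.DataFrame:
    """Apply the table-alignment filters.

    Retains visits inside the observation interval and inside the
    patient's eligibility period, then drops every visit of patients who
    do not have at least one visit per calendar year in at least
    ``min_active_years`` distinct years (non-consecutive accepted).
    """
    out = visits.copy()
    out["visit_date"] = pd.to_datetime(out["visit_date"])
    if observation_interval is not None:
        start, end = (pd.Timestamp(t) for t in observation_interval)
        out = out[(out["visit_date"] >= start) & (out["visit_date"] <= end)]

    elig = eligibility.copy()
    elig["start_date"] = pd.to_datetime(elig["start_date"])
    elig["end_date"] = pd.to_datetime(elig["end_date"])
    merged = out.rename_axis("_row").reset_index().merge(elig, on="patient_id", how="left", suffixes=("", "_e"))
    inside = (
        merged["start_date"].notna()
        & (merged["visit_date"] >= merged["start_date"])
        & (merged["visit_date"] <= merged["end_date"])
    )
    # a visit survives if it lies inside any eligibility period of its patient
    merged = merged[inside.to_numpy()].drop_duplicates(subset="_row")
    out = merged[list(visits.columns)]

    years = out["visit_date"].dt.year
    distinct = years.groupby(out["patient_id"]).nunique()
    active = distinct[distinct >= min_active_years].index
    return out[out["patient_id"].isin(active)].reset_index(drop=True)


def label_visits(
    visits: pd.DataFrame,
    registry: pd.DataFrame,
    policy: CodePolicy | None = None,
    window: WindowSpec = INFINITE,
    eligibility: pd.DataFrame | None = None,
    observation_end: pd.Timestamp | None = None,
) -> pd.DataFrame:
    """Label each visit 1 iff a qualifying discharge lies in its look-back
    window; remove finite-window visits with incomplete observation.

    For width ``w`` the window is ``[visit_date - w months, visit_date]``
    with calendar-month arithmetic (day-of-month overflow clamps to the
    month end) and both endpoints inclusive.  A finite-window visit is
    kept only if the patient's eligibility started at least ``w`` months
    before the visit (requires ``eligibility``).

    Returns a copy of ``visits`` with an integer ``label`` column.
    """
    policy = policy or CodePolicy()
    out = visits.copy().reset_index(drop=True)
    out["visit_date"] = pd.to_datetime(out["visit_date"])

    qual = qualifying_discharges(registry, policy)
    if observation_end is not None and len(registry):
        if pd.to_datetime(registry["discharge_date"]).max() > pd.Timestamp(observation_end):
            raise ValueError("registry contains a discharge after the observation end")

    if not window.infinite:
        if eligibility is None:
            raise ValueError("finite windows require eligibility periods to detect incomplete windows")
        elig_start = (
            eligibility.assign(start_date=pd.to_datetime(eligibility["start_date"]))
            .groupby("patient_id")["start_date"]
            .min()
        )
        starts = out["patient_id"].map(elig_start)
        window_start = out["visit_date"] - pd.DateOffset(months=window.width_months)
        complete = starts.notna() & (starts <= window_start)
        out = out[complete.to_numpy()].reset_index(drop=True)

    labels = np.zeros(len(out), dtype=np.int64)
    if len(qual) and len(out):
        discharges = (
            qual.assign(discharge_date=pd.to_datetime(qual["discharge_date"]))
            .groupby("patient_id")["discharge_date"]
            .apply(lambda s: np.sort(s.to_numpy()))
        )
        win_start = (
            None
            if window.infinite
            else (out["visit_date"] - pd.DateOffset(months=window.width_months)).to_numpy()
        )
        vdates = out["visit_date"].to_numpy()
        for i, (pid, vd) in enumerate(zip(out["patient_id"], vdates)):
            d = discharges.get(pid)
            if d is None:
                continue
            upper = np.searchsorted(d, vd, side="right")  # discharges <= visit date
            if window.infinite:
                labels[i] = int(upper > 0)
            else:
                lower = np.searchsorted(d, win_start[i], side="left")
                labels[i] = int(upper > lower)
    out["label"] = labels
    return out


def aggregate_by_patient(labelled: pd.DataFrame) -> pd.Series:
    """Patient label = OR over the patient's visit labels."""
    return labelled.groupby("patient_id")["label"].max().astype(np.int64)


def split_by_patient(
    patient_ids,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> pd.Series:
    """Random patient-level partition into train/validation/test.

    Counts follow largest-remainder apportionment of ``fractions`` over
    the number of distinct patients; assignment is deterministic given
    ``seed``.  Returns a Series patient_id -> split name.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    unique = np.unique(np.asarray(list(patient_ids)))
    names = ("train", "validation", "test")
    if len(unique) < len(fractions):
        raise ValueError(f"need at least {len(fractions)} patients, got {len(unique)}")
    n = len(unique)
    raw = np.array(fractions, dtype=float) * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    for k in order[:remainder]:
        counts[k] += 1
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(unique)
    assignment: dict[str, str] = {}
    pos = 0
    for name, c in zip(names, counts):
        for pid in shuffled[pos : pos + c]:
            assignment[pid] = name
        pos += c
    return pd.Series(assignment, name="split").rename_axis("patient_id")


def build_labelled_dataset(
    visits: pd.DataFrame,
    registry: pd.DataFrame,
    eligibility: pd.DataFrame,
    window: WindowSpec,
    policy: CodePolicy | None = None,
    observation_interval: tuple | None = None,
    split: pd.Series | None = None,
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    split_seed: int = 0,
) -> pd.DataFrame:
    """Harmonise, label under one window, and attach a patient-grouped
    split column (reusing ``split`` when given, so all windows and the
    by-patient view share one assignment)."""
    harmonised = harmonise(visits, eligibility, observation_interval)
    labelled = label_visits(
        harmonised,
        registry,
        policy,
        window,
        eligibility=eligibility,
        observation_end=None if observation_interval is None else observation_interval[1],
    )
    if split is None:
        split = split_by_patient(labelled["patient_id"], split_fractions, split_seed)
    labelled["split"] = labelled["patient_id"].map(split)
    labelled = labelled[labelled["split"].notna()].reset_index(drop=True)
    return labelled
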