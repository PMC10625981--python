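"""Synthetic EHR cohort generator.

Emulates the two proprietary tables the analysis needs — a diabetes
outpatient visit table (free-form note text) and a hospital discharge
registry (ICD-9-CM codes) — together with per-patient healthcare
eligibility periods.  The generator reproduces the statistical structure
the downstream pipeline assumes:

* a small fraction of visits (a few percent) have a qualifying
  cardiovascular (CVD) discharge within a given look-back window;
* notes written shortly after a CVD discharge usually, but not always,
  mention it (``mention_given_recent_hosp``), mostly with acute/event
  vocabulary ("ricovero", "dimissione", ...);
* some notes mention cardiovascular history with no recent discharge
  behind them (``spurious_mention_rate``), using generic history
  vocabulary — these are the lexically ambiguous cases;
* a fraction of discharges carry only non-CVD codes and must not
  produce positive labels.

All text is templated pseudo-Italian built from clinical theme phrases
(glycaemia, diet, therapy, ...); producing fluent prose is a non-goal.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GeneratorConfig",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "CohortParseError",
]

VISIT_COLUMNS = ["patient_id", "visit_date", "text"]
REGISTRY_COLUMNS = ["patient_id", "discharge_date", "diagnosis_codes", "intervention_codes"]
ELIGIBILITY_COLUMNS = ["patient_id", "start_date", "end_date"]

# Theme phrases for the body of a note.  Tokens are pseudo-Italian
# clinical vocabulary; inflected variants give the stemmer something to do.
_BASE_PHRASES = [
    ("controllo", "glicemia", "a", "digiuno"),
    ("emoglobina", "glicata", "stabile"),
    ("glicemie", "in", "buon", "compenso"),
    ("compenso", "glicemico", "discreto"),
    ("il", "paziente", "riferisce", "benessere"),
    ("la", "paziente", "prosegue", "la", "terapia"),
    ("terapia", "insulinica", "invariata"),
    ("aumentato", "dosaggio", "di", "metformina"),
    ("dieta", "ipocalorica", "consigliata"),
    ("peso", "corporeo", "in", "calo"),
    ("pressione", "arteriosa", "nella", "norma"),
    ("esami", "ematici", "di", "routine"),
    ("funzione", "renale", "conservata"),
    ("microalbuminuria", "assente"),
    ("esame", "del", "piede", "negativo"),
    ("fondo", "oculare", "da", "programmare"),
    ("prossimo", "controllo", "fra", "sei", "mesi"),
    ("attivita", "fisica", "regolare", "consigliata"),
    ("colesterolo", "ai", "limiti", "della", "norma"),
    ("trigliceridi", "elevati"),
]

# Acute/event vocabulary: what a clinician writes when a recent CVD
# hospital discharge is being discussed at the visit.
_ACUTE_CVD_PHRASES = [
    ("recente", "ricovero", "per", "infarto", "miocardico"),
    ("dimissione", "ospedaliera", "dopo", "evento", "coronarico"),
    ("ricoverato", "per", "scompenso", "cardiaco", "acuto"),
    ("recente", "rivascolarizzazione", "coronarica"),
    ("dimesso", "dalla", "cardiologia", "dopo", "angioplastica"),
    ("ricovero", "per", "ictus", "ischemico", "recente"),
]

# Generic history vocabulary: cardiovascular mentions that need not be
# backed by any recent discharge (past history, family history, risk talk).
_HISTORY_CVD_PHRASES = [
    ("pregressa", "cardiopatia", "ischemica"),
    ("storia", "di", "cardiopatia", "nota"),
    ("familiarita", "per", "malattie", "cardiovascolari"),
    ("rischio", "cardiovascolare", "da", "monitorare"),
    ("vasculopatia", "periferica", "nota"),
]

# Qualifying CVD discharge codes (dot-free): ICD-9-CM circulatory
# diagnoses (390-459) and revascularisation procedures.
_CVD_DIAGNOSES = ["41071", "41401", "42731", "4280", "43491", "4019", "45981", "3962"]
_CVD_INTERVENTIONS = ["3606", "0066", "3615", "3950", "3990"]
# Non-circulatory codes (categories outside 390-459).
_NONCVD_DIAGNOSES = ["25000", "25060", "5990", "5859", "7802", "53081", "2720"]
_NONCVD_INTERVENTIONS = ["8952", "9904"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic cohort.

    Defaults target the regime of the real corpus: an observation period
    of 2011-01-01 .. 2018-09-30 and a qualifying-discharge rate giving
    roughly 3% positive visits under a 24-month look-back window.
    """

    n_patients: int = 2000
    visits_per_patient_range: tuple[int, int] = (6, 17)
    observation_start: datetime.date = datetime.date(2011, 1, 1)
    observation_end: datetime.date = datetime.date(2018, 9, 30)
    #: qualifying + non-qualifying discharges per patient-year
    hosp_rate: float = 0.02
    #: P(note mentions CVD | qualifying discharge within mention_horizon_months)
    mention_given_recent_hosp: float = 0.9
    #: P(note mentions CVD | no qualifying discharge within the horizon)
    spurious_mention_rate: float = 0.02
    mention_horizon_months: int = 24
    #: fraction of discharges carrying only non-CVD codes
    noncvd_code_rate: float = 0.25
    #: among hospitalisation-driven mentions, share using acute/event
    #: vocabulary (the rest use generic history vocabulary)
    acute_phrase_share: float = 0.95
    #: fraction of patients eligible only for a random sub-interval
    partial_eligibility_rate: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "hosp_rate": min(self.hosp_rate, 1.0),  # rate per year, sanity-capped below
            "mention_given_recent_hosp": self.mention_given_recent_hosp,
            "spurious_mention_rate": self.spurious_mention_rate,
            "noncvd_code_rate": self.noncvd_code_rate,
            "acute_phrase_share": self.acute_phrase_share,
            "partial_eligibility_rate": self.partial_eligibility_rate,
        }
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.hosp_rate < 0:
            raise ValueError("hosp_rate must be non-negative")
        if self.observation_start >= self.observation_end:
            raise ValueError("observation_start must precede observation_end")
        lo, hi = self.visits_per_patient_range
        if lo < 1 or hi < lo:
            raise ValueError("visits_per_patient_range must be (lo, hi) with 1 <= lo <= hi")
        if self.mention_horizon_months < 1:
            raise ValueError("mention_horizon_months must be positive")
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")


def _days_between(later: np.datetime64, earlier: np.datetime64) -> int:
    return int((later - earlier) / np.timedelta64(1, "D"))


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (visits, hospitalisations, eligibility) tables.

    Pure function of ``config`` (seed included): the same configuration
    always yields byte-identical tables.

    Returns
    -------
    visits : DataFrame with columns patient_id, visit_date, text
    registry : DataFrame with columns patient_id, discharge_date,
        diagnosis_codes, intervention_codes (code lists)
    eligibility : DataFrame with columns patient_id, start_date, end_date
    """
    rng = np.random.default_rng(config.seed)
    obs_start = np.datetime64(config.observation_start.isoformat(), "D")
    obs_end = np.datetime64(config.observation_end.isoformat(), "D")
    obs_days = _days_between(obs_end, obs_start)
    horizon_days = int(round(config.mention_horizon_months * 30.44))

    visit_rows: list[tuple[str, np.datetime64, str]] = []
    hosp_rows: list[tuple[str, np.datetime64, list[str], list[str]]] = []
    elig_rows: list[tuple[str, np.datetime64, np.datetime64]] = []

    lo_v, hi_v = config.visits_per_patient_range
    for i in range(config.n_patients):
        pid = f"P{i:06d}"

        # Eligibility: full observation window for most patients,
        # a random sub-interval for the rest.
        if rng.random() < config.partial_eligibility_rate:
            a, b = np.sort(rng.integers(0, obs_days + 1, size=2))
            if b - a < 365:  # keep sub-intervals long enough to hold visits
                a = max(0, int(b) - 365)
            e_start, e_end = obs_start + int(a), obs_start + int(b)
        else:
            e_start, e_end = obs_start, obs_end
        elig_rows.append((pid, e_start, e_end))
        elig_days = _days_between(e_end, e_start)
        elig_offset = _days_between(e_start, obs_start)

        # Hospital discharges: Poisson process over the eligibility period.
        years = elig_days / 365.25
        n_hosp = rng.poisson(config.hosp_rate * years)
        hosp_dates = np.sort(obs_start + (elig_offset + rng.integers(0, elig_days + 1, size=n_hosp)))
        qualifying_dates: list[np.datetime64] = []
        for d in hosp_dates:
            if rng.random() < config.noncvd_code_rate:
                diag = list(rng.choice(_NONCVD_DIAGNOSES, size=rng.integers(1, 3), replace=False))
                interv = list(rng.choice(_NONCVD_INTERVENTIONS, size=rng.integers(0, 2), replace=False))
            else:
                diag = list(rng.choice(_CVD_DIAGNOSES, size=rng.integers(1, 3), replace=False))
                interv = (
                    list(rng.choice(_CVD_INTERVENTIONS, size=1))
                    if rng.random() < 0.4
                    else []
                )
                qualifying_dates.append(d)
            hosp_rows.append((pid, d, diag, interv))
        q_dates = np.array(qualifying_dates, dtype="datetime64[D]")

        # Visits: uniform dates within eligibility; templated note text.
        n_visits = int(rng.integers(lo_v, hi_v + 1))
        v_dates = np.sort(obs_start + (elig_offset + rng.integers(0, elig_days + 1, size=n_visits)))
        for vd in v_dates:
            n_phrases = int(rng.integers(2, 4))
            idx = rng.choice(len(_BASE_PHRASES), size=n_phrases, replace=False)
            tokens: list[str] = []
            for k in idx:
                tokens.extend(_BASE_PHRASES[k])
            gap = (vd - q_dates) / np.timedelta64(1, "D") if len(q_dates) else np.array([])
            recent = bool(len(gap) and np.any((gap >= 0) & (gap <= horizon_days)))
            if recent:
                if rng.random() < config.mention_given_recent_hosp:
                    pool = (
                        _ACUTE_CVD_PHRASES
                        if rng.random() < config.acute_phrase_share
                        else _HISTORY_CVD_PHRASES
                    )
                    phrase = pool[rng.integers(0, len(pool))]
                    pos = rng.integers(0, len(tokens) + 1)
                    tokens[pos:pos] = phrase
            elif rng.random() < config.spurious_mention_rate:
                phrase = _HISTORY_CVD_PHRASES[rng.integers(0, len(_HISTORY_CVD_PHRASES))]
                pos = rng.integers(0, len(tokens) + 1)
                tokens[pos:pos] = phrase
            visit_rows.append((pid, vd, " ".join(tokens)))

    visits = pd.DataFrame(visit_rows, columns=VISIT_COLUMNS)
    registry = pd.DataFrame(hosp_rows, columns=REGISTRY_COLUMNS)
    eligibility = pd.DataFrame(elig_rows, columns=ELIGIBILITY_COLUMNS)
    visits["visit_date"] = pd.to_datetime(visits["visit_date"])
    if len(registry):
        registry["discharge_date"] = pd.to_datetime(registry["discharge_date"])
    else:
        registry["discharge_date"] = pd.to_datetime(registry["discharge_date"])
    eligibility["start_date"] = pd.to_datetime(eligibility["start_date"])
    eligibility["end_date"] = pd.to_datetime(eligibility["end_date"])
    return visits, registry, eligibility


class CohortParseError(ValueError):
    """Raised when a cohort CSV is malformed; the message names the line."""


def _check_columns(df: pd.DataFrame, expected: list[str], path: Path) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise CohortParseError(f"{path}: missing columns {missing}")


def _parse_dates(df: pd.DataFrame, column: str, path: Path) -> pd.Series:
    parsed = pd.to_datetime(df[column], format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & df[column].notna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +1 header, +1 one-based
        raise CohortParseError(
            f"{path}: line {line}: cannot parse {column!r} value {df[column][bad].iloc[0]!r} as YYYY-MM-DD"
        )
    if parsed.isna().any():
        line = int(np.flatnonzero(parsed.isna().to_numpy())[0]) + 2
        raise CohortParseError(f"{path}: line {line}: missing {column!r}")
    return parsed


def write_cohort(
    visits: pd.DataFrame,
    registry: pd.DataFrame,
    eligibility: pd.DataFrame,
    directory: str | Path,
) -> dict[str, Path]:
    """Write the three tables as UTF-8 CSV with ISO-8601 dates.

    Code lists are semicolon-joined.  Returns the paths written.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "visits": directory / "visits.csv",
        "registry": directory / "hospitalisations.csv",
        "eligibility": directory / "eligibility.csv",
    }
    v = visits.copy()
    v["visit_date"] = pd.to_datetime(v["visit_date"]).dt.strftime("%Y-%m-%d")
    v[VISIT_COLUMNS].to_csv(paths["visits"], index=False)

    r = registry.copy()
    r["discharge_date"] = pd.to_datetime(r["discharge_date"]).dt.strftime("%Y-%m-%d")
    r["diagnosis_codes"] = r["diagnosis_codes"].map(";".join)
    r["intervention_codes"] = r["intervention_codes"].map(";".join)
    r[REGISTRY_COLUMNS].to_csv(paths["registry"], index=False)

    e = eligibility.copy()
    e["start_date"] = pd.to_datetime(e["start_date"]).dt.strftime("%Y-%m-%d")
    e["end_date"] = pd.to_datetime(e["end_date"]).dt.strftime("%Y-%m-%d")
    e[ELIGIBILITY_COLUMNS].to_csv(paths["eligibility"], index=False)
    return paths


def _split_codes(value: object) -> list[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return []
    return str(value).split(";")


def read_cohort(directory: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read tables written by :func:`write_cohort`, validating as it goes."""
    directory = Path(directory)
    vp = directory / "visits.csv"
    rp = directory / "hospitalisations.csv"
    ep = directory / "eligibility.csv"

    visits = pd.read_csv(vp, dtype={"patient_id": str, "text": str})
    _check_columns(visits, VISIT_COLUMNS, vp)
    visits["visit_date"] = _parse_dates(visits, "visit_date", vp)

    registry = pd.read_csv(rp, dtype={"patient_id": str}, keep_default_na=False)
    _check_columns(registry, REGISTRY_COLUMNS, rp)
    registry["discharge_date"] = _parse_dates(registry, "discharge_date", rp)
    registry["diagnosis_codes"] = registry["diagnosis_codes"].map(_split_codes)
    registry["intervention_codes"] = registry["intervention_codes"].map(_split_codes)

    eligibility = pd.read_csv(ep, dtype={"patient_id": str})
    _check_columns(eligibility, ELIGIBILITY_COLUMNS, ep)
    eligibility["start_date"] = _parse_dates(eligibility, "start_date", ep)
    eligibility["end_date"] = _parse_dates(eligibility, "end_date", ep)
    return visits, registry, eligibility
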