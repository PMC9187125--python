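"""Analytic cohort: data model, CSV I/O, inclusion filters, outcome dichotomization.

Pain scores are integer numerical-rating-scale (NRS) values, 0 (no pain) to
10 (worst pain), recorded at irregular times during the inpatient stay.
Times are hours since the end of surgery; the analysis window is the first
96 hours. Patients with more than 4 days of inpatient stay or fewer than 4
in-window pain scores are excluded, mirroring the motivating registry
cohort's selection rules.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MEANINGFUL_PAIN_THRESHOLD = 3

SEX_LEVELS = ("female", "male")
RACE_LEVELS = ("white", "black", "other")
SMOKING_LEVELS = ("smoker", "non-smoker", "former")
CCI_LEVELS = ("0", "1", "2")
ASA_LEVELS = ("I", "III")
SURGERY_LEVELS = ("breast", "cardiothoracic", "MIS", "orthopedic", "other", "vascular")
ANESTHESIA_LEVELS = ("general", "regional")

PAIN_COLUMNS = ("patient_id", "time_h", "score")
BASELINE_COLUMNS = (
    "patient_id", "age_years", "sex", "race", "smoking", "cci", "asa",
    "surgery_category", "anesthesia", "baseline_pain", "pain_30d",
    "pain_1y", "los_days",
)


@dataclass(frozen=True)
class PainObservation:
    """One recorded pain score: integer NRS 0-10 at ``time_h`` hours post surgery."""

    patient_id: str
    time_h: float
    score: int

    def __post_init__(self):
        if not (0 <= self.score <= 10) or int(self.score) != self.score:
            raise ValueError(f"score must be an integer in [0, 10], got {self.score!r}")
        if self.time_h < 0 or not math.isfinite(self.time_h):
            raise ValueError(f"time_h must be a finite non-negative number, got {self.time_h!r}")


@dataclass
class PainSeries:
    """A patient's time-ordered acute pain observations.

    Construction sorts by time and collapses duplicate timestamps to their
    maximum score (conservative for pain; batch charting can produce exact
    ties). After construction observation times are strictly increasing.
    """

    patient_id: str
    observations: list[PainObservation]
    n_duplicates_collapsed: int = 0

    def __post_init__(self):
        for obs in self.observations:
            if obs.patient_id != self.patient_id:
                raise ValueError(
                    f"observation for {obs.patient_id!r} in series {self.patient_id!r}"
                )
        ordered = sorted(self.observations, key=lambda o: o.time_h)
        collapsed: list[PainObservation] = []
        n_dup = 0
        for obs in ordered:
            if collapsed and obs.time_h == collapsed[-1].time_h:
                n_dup += 1
                if obs.score > collapsed[-1].score:
                    collapsed[-1] = obs
            else:
                collapsed.append(obs)
        self.observations = collapsed
        self.n_duplicates_collapsed += n_dup

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def times(self) -> np.ndarray:
        return np.array([o.time_h for o in self.observations], dtype=float)

    @property
    def scores(self) -> np.ndarray:
        return np.array([o.score for o in self.observations], dtype=float)

    def truncated(self, window_h: float) -> "PainSeries":
        """Return a copy keeping only observations with time_h <= window_h."""
        kept = [o for o in self.observations if o.time_h <= window_h]
        out = PainSeries(self.patient_id, kept)
        out.n_duplicates_collapsed = self.n_duplicates_collapsed
        return out


def _as_optional_int_nrs(value) -> Optional[int]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    iv = int(value)
    if iv != value or not (0 <= iv <= 10):
        raise ValueError(f"NRS score must be an integer in [0, 10], got {value!r}")
    return iv


@dataclass
class BaselineRecord:
    """Per-patient baseline covariates and 30-day / 1-year pain outcomes."""

    patient_id: str
    age_years: Optional[float] = None
    sex: Optional[str] = None
    race: Optional[str] = None
    smoking: Optional[str] = None
    cci: Optional[str] = None
    asa: Optional[str] = None
    surgery_category: Optional[str] = None
    anesthesia: Optional[str] = None
    baseline_pain: Optional[int] = None
    pain_30d: Optional[int] = None
    pain_1y: Optional[int] = None
    los_days: Optional[float] = None

    def __post_init__(self):
        for name, levels in (
            ("sex", SEX_LEVELS), ("race", RACE_LEVELS), ("smoking", SMOKING_LEVELS),
            ("cci", CCI_LEVELS), ("asa", ASA_LEVELS),
            ("surgery_category", SURGERY_LEVELS), ("anesthesia", ANESTHESIA_LEVELS),
        ):
            val = getattr(self, name)
            if val is not None and val not in levels:
                raise ValueError(f"{name}={val!r} not in {levels}")
        for name in ("baseline_pain", "pain_30d", "pain_1y"):
            setattr(self, name, _as_optional_int_nrs(getattr(self, name)))


@dataclass
class CohortFilterReport:
    """Audit of the inclusion filters: every input patient is accounted for."""

    n_input: int
    n_retained: int
    exclusions: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self):
        removed = sum(n for _, n in self.exclusions)
        if self.n_input != self.n_retained + removed:
            raise ValueError(
                f"filter report does not reconcile: {self.n_input} != "
                f"{self.n_retained} + {removed}"
            )

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "exclusions": [{"rule": r, "n_removed": n} for r, n in self.exclusions],
        }


@dataclass
class ParseReport:
    """Counts of rows rejected while reading the pain CSV."""

    n_rows: int = 0
    n_bad_score: int = 0
    n_bad_time: int = 0
    n_missing: int = 0

    @property
    def n_dropped(self) -> int:
        return self.n_bad_score + self.n_bad_time + self.n_missing


def is_clinically_meaningful(score) -> Optional[bool]:
    """Dichotomize an NRS score at the clinically meaningful threshold (>= 3).

    A missing score (None/NaN) propagates as None; outcomes are never imputed.
    """
    if score is None or (isinstance(score, float) and math.isnan(score)):
        return None
    if not (0 <= score <= 10):
        raise ValueError(f"NRS score out of range: {score!r}")
    return score >= MEANINGFUL_PAIN_THRESHOLD


def _clean_str(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    return s or None


def read_cohort(pain_path, baseline_path):
    """Read pain and baseline CSV files.

    Returns ``(series_list, baseline_list, parse_report)``. Rows of the pain
    file with a non-integer or out-of-range score, a negative or non-finite
    time, or missing fields are dropped and counted in the parse report.
    Missing required columns are a fatal configuration error.
    """
    pain = pd.read_csv(pain_path, dtype={"patient_id": str})
    base = pd.read_csv(baseline_path, dtype={"patient_id": str, "cci": str, "asa": str})
    for col in PAIN_COLUMNS:
        if col not in pain.columns:
            raise ValueError(f"pain file missing required column {col!r}")
    for col in BASELINE_COLUMNS:
        if col not in base.columns:
            raise ValueError(f"baseline file missing required column {col!r}")

    report = ParseReport(n_rows=len(pain))
    by_patient: dict[str, list[PainObservation]] = {}
    for pid, t, y in pain[["patient_id", "time_h", "score"]].itertuples(index=False):
        if pid is None or (isinstance(t, float) and math.isnan(t)) or (
            isinstance(y, float) and math.isnan(y)
        ):
            report.n_missing += 1
            continue
        t = float(t)
        if t < 0 or not math.isfinite(t):
            report.n_bad_time += 1
            continue
        if float(y) != int(y) or not (0 <= int(y) <= 10):
            report.n_bad_score += 1
            continue
        by_patient.setdefault(str(pid), []).append(PainObservation(str(pid), t, int(y)))
    if report.n_dropped:
        logger.warning("dropped %d malformed pain rows", report.n_dropped)
    if not by_patient:
        logger.warning("pain file %s contains no valid observations", pain_path)

    series = [PainSeries(pid, obs) for pid, obs in by_patient.items()]

    records = []
    for row in base.itertuples(index=False):
        d = row._asdict()
        records.append(
            BaselineRecord(
                patient_id=str(d["patient_id"]),
                age_years=None if pd.isna(d["age_years"]) else float(d["age_years"]),
                sex=_clean_str(d["sex"]),
                race=_clean_str(d["race"]),
                smoking=_clean_str(d["smoking"]),
                cci=_clean_str(d["cci"]),
                asa=_clean_str(d["asa"]),
                surgery_category=_clean_str(d["surgery_category"]),
                anesthesia=_clean_str(d["anesthesia"]),
                baseline_pain=None if pd.isna(d["baseline_pain"]) else int(d["baseline_pain"]),
                pain_30d=None if pd.isna(d["pain_30d"]) else int(d["pain_30d"]),
                pain_1y=None if pd.isna(d["pain_1y"]) else int(d["pain_1y"]),
                los_days=None if pd.isna(d["los_days"]) else float(d["los_days"]),
            )
        )
    return series, records, report


def apply_inclusion_filters(
    series: Iterable[PainSeries],
    baseline: Iterable[BaselineRecord],
    window_h: float = 96.0,
    min_scores: int = 4,
    max_los_days: float = 4.0,
) -> tuple[list[PainSeries], list[BaselineRecord], CohortFilterReport]:
    """Apply the cohort inclusion rules in a fixed order.

    (1) truncate observations to the analysis window, (2) exclude length of
    stay > ``max_los_days``, (3) exclude fewer than ``min_scores`` in-window
    scores, (4) exclude patients absent from the baseline table. The report
    accounts for every input patient. Idempotent.
    """
    if window_h <= 0:
        raise ValueError("window_h must be positive")
    base_by_id = {b.patient_id: b for b in baseline}
    series = list(series)
    n_input = len(series)

    truncated = [s.truncated(window_h) for s in series]

    kept, n_los = [], 0
    for s in truncated:
        b = base_by_id.get(s.patient_id)
        if b is not None and b.los_days is not None and b.los_days > max_los_days:
            n_los += 1
        else:
            kept.append(s)

    kept2, n_min = [], 0
    for s in kept:
        if len(s) < min_scores:
            n_min += 1
        else:
            kept2.append(s)

    kept3, n_nobase = [], 0
    for s in kept2:
        if s.patient_id not in base_by_id:
            n_nobase += 1
            logger.warning("patient %s has pain scores but no baseline record", s.patient_id)
        else:
            kept3.append(s)

    report = CohortFilterReport(
        n_input=n_input,
        n_retained=len(kept3),
        exclusions=[("max_los", n_los), ("min_scores", n_min), ("no_baseline", n_nobase)],
    )
    retained_ids = {s.patient_id for s in kept3}
    base_out = [base_by_id[pid] for pid in sorted(retained_ids)]
    kept3.sort(key=lambda s: s.patient_id)
    return kept3, base_out, report


def series_to_frame(series: Sequence[PainSeries]) -> pd.DataFrame:
    """Long-format DataFrame (patient_id, time_h, score) of a series collection."""
    rows = [
        (s.patient_id, o.time_h, o.score) for s in series for o in s.observations
    ]
    return pd.DataFrame(rows, columns=list(PAIN_COLUMNS))


def baseline_to_frame(records: Sequence[BaselineRecord]) -> pd.DataFrame:
    """DataFrame of baseline records with the canonical column order."""
    return pd.DataFrame(
        [{c: getattr(r, c) for c in BASELINE_COLUMNS} for r in records],
        columns=list(BASELINE_COLUMNS),
    )


def write_cohort(series, records, pain_path, baseline_path) -> None:
    series_to_frame(series).to_csv(pain_path, index=False)
    baseline_to_frame(records).to_csv(baseline_path, index=False)
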