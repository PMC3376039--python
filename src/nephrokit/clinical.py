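"""Clinical computations for the CKD biopsy cohort.

Covers the Japanese serum-creatinine eGFR equation, CKD staging, low-birth-
weight classification, eligibility screening, adjudication of reported
cerebro-cardiovascular events, construction of the composite time-to-event
endpoint (death, renal death, adjudicated cerebro-cardiovascular event, or
50% eGFR reduction from baseline, whichever first) and the annual eGFR
decline rate.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

__all__ = [
    "egfr_japanese",
    "ckd_stage",
    "classify_lbw",
    "check_eligibility",
    "adjudicate_event",
    "composite_endpoint",
    "egfr_slope",
    "PatientBaseline",
    "FollowUpVisit",
    "EventReport",
    "EndpointResult",
    "AdjudicationResult",
    "DAYS_PER_YEAR",
    "LBW_THRESHOLD_G",
    "VISIT_WINDOW_DAYS",
]

DAYS_PER_YEAR = 365.25
LBW_THRESHOLD_G = 2500.0
#: Data recorded within three months of the scheduled (biopsy-anniversary)
#: date is accepted as belonging to that visit.
VISIT_WINDOW_DAYS = int(DAYS_PER_YEAR / 4)

FEMALE_FACTOR = 0.739

#: eGFR lower bounds of CKD stages 1..4 (stage 5 is everything below).
DEFAULT_STAGE_BANDS = (90.0, 60.0, 30.0, 15.0)


def egfr_japanese(age_years: float, sex: str, creatinine_mg_dl: float) -> float:
    """Japanese 3-coefficient eGFR equation, mL/min/1.73 m^2.

    194 * Age^-0.287 * Cre^-1.094, times 0.739 for females.
    """
    if age_years <= 0:
        raise ValueError(f"age must be positive, got {age_years}")
    if creatinine_mg_dl <= 0:
        raise ValueError(f"serum creatinine must be positive, got {creatinine_mg_dl}")
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    egfr = 194.0 * age_years**-0.287 * creatinine_mg_dl**-1.094
    if sex == "female":
        egfr *= FEMALE_FACTOR
    return egfr


def creatinine_from_egfr(egfr: float, age_years: float, sex: str) -> float:
    """Invert the eGFR equation for serum creatinine (used by simulators)."""
    if egfr <= 0:
        raise ValueError("eGFR must be positive")
    base = 194.0 * age_years**-0.287
    if sex == "female":
        base *= FEMALE_FACTOR
    return (egfr / base) ** (-1.0 / 1.094)


def ckd_stage(
    egfr: float,
    kidney_damage_marker: bool,
    bands: Sequence[float] = DEFAULT_STAGE_BANDS,
) -> Optional[int]:
    """CKD stage 1-5 by eGFR bands; stages 1-2 require a damage marker.

    Returns ``None`` when eGFR >= 60 without a kidney-damage marker (no
    CKD by the guideline definition).  Band defaults follow the cited
    guideline (>=90, 60-89, 30-59, 15-29, <15), configurable.
    """
    if egfr < 0:
        raise ValueError(f"eGFR must be >= 0, got {egfr}")
    b1, b2, b3, b4 = bands
    if egfr >= b1:
        return 1 if kidney_damage_marker else None
    if egfr >= b2:
        return 2 if kidney_damage_marker else None
    if egfr >= b3:
        return 3
    if egfr >= b4:
        return 4
    return 5


def classify_lbw(birth_weight) -> str:
    """Classify birth weight: < 2500 g is low, >= 2500 g normal.

    Accepts grams, a categorical answer from the interview fallback
    ("low" | "normal" | "unknown"), or None (unknown).
    """
    if birth_weight is None:
        return "unknown"
    if isinstance(birth_weight, str):
        v = birth_weight.strip().lower()
        if v in ("low", "normal", "unknown"):
            return v
        raise ValueError(f"unknown birth-weight category {birth_weight!r}")
    w = float(birth_weight)
    if math.isnan(w):
        return "unknown"
    if w < 0:
        raise ValueError(f"birth weight must be >= 0, got {w}")
    return "low" if w < LBW_THRESHOLD_G else "normal"


@dataclass(frozen=True)
class EventReport:
    """A reported candidate event with its adjudication criteria.

    ``type``: death | renal_death | mi | angina | stroke.  Criteria maps
    hold the booleans relevant to the type (see :func:`adjudicate_event`).
    """

    type: str
    date: dt.date
    subtype: Optional[str] = None
    criteria: Mapping[str, bool] = field(default_factory=dict)


@dataclass(frozen=True)
class AdjudicationResult:
    accepted: bool
    rule_trace: tuple[str, ...]


class IncompleteReportError(ValueError):
    """An event report lacks the criteria needed for its type."""


def _require(report: EventReport, keys: Sequence[str]) -> list[bool]:
    missing = [k for k in keys if k not in report.criteria]
    if missing:
        raise IncompleteReportError(
            f"{report.type} report is missing criteria: {missing}"
        )
    return [bool(report.criteria[k]) for k in keys]


def adjudicate_event(report: EventReport) -> AdjudicationResult:
    """Apply the protocol's event definitions.

    Myocardial infarction needs at least two of {chest symptoms, ECG
    changes, elevated cardiac enzymes}; angina needs ECG abnormalities AND
    chest symptoms AND need for catheter/surgical treatment; stroke needs
    symptoms lasting over 24 h AND a causative lesion on imaging, and TIA
    or asymptomatic small infarction never counts.  Death and renal death
    are accepted as reported.
    """
    t = report.type
    if t in ("death", "renal_death"):
        return AdjudicationResult(True, (f"{t}: accepted as reported",))
    if t == "mi":
        vals = _require(report, ["chest_symptoms", "ecg_changes", "elevated_enzymes"])
        n = sum(vals)
        return AdjudicationResult(
            n >= 2, (f"mi: {n}/3 criteria met (need >= 2)",)
        )
    if t == "angina":
        vals = _require(
            report, ["ecg_abnormalities", "chest_symptoms", "intervention_needed"]
        )
        return AdjudicationResult(
            all(vals), (f"angina: {sum(vals)}/3 criteria met (need all 3)",)
        )
    if t == "stroke":
        over24, lesion, tia = _require(
            report,
            ["symptoms_over_24h", "lesion_on_imaging", "is_tia_or_asymptomatic"],
        )
        trace = (
            f"stroke: symptoms>24h={over24}, lesion={lesion}, "
            f"tia_or_asymptomatic={tia} (need first two, not TIA/asymptomatic)",
        )
        return AdjudicationResult(over24 and lesion and not tia, trace)
    raise ValueError(f"unknown event type {t!r}")


@dataclass(frozen=True)
class PatientBaseline:
    patient_id: str
    biopsy_date: dt.date
    age_years: float
    sex: str
    serum_creatinine_mg_dl: float
    birth_weight: object = None  # grams, category string or None
    body_weight_kg: Optional[float] = None
    diagnosis: str = ""
    consent: bool = True
    guardian_consent: Optional[bool] = None
    undergoing_biopsy: bool = True
    has_ckd: bool = True
    severe_laterality: bool = False
    cancer_history: bool = False
    years_since_cancer_remission: Optional[float] = None

    @property
    def egfr(self) -> float:
        return egfr_japanese(self.age_years, self.sex, self.serum_creatinine_mg_dl)

    @property
    def lbw_status(self) -> str:
        return classify_lbw(self.birth_weight)


@dataclass(frozen=True)
class FollowUpVisit:
    patient_id: str
    visit_date: dt.date
    serum_creatinine_mg_dl: Optional[float] = None
    body_weight_kg: Optional[float] = None
    urinary_protein: Optional[float] = None
    raas_blocker: Optional[bool] = None
    status: str = "followed"  # followed | lost
    lost_reason: str = ""
    event_reports: tuple[EventReport, ...] = ()


def check_eligibility(baseline: PatientBaseline) -> tuple[bool, list[str]]:
    """Screen one enrolment against all inclusion and exclusion rules.

    Inclusions: CKD by the guideline, undergoing needle biopsy, signed
    consent, age over 14, and guardian consent when under 20.  Exclusions:
    severe laterality in kidney size or function, and cancer history unless
    free from cancer for more than one year before the biopsy.
    """
    reasons: list[str] = []
    if not baseline.has_ckd:
        reasons.append("inclusion: no CKD by guideline criteria")
    if not baseline.undergoing_biopsy:
        reasons.append("inclusion: not undergoing a needle kidney biopsy")
    if not baseline.consent:
        reasons.append("inclusion: consent letter not signed")
    if not baseline.age_years > 14:
        reasons.append("inclusion: age must be over 14 years")
    if baseline.age_years < 20 and not baseline.guardian_consent:
        reasons.append("inclusion: guardian consent required under age 20")
    if baseline.severe_laterality:
        reasons.append("exclusion: severe laterality in kidney size or function")
    if baseline.cancer_history:
        yrs = baseline.years_since_cancer_remission
        if yrs is None or not yrs > 1.0:
            reasons.append(
                "exclusion: cancer history without more than 1 year free of cancer"
            )
    return (not reasons, reasons)


@dataclass(frozen=True)
class EndpointResult:
    patient_id: str
    event_occurred: bool
    event_type: Optional[str]
    time_years: float
    censor_reason: Optional[str]
    baseline_egfr: float
    flags: tuple[str, ...] = ()


def _years_between(start: dt.date, end: dt.date) -> float:
    return (end - start).days / DAYS_PER_YEAR


def composite_endpoint(
    baseline: PatientBaseline,
    visits: Sequence[FollowUpVisit],
    *,
    require_confirmation: bool = False,
) -> EndpointResult:
    """First occurrence of any composite component, or censoring.

    Components: total mortality, renal death (chronic dialysis or
    transplantation), accepted cerebro-cardiovascular events, and the first
    visit at which eGFR has fallen to half the baseline value or below.
    A single sub-50% measurement triggers the endpoint by default; with
    ``require_confirmation`` the fall must persist at the next visit with an
    eGFR value.  Visits must be date-sorted.
    """
    flags: list[str] = []
    base_egfr = baseline.egfr
    visits = sorted(visits, key=lambda v: v.visit_date)

    candidates: list[tuple[float, str]] = []
    for v in visits:
        if v.visit_date < baseline.biopsy_date:
            raise ValueError(
                f"visit {v.visit_date} precedes the biopsy date {baseline.biopsy_date}"
            )
        for rep in v.event_reports:
            if adjudicate_event(rep).accepted:
                candidates.append((_years_between(baseline.biopsy_date, rep.date), rep.type))

    egfr_values = [
        (v, egfr_japanese(baseline.age_years, baseline.sex, v.serum_creatinine_mg_dl))
        for v in visits
        if v.serum_creatinine_mg_dl is not None
    ]
    for i, (v, egfr) in enumerate(egfr_values):
        if egfr <= 0.5 * base_egfr:
            if require_confirmation:
                nxt = egfr_values[i + 1 :]
                if not nxt:
                    flags.append("egfr_reduction_unconfirmed_last_visit")
                    continue
                if nxt[0][1] > 0.5 * base_egfr:
                    continue
            candidates.append(
                (_years_between(baseline.biopsy_date, v.visit_date), "egfr_50_reduction")
            )
            break

    if candidates:
        t, etype = min(candidates)
        return EndpointResult(
            patient_id=baseline.patient_id,
            event_occurred=True,
            event_type=etype,
            time_years=t,
            censor_reason=None,
            baseline_egfr=base_egfr,
            flags=tuple(flags),
        )

    if not visits:
        return EndpointResult(
            patient_id=baseline.patient_id,
            event_occurred=False,
            event_type=None,
            time_years=0.0,
            censor_reason="no_followup",
            baseline_egfr=base_egfr,
            flags=("no_visits",),
        )
    last = visits[-1]
    reason = "lost:" + (last.lost_reason or "unspecified") if last.status == "lost" else "end_of_followup"
    return EndpointResult(
        patient_id=baseline.patient_id,
        event_occurred=False,
        event_type=None,
        time_years=_years_between(baseline.biopsy_date, last.visit_date),
        censor_reason=reason,
        baseline_egfr=base_egfr,
        flags=tuple(flags),
    )


def egfr_slope(
    baseline: PatientBaseline, visits: Sequence[FollowUpVisit]
) -> float:
    """Annual eGFR decline rate: OLS slope of eGFR on years since biopsy.

    Uses the baseline value at time 0 plus every visit with a creatinine
    measurement.  Needs at least two distinct time points.
    """
    times = [0.0]
    values = [baseline.egfr]
    for v in sorted(visits, key=lambda v: v.visit_date):
        if v.serum_creatinine_mg_dl is None:
            continue
        times.append(_years_between(baseline.biopsy_date, v.visit_date))
        values.append(
            egfr_japanese(baseline.age_years, baseline.sex, v.serum_creatinine_mg_dl)
        )
    if len(set(times)) < 2:
        raise ValueError("need eGFR at two or more distinct dates for a slope")
    n = len(times)
    tbar = sum(times) / n
    ybar = sum(values) / n
    sxy = sum((t - tbar) * (y - ybar) for t, y in zip(times, values))
    sxx = sum((t - tbar) ** 2 for t in times)
    return sxy / sxx
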