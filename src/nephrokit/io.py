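"""Readers/writers for the registry and measurement tables, study
configuration, and audit JSON reports.

CSV dialect is pinned: UTF-8, comma separator, ISO-8601 dates, "." decimal.
Validation collects every violation (row and column named) instead of
failing on the first.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import clinical
from .cortex import SliceMeasurement
from .design import DesignSpec
from .stereology import (
    DEFAULT_CUTOFF_DIAMETER_UM,
    DEFAULT_GAUGE_TABLE_MM,
    BiopsySection,
    BiopsySpecimen,
)

__all__ = [
    "StudyConfig",
    "SchemaError",
    "read_sections",
    "read_volumes",
    "read_enrollment",
    "read_followup",
    "write_report",
]

SCHEMA_VERSION = "1"

TOOL_VERSION = "0.1.0"


class SchemaError(ValueError):
    """One or more validation violations; carries them all."""

    def __init__(self, path: str, violations: Sequence[str]):
        self.violations = list(violations)
        super().__init__(
            f"{path}: {len(self.violations)} validation violation(s):\n  "
            + "\n  ".join(self.violations)
        )


@dataclass(frozen=True)
class StudyConfig:
    """All configurable study constants in one serializable place."""

    shrinkage_tissue: float = 0.31
    shrinkage_glomerulus: float = 0.43
    cutoff_diameter_um: float = DEFAULT_CUTOFF_DIAMETER_UM
    cutoff_space: str = "in_vivo"
    gauge_table_mm: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_GAUGE_TABLE_MM)
    )
    stage_bands: tuple[float, ...] = clinical.DEFAULT_STAGE_BANDS
    design: DesignSpec = field(default_factory=DesignSpec)
    schema_version: str = SCHEMA_VERSION

    def to_dict(self) -> dict:
        return {
            "shrinkage_tissue": self.shrinkage_tissue,
            "shrinkage_glomerulus": self.shrinkage_glomerulus,
            "cutoff_diameter_um": self.cutoff_diameter_um,
            "cutoff_space": self.cutoff_space,
            "gauge_table_mm": {str(k): v for k, v in self.gauge_table_mm.items()},
            "stage_bands": list(self.stage_bands),
            "design": dataclasses.asdict(self.design),
            "schema_version": self.schema_version,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyConfig":
        d = dict(d)
        design = d.pop("design", {})
        gauge = d.pop("gauge_table_mm", None)
        kwargs = {}
        if gauge is not None:
            kwargs["gauge_table_mm"] = {int(k): float(v) for k, v in gauge.items()}
        if "stage_bands" in d:
            kwargs["stage_bands"] = tuple(d.pop("stage_bands"))
        kwargs.update(d)
        return cls(design=DesignSpec(**design), **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def content_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode("utf-8")).hexdigest()


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(str(path), [f"missing required columns: {missing}"])
    return df


def _num(
    df: pd.DataFrame, col: str, violations: list, *, minimum=None, required=True
) -> pd.Series:
    def conv(i, v):
        if v == "":
            if required:
                violations.append(f"row {i}, column {col!r}: missing value")
            return None
        try:
            x = float(v)
        except ValueError:
            violations.append(f"row {i}, column {col!r}: not a number: {v!r}")
            return None
        if minimum is not None and x < minimum:
            violations.append(
                f"row {i}, column {col!r}: value {x} below minimum {minimum}"
            )
            return None
        return x

    return pd.Series(
        [conv(i, v) for i, v in zip(df.index, df[col])], index=df.index, dtype=object
    )


def _date(df: pd.DataFrame, col: str, violations: list) -> pd.Series:
    def conv(i, v):
        if v == "":
            violations.append(f"row {i}, column {col!r}: missing date")
            return None
        try:
            return dt.date.fromisoformat(v)
        except ValueError:
            violations.append(f"row {i}, column {col!r}: malformed ISO date: {v!r}")
            return None

    return pd.Series(
        [conv(i, v) for i, v in zip(df.index, df[col])], index=df.index, dtype=object
    )


def _bool(v: str) -> Optional[bool]:
    if v == "":
        return None
    return v.strip().lower() in ("true", "1", "yes", "y")


# ---------------------------------------------------------------- sections

SECTIONS_COLUMNS = [
    "patient_id",
    "section_id",
    "cortex_segment_lengths",
    "n_glomeruli",
    "n_global_sclerosis",
    "needle_gauge",
    "stain",
]


def read_sections(path: str | Path) -> dict[str, BiopsySpecimen]:
    """Read per-section biopsy morphometry into one specimen per patient.

    ``cortex_segment_lengths`` holds semicolon-separated on-slide lengths in
    mm (several segments when medulla splits the cortex).
    """
    df = _read_csv(path, SECTIONS_COLUMNS)
    violations: list[str] = []
    by_patient: dict[str, list[BiopsySection]] = {}
    gauges: dict[str, int] = {}
    for i, row in df.iterrows():
        try:
            lengths = [
                float(x) for x in str(row["cortex_segment_lengths"]).split(";") if x
            ]
            section = BiopsySection(
                cortex_segment_lengths_mm=lengths,
                glomeruli_observed=int(row["n_glomeruli"]),
                glomeruli_global_sclerosis=int(row["n_global_sclerosis"] or 0),
            )
        except (ValueError, TypeError) as exc:
            violations.append(f"row {i}: {exc}")
            continue
        pid = row["patient_id"]
        by_patient.setdefault(pid, []).append(section)
        try:
            gauge = int(row["needle_gauge"])
        except ValueError:
            violations.append(
                f"row {i}, column 'needle_gauge': not an integer: "
                f"{row['needle_gauge']!r}"
            )
            continue
        if pid in gauges and gauges[pid] != gauge:
            violations.append(f"row {i}: inconsistent needle gauge for patient {pid}")
        gauges[pid] = gauge
    if violations:
        raise SchemaError(str(path), violations)
    return {
        pid: BiopsySpecimen(
            sections=secs,
            needle_gauge=gauges[pid],
            stain=df.loc[df["patient_id"] == pid, "stain"].iloc[0] or "PAS",
        )
        for pid, secs in by_patient.items()
    }


# ----------------------------------------------------------------- volumes

VOLUMES_COLUMNS = [
    "patient_id",
    "side",
    "slice_index",
    "kidney_area_cm2",
    "cortex_area_cm2",
    "spacing_cm",
]


def read_volumes(path: str | Path) -> dict[tuple[str, str], list[SliceMeasurement]]:
    """Read per-slice tomographic areas keyed by (patient, side)."""
    df = _read_csv(path, VOLUMES_COLUMNS)
    violations: list[str] = []
    out: dict[tuple[str, str], list[SliceMeasurement]] = {}
    kidney = _num(df, "kidney_area_cm2", violations, minimum=0.0)
    cortex = _num(df, "cortex_area_cm2", violations, minimum=0.0)
    spacing = _num(df, "spacing_cm", violations)
    for i, row in df.iterrows():
        if kidney[i] is None or cortex[i] is None or spacing[i] is None:
            continue
        try:
            m = SliceMeasurement(
                slice_index=int(row["slice_index"]),
                kidney_area_cm2=kidney[i],
                cortex_area_cm2=cortex[i],
                spacing_cm=spacing[i],
            )
        except ValueError as exc:
            violations.append(f"row {i}: {exc}")
            continue
        out.setdefault((row["patient_id"], row["side"]), []).append(m)
    if violations:
        raise SchemaError(str(path), violations)
    return out


# -------------------------------------------------------------- enrollment

ENROLLMENT_REQUIRED = [
    "patient_id",
    "biopsy_date",
    "age",
    "sex",
    "serum_creatinine_mg_dl",
]


def read_enrollment(path: str | Path) -> dict[str, clinical.PatientBaseline]:
    """Read the enrolment registry into baselines keyed by patient id."""
    df = _read_csv(path, ENROLLMENT_REQUIRED)
    violations: list[str] = []
    dates = _date(df, "biopsy_date", violations)
    ages = _num(df, "age", violations, minimum=0.0)
    cre = _num(df, "serum_creatinine_mg_dl", violations, minimum=0.0)
    seen: set[str] = set()
    out: dict[str, clinical.PatientBaseline] = {}
    for i, row in df.iterrows():
        pid = row["patient_id"]
        if pid in seen:
            violations.append(f"row {i}: duplicate patient_id {pid!r}")
            continue
        seen.add(pid)
        if row["sex"] not in ("male", "female"):
            violations.append(f"row {i}, column 'sex': must be male/female")
            continue
        if dates[i] is None or ages[i] is None or cre[i] is None:
            continue
        if cre[i] <= 0:
            violations.append(
                f"row {i}, column 'serum_creatinine_mg_dl': must be positive"
            )
            continue
        bw: object = None
        if "birth_weight_g" in df.columns and row.get("birth_weight_g", "") != "":
            try:
                bw = float(row["birth_weight_g"])
                if bw < 0:
                    violations.append(
                        f"row {i}, column 'birth_weight_g': must be >= 0"
                    )
                    continue
            except ValueError:
                violations.append(f"row {i}, column 'birth_weight_g': not a number")
                continue
        elif (
            "birth_weight_category" in df.columns
            and row.get("birth_weight_category", "") != ""
        ):
            bw = row["birth_weight_category"]
        yrs = None
        if row.get("years_since_cancer_remission", "") not in ("", None):
            yrs = float(row["years_since_cancer_remission"])
        out[pid] = clinical.PatientBaseline(
            patient_id=pid,
            biopsy_date=dates[i],
            age_years=ages[i],
            sex=row["sex"],
            serum_creatinine_mg_dl=cre[i],
            birth_weight=bw,
            body_weight_kg=float(row["body_weight_kg"])
            if row.get("body_weight_kg", "") != ""
            else None,
            diagnosis=row.get("diagnosis", ""),
            consent=_bool(row.get("consent", "true")) is not False,
            guardian_consent=_bool(row.get("guardian_consent", "")),
            severe_laterality=_bool(row.get("severe_laterality", "")) is True,
            cancer_history=_bool(row.get("cancer_history", "")) is True,
            years_since_cancer_remission=yrs,
        )
    if violations:
        raise SchemaError(str(path), violations)
    return out


# ---------------------------------------------------------------- followup

FOLLOWUP_REQUIRED = ["patient_id", "visit_date", "status"]

_CRITERIA_COLS = {
    "mi": ("chest_symptoms", "ecg_changes", "elevated_enzymes"),
    "angina": ("ecg_abnormalities", "chest_symptoms", "intervention_needed"),
    "stroke": ("symptoms_over_24h", "lesion_on_imaging", "is_tia_or_asymptomatic"),
}


@dataclass(frozen=True)
class FollowUpTable:
    visits: dict[str, list[clinical.FollowUpVisit]]
    window_flags: list[str]


def read_followup(
    path: str | Path,
    baselines: Mapping[str, clinical.PatientBaseline] | None = None,
) -> FollowUpTable:
    """Read the annual follow-up registry.

    With baselines supplied, each visit is checked against the +/- 3 month
    window around its biopsy anniversary; off-window visits are accepted
    but flagged.
    """
    df = _read_csv(path, FOLLOWUP_REQUIRED)
    violations: list[str] = []
    flags: list[str] = []
    dates = _date(df, "visit_date", violations)
    out: dict[str, list[clinical.FollowUpVisit]] = {}
    seen: set[tuple[str, str]] = set()
    for i, row in df.iterrows():
        pid = row["patient_id"]
        if dates[i] is None:
            continue
        key = (pid, row["visit_date"])
        if key in seen:
            violations.append(f"row {i}: duplicate visit for {pid} on {row['visit_date']}")
            continue
        seen.add(key)
        cre = None
        if row.get("serum_creatinine_mg_dl", "") != "":
            try:
                cre = float(row["serum_creatinine_mg_dl"])
            except ValueError:
                violations.append(
                    f"row {i}, column 'serum_creatinine_mg_dl': not a number"
                )
                continue
            if cre <= 0:
                violations.append(
                    f"row {i}, column 'serum_creatinine_mg_dl': must be positive"
                )
                continue
        reports = ()
        etype = row.get("event_type", "")
        if etype:
            if etype not in ("death", "renal_death", "mi", "angina", "stroke"):
                violations.append(f"row {i}, column 'event_type': unknown {etype!r}")
                continue
            edate_raw = row.get("event_date", "") or row["visit_date"]
            try:
                edate = dt.date.fromisoformat(edate_raw)
            except ValueError:
                violations.append(f"row {i}, column 'event_date': malformed")
                continue
            criteria = {}
            for crit in _CRITERIA_COLS.get(etype, ()):
                val = _bool(row.get(f"{etype}_{crit}", ""))
                if val is not None:
                    criteria[crit] = val
            reports = (
                clinical.EventReport(
                    type=etype,
                    date=edate,
                    subtype=row.get("event_subtype", "") or None,
                    criteria=criteria,
                ),
            )
        visit = clinical.FollowUpVisit(
            patient_id=pid,
            visit_date=dates[i],
            serum_creatinine_mg_dl=cre,
            body_weight_kg=float(row["body_weight_kg"])
            if row.get("body_weight_kg", "") != ""
            else None,
            urinary_protein=float(row["urinary_protein"])
            if row.get("urinary_protein", "") != ""
            else None,
            raas_blocker=_bool(row.get("raas_blocker", "")),
            status=row["status"] or "followed",
            lost_reason=row.get("lost_reason", ""),
            event_reports=reports,
        )
        out.setdefault(pid, []).append(visit)

    for pid, visits in out.items():
        visits.sort(key=lambda v: v.visit_date)
        if baselines and pid in baselines:
            base = baselines[pid]
            for v in visits:
                if v.event_reports:
                    continue  # event-report rows are not anniversary visits
                days = (v.visit_date - base.biopsy_date).days
                anniversary = round(days / clinical.DAYS_PER_YEAR) * clinical.DAYS_PER_YEAR
                off = abs(days - anniversary)
                if off > clinical.VISIT_WINDOW_DAYS:
                    flags.append(
                        f"{pid} visit {v.visit_date}: outside the 3-month "
                        "anniversary window"
                    )
                elif off > 14:
                    flags.append(
                        f"{pid} visit {v.visit_date}: off-anniversary, accepted "
                        "within the 3-month window"
                    )
    if violations:
        raise SchemaError(str(path), violations)
    return FollowUpTable(visits=out, window_flags=flags)


# ------------------------------------------------------------------ report


def write_report(
    results: Mapping,
    path: str | Path,
    *,
    config: StudyConfig | None = None,
    seed: int | None = None,
    inputs: Mapping | None = None,
) -> None:
    """Write an audit JSON report: inputs echo, config hash, seed, all
    intermediates, tool version.  Byte-stable for identical inputs."""
    config = config or StudyConfig()
    payload = {
        "tool": "nephrokit",
        "version": TOOL_VERSION,
        "schema_version": config.schema_version,
        "config_hash": config.content_hash(),
        "seed": seed,
        "inputs": dict(inputs or {}),
        "results": _jsonable(results),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, sort_keys=True, indent=2)
        fh.write("\n")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        if hasattr(obj, "to_dict"):
            return _jsonable(obj.to_dict())
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (dt.date, dt.datetime)):
        return obj.isoformat()
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj
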