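"""Synthetic kidneys, biopsies, tomography phantoms and cohorts.

Everything here realizes the generative assumptions behind the estimators
so that parameter recovery can be verified against known truth: spherical
glomeruli of a common radius placed homogeneously (Poisson) in a cortex of
known volume, random planar sections with a detection cut-off on observed
profile diameter, forward tissue shrinkage onto the slide, ellipsoid
tomography phantoms with closed-form volumes, and patient cohorts with the
study's assumed statistical structure (two-component birth-weight mixture
calibrated to the LBW prevalence, nephron number linear in birth weight,
exponential event times with group-specific rates, uniform accrual, linear
eGFR decline).  Every generator is deterministic given its seed, and every
synthetic output is accompanied by its truth table and generating
parameters.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import asdict, dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import clinical
from .cortex import SliceMeasurement, VolumeResult
from .design import DesignSpec
from .stereology import (
    BiopsySection,
    BiopsySpecimen,
    GlomerularGeometry,
    ShrinkageModel,
    needle_internal_diameter,
)
from .units import MM_TO_UM, Volume

__all__ = [
    "VirtualKidney",
    "BiopsySample",
    "SimCohortConfig",
    "CohortTables",
    "sample_biopsy",
    "mri_phantom",
    "generate_cohort",
]


@dataclass(frozen=True)
class VirtualKidney:
    """A kidney with known glomerular content for recovery experiments."""

    n_glomeruli_true: float = 7.0e5
    glomerular_radius_um: float = 100.0
    cortex_volume: Volume = field(default_factory=lambda: Volume(100.0, "cm3"))
    sclerotic_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sclerotic_fraction <= 1.0:
            raise ValueError("sclerotic fraction must lie in [0, 1]")
        vf = (
            self.n_glomeruli_true
            * 4.0 / 3.0 * math.pi * self.glomerular_radius_um**3
            / self.cortex_volume.to_um3()
        )
        if vf > 0.2:
            raise ValueError(
                f"implied glomerular volume fraction {vf:.3f} exceeds the "
                "physiological guard of 0.2"
            )


@dataclass(frozen=True)
class BiopsySample:
    """A simulated specimen plus the underlying truth."""

    specimen: BiopsySpecimen
    profile_radii_um: tuple[float, ...]  # in-vivo scale, countable profiles only
    profile_radii_on_slide_um: tuple[float, ...]
    expected_profiles_per_section: float


def sample_biopsy(
    kidney: VirtualKidney,
    needle_gauge: int = 16,
    n_sections: int = 3,
    section_length_mm: float = 10.0,
    *,
    cutoff_diameter_um: float = 5.0,
    shrinkage: ShrinkageModel | None = None,
    gauge_table: Mapping[int, float] | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> BiopsySample:
    """Simulate needle-biopsy sections through a virtual kidney.

    Glomerular centres form a Poisson field with intensity
    n_true / V_cortex; a sphere yields a countable profile iff the section
    plane passes within h = sqrt(r^2 - r_o^2) of its centre, in which case
    the profile radius is sqrt(r^2 - x^2) with x uniform on (-h, h).  The
    expected countable count per section is therefore
    intensity x (L x d_b) x 2h.  The centre field is taken as unbounded
    (equivalently, the simulated cortex block is buffered by at least r on
    every side), matching the estimator's unbiased uniform-sampling
    assumption.  The returned specimen is expressed in on-slide units:
    lengths multiplied by the tissue factor, radii by the glomerular factor.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    shrinkage = shrinkage or ShrinkageModel()
    r = kidney.glomerular_radius_um
    geom = GlomerularGeometry(r=r, r_o=cutoff_diameter_um / 2.0)
    h = geom.h
    d_b_um = needle_internal_diameter(needle_gauge, gauge_table) * MM_TO_UM
    section_length_um = section_length_mm * MM_TO_UM
    if section_length_um <= 0:
        raise ValueError("section length must be positive")
    intensity = kidney.n_glomeruli_true / kidney.cortex_volume.to_um3()
    mean_count = intensity * section_length_um * d_b_um * 2.0 * h

    sections = []
    radii_vivo: list[float] = []
    for _ in range(n_sections):
        count = int(rng.poisson(mean_count))
        x = rng.uniform(-h, h, size=count)
        radii = np.sqrt(r**2 - x**2)
        radii_vivo.extend(radii.tolist())
        n_sclerotic = int(rng.binomial(count, kidney.sclerotic_fraction)) if count else 0
        sections.append(
            BiopsySection(
                cortex_segment_lengths_mm=(
                    section_length_mm * shrinkage.linear_tissue,
                ),
                glomeruli_observed=count,
                glomeruli_global_sclerosis=n_sclerotic,
            )
        )
    radii_slide = [x * shrinkage.linear_glomerulus for x in radii_vivo]
    return BiopsySample(
        specimen=BiopsySpecimen(sections=sections, needle_gauge=needle_gauge),
        profile_radii_um=tuple(radii_vivo),
        profile_radii_on_slide_um=tuple(radii_slide),
        expected_profiles_per_section=mean_count,
    )


def mri_phantom(
    semi_axes_cm: tuple[float, float, float] = (3.0, 2.0, 5.0),
    cortex_shell_fraction: float = 0.5,
    spacing_cm: float = 0.1,
) -> tuple[list[SliceMeasurement], VolumeResult]:
    """Axially sliced ellipsoid phantom with an inner-ellipsoid medulla.

    The organ is an ellipsoid with the given semi-axes; the medulla is a
    concentric ellipsoid scaled by (1 - shell fraction), so the cortex
    (shell) volume is (1 - (1 - shell)^3) of the whole.  Slices are midpoint
    samples of the cross-sectional ellipse areas pi a b (1 - z^2/c^2) at the
    requested spacing (adjusted so an integer number of slices spans the
    organ).  Returns the slice list and the analytic truth.
    """
    a, b, c = semi_axes_cm
    if min(a, b, c) <= 0:
        raise ValueError("semi-axes must be positive")
    if not 0.0 < cortex_shell_fraction < 1.0:
        raise ValueError("shell fraction must lie in (0, 1)")
    if not 0.0 < spacing_cm < 2.0 * c:
        raise ValueError("spacing must lie in (0, 2c)")
    k_inner = 1.0 - cortex_shell_fraction
    n_slices = math.ceil(2.0 * c / spacing_cm)
    dz = 2.0 * c / n_slices
    slices = []
    for k in range(n_slices):
        z = -c + (k + 0.5) * dz
        whole = math.pi * a * b * max(0.0, 1.0 - (z / c) ** 2)
        if abs(z) < k_inner * c:
            inner = (
                math.pi * (k_inner * a) * (k_inner * b)
                * (1.0 - (z / (k_inner * c)) ** 2)
            )
        else:
            inner = 0.0
        slices.append(
            SliceMeasurement(
                slice_index=k,
                kidney_area_cm2=whole,
                cortex_area_cm2=whole - inner,
                spacing_cm=dz,
            )
        )
    whole_true = 4.0 / 3.0 * math.pi * a * b * c
    truth = VolumeResult(
        whole_kidney_cm3=whole_true,
        cortex_cm3=whole_true * (1.0 - k_inner**3),
    )
    return slices, truth


@dataclass(frozen=True)
class SimCohortConfig:
    """Generating parameters of the synthetic cohort.

    Defaults are the study's stated assumptions: LBW prevalence 0.095,
    event rates 0.1 (normal) vs 0.2 (LBW) read as cumulative probabilities
    over the study, 2-year uniform accrual, 3 further years of follow-up,
    10% loss to follow-up.  The birth-weight mixture weight is calibrated so
    that the realized fraction below 2500 g equals the LBW prevalence; the
    nephron-birth-weight link is linear (a correlation is asserted by the
    literature, the functional form is a modelling choice).
    """

    n_patients: int = 600
    lbw_fraction: float = 0.095
    bw_normal_mean_g: float = 3050.0
    bw_normal_sd_g: float = 350.0
    bw_lbw_mean_g: float = 2100.0
    bw_lbw_sd_g: float = 250.0
    nephron_intercept: float = 1.5e5
    nephron_slope_per_g: float = 250.0
    nephron_noise_sd: float = 1.5e5
    event_rate_normal: float = 0.1
    event_rate_lbw: float = 0.2
    event_rate_interpretation: str = "cumulative_probability"
    accrual_years: float = 2.0
    followup_years: float = 3.0
    dropout_fraction: float = 0.10
    egfr_baseline_mean: float = 60.0
    egfr_baseline_sd: float = 15.0
    egfr_slope_base: float = -2.5
    egfr_slope_per_1e5_nephrons: float = 0.8
    egfr_noise_sd: float = 0.0
    study_start: dt.date = dt.date(2011, 1, 1)
    event_type_probs: tuple[float, ...] = (0.25, 0.35, 0.15, 0.10, 0.15)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("need at least one patient")
        for name in ("lbw_fraction", "event_rate_normal", "event_rate_lbw"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        for name in ("bw_normal_sd_g", "bw_lbw_sd_g", "egfr_baseline_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if abs(sum(self.event_type_probs) - 1.0) > 1e-9:
            raise ValueError("event type probabilities must sum to 1")

    def mixture_weight(self) -> float:
        """Mixing weight of the LBW component such that the realized
        P(birth weight < 2500 g) equals ``lbw_fraction`` exactly."""
        p_low = _trunc_normal_cdf_2500(self.bw_lbw_mean_g, self.bw_lbw_sd_g)
        p_norm = _trunc_normal_cdf_2500(self.bw_normal_mean_g, self.bw_normal_sd_g)
        if not p_norm < self.lbw_fraction < p_low:
            raise ValueError(
                "mixture components cannot be calibrated to the LBW fraction"
            )
        return (self.lbw_fraction - p_norm) / (p_low - p_norm)

    def hazards(self) -> tuple[float, float]:
        spec = DesignSpec(
            event_rate_normal=self.event_rate_normal,
            event_rate_lbw=self.event_rate_lbw,
            lbw_fraction=self.lbw_fraction,
            accrual_years=self.accrual_years,
            followup_years=self.followup_years,
            rate_interpretation=self.event_rate_interpretation,
        )
        return spec.hazards()


def _trunc_normal_cdf_2500(mean: float, sd: float) -> float:
    # birth weights are truncated at 0; the truncation mass is negligible but
    # kept for exactness of the calibration
    a = (0.0 - mean) / sd
    return float(
        sps.truncnorm.cdf(clinical.LBW_THRESHOLD_G, a, np.inf, loc=mean, scale=sd)
    )


def _sample_birth_weights(cfg: SimCohortConfig, rng: np.random.Generator) -> np.ndarray:
    w = cfg.mixture_weight()
    is_low_comp = rng.uniform(size=cfg.n_patients) < w
    out = np.empty(cfg.n_patients)
    for mask, mean, sd in (
        (is_low_comp, cfg.bw_lbw_mean_g, cfg.bw_lbw_sd_g),
        (~is_low_comp, cfg.bw_normal_mean_g, cfg.bw_normal_sd_g),
    ):
        n = int(mask.sum())
        if n:
            a = (0.0 - mean) / sd
            out[mask] = sps.truncnorm.rvs(
                a, np.inf, loc=mean, scale=sd, size=n, random_state=rng
            )
    return out


EVENT_TYPES = ("death", "renal_death", "mi", "angina", "stroke")
_EVENT_SUBTYPES = {"renal_death": "hemodialysis", "stroke": "infarction"}
_EVENT_CRITERIA = {
    "mi": {"chest_symptoms": True, "ecg_changes": True, "elevated_enzymes": True},
    "angina": {
        "ecg_abnormalities": True,
        "chest_symptoms": True,
        "intervention_needed": True,
    },
    "stroke": {
        "symptoms_over_24h": True,
        "lesion_on_imaging": True,
        "is_tia_or_asymptomatic": False,
    },
}


@dataclass(frozen=True)
class CohortTables:
    enrollment: pd.DataFrame
    followup: pd.DataFrame
    truth: pd.DataFrame
    config: SimCohortConfig
    seed: Optional[int]

    def metadata(self) -> dict:
        d = asdict(self.config)
        d["study_start"] = self.config.study_start.isoformat()
        return {"generator": "generate_cohort", "seed": self.seed, "config": d}


def generate_cohort(config: SimCohortConfig, seed: int | None = None) -> CohortTables:
    """Draw a synthetic cohort and its truth table.

    Emits enrolment and follow-up tables in the package's CSV schemas plus
    a truth table holding, per patient, the generating quantities and the
    composite-endpoint time computed directly from them (so that endpoint
    construction from the emitted tables can be checked for exact recovery
    in the noiseless case).
    """
    cfg = config
    rng = np.random.default_rng(seed)
    n = cfg.n_patients
    ids = [f"P{i:05d}" for i in range(1, n + 1)]

    age = rng.uniform(20.0, 75.0, n)
    sex = np.where(rng.uniform(size=n) < 0.5, "male", "female")
    bw = _sample_birth_weights(cfg, rng)
    lbw = bw < clinical.LBW_THRESHOLD_G
    nephrons = np.maximum(
        cfg.nephron_intercept
        + cfg.nephron_slope_per_g * bw
        + rng.normal(0.0, cfg.nephron_noise_sd, n),
        5.0e4,
    )

    lam0, lam1 = cfg.hazards()
    hazard = np.where(lbw, lam1, lam0)
    event_time = rng.exponential(1.0 / hazard)
    entry = rng.uniform(0.0, cfg.accrual_years, n)
    max_followup = cfg.accrual_years + cfg.followup_years - entry
    lost = rng.uniform(size=n) < cfg.dropout_fraction
    lost_time = np.where(lost, rng.uniform(0.0, max_followup), np.inf)
    event_kind = rng.choice(len(EVENT_TYPES), size=n, p=cfg.event_type_probs)

    egfr0 = np.clip(
        rng.normal(cfg.egfr_baseline_mean, cfg.egfr_baseline_sd, n), 15.0, None
    )
    slope = cfg.egfr_slope_base + cfg.egfr_slope_per_1e5_nephrons * (
        (nephrons - np.mean(nephrons)) / 1.0e5
    )

    enroll_rows = []
    visit_rows = []
    truth_rows = []
    for i in range(n):
        biopsy_date = cfg.study_start + dt.timedelta(
            days=round(entry[i] * clinical.DAYS_PER_YEAR)
        )
        cre0 = clinical.creatinine_from_egfr(egfr0[i], age[i], sex[i])
        base_egfr = clinical.egfr_japanese(age[i], sex[i], cre0)
        enroll_rows.append(
            {
                "patient_id": ids[i],
                "biopsy_date": biopsy_date.isoformat(),
                "age": round(float(age[i]), 1),
                "sex": sex[i],
                "serum_creatinine_mg_dl": cre0,
                "birth_weight_g": round(float(bw[i])),
                "birth_weight_category": "",
                "body_weight_kg": round(float(rng.normal(62.0, 12.0)), 1),
                "us_major_axis_cm": round(float(rng.normal(10.5, 0.8)), 2),
                "us_minor_axis_cm": round(float(rng.normal(4.8, 0.5)), 2),
                "us_transverse_axis_cm": round(float(rng.normal(5.0, 0.5)), 2),
                "biopsied_side": "left",
                "diagnosis": "CKD",
                "consent": True,
                "guardian_consent": "",
                "severe_laterality": False,
                "cancer_history": False,
                "years_since_cancer_remission": "",
            }
        )

        # calendar of annual visits until loss, event or study end
        horizon = min(max_followup[i], lost_time[i])
        hard_event_t = event_time[i] if event_time[i] <= horizon else np.inf

        egfr_event_t = np.inf
        visit_records = []
        k = 1
        while True:
            visit_date = biopsy_date + dt.timedelta(
                days=round(k * clinical.DAYS_PER_YEAR)
            )
            t_visit = (visit_date - biopsy_date).days / clinical.DAYS_PER_YEAR
            if t_visit > horizon or t_visit >= hard_event_t:
                break
            egfr_t = egfr0[i] + slope[i] * t_visit
            if cfg.egfr_noise_sd > 0:
                egfr_t += rng.normal(0.0, cfg.egfr_noise_sd)
            egfr_t = max(egfr_t, 5.0)
            cre_t = clinical.creatinine_from_egfr(egfr_t, age[i], sex[i])
            visit_records.append((visit_date, t_visit, cre_t))
            if egfr_t <= 0.5 * base_egfr and not np.isfinite(egfr_event_t):
                egfr_event_t = t_visit
                break
            k += 1

        etype = None
        if np.isfinite(hard_event_t) and hard_event_t <= egfr_event_t:
            endpoint_t = hard_event_t
            etype = EVENT_TYPES[event_kind[i]]
        elif np.isfinite(egfr_event_t):
            endpoint_t = egfr_event_t
            etype = "egfr_50_reduction"
        else:
            endpoint_t = min(horizon, max_followup[i])
        event_occurred = etype is not None

        for visit_date, t_visit, cre_t in visit_records:
            visit_rows.append(
                _visit_row(ids[i], visit_date, cre_t, status="followed")
            )
        if event_occurred and etype != "egfr_50_reduction":
            event_date = biopsy_date + dt.timedelta(
                days=round(hard_event_t * clinical.DAYS_PER_YEAR)
            )
            # reported on a visit row strictly after the previous visit
            last_visit = visit_records[-1][0] if visit_records else biopsy_date
            report_date = max(event_date, last_visit + dt.timedelta(days=1))
            endpoint_t = (event_date - biopsy_date).days / clinical.DAYS_PER_YEAR
            visit_rows.append(
                _visit_row(
                    ids[i],
                    report_date,
                    None,
                    status="followed",
                    event_type=etype,
                    event_subtype=_EVENT_SUBTYPES.get(etype, ""),
                    event_date=event_date,
                )
            )
        elif not event_occurred and lost[i] and lost_time[i] < max_followup[i]:
            if visit_records:
                visit_rows[-1]["status"] = "lost"
                visit_rows[-1]["lost_reason"] = "stopped visiting the hospital"
                endpoint_t = visit_records[-1][1]
            else:
                endpoint_t = 0.0
        elif not event_occurred:
            # censored administratively at the last emitted visit
            endpoint_t = visit_records[-1][1] if visit_records else 0.0
        if event_occurred and etype == "egfr_50_reduction":
            endpoint_t = egfr_event_t

        truth_rows.append(
            {
                "patient_id": ids[i],
                "birth_weight_g": float(bw[i]),
                "lbw": bool(lbw[i]),
                "nephron_number": float(nephrons[i]),
                "hazard_per_year": float(hazard[i]),
                "entry_years": float(entry[i]),
                "latent_event_time_years": float(event_time[i]),
                "baseline_egfr": float(base_egfr),
                "egfr_slope_true": float(slope[i]),
                "event": bool(event_occurred),
                "endpoint_type": etype if etype else "",
                "endpoint_time_years": float(endpoint_t),
            }
        )

    enrollment = pd.DataFrame(enroll_rows)
    followup = pd.DataFrame(visit_rows).sort_values(
        ["patient_id", "visit_date"], kind="stable"
    ).reset_index(drop=True)
    truth = pd.DataFrame(truth_rows)
    return CohortTables(
        enrollment=enrollment, followup=followup, truth=truth, config=cfg, seed=seed
    )


def _visit_row(
    patient_id: str,
    visit_date: dt.date,
    creatinine: Optional[float],
    *,
    status: str,
    event_type: str = "",
    event_subtype: str = "",
    event_date: Optional[dt.date] = None,
) -> dict:
    row = {
        "patient_id": patient_id,
        "visit_date": visit_date.isoformat(),
        "serum_creatinine_mg_dl": "" if creatinine is None else creatinine,
        "body_weight_kg": "",
        "urinary_protein": "",
        "raas_blocker": "",
        "status": status,
        "lost_reason": "",
        "event_type": event_type,
        "event_subtype": event_subtype,
        "event_date": event_date.isoformat() if event_date else "",
    }
    for etype, crit in _EVENT_CRITERIA.items():
        for key, default in crit.items():
            row[f"{etype}_{key}"] = default if event_type == etype else ""
    return row
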