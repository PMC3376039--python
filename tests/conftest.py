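import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def shrinkage():
    from nephrokit.stereology import ShrinkageModel

    return ShrinkageModel()


@pytest.fixture
def geometry():
    from nephrokit.stereology import GlomerularGeometry

    return GlomerularGeometry(r=100.0, r_o=2.5)


@pytest.fixture
def study_design():
    """The cohort's stated design parameters."""
    from nephrokit.design import DesignSpec

    return DesignSpec()


@pytest.fixture
def baseline():
    from nephrokit.clinical import PatientBaseline

    return PatientBaseline(
        patient_id="P1",
        biopsy_date=dt.date(2011, 6, 1),
        age_years=50.0,
        sex="male",
        serum_creatinine_mg_dl=1.0,
        birth_weight=3000.0,
    )


@pytest.fixture
def golden_sections_csv(tmp_path):
    path = tmp_path / "sections.csv"
    path.write_text(
        "patient_id,section_id,cortex_segment_lengths,n_glomeruli,"
        "n_global_sclerosis,needle_gauge,stain\n"
        "P1,0,4.2;3.1,6,1,16,PAS\n"
        "P1,1,5.0,1,0,16,PAS\n"
        "P1,2,6.3,7,0,16,PAS\n"
        "P2,0,8.0,12,2,18,PAM-HE\n",
        encoding="utf-8",
    )
    return path


@pytest.fixture
def golden_volumes_csv(tmp_path):
    path = tmp_path / "volumes.csv"
    rows = ["patient_id,side,slice_index,kidney_area_cm2,cortex_area_cm2,spacing_cm"]
    for side in ("left", "right"):
        for k, (kid, cor) in enumerate([(2.0, 1.0), (4.0, 2.0), (4.0, 2.0), (2.0, 1.0)]):
            rows.append(f"P1,{side},{k},{kid},{cor},0.5")
    path.write_text("\n".join(rows) + "\n", encoding="utf-8")
    return path


@pytest.fixture
def golden_enrollment_csv(tmp_path):
    path = tmp_path / "enrollment.csv"
    path.write_text(
        "patient_id,biopsy_date,age,sex,serum_creatinine_mg_dl,birth_weight_g,"
        "consent,severe_laterality,cancer_history\n"
        "P1,2011-06-01,50,male,1.0,3000,true,false,false\n"
        "P2,2011-07-15,34,female,0.8,2300,true,false,false\n",
        encoding="utf-8",
    )
    return path


@pytest.fixture
def golden_followup_csv(tmp_path):
    path = tmp_path / "followup.csv"
    path.write_text(
        "patient_id,visit_date,serum_creatinine_mg_dl,status,event_type,"
        "event_date,mi_chest_symptoms,mi_ecg_changes,mi_elevated_enzymes\n"
        "P1,2012-06-01,1.1,followed,,,,,\n"
        "P1,2013-05-20,2.4,followed,,,,,\n"
        "P2,2012-07-14,0.9,followed,,,,,\n"
        "P2,2013-01-10,,followed,mi,2013-01-05,true,false,true\n",
        encoding="utf-8",
    )
    return path
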