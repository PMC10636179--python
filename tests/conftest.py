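import pandas as pd
import pytest

import cppflow as cf


@pytest.fixture(scope="session")
def catalogue():
    return cf.load_catalogue()


@pytest.fixture()
def cohort_config():
    return cf.CohortConfig(study_year=2018, censor_date=pd.Timestamp("2019-12-31"))


def write_csv(path, header, rows):
    lines = [header] + rows
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture()
def tiny_tables(tmp_path):
    """Three consistent CSVs: two adults, one referral each, one diagnosis."""
    referrals = write_csv(
        tmp_path / "referrals.csv",
        "patient_id,cpp_id,wfs_date,stop_date,stop_code",
        [
            "p1,breast,2018-03-01,2018-04-13,TREATMENT_START",
            "p2,colorectal,2018-05-10,2018-06-20,SUSPICION_REJECTED",
        ],
    )
    cancer = write_csv(
        tmp_path / "cancer.csv",
        "patient_id,diagnosis_date,icd_code,histology_code",
        ["p1,2018-02-19,C50.9,8500/3"],
    )
    patients = write_csv(
        tmp_path / "patients.csv",
        "patient_id,sex,birth_year,death_date",
        ["p1,female,1960,", "p2,male,1950,"],
    )
    return {"referrals": referrals, "cancer": cancer, "patients": patients}


def make_traj(
    cpp_id="colorectal",
    segments=(),
    censor_day=365,
    psd_dx_day=None,
    other_dx_day=None,
    stop_day=None,
    stop_code=None,
    patient_id="p",
    sex=None,
    age_at_wfs=None,
):
    """Hand-built trajectory for tabulation/target tests."""
    return cf.StateTrajectory(
        patient_id=patient_id,
        cpp_id=cpp_id,
        segments=[
            (s, e, x) for s, e, x in segments
        ],
        censor_day=censor_day,
        psd_dx_day=psd_dx_day,
        other_dx_day=other_dx_day,
        stop_day=stop_day,
        stop_code=stop_code,
        sex=sex,
        age_at_wfs=age_at_wfs,
    )
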