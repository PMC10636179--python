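"""Readers, diagnosis grouping, cohort construction and linkage rules."""

import pandas as pd
import pytest

import cppflow as cf
from cppflow.registry import LinkageError, RowError, SchemaError

from conftest import write_csv


class TestReaders:
    def test_valid_file_parses_all_rows(self, tiny_tables):
        refs = cf.read_referrals(tiny_tables["referrals"])
        assert len(refs) == 2
        assert refs["stop_code"].tolist() == ["TREATMENT_START", "SUSPICION_REJECTED"]
        assert refs["wfs_date"].iloc[0] == pd.Timestamp("2018-03-01")

    def test_unknown_stop_code_lists_allowed(self, tmp_path):
        path = write_csv(
            tmp_path / "r.csv",
            "patient_id,cpp_id,wfs_date,stop_date,stop_code",
            ["p1,breast,2018-03-01,2018-04-01,X9"],
        )
        with pytest.raises(RowError, match="TREATMENT_START"):
            cf.read_referrals(path)

    def test_stop_before_wfs_rejected_with_line_number(self, tmp_path):
        path = write_csv(
            tmp_path / "r.csv",
            "patient_id,cpp_id,wfs_date,stop_date,stop_code",
            [
                "p1,breast,2018-03-01,2018-04-01,TREATMENT_START",
                "p2,breast,2018-03-01,2018-02-01,TREATMENT_START",
            ],
        )
        with pytest.raises(RowError, match=r"\[3\]"):
            cf.read_referrals(path)

    def test_missing_column_named_in_error(self, tmp_path):
        path = write_csv(
            tmp_path / "r.csv", "patient_id,cpp_id,wfs_date", ["p1,breast,2018-03-01"]
        )
        with pytest.raises(SchemaError, match="stop_date"):
            cf.read_referrals(path)

    def test_unparseable_date_reports_line(self, tmp_path):
        path = write_csv(
            tmp_path / "r.csv",
            "patient_id,cpp_id,wfs_date,stop_date,stop_code",
            ["p1,breast,not-a-date,,"],
        )
        with pytest.raises(RowError, match="wfs_date"):
            cf.read_referrals(path)

    def test_stop_date_without_code_rejected(self, tmp_path):
        path = write_csv(
            tmp_path / "r.csv",
            "patient_id,cpp_id,wfs_date,stop_date,stop_code",
            ["p1,breast,2018-03-01,2018-04-01,"],
        )
        with pytest.raises(RowError, match="both"):
            cf.read_referrals(path)

    def test_cancer_register_empty_and_multi_tumour(self, tmp_path, catalogue):
        empty = write_csv(
            tmp_path / "c0.csv", "patient_id,diagnosis_date,icd_code,histology_code", []
        )
        assert len(cf.read_cancer_register(empty, catalogue)) == 0
        two = write_csv(
            tmp_path / "c2.csv",
            "patient_id,diagnosis_date,icd_code,histology_code",
            ["p1,2018-02-01,C50.9,8500/3", "p1,2018-06-01,C34.9,8140/3"],
        )
        recs = cf.read_cancer_register(two, catalogue)
        assert len(recs) == 2
        assert recs["patient_id"].nunique() == 1
        assert set(recs["diagnosis_group"]) == {"BREAST", "LUNG"}

    def test_cancer_register_populates_pancreatic_group(self, tmp_path, catalogue):
        path = write_csv(
            tmp_path / "c.csv",
            "patient_id,diagnosis_date,icd_code,histology_code",
            ["p1,2018-02-01,C25.2,8140/3"],
        )
        recs = cf.read_cancer_register(path, catalogue)
        assert recs["diagnosis_group"].iloc[0] == "PANCREATIC"


class TestClassifyDiagnosis:
    @pytest.mark.parametrize(
        "icd,hist,expected",
        [
            ("C25.1", None, "PANCREATIC"),
            ("C25.0", None, "PANCREATIC"),
            ("C25.9", None, "PANCREATIC"),
            ("C25.4", None, "OTHER"),  # endocrine pancreas not in the split
            ("C24.1", None, "HEPATOBILIARY"),
            ("C17.0", None, "HEPATOBILIARY"),
            ("C23.9", None, "HEPATOBILIARY"),
            ("C80.9", None, "CUP"),
            ("C50.4", None, "BREAST"),
            ("C18.2", None, "COLORECTAL"),
            ("C91.1", None, "LYMPHOMA"),
            ("C91.0", None, "ACUTE_LEUKAEMIA"),
            ("D12.6", None, "OTHER"),
            ("C50.9", "8500/0", "OTHER"),  # benign behaviour -> Other
            ("C50.9", "8500/1", "OTHER"),
            ("C50.9", "8500/3", "BREAST"),
        ],
    )
    def test_code_family_assignments(self, catalogue, icd, hist, expected):
        assert cf.classify_diagnosis(icd, hist, catalogue.code_groups) == expected

    def test_total_and_deterministic(self, catalogue):
        for icd in ("C99.9", "Z00", "C7A.1", "C179"):
            g1 = cf.classify_diagnosis(icd, None, catalogue.code_groups)
            g2 = cf.classify_diagnosis(icd, None, catalogue.code_groups)
            assert g1 == g2
            assert isinstance(g1, str)

    def test_empty_code_raises(self, catalogue):
        with pytest.raises(ValueError):
            cf.classify_diagnosis("", None, catalogue.code_groups)


def _patients(rows):
    return pd.DataFrame(
        rows, columns=["patient_id", "sex", "birth_year", "death_date"]
    ).assign(death_date=lambda d: pd.to_datetime(d["death_date"]))


def _referrals(rows):
    df = pd.DataFrame(
        rows, columns=["patient_id", "cpp_id", "wfs_date", "stop_date", "stop_code"]
    )
    df["wfs_date"] = pd.to_datetime(df["wfs_date"])
    df["stop_date"] = pd.to_datetime(df["stop_date"])
    return df


class TestBuildCohort:
    def test_single_adult_retained(self, cohort_config):
        refs = _referrals([("p1", "breast", "2018-03-01", None, None)])
        pats = _patients([("p1", "female", 1960, None)])
        cohort, report = cf.build_cohort(refs, pats, cohort_config)
        assert len(cohort) == 1
        assert report["retained"] == 1

    def test_multi_cpp_patient_excluded_and_counted(self, cohort_config):
        refs = _referrals(
            [
                ("p1", "breast", "2018-03-01", "2018-04-01", "TREATMENT_START"),
                ("p1", "colorectal", "2018-06-01", None, None),
                ("p2", "lung", "2018-03-01", None, None),
            ]
        )
        pats = _patients([("p1", "female", 1960, None), ("p2", "male", 1950, None)])
        cohort, report = cf.build_cohort(refs, pats, cohort_config)
        assert cohort["patient_id"].tolist() == ["p2"]
        assert report["multi_cpp_patients"] == 1
        assert report["multi_cpp_referrals"] == 2
        assert report["multi_cpp_overlapping_patients"] == 0

    def test_overlapping_episodes_counted_separately(self, cohort_config):
        refs = _referrals(
            [
                ("p1", "breast", "2018-03-01", "2018-05-01", "SUSPICION_REJECTED"),
                ("p1", "colorectal", "2018-04-01", None, None),
            ]
        )
        pats = _patients([("p1", "female", 1960, None)])
        _, report = cf.build_cohort(refs, pats, cohort_config)
        assert report["multi_cpp_overlapping_patients"] == 1

    def test_minor_excluded(self, cohort_config):
        refs = _referrals([("p1", "breast", "2018-03-01", None, None)])
        pats = _patients([("p1", "female", 2001, None)])  # 17 at WFS
        cohort, report = cf.build_cohort(refs, pats, cohort_config)
        assert len(cohort) == 0
        assert report["minors"] == 1

    def test_partition_property(self, cohort_config):
        refs = _referrals(
            [
                ("p1", "breast", "2018-03-01", None, None),
                ("p2", "breast", "2017-03-01", None, None),  # wrong year
                ("p3", "breast", "2018-03-01", None, None),  # minor
                ("p4", "breast", "2018-03-01", None, None),
                ("p4", "lung", "2018-07-01", None, None),  # multi
            ]
        )
        pats = _patients(
            [
                ("p1", "female", 1960, None),
                ("p2", "female", 1960, None),
                ("p3", "female", 2002, None),
                ("p4", "male", 1950, None),
            ]
        )
        _, report = cf.build_cohort(refs, pats, cohort_config)
        assert (
            report["retained"]
            + report["wfs_outside_study_year"]
            + report["minors"]
            + report["multi_cpp_referrals"]
            == report["input_referrals"]
        )

    def test_unknown_patient_raises(self, cohort_config):
        refs = _referrals([("ghost", "breast", "2018-03-01", None, None)])
        pats = _patients([("p1", "female", 1960, None)])
        with pytest.raises(LinkageError, match="ghost"):
            cf.build_cohort(refs, pats, cohort_config)


def _cancer(rows):
    df = pd.DataFrame(
        rows, columns=["patient_id", "diagnosis_date", "icd_code", "histology_code"]
    )
    df["diagnosis_date"] = pd.to_datetime(df["diagnosis_date"])
    return df


class TestLinkDiagnoses:
    def _cohort(self, cohort_config, rows, pats=None):
        refs = _referrals(rows)
        pats = pats or _patients(
            [(p, "female", 1960, None) for p in refs["patient_id"].unique()]
        )
        cohort, _ = cf.build_cohort(refs, pats, cohort_config)
        return cohort

    def test_psd_before_wfs_links_and_flags(self, catalogue, cohort_config):
        cohort = self._cohort(
            cohort_config, [("p1", "breast", "2018-03-11", None, None)]
        )
        cancer = cf.registry.attach_diagnosis_groups(
            _cancer([("p1", "2018-03-01", "C50.9", "8500/3")]), catalogue
        )
        linked = cf.link_diagnoses(cohort, cancer, catalogue, cohort_config)
        assert linked["psd_dx_date"].iloc[0] == pd.Timestamp("2018-03-01")
        assert bool(linked["dx_before_wfs"].iloc[0])

    def test_dx_on_wfs_day_counts_on_or_after(self, catalogue, cohort_config):
        cohort = self._cohort(
            cohort_config, [("p1", "breast", "2018-03-11", None, None)]
        )
        cancer = cf.registry.attach_diagnosis_groups(
            _cancer([("p1", "2018-03-11", "C50.9", "8500/3")]), catalogue
        )
        linked = cf.link_diagnoses(cohort, cancer, catalogue, cohort_config)
        assert not bool(linked["dx_before_wfs"].iloc[0])

    def test_no_psd_cpp_links_any_cancer_as_other(self, catalogue, cohort_config):
        cohort = self._cohort(cohort_config, [("p1", "cup", "2018-03-01", None, None)])
        cancer = cf.registry.attach_diagnosis_groups(
            _cancer([("p1", "2018-04-10", "C50.9", "8500/3")]), catalogue
        )
        linked = cf.link_diagnoses(cohort, cancer, catalogue, cohort_config)
        assert pd.isna(linked["psd_dx_date"].iloc[0])
        assert linked["other_dx_date"].iloc[0] == pd.Timestamp("2018-04-10")

    def test_diagnosis_outside_window_not_linked(self, catalogue, cohort_config):
        cohort = self._cohort(
            cohort_config, [("p1", "breast", "2018-01-01", None, None)]
        )
        cancer = cf.registry.attach_diagnosis_groups(
            _cancer(
                [
                    ("p1", "2018-09-08", "C50.9", "8500/3"),  # day 250 > 183
                    ("p1", "2017-10-01", "C50.9", "8500/3"),  # beyond lookback 31
                ]
            ),
            catalogue,
        )
        linked = cf.link_diagnoses(cohort, cancer, catalogue, cohort_config)
        assert pd.isna(linked["psd_dx_date"].iloc[0])

    def test_earliest_diagnosis_wins_order_independent(self, catalogue, cohort_config):
        cohort = self._cohort(
            cohort_config, [("p1", "breast", "2018-03-01", None, None)]
        )
        rows = [
            ("p1", "2018-05-01", "C50.9", "8500/3"),
            ("p1", "2018-03-15", "C50.1", "8500/3"),
        ]
        for order in (rows, rows[::-1]):
            cancer = cf.registry.attach_diagnosis_groups(_cancer(order), catalogue)
            linked = cf.link_diagnoses(cohort, cancer, catalogue, cohort_config)
            assert linked["psd_dx_date"].iloc[0] == pd.Timestamp("2018-03-15")

    def test_prewfs_full_history_flag_extends_lookback(self, catalogue):
        cfg = cf.CohortConfig(
            study_year=2018,
            censor_date=pd.Timestamp("2019-12-31"),
            prewfs_full_history=True,
        )
        cohort = self._cohort(cfg, [("p1", "breast", "2018-06-01", None, None)])
        cancer = cf.registry.attach_diagnosis_groups(
            _cancer([("p1", "2017-10-01", "C50.9", "8500/3")]), catalogue
        )
        linked = cf.link_diagnoses(cohort, cancer, catalogue, cfg)
        assert linked["psd_dx_date"].iloc[0] == pd.Timestamp("2017-10-01")
        assert bool(linked["dx_before_wfs"].iloc[0])
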