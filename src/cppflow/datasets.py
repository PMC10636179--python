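"""Published 2018 summary statistics for worked examples.

Patient-level registry extracts are confidential, but the 2018 evaluation
of the 28 CPPs in a southern Swedish healthcare region published aggregated
target statistics: per diagnosis group, the number of registered diagnoses,
of diagnosed patients and of those investigated through the corresponding
CPP (inclusion target); and per CPP, the lead-time range and the share of
completed investigations within the longest lead time (lead-time target).
These tables are small enough to ship in source and let the target-counting
and rounding logic be exercised against real published numbers.
"""

from __future__ import annotations

import pandas as pd

# diagnosis_group -> (n_diagnoses, n_patients, n_in_cpp), 2018
_INCLUSION_2018 = {
    "BREAST": (1513, 1211, 1111),
    "MELANOMA": (1379, 1291, 953),
    "PROSTATE": (1344, 1344, 665),
    "COLORECTAL": (882, 852, 683),
    "LUNG": (740, 733, 525),
    "UROTHELIAL": (542, 526, 320),
    "LYMPHOMA": (354, 348, 207),
    "HEAD_NECK": (227, 222, 167),
    "OESOPHAGEAL_STOMACH": (193, 193, 174),
    "KIDNEY": (188, 179, 135),
    "PANCREATIC": (169, 169, 116),
    "UTERINE": (164, 164, 139),
    "THYROID": (124, 122, 55),
    "MYELOMA": (109, 109, 63),
    "BRAIN": (90, 90, 70),
    "HEPATOBILIARY": (78, 78, 25),
    "CERVIX": (74, 73, 54),
    "ACUTE_LEUKAEMIA": (72, 72, 24),
    "ABDOMINAL_SARCOMA": (67, 67, 10),
    "LIVER": (61, 61, 40),
    "NEUROENDOCRINE": (51, 51, 4),
    "TESTICULAR": (50, 49, 43),
    "ANAL": (35, 35, 30),
    "PENILE": (34, 34, 13),
    "BONE_SOFT_SARCOMA": (34, 34, 9),
    "VULVAR": (19, 19, 11),
}

# cpp_id -> (lead_time_min, lead_time_max, % of completed investigations
# ending within the longest lead time), 2018
_LEAD_TIME_2018 = {
    "colorectal": (25, 39, 36),
    "urothelial": (22, 43, 22),
    "breast": (28, 28, 47),
    "prostate": (47, 68, 42),
    "melanoma": (33, 57, 95),
    "lung": (30, 44, 30),
    "head_neck": (18, 38, 74),
    "uterine": (25, 39, 64),
    "pancreatic": (22, 36, 44),
    "kidney": (27, 41, 24),
    "lymphoma": (18, 26, 55),
    "cup": (24, 35, 85),
    "oesophageal_stomach": (24, 38, 36),
    "brain": (37, 97, 97),
    "bone_soft_sarcoma": (28, 39, 81),
    "testicular": (31, 38, 51),
    "thyroid": (31, 31, 36),
    "cervix": (11, 25, 19),
    "liver": (22, 55, 41),
    "myeloma": (15, 20, 73),
    "hepatobiliary": (22, 36, 49),
    "anal": (32, 46, 25),
    "penile": (17, 31, 44),
    "vulvar": (20, 34, 60),
    "acute_leukaemia": (9, 9, 97),
    "abdominal_sarcoma": (28, 39, 25),
    "neuroendocrine": (35, 56, 50),
}


def regional_2018_inclusion() -> pd.DataFrame:
    """Published 2018 per-group inclusion counts (26 PSD groups).

    Columns: ``n_diagnoses``, ``n_patients``, ``n_in_cpp``; indexed by
    diagnosis group.  Feed to
    :func:`cppflow.targets.inclusion_target_from_counts` to recompute the
    inclusion-target proportions and met flags.
    """
    df = pd.DataFrame.from_dict(
        _INCLUSION_2018,
        orient="index",
        columns=["n_diagnoses", "n_patients", "n_in_cpp"],
    )
    df.index.name = "diagnosis_group"
    return df


def regional_2018_lead_time() -> pd.DataFrame:
    """Published 2018 per-CPP lead-time ranges and within-lead-time shares.

    Covers the 27 CPPs with specified lead times (the nonspecific-symptoms
    pathway has none).  Columns: ``lead_time_min_days``,
    ``lead_time_used_days`` (the longest, used for the conservative target
    evaluation), ``proportion_within_pct``.
    """
    df = pd.DataFrame.from_dict(
        _LEAD_TIME_2018,
        orient="index",
        columns=["lead_time_min_days", "lead_time_used_days", "proportion_within_pct"],
    )
    df.index.name = "cpp_id"
    return df
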