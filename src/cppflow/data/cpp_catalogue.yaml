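# Catalogue of the 28 standardized cancer patient pathways (CPPs) analysed
# for Swedish regional data, 2018.  Lead times are the published
# recommended ranges in days (modality-dependent; target evaluation uses the
# maximum).  Two pathways (nonspecific symptoms, CUP) have no primarily
# suspected diagnosis (PSD), giving 26 PSD groups.
#
# Code rules: only the pancreatic / hepatobiliary split (C25.0-3, C25.8-9 vs
# C17.0, C23.9, C24*) and the CUP rule (C80.9) are fixed registry coding
# conventions; the remaining ICD prefix maps are editable defaults and should
# be reviewed against local coding practice.  Filter-function flags are set
# for the pathways with a documented filter step (mammography for breast,
# computed tomography for kidney, ultrasound + fine-needle biopsy for
# thyroid); the rest default to false and are user-editable.
cpps:
  - {cpp_id: colorectal, name: Colorectal cancer, has_psd: true, psd_group: COLORECTAL, has_filter_function: false, lead_time_min_days: 25, lead_time_max_days: 39}
  - {cpp_id: urothelial, name: Urothelial cancer, has_psd: true, psd_group: UROTHELIAL, has_filter_function: false, lead_time_min_days: 22, lead_time_max_days: 43}
  - {cpp_id: breast, name: Breast cancer, has_psd: true, psd_group: BREAST, has_filter_function: true, lead_time_min_days: 28, lead_time_max_days: 28}
  - {cpp_id: prostate, name: Prostate cancer, has_psd: true, psd_group: PROSTATE, has_filter_function: false, lead_time_min_days: 47, lead_time_max_days: 68}
  - {cpp_id: melanoma, name: Melanoma, has_psd: true, psd_group: MELANOMA, has_filter_function: false, lead_time_min_days: 33, lead_time_max_days: 57}
  - {cpp_id: lung, name: Lung cancer, has_psd: true, psd_group: LUNG, has_filter_function: false, lead_time_min_days: 30, lead_time_max_days: 44}
  - {cpp_id: head_neck, name: Head and neck cancer, has_psd: true, psd_group: HEAD_NECK, has_filter_function: false, lead_time_min_days: 18, lead_time_max_days: 38}
  - {cpp_id: uterine, name: Uterine cancer, has_psd: true, psd_group: UTERINE, has_filter_function: false, lead_time_min_days: 25, lead_time_max_days: 39}
  - {cpp_id: nonspecific, name: Nonspecific symptoms possibly indicative of cancer, has_psd: false, psd_group: null, has_filter_function: false, lead_time_min_days: null, lead_time_max_days: null}
  - {cpp_id: pancreatic, name: Pancreatic cancer, has_psd: true, psd_group: PANCREATIC, has_filter_function: false, lead_time_min_days: 22, lead_time_max_days: 36}
  - {cpp_id: kidney, name: Kidney cancer, has_psd: true, psd_group: KIDNEY, has_filter_function: true, lead_time_min_days: 27, lead_time_max_days: 41}
  - {cpp_id: lymphoma, name: Malignant lymphoma and chronic lymphocytic leukaemia, has_psd: true, psd_group: LYMPHOMA, has_filter_function: false, lead_time_min_days: 18, lead_time_max_days: 26}
  - {cpp_id: cup, name: Cancer with unknown primary tumour, has_psd: false, psd_group: null, has_filter_function: false, lead_time_min_days: 24, lead_time_max_days: 35}
  - {cpp_id: oesophageal_stomach, name: Oesophageal and stomach cancer, has_psd: true, psd_group: OESOPHAGEAL_STOMACH, has_filter_function: false, lead_time_min_days: 24, lead_time_max_days: 38}
  - {cpp_id: brain, name: Brain tumour, has_psd: true, psd_group: BRAIN, has_filter_function: false, lead_time_min_days: 37, lead_time_max_days: 97}
  - {cpp_id: bone_soft_sarcoma, name: Bone and soft tissue sarcoma, has_psd: true, psd_group: BONE_SOFT_SARCOMA, has_filter_function: false, lead_time_min_days: 28, lead_time_max_days: 39}
  - {cpp_id: testicular, name: Testicular cancer, has_psd: true, psd_group: TESTICULAR, has_filter_function: false, lead_time_min_days: 31, lead_time_max_days: 38}
  - {cpp_id: thyroid, name: Thyroid cancer, has_psd: true, psd_group: THYROID, has_filter_function: true, lead_time_min_days: 31, lead_time_max_days: 31}
  - {cpp_id: cervix, name: Cervical cancer, has_psd: true, psd_group: CERVIX, has_filter_function: false, lead_time_min_days: 11, lead_time_max_days: 25}
  - {cpp_id: liver, name: Liver cancer, has_psd: true, psd_group: LIVER, has_filter_function: false, lead_time_min_days: 22, lead_time_max_days: 55}
  - {cpp_id: myeloma, name: Myeloma, has_psd: true, psd_group: MYELOMA, has_filter_function: false, lead_time_min_days: 15, lead_time_max_days: 20}
  - {cpp_id: hepatobiliary, name: Hepatobiliary cancer, has_psd: true, psd_group: HEPATOBILIARY, has_filter_function: false, lead_time_min_days: 22, lead_time_max_days: 36}
  - {cpp_id: anal, name: Anal cancer, has_psd: true, psd_group: ANAL, has_filter_function: false, lead_time_min_days: 32, lead_time_max_days: 46}
  - {cpp_id: penile, name: Penile cancer, has_psd: true, psd_group: PENILE, has_filter_function: false, lead_time_min_days: 17, lead_time_max_days: 31}
  - {cpp_id: vulvar, name: Vulvar cancer, has_psd: true, psd_group: VULVAR, has_filter_function: false, lead_time_min_days: 20, lead_time_max_days: 34}
  - {cpp_id: acute_leukaemia, name: Acute leukaemia, has_psd: true, psd_group: ACUTE_LEUKAEMIA, has_filter_function: false, lead_time_min_days: 9, lead_time_max_days: 9}
  - {cpp_id: abdominal_sarcoma, name: Abdominal and gynaecological sarcoma, has_psd: true, psd_group: ABDOMINAL_SARCOMA, has_filter_function: false, lead_time_min_days: 28, lead_time_max_days: 39}
  - {cpp_id: neuroendocrine, name: Neuroendocrine tumours, has_psd: true, psd_group: NEUROENDOCRINE, has_filter_function: false, lead_time_min_days: 35, lead_time_max_days: 56}

code_groups:
  PANCREATIC:
    exact: [C25.0, C25.1, C25.2, C25.3, C25.8, C25.9]
  HEPATOBILIARY:
    exact: [C17.0, C23.9]
    prefixes: [C24]
  CUP:
    exact: [C80.9]
  COLORECTAL:
    prefixes: [C18, C19, C20]
  UROTHELIAL:
    prefixes: [C65, C66, C67, C68]
  BREAST:
    prefixes: [C50]
  PROSTATE:
    prefixes: [C61]
  MELANOMA:
    prefixes: [C43]
  LUNG:
    prefixes: [C33, C34]
  HEAD_NECK:
    prefixes: [C00, C01, C02, C03, C04, C05, C06, C07, C08, C09, C10, C11, C12, C13, C14, C30, C31, C32]
  UTERINE:
    prefixes: [C54, C55]
  KIDNEY:
    prefixes: [C64]
  LYMPHOMA:
    exact: [C91.1]
    prefixes: [C81, C82, C83, C84, C85, C86]
  OESOPHAGEAL_STOMACH:
    prefixes: [C15, C16]
  BRAIN:
    prefixes: [C70, C71, C72]
  BONE_SOFT_SARCOMA:
    prefixes: [C40, C41, C49]
  TESTICULAR:
    prefixes: [C62]
  THYROID:
    prefixes: [C73]
  CERVIX:
    prefixes: [C53]
  LIVER:
    prefixes: [C22]
  MYELOMA:
    prefixes: [C90]
  ANAL:
    prefixes: [C21]
  PENILE:
    prefixes: [C60]
  VULVAR:
    prefixes: [C51]
  ACUTE_LEUKAEMIA:
    exact: [C91.0, C92.0, C92.4, C92.5, C95.0]
  ABDOMINAL_SARCOMA:
    prefixes: [C48]
  NEUROENDOCRINE:
    prefixes: [C7A]
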