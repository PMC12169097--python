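"""Published reference-cohort tables used as worked-example inputs.

Data from a published cohort of 20 HCV-cirrhotic patients whose explanted
livers were biopsied in five predefined segments at transplantation:
per-patient demographics/clinical values, and per-patient intra-liver
sampling-variability results (mean phenotypic fibrosis composite score
Ph-FCS, its five-biopsy CoV, and the CPA CoV measured on the same
biopsies).  These printed per-patient values let the cohort-summary and
CoV machinery be exercised — and its statistical conventions verified —
against an independent published analysis.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["demographics_table", "sampling_variability_table"]

_DEMOGRAPHICS = [
    # case, age, sex, meld, svr, liver_weight_g, platelets_1e9_per_l,
    # bilirubin_mg_dl, albumin_g_dl, hcc
    (1, 53, "M", 9, True, 2014, 111, 0.2, 3.9, True),
    (2, 62, "M", 42, False, 1480, 61, 31.0, 2.8, False),
    (3, 56, "F", 15, False, 1118, 86, 3.1, 3.6, True),
    (4, 54, "M", 13, False, 1027, 52, 2.2, 2.8, True),
    (5, 74, "F", 33, False, 656, 82, 7.3, 3.3, True),
    (6, 71, "M", 32, False, 835, 92, 15.4, 4.0, False),
    (7, 61, "M", 12, True, 1141, 73, 2.7, 4.0, True),
    (8, 62, "M", 17, False, 1885, 97, 0.5, 3.1, True),
    (9, 62, "M", 36, False, 968, 21, 7.5, 3.9, True),
    (10, 68, "M", 40, False, 1075, 28, 3.3, 4.6, False),
    (11, 62, "F", 11, True, 1600, 146, 1.7, 3.9, True),
    (12, 64, "M", 17, False, 1111, 94, 2.6, 2.4, True),
    (13, 69, "M", 7, False, 1260, 112, 0.5, 4.0, True),
    (14, 62, "F", 14, False, 612, 61, 2.2, 2.4, False),
    (15, 48, "M", 23, False, 890, 42, 4.3, 2.7, True),
    (16, 58, "M", 30, False, 1258, 98, 0.6, 3.3, True),
    (17, 59, "M", 39, False, 1289, 31, 13.2, 3.6, False),
    (18, 63, "M", 18, False, 848, 77, 4.3, 2.8, True),
    (19, 66, "M", 23, False, 1160, 58, 5.5, 2.4, True),
    (20, 61, "M", 12, False, 1378, 59, 1.5, 3.1, True),
]

_SAMPLING = [
    # patient_id, phfcs_mean, phfcs_cov_percent, cpa_cov_percent
    ("001", 5.0, 19.0, 32.4),
    ("002", 5.4, 9.2, 27.1),
    ("003", 6.0, 22.9, 55.7),
    ("004", 7.0, 20.5, 32.4),
    ("005", 7.8, 21.1, 44.1),
    ("006", 8.5, 16.3, 44.8),
    ("007", 7.9, 8.6, 42.8),
    ("008", 7.4, 22.5, 64.7),
    ("009", 6.8, 23.8, 42.5),
    ("010", 6.3, 22.0, 54.8),
    ("011", 6.7, 9.7, 28.3),
    ("012", 6.7, 12.7, 36.3),
    ("013", 7.1, 23.8, 47.7),
    ("014", 6.8, 10.7, 21.0),
    ("015", 6.8, 12.3, 31.7),
    ("016", 6.1, 18.3, 67.6),
    ("017", 6.1, 14.0, 45.6),
    ("018", 5.6, 13.6, 35.5),
    ("019", 6.1, 8.4, 36.8),
    ("020", 6.4, 24.1, 36.1),
]


def demographics_table() -> pd.DataFrame:
    """Per-patient demographic and clinical data of the reference cohort."""
    return pd.DataFrame(
        _DEMOGRAPHICS,
        columns=[
            "case",
            "age",
            "sex",
            "meld",
            "svr",
            "liver_weight_g",
            "platelets_1e9_per_l",
            "bilirubin_mg_dl",
            "albumin_g_dl",
            "hcc",
        ],
    ).set_index("case")


def sampling_variability_table() -> pd.DataFrame:
    """Per-patient intra-liver sampling variability of the reference cohort.

    Columns: ``phfcs_mean`` (five-biopsy mean composite score),
    ``phfcs_cov_percent`` and ``cpa_cov_percent`` (five-biopsy CoV of the
    composite score and of CPA, percent).
    """
    return pd.DataFrame(
        _SAMPLING,
        columns=["patient_id", "phfcs_mean", "phfcs_cov_percent", "cpa_cov_percent"],
    ).set_index("patient_id")
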