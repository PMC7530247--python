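"""Default two-cluster effect profiles and clinical models.

These constants parameterize the cohort generator.  The per-channel MMN
amplitude profiles, 6-month change profiles, and delta-band
AverageDifference profiles are the published per-cluster means and
pooled SDs over the 24 frontocentral sites for each clustering design;
the clinical models are the corresponding per-cluster means/SDs of the
demographic, cognitive, functioning, and symptom variables, and the
cohort model the three-group (controls / baseline patients / follow-up
patients) description.  Using them as generator defaults makes the
synthetic cohorts reproduce the effect scales the analysis is meant to
resolve.

Site order is the canonical 24-site list.  AverageDifference profiles
are stored in units of 1e5 μV²·samples (the scale the index reaches on
real recordings); the generator converts as needed.
"""

from __future__ import annotations

import numpy as np

from ..montage import FRONTOCENTRAL_24

# ---------------------------------------------------------------------------
# MMN amplitude profiles (μV): per design, (cluster1 mean, cluster2 mean, SD)
# designs: "HC+baselineFEP" (n 16/37), "HC+followupFEP" (40/11),
#          "baselineFEP+followupFEP" (27/11)
# ---------------------------------------------------------------------------

_MMN_ROWS = {
    #        HC+baseline          HC+followup          baseline+followup
    "AFz": ((-3.71, -1.48, 1.1), (-2.57, 0.22, 1.3), (-2.26, 0.09, 1.5)),
    "AF3": ((-3.36, -1.36, 1.3), (-2.57, 0.47, 1.2), (-2.19, 0.34, 1.2)),
    "AF4": ((-3.69, -1.51, 1.2), (-2.66, 0.26, 1.3), (-2.40, 0.07, 1.2)),
    "Fz":  ((-3.51, -1.44, 0.8), (-2.42, -0.27, 1.0), (-2.35, -0.32, 0.9)),
    "F1":  ((-3.51, -1.50, 0.8), (-2.50, -0.25, 1.0), (-2.38, -0.18, 0.8)),
    "F2":  ((-3.49, -1.56, 0.9), (-2.51, -0.14, 1.0), (-2.48, -0.13, 0.8)),
    "F3":  ((-3.43, -1.58, 0.9), (-2.58, -0.20, 1.0), (-2.41, -0.05, 1.0)),
    "F4":  ((-3.53, -1.39, 0.9), (-2.56, -0.17, 1.1), (-2.36, -0.19, 0.8)),
    "F5":  ((-2.95, -1.35, 1.2), (-2.24, 0.06, 1.0), (-2.14, 0.14, 1.2)),
    "F6":  ((-3.07, -1.40, 0.9), (-2.39, 0.03, 1.0), (-2.30, -0.13, 1.0)),
    "FCz": ((-3.28, -1.45, 0.8), (-2.31, -0.17, 0.9), (-2.42, -0.32, 0.6)),
    "FC1": ((-3.44, -1.47, 0.9), (-2.43, -0.19, 1.0), (-2.45, -0.39, 0.7)),
    "FC2": ((-3.41, -1.42, 0.8), (-2.37, -0.12, 1.0), (-2.40, -0.28, 0.5)),
    "FC3": ((-3.04, -1.39, 0.7), (-2.17, -0.41, 0.9), (-2.27, -0.31, 0.7)),
    "FC4": ((-3.27, -1.37, 0.8), (-2.35, 0.07, 1.0), (-2.36, -0.36, 0.5)),
    "FC5": ((-2.68, -1.28, 0.9), (-1.94, -0.31, 0.9), (-2.03, -0.16, 0.9)),
    "FC6": ((-3.00, -1.25, 0.9), (-2.16, -0.19, 1.0), (-2.10, -0.22, 0.4)),
    "Cz":  ((-2.84, -1.17, 0.8), (-1.95, -0.07, 1.0), (-2.10, -0.35, 0.5)),
    "C1":  ((-2.91, -1.13, 0.8), (-1.97, -0.29, 1.0), (-2.03, -0.38, 0.5)),
    "C2":  ((-2.80, -1.22, 0.7), (-1.98, -0.10, 1.0), (-2.17, -0.38, 0.6)),
    "C3":  ((-2.73, -1.21, 0.9), (-1.95, -0.37, 1.0), (-2.02, -0.41, 0.7)),
    "C4":  ((-2.81, -1.09, 0.6), (-1.96, 0.02, 1.0), (-2.07, -0.21, 0.6)),
    "C5":  ((-2.28, -1.09, 0.8), (-1.67, -0.36, 0.9), (-1.70, -0.28, 0.7)),
    "C6":  ((-2.34, -1.00, 0.7), (-1.64, 0.09, 1.0), (-1.80, -0.20, 0.6)),
}

# MMN 6-month change profile (μV): (improved mean, worsened mean, SD), n 10/8
_CHANGE_ROWS = {
    "AFz": (-0.79, 2.34, 1.8), "AF3": (-1.06, 1.80, 1.2),
    "AF4": (-0.81, 2.09, 1.7), "Fz": (-0.65, 1.39, 1.6),
    "F1": (-0.87, 1.62, 1.4), "F2": (-0.69, 1.65, 1.3),
    "F3": (-0.84, 1.54, 1.3), "F4": (-1.27, 1.45, 1.1),
    "F5": (-0.74, 1.53, 1.6), "F6": (-1.31, 1.79, 1.1),
    "FCz": (-0.48, 1.38, 1.2), "FC1": (-0.55, 1.33, 1.2),
    "FC2": (-0.52, 1.39, 1.2), "FC3": (-0.42, 1.13, 1.2),
    "FC4": (-0.47, 1.29, 0.8), "FC5": (-0.25, 1.05, 1.3),
    "FC6": (-0.87, 1.21, 0.8), "Cz": (-0.39, 1.10, 0.9),
    "C1": (-0.63, 1.00, 0.9), "C2": (-0.40, 0.99, 0.8),
    "C3": (-0.50, 0.95, 1.0), "C4": (-0.53, 1.04, 0.8),
    "C5": (-0.37, 0.73, 1.1), "C6": (-0.41, 1.15, 0.6),
}

# Delta-band AverageDifference profiles (units of 1e5 μV²·samples):
# (higher cluster mean, lower cluster mean, SD) per design,
# designs as above with n 29/22, 24/23, 10/26
_AVGDIFF_ROWS = {
    "AFz": ((3.2, -6.4, 3.9), (3.3, -6.0, 3.6), (5.5, -3.5, 3.1)),
    "AF3": ((3.4, -5.7, 3.8), (3.6, -5.5, 3.4), (6.0, -3.2, 2.3)),
    "AF4": ((3.3, -6.2, 4.5), (3.8, -6.3, 4.0), (5.6, -3.6, 4.1)),
    "Fz":  ((1.8, -3.2, 2.0), (2.0, -3.1, 1.9), (2.7, -1.6, 1.4)),
    "F1":  ((2.2, -3.2, 2.2), (1.9, -3.2, 1.6), (2.7, -1.2, 1.4)),
    "F2":  ((1.6, -3.1, 2.3), (2.0, -3.0, 1.8), (2.8, -1.9, 1.6)),
    "F3":  ((1.6, -3.3, 2.3), (1.9, -3.1, 1.7), (2.9, -1.7, 1.3)),
    "F4":  ((2.9, -2.9, 5.9), (1.9, -3.0, 1.9), (3.0, -0.04, 1.9)),
    "F5":  ((1.6, -3.9, 2.8), (2.2, -3.6, 2.7), (3.4, -1.6, 2.5)),
    "F6":  ((1.9, -4.5, 3.2), (1.7, -4.7, 3.3), (3.5, -2.1, 3.6)),
    "FCz": ((1.1, -2.0, 1.5), (1.3, -2.1, 1.4), (1.4, -0.9, 0.8)),
    "FC1": ((1.4, -1.9, 1.6), (1.4, -1.8, 1.6), (1.5, -0.9, 0.7)),
    "FC2": ((1.0, -1.8, 1.6), (1.2, -1.8, 1.4), (1.6, -1.1, 0.8)),
    "FC3": ((0.9, -2.2, 1.6), (1.2, -2.1, 1.3), (1.3, -0.8, 1.3)),
    "FC4": ((2.9, -1.5, 9.9), (3.4, -1.6, 11.0), (1.7, -1.1, 0.9)),
    "FC5": ((0.9, -2.6, 2.4), (1.1, -2.4, 1.5), (1.3, -0.6, 1.6)),
    "FC6": ((0.9, -1.6, 1.9), (1.0, -1.8, 1.5), (1.6, -1.3, 1.6)),
    "Cz":  ((0.7, -1.3, 1.6), (0.8, -1.5, 1.6), (0.9, -0.7, 0.5)),
    "C1":  ((1.0, -1.1, 1.9), (1.2, -1.3, 1.9), (0.9, -0.6, 0.4)),
    "C2":  ((0.7, -1.1, 1.5), (0.8, -1.3, 1.3), (1.0, -0.6, 0.5)),
    "C3":  ((0.6, -1.2, 1.3), (0.8, -1.2, 1.1), (0.7, -0.5, 0.5)),
    "C4":  ((0.6, -0.9, 1.8), (0.8, -1.1, 1.3), (1.2, -0.9, 0.6)),
    "C5":  ((0.6, -1.5, 1.4), (0.9, -1.5, 1.0), (0.6, -0.5, 0.7)),
    "C6":  ((0.6, -0.8, 1.3), (0.6, -1.0, 1.1), (0.9, -0.6, 0.9)),
}

_DESIGN_COL = {"HC+baselineFEP": 0, "HC+followupFEP": 1,
               "baselineFEP+followupFEP": 2}


def _unpack(rows: dict, col: int | None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    c1, c2, sd = [], [], []
    for site in FRONTOCENTRAL_24:
        entry = rows[site] if col is None else rows[site][col]
        c1.append(entry[0])
        c2.append(entry[1])
        sd.append(entry[2])
    return np.array(c1), np.array(c2), np.array(sd)


def mmn_profile(design: str = "HC+baselineFEP"):
    """(cluster1 means, cluster2 means, SDs) of MMN amplitude, μV."""
    return _unpack(_MMN_ROWS, _DESIGN_COL[design])


def change_profile():
    """(improved means, worsened means, SDs) of 6-month MMN change, μV."""
    return _unpack(_CHANGE_ROWS, None)


def avgdiff_profile(design: str = "HC+baselineFEP", scale: float = 1e5):
    """(higher means, lower means, SDs) of delta AverageDifference.

    Stored in 1e5 units; ``scale`` converts to raw μV²·samples.
    """
    c1, c2, sd = _unpack(_AVGDIFF_ROWS, _DESIGN_COL[design])
    return c1 * scale, c2 * scale, sd * scale

#: published cluster sizes per design, (n cluster1, n cluster2)
CLUSTER_SIZES_MMN = {"HC+baselineFEP": (16, 37), "HC+followupFEP": (40, 11),
                     "baselineFEP+followupFEP": (27, 11)}
CLUSTER_SIZES_CHANGE = (10, 8)
CLUSTER_SIZES_AVGDIFF = {"HC+baselineFEP": (29, 22), "HC+followupFEP": (24, 23),
                         "baselineFEP+followupFEP": (10, 26)}

# ---------------------------------------------------------------------------
# clinical models: variable -> {cluster: (mean, sd)}; proportions for
# categorical variables are variable -> {cluster: proportion}
# ---------------------------------------------------------------------------

#: mixed HC/patient clustering run (both-cluster profile, HC+baseline design)
CLINICAL_MODEL_MIXED = {
    "age": {1: (24.44, 4.6), 2: (22.14, 4.6)},
    "education_years": {1: (16.31, 1.8), 2: (14.89, 1.8)},
    "UPSA": {1: (80.99, 9.8), 2: (82.59, 9.8)},
    "MCAS": {1: (52.21, 4.3), 2: (51.88, 4.3)},
    "MCAS_independent": {1: (9.75, 0.8), 2: (9.31, 0.8)},
    "MCAS_social": {1: (18.94, 2.0), 2: (18.83, 2.0)},
    "MATRICS_social": {1: (54.50, 8.7), 2: (54.03, 8.7)},
    "MATRICS_composite": {1: (50.30, 5.1), 2: (48.27, 5.1)},
    "TASIT": {1: (55.25, 6.0), 2: (54.87, 6.0)},
}
CATEGORICAL_MODEL_MIXED = {
    "patient": {1: 0.3125, 2: 0.4054},
    "female": {1: 0.375, 2: 0.3514},
}

#: patients-only 6-month-change clustering run (follow-up measures)
CLINICAL_MODEL_CHANGE = {
    "age": {1: (23.40, 3.5), 2: (23.38, 3.5)},
    "education_years": {1: (14.90, 1.8), 2: (15.25, 1.8)},
    "UPSA": {1: (88.23, 14.6), 2: (75.19, 14.6)},
    "MCAS": {1: (49.33, 5.7), 2: (46.50, 5.7)},
    "MCAS_independent": {1: (8.00, 1.5), 2: (6.50, 1.5)},
    "MCAS_social": {1: (17.67, 2.1), 2: (16.67, 2.1)},
    "MATRICS_social": {1: (59.00, 16.1), 2: (51.14, 16.1)},
    "MATRICS_composite": {1: (50.00, 10.6), 2: (46.81, 10.6)},
    "TASIT": {1: (55.89, 5.7), 2: (52.83, 5.7)},
    "PANSS_positive": {1: (12.00, 5.3), 2: (14.50, 5.3)},
    "PANSS_negative": {1: (10.33, 3.7), 2: (10.50, 3.7)},
    "PANSS_general": {1: (23.56, 8.2), 2: (30.25, 8.2)},
    "PANSS_total": {1: (45.89, 15.9), 2: (55.25, 15.9)},
}
CATEGORICAL_MODEL_CHANGE = {
    "schizophrenia": {1: 0.50, 2: 0.375},
    "female": {1: 0.40, 2: 0.25},
}

#: three-group cohort description: variable -> {group: (mean, sd)}
COHORT_MODEL = {
    "age": {"HC": (22.91, 3.9), "baseline": (22.70, 3.2), "followup": (23.39, 3.3)},
    "education_years": {"HC": (15.55, 1.7), "baseline": (14.95, 1.6),
                        "followup": (15.06, 1.6)},
    "UPSA": {"HC": (83.45, 8.3), "baseline": (79.99, 10.9), "followup": (82.52, 12.0)},
    "MCAS": {"HC": (54.75, 0.6), "baseline": (48.10, 5.8), "followup": (48.00, 6.2)},
    "MATRICS_composite": {"HC": (50.45, 5.2), "baseline": (46.21, 6.4),
                          "followup": (48.63, 8.1)},
    "MATRICS_social": {"HC": (54.52, 6.6), "baseline": (53.58, 11.5),
                       "followup": (55.33, 13.8)},
    "TASIT": {"HC": (55.77, 4.5), "baseline": (53.69, 6.4), "followup": (54.67, 5.2)},
    "PANSS_positive": {"baseline": (14.45, 6.8), "followup": (13.18, 5.4)},
    "PANSS_negative": {"baseline": (12.50, 3.8), "followup": (10.41, 3.5)},
    "PANSS_general": {"baseline": (30.60, 7.9), "followup": (26.70, 8.4)},
    "PANSS_total": {"baseline": (57.55, 16.7), "followup": (50.29, 16.1)},
    "chlorpromazine_eq": {"baseline": (226.51, 234.3), "followup": (292.45, 241.6)},
}
COHORT_FEMALE = {"HC": 12 / 33, "baseline": 7 / 20, "followup": 6 / 18}
COHORT_SIZES = {"HC": 33, "baseline": 20, "followup": 18}
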