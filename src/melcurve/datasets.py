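"""Reference parameter tables for a studied Angelman syndrome cohort.

Published fitted melatonin-model parameters for nine children with
Angelman syndrome (AG group; 3-hourly plasma sampling over 24 h), along
with group medians for an epilepsy cohort (EG, n = 80) and a
non-epileptic comparison cohort (CG, n = 40) examined with the same
model.  Raw concentration measurements were never published, so these
fitted values are the anchor for the synthetic-cohort priors and for
regression tests of the derived circadian markers.

All times are decimal hours on a 24-h clock; concentrations are pg/mL.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "angelman_reference_cohort",
    "reference_group_medians",
    "REFERENCE_GROUP_SIZES",
]

# per-patient fitted parameters and derived markers (patients 1..9)
_AG_ROWS = {
    "b1": [0.1787, 8.2274, 4.8639, 10.0281, 2.53770, 9.2324, 11.2680, 7.8354, 0.3444],
    "b2": [466.7658, 167.4662, 208.3878, 153.9621, 79.88783, 222.4951, 162.7621,
           100.3606, 201.1275],
    "b3": [5.6183, 12.1787, 6.3585, 9.1097, 2.30309, 2.1005, 3.5904, 1.5535, 2.1150],
    "b4": [8.402, 11.2672, 8.0544, 6.8388, 12.83515, 7.2964, 7.7087, 7.3945, 11.4236],
    "b_max": [466.9445, 175.6936, 213.2517, 163.9902, 82.4255, 231.7275, 174.0301,
              108.1960, 201.4719],
    "dlmo_on50": [1.4173, 6.5451, 2.3313, 5.6903, 19.8855, 22.4523, 23.7360,
                  21.8562, 20.4033],
    "dlmo_off50": [9.8193, 17.8123, 10.3857, 12.5291, 8.7207, 5.7487, 7.4447,
                   5.2507, 7.8268],
    "dlmo_on25": [0.2667, 5.0021, 1.2283, 4.7537, 18.1278, 21.4531, 22.6803,
                  20.8436, 18.8389],
    "dlmo_off25": [10.9699, 19.3553, 11.4887, 13.4656, 10.4783, 6.7479, 8.5004,
                   6.2633, 9.3912],
    "max_gamma": [3.2600, 5.0490, 2.0780, 0.3255, 3.6410, 0.9718, 2.6570,
                  0.5221, 3.2590],
}

# published group medians (EG/CG per-subject values were not released)
_GROUP_MEDIANS = {
    "AG": {"b1": 7.83, "b2": 167.46, "b3": 3.59, "b4": 8.05, "b_max": 175.69,
           "dlmo_on50": 23.74, "dlmo_off50": 8.72, "dlmo_on25": 22.69,
           "dlmo_off25": 10.47, "max_gamma": 2.65},
    "CG": {"b1": 6.16, "b2": 142.51, "b3": 1.38, "b4": 7.07, "b_max": 152.14,
           "dlmo_on50": 22.1, "dlmo_off50": 5.2, "dlmo_on25": 21.33,
           "dlmo_off25": 6.06, "max_gamma": 1.81},
    "EG": {"b1": 5.84, "b2": 116.34, "b3": 2.34, "b4": 7.32, "b_max": 117.38,
           "dlmo_on50": 23.02, "dlmo_off50": 5.83, "dlmo_on25": 22.0,
           "dlmo_off25": 6.69, "max_gamma": 1.02},
}

REFERENCE_GROUP_SIZES = {"AG": 9, "EG": 80, "CG": 40}


def angelman_reference_cohort() -> pd.DataFrame:
    """Fitted parameters of the nine-child AG reference cohort.

    One row per patient (index ``patient_1`` .. ``patient_9``); columns
    are the four model parameters, the derived markers (``b_max``, DLMO
    onsets/offsets at the 50% and 25% relative thresholds) and the
    max-gamma shape score, exactly as published (clock times truncated/
    rounded to four decimals by the source).
    """
    df = pd.DataFrame(_AG_ROWS, index=[f"patient_{i}" for i in range(1, 10)])
    df.index.name = "subject_id"
    return df.copy()


def reference_group_medians(group: str) -> dict:
    """Published parameter medians for one of the cohorts AG, EG or CG."""
    try:
        return dict(_GROUP_MEDIANS[group])
    except KeyError:
        raise KeyError(f"unknown group {group!r}; expected one of {sorted(_GROUP_MEDIANS)}")
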