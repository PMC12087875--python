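"""Cohort table schema shared by every stage of the pipeline.

All distances are millimetres, all powers dioptres, refraction is the
cycloplegic spherical equivalent in dioptres.  One row per (right) eye.
"""

from __future__ import annotations

#: Columns of a raw cohort CSV, in header order.
RAW_COLUMNS = [
    "eye_id",
    "age_y",
    "sex",
    "SE_D",
    "r_ca_mm",
    "r_cp_mm",
    "CCT_mm",
    "AD_mm",
    "LT_mm",
    "AL_mm",
]

#: Measured numeric columns (exclude identifiers/covariates).
MEASURED_COLUMNS = ["SE_D", "r_ca_mm", "r_cp_mm", "CCT_mm", "AD_mm", "LT_mm", "AL_mm"]

#: Columns appended by the optical derivation, in header order.
DERIVED_COLUMNS = [
    "ACD_tot_mm",
    "ASL_mm",
    "VCD_mm",
    "P_ca_D",
    "P_cp_D",
    "P_c_D",
    "P_lb_D",
    "P_eye_D",
    "pp_eye2_mm",
    "P_ax_D",
    "SE_model_D",
    "P_cr",
    "AL_CR",
]

#: Column appended by the subgroup classification.
SUBGROUP_COLUMN = "subgroup"

#: Screening limit on refractive error, dioptres (|SE| above this is excluded).
SE_SCREEN_LIMIT = 15.0
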