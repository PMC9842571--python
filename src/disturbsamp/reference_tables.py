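"""Published per-passage summary statistics from the Salonga National Park survey.

These are the printed summary tables of the 2016-2018 multi-passage
line-transect survey of five diurnal primate species in the southern block
of Salonga National Park (DRC) — the study system this package analyses.
They serve as worked-example inputs and as regression fixtures for the
categorical tests and the descriptive arithmetic; the underlying raw
distance data are deposited separately and are not required here.

Species codes: Lophocebus aterrimus, Piliocolobus tholloni, Colobus
angolensis, Cercopithecus ascanius, Cercopithecus wolfi.
"""

from __future__ import annotations

import pandas as pd

#: heard-only group counts per passage and distance category
#: (close < 100 m, far 100-500 m, very far > 500 m)
HEARD_COUNTS = pd.DataFrame(
    {
        "close": [122, 46, 100, 13],
        "far": [102, 57, 68, 4],
        "very_far": [5, 3, 5, 0],
    },
    index=pd.Index(["P1", "P2", "P3", "P4"], name="passage"),
)

#: per-passage survey effort and walk counts
PASSAGE_TABLE = pd.DataFrame(
    {
        "n_transects": [378, 358, 371, 51],
        "morning_fraction": [0.963, 0.000, 0.992, 0.569],
        "effort_km": [374.17, 354.63, 367.46, 51.02],
        "encounter_rate": [0.935, 0.936, 1.230, 1.196],
        "poly_encounter_rate": [0.037, 0.054, 0.086, 0.118],
    },
    index=pd.Index(["P1", "P2", "P3", "P4"], name="passage"),
)

#: overall mean group sizes across all species and passages
OVERALL_GROUP_SIZE = {
    "observed_mean": 8.89,
    "observed_sd": 8.87,
    "estimated_mean": 12.34,
    "estimated_sd": 12.14,
}

#: per-species, per-passage density estimates (individuals/km^2) obtained
#: with observed vs estimated group size, plus the group-size summaries.
#: Cells where too few sightings allowed no detection-function fit are absent.
_DENSITY_ROWS = [
    # species, passage, d_obs, d_obs_lo, d_obs_hi, d_est, d_est_lo, d_est_hi,
    # size_obs, size_obs_sd, size_est, size_est_sd, n
    ("L_aterrimus", 2, 52.23, 33.10, 82.41, 68.34, 43.65, 107.01, 8.58, 8.89, 11.24, 10.83, 76),
    ("L_aterrimus", 3, 61.32, 38.72, 97.12, 79.36, 48.45, 129.98, 9.40, 8.19, 12.29, 9.81, 90),
    ("L_aterrimus", 4, 52.13, 27.88, 97.49, 75.15, 28.38, 198.97, 12.59, 7.62, 16.53, 10.03, 17),
    ("P_tholloni", 2, 25.27, 12.35, 51.73, 39.94, 19.45, 82.05, 18.65, 13.43, 28.65, 21.54, 26),
    ("P_tholloni", 3, 69.31, 43.07, 111.54, 90.46, 55.81, 129.98, 22.27, 12.62, 30.88, 17.88, 40),
    ("C_angolensis", 2, 2.97, 1.51, 5.86, 4.12, 2.01, 8.49, 2.40, 1.18, 3.40, 2.23, 15),
    ("C_angolensis", 3, 4.50, 2.43, 8.34, 5.40, 2.76, 10.55, 3.00, 1.55, 5.08, 3.44, 25),
    ("C_ascanius", 2, 13.73, 9.14, 20.62, 20.19, 13.31, 30.62, 5.38, 4.70, 7.45, 5.97, 69),
    ("C_ascanius", 3, 36.50, 27.84, 47.84, 50.23, 38.47, 65.60, 6.67, 5.14, 9.30, 6.68, 110),
    ("C_ascanius", 4, 56.92, 25.49, 127.11, 68.31, 30.78, 151.60, 8.22, 4.73, 10.83, 4.59, 18),
    ("C_wolfi", 2, 8.32, 4.53, 15.29, 10.84, 5.91, 19.82, 6.79, 5.12, 9.32, 6.49, 19),
    ("C_wolfi", 3, 19.52, 12.07, 31.58, 30.39, 18.94, 48.76, 6.43, 5.59, 9.88, 8.11, 49),
    ("all", 2, 112.45, 81.84, 154.52, 147.57, 105.69, 206.40, 8.16, 8.96, 11.42, 12.82, 205),
    ("all", 3, 196.87, 155.87, 248.67, 277.71, 220.00, 350.55, 9.11, 9.03, 12.66, 12.08, 314),
    ("all", 4, 230.10, 147.10, 359.93, 311.55, 181.63, 534.41, 10.46, 7.25, 14.08, 9.28, 50),
]

DENSITY_TABLE = pd.DataFrame(
    _DENSITY_ROWS,
    columns=[
        "species", "passage", "density_observed", "d_obs_lo", "d_obs_hi",
        "density_estimated", "d_est_lo", "d_est_hi",
        "size_observed", "size_observed_sd", "size_estimated", "size_estimated_sd", "n",
    ],
)

#: per-passage mean *estimated* group sizes for species with P4 data missing
#: from DENSITY_TABLE density cells but with recorded sizes
EXTRA_P4_SIZES = pd.DataFrame(
    [
        ("P_tholloni", 4, 16.67, 10.98, 22.17, 12.92, 6),
        ("C_angolensis", 4, 1.50, 0.71, 1.50, 0.71, 2),
        ("C_wolfi", 4, 8.29, 3.45, 13.14, 8.28, 7),
    ],
    columns=["species", "passage", "size_observed", "size_observed_sd",
             "size_estimated", "size_estimated_sd", "n"],
)

#: corrected densities (individuals/km^2) with 95% CI, pooling the
#: undepressed passages (P3+P4) and the largest passage-mean estimated size
CORRECTED_DENSITIES = {
    "L_aterrimus": (90.1, 60.7, 133.7),
    "P_tholloni": (99.2, 61.0, 161.2),
    "C_angolensis": (6.7, 3.6, 12.4),
    "C_ascanius": (62.2, 45.2, 85.8),
    "C_wolfi": (43.1, 26.5, 70.0),
}
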