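"""Published random-forest fit metrics for the seven Toronto Harbour species.

These are the printed test-set fit statistics from the source study's model
evaluation table (two decimal places, as published). They are used as *input
data* for the metric-identity worked examples: from the printed sensitivity,
specificity and null accuracy one can reconstruct a confusion table at a
nominal test size and recompute the remaining statistics, which must agree
with the printed values up to the rounding of the inputs.

Accuracy p-values are printed as inequalities for most species and depend on
the (unpublished) per-species test-set sizes; they are kept here for
completeness but are only checked qualitatively.
"""

from __future__ import annotations

import pandas as pd

SPECIES = (
    "largemouth_bass",
    "northern_pike",
    "walleye",
    "yellow_perch",
    "bowfin",
    "common_carp",
    "white_sucker",
)

#: Printed per-species fit metrics (test data).  Columns follow the
#: published table; ``accuracy_p`` holds the upper bound for "< 0.001" rows.
PUBLISHED_FIT_METRICS = pd.DataFrame(
    [
        # species, accuracy, kappa, accuracy_null, accuracy_p, sens, spec, precision, npv, f1, balance
        ("largemouth_bass", 0.83, 0.53, 0.75, 0.001, 0.60, 0.91, 0.68, 0.87, 0.64, 0.75),
        ("northern_pike",   0.70, 0.40, 0.52, 0.001, 0.71, 0.69, 0.68, 0.72, 0.70, 0.70),
        ("walleye",         0.81, 0.43, 0.82, 0.98,  0.64, 0.84, 0.47, 0.92, 0.55, 0.74),
        ("yellow_perch",    0.88, 0.58, 0.83, 0.001, 0.70, 0.91, 0.63, 0.94, 0.66, 0.80),
        ("bowfin",          0.88, 0.55, 0.88, 0.20,  0.78, 0.90, 0.51, 0.97, 0.62, 0.84),
        ("common_carp",     0.74, 0.43, 0.69, 0.001, 0.72, 0.74, 0.55, 0.86, 0.63, 0.73),
        ("white_sucker",    0.83, 0.54, 0.75, 0.001, 0.65, 0.89, 0.66, 0.89, 0.66, 0.77),
    ],
    columns=[
        "species", "accuracy", "kappa", "accuracy_null", "accuracy_p",
        "sensitivity", "specificity", "precision", "npv", "f1", "balance",
    ],
).set_index("species")

#: Rows whose printed accuracy p-value is an exact "< 0.001" bound.
P_LT_0_001 = ("largemouth_bass", "northern_pike", "yellow_perch", "common_carp", "white_sucker")
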