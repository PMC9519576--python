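"""Published summary statistics of the cybrid activity/sleep experiment.

These are the printed cell means, variance components and derived
percentages from the study this pipeline re-implements.  They serve two
roles: calibration targets for the synthetic generator, and inputs to the
arithmetic-verification report that recomputes every derived quantity
from its printed components.
"""

# Mean total activity (beam breaks over 3 days) by (genome_type, sex).
TOTAL_ACTIVITY_MEAN = {
    ("coevolved", "female"): 1988.0,
    ("coevolved", "male"): 1750.0,
    ("cybrid", "female"): 3847.0,
    ("cybrid", "male"): 2652.0,
}

# Panel-average total activity.
PANEL_TOTAL_ACTIVITY = {"coevolved": 1867.0, "cybrid": 3266.0}

# Proportion of time asleep by (genome_type, sex) and panel average.
SLEEP_FRACTION = {
    ("coevolved", "female"): 0.55,
    ("coevolved", "male"): 0.64,
    ("cybrid", "female"): 0.30,
    ("cybrid", "male"): 0.46,
}
PANEL_SLEEP_FRACTION = {"coevolved": 0.59, "cybrid": 0.38}

# Mean awake activity (beam breaks per 5-min awake bin) by cell, and the
# panel averages quoted with the "57% increase" statement.
AWAKE_ACTIVITY_MEAN = {
    ("coevolved", "female"): 5.0,
    ("coevolved", "male"): 5.74,
    ("cybrid", "female"): 6.3,
    ("cybrid", "male"): 5.6,
}
PANEL_AWAKE_ACTIVITY = {"coevolved": 2.2, "cybrid": 3.8}

# Printed derived percentages.
PRINTED_SEX_GAP_PCT = {"coevolved": 14.0, "cybrid": 45.0}
PRINTED_CYBRID_INCREASE_PCT = 75.0
PRINTED_AWAKE_INCREASE_PCT = 57.0

# Among-line variance components per trait and panel (activity traits on
# the response scale, sleep on the latent logit scale) and printed ratios.
LINE_VARIANCE = {
    "total_activity": {"original": 5.79e5, "cybrid": 1.14e5},
    "mean_awake_activity": {"original": 0.02, "cybrid": 0.15},
    "prop_asleep": {"original": 0.48, "cybrid": 0.07},
}
PRINTED_RATIO = {
    "total_activity": 0.20,
    "mean_awake_activity": 6.04,
    "prop_asleep": 0.14,
}

# Design: 8 coevolved + 8 cybrid strains, 2 sexes, 15 flies per sex and
# strain over 5 blocks; 4 flies died during recording.
DESIGN = {
    "n_strains": 16,
    "n_sexes": 2,
    "n_per_sex_line": 15,
    "n_blocks": 5,
    "n_deaths": 4,
}
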