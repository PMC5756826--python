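"""Reference values from the original west-central Alberta grizzly bear
field deployments of this protocol (2006–2007 random site visits and
2013–2014 cluster-guided visits).

These printed field results — outcome count tables, group summary
statistics, model-selection rows and fitted model coefficients — are
packaged as plain data so the package's statistics and scoring functions can
be exercised and cross-checked without access to the raw collar data.
"""

from __future__ import annotations

from .stats import ContingencyTable

# ---------------------------------------------------------------------------
# Outcome count tables (predation / no-predation and carcass-size splits).

#: 2006-2007 validation: random GPS locations within vs outside a
#: posteriori-detected clusters, by predation outcome.  23 of 27 verified
#: predation sites fell inside clusters (187 within-cluster visits, 277
#: outside).
WITHIN_OUTSIDE_2006 = ContingencyTable(
    counts=((23, 164), (4, 273)),
    row_labels=("within_cluster", "outside_cluster"),
    col_labels=("predation", "no_predation"),
)

#: Detection-rate comparison between campaigns: 54 predation events in 335
#: cluster-guided visits (2013-2014) vs 27 in 464 random visits (2006-2007).
CAMPAIGN_COMPARISON = ContingencyTable(
    counts=((54, 281), (27, 437)),
    row_labels=("clusters_2013_14", "random_2006_07"),
    col_labels=("predation", "no_predation"),
)

#: 2013-2014 cluster visits: predation outcome by categorical cluster
#: characteristics (two-column: predation / no predation).
PREDATION_BY_SEASON = ContingencyTable(
    counts=((17, 53), (19, 65), (18, 163)),
    row_labels=("spring", "summer", "fall"),
    col_labels=("predation", "no_predation"),
)
PREDATION_BY_STOD = ContingencyTable(
    counts=((38, 78), (14, 194), (2, 9)),
    row_labels=("day", "night", "twilight"),
    col_labels=("predation", "no_predation"),
)
PREDATION_BY_SEX = ContingencyTable(
    counts=((38, 169), (16, 112)),
    row_labels=("male", "female"),
    col_labels=("predation", "no_predation"),
)
PREDATION_BY_AGE = ContingencyTable(
    counts=((43, 214), (11, 67)),
    row_labels=("adult", "subadult"),
    col_labels=("predation", "no_predation"),
)

#: Carcass-size splits as three-outcome tables (small/medium carcass, large
#: carcass, no predation) against each grouping factor.
CARCASS_BY_SEASON = ContingencyTable(
    counts=((11, 6, 53), (17, 2, 65), (9, 9, 163)),
    row_labels=("spring", "summer", "fall"),
    col_labels=("small_medium", "large", "no_predation"),
)
CARCASS_BY_STOD = ContingencyTable(
    counts=((30, 8, 78), (6, 8, 194), (1, 1, 9)),
    row_labels=("day", "night", "twilight"),
    col_labels=("small_medium", "large", "no_predation"),
)
CARCASS_BY_SEX = ContingencyTable(
    counts=((24, 14, 169), (13, 3, 112)),
    row_labels=("male", "female"),
    col_labels=("small_medium", "large", "no_predation"),
)
CARCASS_BY_AGE = ContingencyTable(
    counts=((27, 16, 214), (10, 1, 67)),
    row_labels=("adult", "subadult"),
    col_labels=("small_medium", "large", "no_predation"),
)

#: Visit totals for detection-probability summaries.
DETECTION_COUNTS = {
    "random_2006_07": {"events": 27, "visits": 464},
    "clusters_2013_14": {"events": 54, "visits": 335},
}

# ---------------------------------------------------------------------------
# Continuous cluster characteristics: group means (standard errors).

#: Predation (n=54) vs no-predation (n=281) cluster summaries.
GROUP_SUMMARIES = {
    "predation": {
        "n": 54,
        "spread": (19.9, 1.0),
        "n_gps_obs": (24.7, 3.0),
        "duration": (41.1, 6.1),
        "return_events": (1.8, 0.2),
        "occupation": (0.7, 0.0),
    },
    "no_predation": {
        "n": 281,
        "spread": (16.6, 0.4),
        "n_gps_obs": (7.1, 0.2),
        "duration": (18.8, 2.7),
        "return_events": (0.4, 0.1),
        "occupation": (0.8, 0.0),
    },
    "small_medium": {
        "n": 37,
        "spread": (19.6, 1.1),
        "n_gps_obs": (20.5, 2.3),
        "duration": (37.8, 6.6),
        "return_events": (1.75, 0.3),
        "occupation": (0.72, 0.0),
    },
    "large": {
        "n": 17,
        "spread": (20.6, 1.9),
        "n_gps_obs": (32.9, 7.6),
        "duration": (47.7, 12.9),
        "return_events": (2.0, 0.6),
        "occupation": (0.79, 0.1),
    },
}

# ---------------------------------------------------------------------------
# Model-selection rows (log-likelihood, parameter count, sample size) for
# the top-ranked random-intercept logistic models.

MODEL_SELECTION_ROWS = {
    "predation": [
        {"rank": 1, "terms": "nGPSObs + duration + SToD + sex", "ll": -60.5, "k": 7, "n": 335, "aicc": 135.3, "sensitivity": 72.2},
        {"rank": 2, "terms": "nGPSObs + SToD + sex", "ll": -61.9, "k": 6, "n": 335, "aicc": 136.0, "sensitivity": 72.2},
        {"rank": 3, "terms": "nGPSObs + occupation + sex + SToD", "ll": -61.1, "k": 7, "n": 335, "aicc": 136.5, "sensitivity": 72.2},
    ],
    "carcass": [
        {"rank": 1, "terms": "season + SToD + nGPSObs + spread", "ll": -25.0, "k": 8, "n": 54, "aicc": 69.3, "sensitivity": 94.4},
        {"rank": 2, "terms": "season", "ll": -29.8, "k": 4, "n": 54, "aicc": 68.4, "sensitivity": 77.8},
        {"rank": 3, "terms": "season + SToD", "ll": -27.6, "k": 6, "n": 54, "aicc": 69.0, "sensitivity": 77.8},
    ],
}

# ---------------------------------------------------------------------------
# Fitted coefficients of the selected models (population-level scoring;
# random intercept set to 0).  Count and duration predictors enter on the
# log10 scale; in the carcass model spread does too.  Reference levels:
# SToD = day, season = fall, sex = female.

PREDATION_MODEL = {
    "intercept": -10.75,
    "log10_n_gps_obs": 11.24,
    "log10_duration": -1.46,
    "sex_male": 1.32,
    "stod_night": -2.45,
    "stod_twilight": -3.21,
}

#: Positive class: small/medium carcass (the usual outcome).
CARCASS_MODEL = {
    "intercept": 4.80,
    "season_spring": 0.54,
    "season_summer": 2.65,
    "stod_night": -1.91,
    "stod_twilight": -1.92,
    "log10_n_gps_obs": -1.97,
    "log10_spread": -3.48,
}

#: Printed odds ratios for coefficient-consistency checks (exp(beta)).
#: The source table's intercept and duration rows are internally
#: inconsistent (printed OR does not equal exp(printed estimate); the
#: duration row also repeats the nGPSObs z statistic) — a typesetting
#: defect, so those rows are excluded from consistency checks and the
#: printed coefficient estimates are kept as the packaged values.
PREDATION_MODEL_ODDS_RATIOS = {
    "log10_n_gps_obs": 7.5904e4,
    "sex_male": 3.7373,
    "stod_night": 0.0859,
    "stod_twilight": 0.0404,
}

#: Reported classification performance of the selected models at the 0.5
#: probability threshold (not re-derivable without the raw field data).
REPORTED_PERFORMANCE = {
    "predation": {"accuracy": 0.934, "sensitivity": 0.722, "specificity": 0.975,
                  "auc": 0.945, "auc_se": 0.018},
    "carcass": {"accuracy": 0.852, "sensitivity": 0.944, "specificity": 0.667,
                "auc": 0.852, "auc_se": 0.062},
}
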