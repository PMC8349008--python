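"""Published reference values for the Colorado all-payer claims mental-health
provider-network study (2016-2017) used for arithmetic-consistency checks.

These numbers come from the published summary tables of the original
analysis of the restricted Colorado APCD extract; the raw data are not
public, so they serve only to validate table arithmetic and to seed realistic
defaults for the synthetic generator.

Data note: the published bipolar-disorder count contains a digit
transposition (it is inconsistent with both its printed percentage, 8.2%,
and the column total); the value stored here, 38,984, is reconstructed from
the printed percentage and the constraint that the six mutually exclusive
diagnosis counts sum to N.
"""

from __future__ import annotations

# largest-connected-component cohort
N_PATIENTS = 476_802
PATIENT_RETENTION_PCT = 97.0  # of the filtered BH cohort
N_PROVIDERS_LCC = 8_256
PROVIDER_RETENTION_PCT = 21.0  # of all providers billing for the cohort

# sample characteristics: category -> (count, printed percent)
SEX = {
    "female": (295_618, 62.0),
    "male": (180_563, 37.9),
    "missing": (621, 0.1),
}
AGE_BANDS = {
    "17_29": (117_782, 24.7),
    "30_40": (118_902, 24.9),
    "41_51": (110_361, 23.2),
    "52_63": (129_757, 27.2),
}
DIAGNOSIS = {
    "schizophrenia_psychotic": (29_887, 6.3),
    "bipolar": (38_984, 8.2),  # reconstructed; see data note above
    "depression_mood": (205_378, 43.1),
    "anxiety_stress": (146_790, 30.8),
    "other_mental": (37_031, 7.8),
    "substance_use": (18_732, 3.9),
}
INSURANCE = {
    "medicaid_only": (161_843, 33.9),
    "medicare_only": (21_698, 4.6),
    "dual": (42_514, 8.9),
    "commercial_only": (223_103, 46.8),
    "commercial_plus_public": (27_644, 5.8),
}

# provider composition of the largest connected component
PROVIDER_COMPOSITION = {
    "pcp": 3_833,
    "psychiatrist": 823,
    "psychologist": 498,
    "bh_specialist": 3_102,
}

# provider-level network summaries (min, median, mean, max)
PROVIDER_SUMMARY = {
    "degree": (1, 26, 59.54, 1011),
    "transitivity": (0.0, 0.58, 0.60, 1.0),
    "degree_to_pcp": (0, 12, 31.82, 681),
    "degree_to_pcp_same_community": (0, 11, 28.73, 506),
    "n_patients": (3, 91, 178.98, 3356),
    "n_patients_with_pcp": (0, 41, 113.07, 1684),
    "n_patients_with_pcp_same_community": (0, 38, 108.40, 1682),
}

# community structure
N_COMMUNITIES = 5
COMMUNITY_MODULARITY = 0.69
COMMUNITY_SIZE_RANGE = (592, 3_139)
N_SUBCOMMUNITIES = 24
SUBCOMMUNITY_MODULARITY_RANGE = (0.28, 0.69)
SUBCOMMUNITY_SIZE_RANGE = (14, 1_320)

# size-vs-characteristic correlations over the 24 sub-communities
# characteristic -> (pearson, spearman)
SIZE_CORRELATIONS = {
    "mean_degree": (0.37, 0.66),
    "mean_degree_to_pcp": (0.24, 0.65),
    "pct_pcp_within": (0.12, -0.04),
    "mean_transitivity": (-0.02, 0.08),
    "mean_coc": (0.00, 0.03),
    "prop_psychiatrist": (0.42, 0.30),
    "prop_pcp": (-0.02, -0.11),
    "prop_psychologist": (-0.18, 0.09),
    "prop_bh_specialist": (0.03, 0.09),
}

UNADJUSTED_TRANSITIVITY_COC = {"pearson": 0.08, "spearman": 0.7}

# random-intercept model coefficients (term -> (slope, p)) for the two models
MODEL1 = {
    "intercept": (0.25, "<0.001"),
    "transitivity": (-0.011, 0.006),
    "n_patients": (0.0000060, 0.26),
    "bh_specialist": (0.061, "<0.001"),
    "psychiatrist": (0.027, "<0.001"),
    "psychologist": (0.034, "<0.001"),
}
MODEL2 = {
    "intercept": (-0.032, "<0.001"),
    "transitivity": (0.00062, 0.85),
    "n_patients": (-0.00000022, 0.96),
    "bh_specialist": (0.021, "<0.001"),
    "psychiatrist": (0.010, "<0.001"),
    "psychologist": (0.017, "<0.001"),
    "alter_coc": (1.1, "<0.001"),
}
STANDARDIZED_TRANSITIVITY_EFFECT_PCT = -32.0  # % of an SD of CoC per SD of T
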