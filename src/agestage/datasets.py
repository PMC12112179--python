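"""Published summary tables from a multigeneration chlorantraniliprole
resistance-selection study on the tomato leafminer (*Phthorimaea absoluta*).

The raw cohort and per-replicate mortality data of that study are not
deposited, so these printed summaries serve as inputs for the arithmetic
consistency identities the package can verify: the probit quantile relation
between slope, LC50 and LC25; resistance ratios; relative fitness; the
λ = e^r identity; and differences between strain means.

Strains: SS is the susceptible reference; CX-Sub_n is the field-derived
strain after n generations of selection at LC25; "control" is the parallel
unselected strain (CX-S_8).
"""

from __future__ import annotations

#: Dose-mortality probit summaries: slope ± SE (probits per log10 mg/L),
#: LC25 and LC50 in mg/L, Pearson chi-square with df, and resistance ratio
#: relative to SS.
PROBIT_SUMMARY: dict[str, dict[str, float]] = {
    "SS":       {"slope": 0.465, "slope_se": 0.102, "lc25": 0.006,
                 "lc50": 0.170, "chi2": 1.331, "df": 4},
    "CX-Sub_1": {"slope": 1.213, "slope_se": 0.175, "lc25": 1.873,
                 "lc50": 6.741, "chi2": 6.383, "df": 4, "rr_ss": 39.65},
    "CX-Sub_2": {"slope": 1.332, "slope_se": 0.178, "lc25": 2.160,
                 "lc50": 6.933, "chi2": 1.482, "df": 4, "rr_ss": 40.78},
    "CX-Sub_3": {"slope": 0.558, "slope_se": 0.110, "lc25": 4.734,
                 "lc50": 36.504, "chi2": 3.419, "df": 4, "rr_ss": 214.73},
    "CX-Sub_4": {"slope": 0.983, "slope_se": 0.134, "lc25": 6.762,
                 "lc50": 32.816, "chi2": 2.223, "df": 4, "rr_ss": 193.04},
    "CX-Sub_5": {"slope": 0.923, "slope_se": 0.129, "lc25": 5.906,
                 "lc50": 31.722, "chi2": 1.553, "df": 4, "rr_ss": 186.60},
    "CX-Sub_6": {"slope": 0.791, "slope_se": 0.121, "lc25": 4.871,
                 "lc50": 34.708, "chi2": 1.425, "df": 4, "rr_ss": 204.16},
    "CX-Sub_7": {"slope": 0.844, "slope_se": 0.124, "lc25": 5.699,
                 "lc50": 35.878, "chi2": 0.819, "df": 4, "rr_ss": 211.05},
    "CX-Sub_8": {"slope": 0.947, "slope_se": 0.132, "lc25": 7.426,
                 "lc50": 38.313, "chi2": 2.144, "df": 4, "rr_ss": 225.37},
}

#: Life-table population parameters (bootstrap means) per strain.
LIFETABLE_SUMMARY: dict[str, dict[str, float]] = {
    "control":  {"GRR": 47.14, "R0": 33.72, "r": 0.13, "T": 27.82,
                 "lambda": 1.14, "Rf": 1.00},
    "CX-Sub_2": {"GRR": 32.56, "R0": 24.87, "r": 0.11, "T": 28.17,
                 "lambda": 1.12, "Rf": 0.74},
    "CX-Sub_4": {"GRR": 28.37, "R0": 21.90, "r": 0.11, "T": 28.58,
                 "lambda": 1.11, "Rf": 0.65},
    "CX-Sub_8": {"GRR": 27.68, "R0": 20.88, "r": 0.10, "T": 30.17,
                 "lambda": 1.10, "Rf": 0.62},
}

#: Development-time / fecundity means per strain (days; eggs per female).
STAGE_SUMMARY: dict[str, dict[str, float]] = {
    "control":  {"egg": 4.87, "L1": 3.02, "L2": 2.81, "L3": 2.72, "L4": 2.77,
                 "pupa": 7.14, "preadult": 23.26, "adult": 17.53,
                 "female_longevity": 18.09, "male_longevity": 17.07,
                 "APOP": 2.12, "TPOP": 25.12, "oviposition_days": 5.79,
                 "fecundity": 102.18},
    "CX-Sub_2": {"egg": 4.77, "L1": 2.88, "L2": 2.76, "L3": 2.80, "L4": 2.63,
                 "pupa": 6.94, "preadult": 22.93, "adult": 17.54,
                 "female_longevity": 16.80, "male_longevity": 18.27,
                 "APOP": 3.03, "TPOP": 26.00, "oviposition_days": 5.23,
                 "fecundity": 71.06},
    "CX-Sub_4": {"egg": 4.98, "L1": 3.28, "L2": 3.22, "L3": 3.10, "L4": 2.52,
                 "pupa": 7.25, "preadult": 24.24, "adult": 19.03,
                 "female_longevity": 18.79, "male_longevity": 19.24,
                 "APOP": 3.11, "TPOP": 27.34, "oviposition_days": 4.24,
                 "fecundity": 57.63},
    "CX-Sub_8": {"egg": 5.52, "L1": 3.59, "L2": 3.28, "L3": 3.14, "L4": 2.71,
                 "pupa": 7.58, "preadult": 25.71, "adult": 20.06,
                 "female_longevity": 21.12, "male_longevity": 18.77,
                 "APOP": 2.68, "TPOP": 28.45, "oviposition_days": 4.13,
                 "fecundity": 48.56},
}
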