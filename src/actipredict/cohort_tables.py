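"""Published univariate tables of the 48-patient pancreatectomy cohort.

These are the printed group summaries from the prospective cohort this
package's methodology was developed on (n=48: 20 patients with
complications, 28 with textbook outcomes).  They serve as fixed inputs for
reproducing the cohort's univariate statistics: contingency tables for the
chi-square tests and per-group mean/SD summaries (population-SD convention)
for the one-way ANOVA F reconstructions.
"""

from __future__ import annotations

# Contingency tables: rows = variable levels,
# columns = (complications n=20, textbook n=28)
CONTINGENCY_TABLES: dict[str, dict] = {
    "gender": {
        "levels": ["male", "female"],
        "counts": [[11, 8], [9, 20]],
        "printed_p": 0.12,
    },
    "race": {
        "levels": ["white", "non_white"],
        "counts": [[19, 25], [1, 3]],
        "printed_p": 0.86,
    },
    "comorbidities_ge5": {
        "levels": [">=5", "<5"],
        "counts": [[12, 8], [8, 20]],
        "printed_p": 0.06,
    },
    "tobacco": {
        "levels": ["never", "active_gt10py", "active_lt10py",
                   "past_gt30py", "past_lt30py"],
        "counts": [[11, 19], [1, 3], [0, 1], [7, 4], [1, 1]],
        "printed_p": 0.45,
    },
    "medications_ge5": {
        "levels": [">=5", "<5"],
        "counts": [[7, 6], [13, 22]],
        "printed_p": 0.48,
    },
    "asa_class": {
        "levels": ["1", "2", "3"],
        "counts": [[0, 1], [7, 18], [13, 9]],
        "printed_p": 0.07,
    },
    "prior_surgery": {
        "levels": ["yes", "no"],
        "counts": [[15, 10], [5, 18]],
        "printed_p": 0.02,
    },
    "operative_approach": {
        "levels": ["open", "laparoscopic", "robotic"],
        "counts": [[14, 14], [4, 9], [2, 5]],
        "printed_p": 0.38,
    },
    "operation_type": {
        "levels": ["pancreaticoduodenectomy", "distal", "total"],
        "counts": [[18, 23], [1, 5], [1, 0]],
        "printed_p": 0.22,
    },
}

# Per-group summaries (complications n=20, textbook n=28): mean, SD with
# divisor n (verified by sqrt(p*(1-p)) on the binary rows).
GROUP_SIZES = (20, 28)

GROUP_SUMMARIES: dict[str, dict] = {
    "prior_surgery": {
        "means": (0.7500, 0.3571), "sds": (0.4330, 0.4792), "printed_F": 8.1374,
    },
    "asa_class": {
        "means": (2.6500, 2.2857), "sds": (0.4770, 0.5249), "printed_F": 5.8069,
    },
    "neutrophils": {
        "means": (50.8000, 31.5393), "sds": (27.5481, 30.4855),
        "printed_F": 4.8323,
    },
    "calcium": {
        "means": (9.2450, 9.6071), "sds": (0.4955, 0.6464), "printed_F": 4.2378,
    },
    "hyperlipidemia": {
        "means": (0.6000, 0.3571), "sds": (0.4899, 0.4792), "printed_F": 2.8189,
    },
}

# Cohort-level activity statistics used as synthetic-generator defaults.
COHORT_STATS = {
    "n_patients": 48,
    "textbook_fraction": 28 / 48,
    "steps_per_day_mean": 4162.1,
    "steps_per_day_sd": 4052.6,
    "heart_rate_mean": 75.6,
    "heart_rate_sd": 14.8,
    "daily_yield_mean": 0.821,
    "daily_yield_sd": 0.235,
    "monitoring_days_mean": 26,
    "monitoring_days_range": (6, 153),
    "src_any_mean": 0.273, "src_any_sd": 0.064,
    "src_serious_mean": 0.233, "src_serious_sd": 0.055,
    "src_readmit_mean": 0.151, "src_readmit_sd": 0.034,
}
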