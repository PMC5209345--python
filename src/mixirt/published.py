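"""Published reference values for the HILDA wave-1 job-satisfaction scale.

These are the printed results of a three-class restricted mixture GPCM
analysis of the five job-satisfaction items (n = 7036, 11 categories each):
the descriptive table of the raw items, the model-comparison table
(free-parameter counts, log-likelihoods, consistent-AIC values, difference
tests), and two illustrative threshold sets (an ordinary ordered item and
a partly disordered one).  They serve as fixed inputs for internal-
consistency checks: recomputing a mean from the printed frequencies,
recomputing a CAIC from a printed (LL, N_par) pair, locating the printed
characteristic-curve intersections.
"""

from __future__ import annotations

import numpy as np

N_PERSONS = 7036

#: item -> (mean, sd, [relative category frequencies in percent, cats 0..10])
DESCRIPTIVES = {
    "total_pay": (6.73, 2.41, [1.9, 1.6, 3.2, 4.9, 5.1, 10.8, 10.0, 18.5, 21.4, 9.7, 12.8]),
    "job_security": (7.72, 2.50, [1.9, 1.5, 2.5, 2.9, 2.9, 7.1, 4.6, 10.0, 18.6, 17.6, 30.8]),
    "work_itself": (7.67, 2.06, [0.5, 0.7, 1.4, 2.4, 2.6, 7.3, 7.7, 15.2, 23.6, 17.5, 21.1]),
    "working_hours": (7.14, 2.35, [1.0, 1.4, 2.7, 3.9, 4.3, 10.8, 8.7, 15.1, 20.8, 13.3, 18.0]),
    "flexibility": (7.36, 2.60, [2.0, 1.7, 3.2, 3.8, 3.8, 8.5, 6.3, 11.6, 18.0, 15.0, 26.0]),
}

#: model label -> (n_par, log-likelihood, printed CAIC)
MODEL_COMPARISON = {
    "rmgpcm_1": (55, -69917, 140376),
    "rmgpcm_2": (107, -68382, 137819),
    "rmgpcm_3": (159, -68035, 137637),
    "rmgpcm_4": (211, -67877, 137833),
    "rmgpcm_5": (263, -67736, 138065),
    "mpcm_3": (155, -68173, 137873),
    "mgpcm_3": (169, -68009, 137684),
}

#: printed bootstrapped difference tests: (delta, df)
DIFFERENCE_TESTS = {
    "rmgpcm3_vs_mpcm3": (272.81, 4),
    "mgpcm3_vs_rmgpcm3": (51.87, 10),
}

#: ordinary ordered 11-category item (figure example), slopes 1.5 / 3.0
ORDERED_THRESHOLDS = np.arange(-2.25, 2.26, 0.5)

#: partly disordered variant: thresholds 7 and 8 reversed -> category 7 avoided
DISORDERED_THRESHOLDS = np.array(
    [-2.25, -1.75, -1.25, -0.75, -0.25, 0.25, 1.25, 0.75, 1.75, 2.25]
)

FIGURE_DISCRIMINATIONS = (1.5, 3.0)

#: reliability of the trait after separating scale usage vs raw-score alpha
RELIABILITY_EAP = 0.59
CRONBACH_ALPHA = 0.67

CLASS_PROPORTIONS = (0.40, 0.33, 0.27)
MEAN_ASSIGNMENT_PROBABILITIES = (0.79, 0.85, 0.76)
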