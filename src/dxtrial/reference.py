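"""Published values from the reference trial, used as model inputs and
regression targets.

The trial randomised doctors to four presentation formats for the accuracy
of a fictitious blood test ("anti-celadon" test for "Green syndrome") and
recorded their management choice and post-test probability answer. All
constants below are printed in the trial report; nothing here is fitted.
"""

from __future__ import annotations

from .bayes_core import TestAccuracy

# Trial arm labels, in randomisation order; "text" is the reference arm.
ARMS = ("text", "nomogram", "pmp", "nft")

ARM_TITLES = {
    "text": "Text-only",
    "nomogram": "Nomogram",
    "pmp": "Probability modifying plot",
    "nft": "Natural frequencies",
}

# Vignette scenario: pre-test probability 50%, index test sens 60% / spec 90%.
VIGNETTE_PRETEST = 0.5
VIGNETTE_ACCURACY = TestAccuracy(sensitivity=0.60, specificity=0.90)
# Comparator (biopsy): perfect specificity, sens 95% — infinite LR+.
BIOPSY_ACCURACY = TestAccuracy(sensitivity=0.95, specificity=1.00)
# Cohort size used by the natural-frequency-tree format.
TREE_COHORT_SIZE = 1000

# Baseline-knowledge quiz test: sens 90 / spec 50, stated PPV 33% / NPV 95%.
# The implied prevalence (~0.217 from the PPV) is never printed; it is an
# explicit input wherever needed, not inferred here.
QUIZ_ACCURACY = TestAccuracy(sensitivity=0.90, specificity=0.50)
QUIZ_PPV = 0.33
QUIZ_NPV = 0.95

# Outcome counts by arm: management {treat, biopsy, no_treat, blank} and
# post-test-answer correctness {correct, incorrect, blank}.
ARM_TOTALS = {"text": 255, "nomogram": 194, "pmp": 218, "nft": 207}

MANAGEMENT_COUNTS = {
    "text": {"treat": 142, "biopsy": 79, "no_treat": 31, "blank": 3},
    "nomogram": {"treat": 112, "biopsy": 56, "no_treat": 24, "blank": 2},
    "pmp": {"treat": 142, "biopsy": 57, "no_treat": 16, "blank": 3},
    "nft": {"treat": 133, "biopsy": 55, "no_treat": 18, "blank": 1},
}

CORRECTNESS_COUNTS = {
    "text": {"correct": 30, "incorrect": 218, "blank": 7},
    "nomogram": {"correct": 50, "incorrect": 137, "blank": 7},
    "pmp": {"correct": 87, "incorrect": 129, "blank": 2},
    "nft": {"correct": 73, "incorrect": 129, "blank": 5},
}

# Printed odds ratios (vs the text-only arm) with 95% CIs, two decimals.
PUBLISHED_TREAT_ORS = {
    "nomogram": (1.09, 0.75, 1.58),
    "pmp": (1.49, 1.02, 2.16),
    "nft": (1.43, 0.98, 2.08),
}
PUBLISHED_CORRECT_ORS = {
    "nomogram": (2.60, 1.58, 4.29),
    "pmp": (4.98, 3.12, 7.95),
    "nft": (4.09, 2.54, 6.58),
}

# Participant-characteristic margins, pooled across arms. Column sums in the
# published table fall slightly short of 874 for some characteristics
# (item non-response); values are used as sampling weights, not counts.
AGE_BANDS = ("20-29", "30-34", "35-39", "40-44", "45-49", "50-54", "55-59", "60+")
AGE_MARGIN = {
    "20-29": 147, "30-34": 177, "35-39": 173, "40-44": 128,
    "45-49": 82, "50-54": 73, "55-59": 49, "60+": 45,
}
SEX_MARGIN = {"male": 511, "female": 363}
STATUS_MARGIN = {
    "GP": 93, "consultant": 277, "trainee_gp": 35,
    "trainee_junior": 352, "other": 111,
}
POSTGRAD_MARGIN = {"yes": 298, "no": 562}
CONFIDENCE_MARGIN = {1: 70, 2: 225, 3: 365, 4: 187, 5: 15}

# Mean (SD) total baseline-knowledge score, pooled.
KNOWLEDGE_MEAN = 2.2
KNOWLEDGE_SD = 1.3

# Optional-tutorial uptake model: 36.2% overall uptake, odds ratio 1.18 per
# correct quiz answer and 1.22 per self-rated-confidence category.
TUTORIAL_UPTAKE_OVERALL = 0.362
TUTORIAL_OR_PER_CORRECT = 1.18
TUTORIAL_OR_PER_CONFIDENCE = 1.22

# Design power calculation: 200 per arm, 80% power, 5% two-sided significance,
# detectable differences of 11-15% over baseline probabilities 0.2-0.8.
DESIGN_N_PER_ARM = 200
DESIGN_POWER = 0.80
DESIGN_ALPHA = 0.05
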