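"""Diagnostic accuracy measures and Bayesian updating in odds form.

Everything downstream (presentation formats, answer keys, trial outcomes)
is a re-encoding of the arithmetic in this module: likelihood ratios from
sensitivity/specificity, the odds-form update from pre-test to post-test
probability, and predictive values at a stated prevalence.

Probabilities may be supplied either as proportions in ``[0, 1]`` or as
percents in ``(0, 100]``; the unit is always stated explicitly via a
``unit`` argument — it is never guessed from the magnitude of the value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

__all__ = [
    "TestAccuracy",
    "LikelihoodRatios",
    "ProbabilityUpdate",
    "PredictiveValues",
    "DegenerateTestError",
    "likelihood_ratios",
    "posttest_probability",
    "predictive_values",
    "accuracy_from_counts",
    "odds",
    "probability_from_odds",
    "as_proportion",
    "round_half_up_percent",
]

Unit = Literal["proportion", "percent"]


class DegenerateTestError(ValueError):
    """Raised when an accuracy/prevalence combination makes a quantity undefined."""


def as_proportion(value: float, unit: Unit = "proportion") -> float:
    """Convert ``value`` in the given unit to a proportion in ``[0, 1]``."""
    if unit == "proportion":
        return float(value)
    if unit == "percent":
        return float(value) / 100.0
    raise ValueError(f"unknown unit {unit!r}; expected 'proportion' or 'percent'")


def _check_proportion(value: float, name: str) -> float:
    value = float(value)
    if not (0.0 <= value <= 1.0) or math.isnan(value):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
    return value


@dataclass(frozen=True)
class TestAccuracy:
    """Sensitivity/specificity pair defining a binary diagnostic test."""

    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        _check_proportion(self.sensitivity, "sensitivity")
        _check_proportion(self.specificity, "specificity")

    @classmethod
    def from_percent(cls, sensitivity: float, specificity: float) -> "TestAccuracy":
        return cls(sensitivity / 100.0, specificity / 100.0)


@dataclass(frozen=True)
class LikelihoodRatios:
    """Positive and negative likelihood ratios of a test.

    ``lr_positive`` is ``math.inf`` (and ``lr_positive_infinite`` is True)
    for a test with perfect specificity — a positive result is then
    pathognomonic and post-test probability is 1 regardless of the prior.
    """

    lr_positive: float
    lr_negative: float

    def __post_init__(self) -> None:
        if self.lr_positive < 0 or self.lr_negative < 0:
            raise ValueError("likelihood ratios must be non-negative")

    @property
    def lr_positive_infinite(self) -> bool:
        return math.isinf(self.lr_positive)


@dataclass(frozen=True)
class ProbabilityUpdate:
    """One Bayesian update: prior, likelihood ratio applied, posterior."""

    pretest: float
    lr_applied: float
    posttest: float

    @property
    def posttest_percent(self) -> int:
        """Whole-percent view of the posterior, rounded half-up (85.71 -> 86)."""
        return round_half_up_percent(self.posttest)


@dataclass(frozen=True)
class PredictiveValues:
    """PPV and NPV of a test at a stated prevalence."""

    ppv: float
    npv: float
    prevalence: float

    def __post_init__(self) -> None:
        _check_proportion(self.ppv, "ppv")
        _check_proportion(self.npv, "npv")
        _check_proportion(self.prevalence, "prevalence")


def odds(probability: float) -> float:
    """Probability -> odds. Defined on [0, 1); 1 maps to ``inf``."""
    p = _check_proportion(probability, "probability")
    if p == 1.0:
        return math.inf
    return p / (1.0 - p)


def probability_from_odds(o: float) -> float:
    """Odds -> probability; ``inf`` maps to 1."""
    if o < 0:
        raise ValueError(f"odds must be non-negative, got {o!r}")
    if math.isinf(o):
        return 1.0
    return o / (1.0 + o)


def round_half_up_percent(probability: float) -> int:
    """Round a proportion to the nearest whole percent, halves upward."""
    return int(math.floor(probability * 100.0 + 0.5))


def likelihood_ratios(acc: TestAccuracy) -> LikelihoodRatios:
    """LR+ = sens/(1-spec), LR- = (1-sens)/spec.

    Perfect specificity yields an infinite LR+ (flagged, not an error);
    zero specificity makes LR- undefined and raises ``DegenerateTestError``.
    """
    sens, spec = acc.sensitivity, acc.specificity
    if spec == 0.0:
        raise DegenerateTestError(
            "degenerate test: specificity 0 leaves the negative likelihood ratio undefined"
        )
    lr_pos = math.inf if spec == 1.0 else sens / (1.0 - spec)
    lr_neg = (1.0 - sens) / spec
    return LikelihoodRatios(lr_positive=lr_pos, lr_negative=lr_neg)


def posttest_probability(
    pretest: float, lr: float, unit: Unit = "proportion"
) -> ProbabilityUpdate:
    """Apply a likelihood ratio to a prior probability, in odds form.

    posttest = odds(pretest) * lr / (1 + odds(pretest) * lr)
    """
    p = as_proportion(pretest, unit)
    if p <= 0.0 or p >= 1.0:
        raise ValueError("prior already certain: pretest probability must lie strictly in (0, 1)")
    if lr < 0:
        raise ValueError(f"likelihood ratio must be non-negative, got {lr!r}")
    if math.isinf(lr):
        post = 1.0
    else:
        post_odds = odds(p) * lr
        post = probability_from_odds(post_odds)
    return ProbabilityUpdate(pretest=p, lr_applied=lr, posttest=post)


def predictive_values(
    acc: TestAccuracy, prevalence: float, unit: Unit = "proportion"
) -> PredictiveValues:
    """PPV and NPV at a stated prevalence.

    PPV equals the positive-result post-test probability with the
    prevalence as prior; NPV is the complement for a negative result.
    """
    prev = as_proportion(prevalence, unit)
    if prev <= 0.0 or prev >= 1.0:
        raise ValueError("prevalence must lie strictly in (0, 1)")
    sens, spec = acc.sensitivity, acc.specificity
    ppv_num = sens * prev
    ppv_den = ppv_num + (1.0 - spec) * (1.0 - prev)
    npv_num = spec * (1.0 - prev)
    npv_den = npv_num + (1.0 - sens) * prev
    if ppv_den == 0.0 or npv_den == 0.0:
        raise DegenerateTestError(
            "degenerate test: no positive (or negative) results possible at this prevalence"
        )
    return PredictiveValues(ppv=ppv_num / ppv_den, npv=npv_num / npv_den, prevalence=prev)


def accuracy_from_counts(tp: int, fn: int, fp: int, tn: int) -> TestAccuracy:
    """Recover sensitivity/specificity from 2x2 classification counts."""
    for name, v in (("tp", tp), ("fn", fn), ("fp", fp), ("tn", tn)):
        if v < 0:
            raise ValueError(f"{name} must be a non-negative count, got {v!r}")
    if tp + fn == 0:
        raise ValueError("empty disease margin: tp + fn must be positive")
    if fp + tn == 0:
        raise ValueError("empty non-disease margin: fp + tn must be positive")
    return TestAccuracy(sensitivity=tp / (tp + fn), specificity=tn / (fp + tn))
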